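"""Variance-based (Sobol) sensitivity decomposition.

Saltelli-type sampling over the declared parameter ranges (by default
+-50% of each default value) with low-discrepancy Sobol'-sequence points,
first-order indices by the Saltelli-2010 estimator, total-order by the
Jansen estimator, second-order by the Saltelli cross-matrix estimator, and
percentile-bootstrap confidence intervals.  Influence is declared at
ST >= 0.05; an interaction is flagged when ST - S1 >= 0.05 or any pairwise
S2 >= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .parameters import ParameterSpec

__all__ = [
    "SaltelliDesign",
    "SobolResult",
    "saltelli_sample",
    "sobol_indices",
    "bootstrap_ci",
    "flag_influential_sobol",
]

ESTIMATORS = {"S1": "Saltelli-2010", "ST": "Jansen", "S2": "Saltelli cross-matrix"}


@dataclass(frozen=True)
class SaltelliDesign:
    """Evaluation points laid out as blocks A, B, AB_1..AB_k (and BA_1..BA_k
    when second-order indices are requested)."""

    points: np.ndarray          # (n*(2k+2) or n*(k+2), k), physical units
    n: int
    k: int
    second_order: bool
    ranges: np.ndarray          # (k, 2)
    seed: int
    factor_names: tuple[str, ...] = ()

    @property
    def n_rows(self) -> int:
        return self.points.shape[0]

    def blocks(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                             np.ndarray | None]:
        """Split a flat output vector into (f_A, f_B, f_AB, f_BA)."""
        y = np.asarray(y, float)
        if y.shape != (self.n_rows,):
            raise ValueError(f"expected {self.n_rows} outputs, got {y.shape}")
        n, k = self.n, self.k
        f_a = y[:n]
        f_b = y[n:2 * n]
        f_ab = y[2 * n:2 * n + n * k].reshape(k, n).T
        f_ba = None
        if self.second_order:
            f_ba = y[2 * n + n * k:].reshape(k, n).T
        return f_a, f_b, f_ab, f_ba


def saltelli_sample(
    specs: list[ParameterSpec],
    n: int,
    second_order: bool = True,
    seed: int = 0,
    ranges: np.ndarray | None = None,
) -> SaltelliDesign:
    """Saltelli design over scrambled Sobol'-sequence base points.

    ``ranges`` defaults to +-50% of each spec's default value.  ``n`` should
    be a power of two for the balance properties of the sequence (a warning
    is emitted otherwise).
    """
    k = len(specs)
    if k < 2:
        raise ValueError("need at least 2 factors")
    if n & (n - 1):
        warnings.warn("base sample n is not a power of 2; Sobol'-sequence "
                      "balance is degraded", stacklevel=2)
    if ranges is None:
        ranges = np.array([[0.5 * s.default, 1.5 * s.default] for s in specs])
    ranges = np.asarray(ranges, float)
    if np.any(ranges[:, 1] - ranges[:, 0] <= 0):
        bad = [specs[i].code for i in np.flatnonzero(ranges[:, 1] - ranges[:, 0] <= 0)]
        raise ValueError(f"zero-width range for {bad}")

    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        base = sampler.random(n)
    a_unit, b_unit = base[:, :k], base[:, k:]

    low, width = ranges[:, 0], ranges[:, 1] - ranges[:, 0]
    a = low + a_unit * width
    b = low + b_unit * width
    blocks = [a, b]
    for i in range(k):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    if second_order:
        for i in range(k):
            ba = b.copy()
            ba[:, i] = a[:, i]
            blocks.append(ba)
    return SaltelliDesign(points=np.vstack(blocks), n=n, k=k,
                          second_order=second_order, ranges=ranges, seed=seed,
                          factor_names=tuple(s.code for s in specs))


@dataclass(frozen=True)
class SobolResult:
    """First-, second- and total-order indices with partial variances."""

    s1: np.ndarray
    st: np.ndarray
    s2: np.ndarray | None           # (k, k), symmetric, NaN diagonal
    variance: float
    v_i: np.ndarray
    v_ij: np.ndarray | None
    n: int
    factor_names: tuple[str, ...]
    s1_ci: np.ndarray | None = None  # 95% half-widths
    st_ci: np.ndarray | None = None
    estimators: dict = None

    def to_frame(self) -> pd.DataFrame:
        d = {"factor": list(self.factor_names), "S1": self.s1, "ST": self.st}
        if self.s1_ci is not None:
            d["S1_ci95"] = self.s1_ci
            d["ST_ci95"] = self.st_ci
        return pd.DataFrame(d)


def _indices_from_blocks(f_a, f_b, f_ab, f_ba):
    all_f = np.concatenate([f_a, f_b])
    v = float(np.var(all_f, ddof=0))
    if v <= 0.0:
        raise ValueError("zero total output variance: indices undefined")
    k = f_ab.shape[1]
    v_i = np.array([np.mean(f_b * (f_ab[:, i] - f_a)) for i in range(k)])
    s1 = v_i / v
    st = np.array([0.5 * np.mean((f_a - f_ab[:, i]) ** 2) for i in range(k)]) / v
    s2 = v_ij = None
    if f_ba is not None:
        v_ij = np.full((k, k), np.nan)
        s2 = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                vij_closed = np.mean(f_ba[:, i] * f_ab[:, j]) - np.mean(f_a * f_b)
                vij = vij_closed - v_i[i] - v_i[j]
                v_ij[i, j] = v_ij[j, i] = vij
                s2[i, j] = s2[j, i] = vij / v
    return s1, st, s2, v, v_i, v_ij


def _finite_blocks(design: SaltelliDesign, y: np.ndarray,
                   max_dropped: float):
    """Split outputs into blocks, dropping base samples with any non-finite
    output in any block (keeps the estimators' row pairing intact)."""
    f_a, f_b, f_ab, f_ba = design.blocks(y)
    mask = np.isfinite(f_a) & np.isfinite(f_b) \
        & np.all(np.isfinite(f_ab), axis=1)
    if f_ba is not None:
        mask &= np.all(np.isfinite(f_ba), axis=1)
    dropped = design.n - int(mask.sum())
    if dropped > max_dropped * design.n:
        raise ValueError(
            f"{dropped}/{design.n} base samples dropped for non-finite "
            f"outputs (> {max_dropped:.0%} allowed)")
    return (f_a[mask], f_b[mask], f_ab[mask],
            f_ba[mask] if f_ba is not None else None, dropped)


def sobol_indices(design: SaltelliDesign, y: np.ndarray,
                  max_dropped: float = 0.05) -> SobolResult:
    """Estimate indices from outputs evaluated at the design rows.

    Base samples with non-finite outputs (failed model evaluations) are
    dropped consistently across all blocks; more than ``max_dropped`` of
    them is refused.
    """
    f_a, f_b, f_ab, f_ba, _ = _finite_blocks(design, y, max_dropped)
    s1, st, s2, v, v_i, v_ij = _indices_from_blocks(f_a, f_b, f_ab, f_ba)
    return SobolResult(s1=s1, st=st, s2=s2, variance=v, v_i=v_i, v_ij=v_ij,
                       n=design.n, factor_names=design.factor_names,
                       estimators=dict(ESTIMATORS))


def bootstrap_ci(design: SaltelliDesign, y: np.ndarray, level: float = 0.95,
                 reps: int = 200, seed: int = 0) -> SobolResult:
    """Indices plus percentile-bootstrap CI half-widths over resampled base
    rows (the same resample is applied to every block, preserving the
    pairing that the estimators rely on)."""
    if reps < 2:
        raise ValueError("reps must be >= 2")
    result = sobol_indices(design, y)
    f_a, f_b, f_ab, f_ba, _ = _finite_blocks(design, y, max_dropped=0.05)
    rng = np.random.default_rng(seed)
    k = design.k
    n_used = len(f_a)
    s1_bs = np.empty((reps, k))
    st_bs = np.empty((reps, k))
    for b in range(reps):
        idx = rng.integers(0, n_used, size=n_used)
        try:
            s1b, stb, *_ = _indices_from_blocks(
                f_a[idx], f_b[idx], f_ab[idx],
                f_ba[idx] if f_ba is not None else None)
        except ValueError:          # constant resample -> zero-width CI
            s1b = result.s1
            stb = result.st
        s1_bs[b] = s1b
        st_bs[b] = stb
    alpha = 100 * (1 - level) / 2
    s1_ci = 0.5 * (np.percentile(s1_bs, 100 - alpha, axis=0)
                   - np.percentile(s1_bs, alpha, axis=0))
    st_ci = 0.5 * (np.percentile(st_bs, 100 - alpha, axis=0)
                   - np.percentile(st_bs, alpha, axis=0))
    return SobolResult(s1=result.s1, st=result.st, s2=result.s2,
                       variance=result.variance, v_i=result.v_i,
                       v_ij=result.v_ij, n=result.n,
                       factor_names=result.factor_names,
                       s1_ci=s1_ci, st_ci=st_ci, estimators=dict(ESTIMATORS))


@dataclass(frozen=True)
class SobolInfluenceReport:
    influential: list[str]              # ST >= threshold
    interacting: list[str]              # ST - S1 >= threshold or any S2 >= threshold
    suspicious_negative: list[str]      # estimates below -threshold (MC noise flag)
    threshold: float
    pairwise: pd.DataFrame | None       # S2 matrix for chord-style plots
    table: pd.DataFrame


def flag_influential_sobol(result: SobolResult,
                           threshold: float = 0.05) -> SobolInfluenceReport:
    """Influence/interaction flags at the given total-order threshold."""
    names = list(result.factor_names)
    influential = [n for n, st in zip(names, result.st) if st >= threshold]
    interacting = set()
    for i, n in enumerate(names):
        if result.st[i] - result.s1[i] >= threshold:
            interacting.add(n)
        if result.s2 is not None:
            row = result.s2[i]
            if np.any(row[np.isfinite(row)] >= threshold):
                interacting.add(n)
    suspicious = [n for n, v in zip(names, np.minimum(result.s1, result.st))
                  if v < -threshold]
    pairwise = None
    if result.s2 is not None:
        pairwise = pd.DataFrame(result.s2, index=names, columns=names)
    table = result.to_frame()
    table["influential"] = [n in influential for n in names]
    table["interacting"] = [n in interacting for n in names]
    return SobolInfluenceReport(influential=influential,
                                interacting=sorted(interacting),
                                suspicious_negative=suspicious,
                                threshold=threshold, pairwise=pairwise,
                                table=table)
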