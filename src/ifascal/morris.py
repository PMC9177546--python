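"""Method-of-Morris elementary-effects screening.

One-at-a-time trajectories on a p-level grid in the unit hypercube give r
elementary effects (EEs) per factor at a cost of r(k+1) model evaluations.
Per factor the screen reports the EE mean mu, absolute mean mu* (immune to
sign cancellation in non-monotonic responses), standard deviation sigma
(interaction/non-linearity signal), the rank score B = sqrt(mu*^2 + sigma^2),
the sign of mu as a polarity, and a min-max normalized mu* thresholded at
0.1 to split influential from negligible factors.

EEs are computed in unit-hypercube coordinates, so mu* is range-scaled and
comparable across factors with different physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MorrisDesign",
    "MorrisResult",
    "sample_morris_design",
    "elementary_effects",
    "morris_summary",
    "normalize_scores",
    "screen_influential",
]

CATEGORY_NEGLIGIBLE = "negligible"
CATEGORY_LINEAR = "linear-additive"
CATEGORY_NONLINEAR = "nonlinear/interacting"


@dataclass(frozen=True)
class MorrisDesign:
    """r trajectories of k+1 points each on a p-level unit-hypercube grid."""

    unit_points: np.ndarray        # (r*(k+1), k) in [0, 1]
    physical_points: np.ndarray    # (r*(k+1), k) mapped to [low, high]
    moved_factor: np.ndarray       # (r*(k+1),), -1 for trajectory base rows
    step_sign: np.ndarray          # (r*(k+1),), +-1 where a factor moved
    k: int
    r: int
    p: int
    delta: float
    ranges: np.ndarray             # (k, 2)
    seed: int

    @property
    def n_rows(self) -> int:
        return self.unit_points.shape[0]


def sample_morris_design(
    k: int,
    r: int,
    ranges: np.ndarray | list[tuple[float, float]],
    p: int = 4,
    seed: int = 0,
) -> MorrisDesign:
    """Random Morris trajectories (plain, unoptimized).

    Each trajectory starts at a random grid point with coordinates in
    {0, 1/(p-1), ..., 1 - delta} or {delta, ..., 1} as orientation allows,
    and moves each factor exactly once, in random order, by +-delta with
    delta = p / (2(p-1)).
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if p % 2 != 0:
        raise ValueError("p must be even for the standard delta = p/(2(p-1))")
    if k < 1 or r < 1:
        raise ValueError("k and r must be >= 1")
    ranges = np.asarray(ranges, float)
    if ranges.shape != (k, 2):
        raise ValueError(f"ranges must have shape ({k}, 2)")
    if np.any(ranges[:, 1] <= ranges[:, 0]):
        raise ValueError("empty parameter range")

    delta = p / (2.0 * (p - 1.0))
    rng = np.random.default_rng(seed)
    grid = np.arange(p) / (p - 1.0)

    rows_unit = np.empty((r * (k + 1), k))
    moved = np.full(r * (k + 1), -1, dtype=int)
    signs = np.zeros(r * (k + 1))
    row = 0
    for _ in range(r):
        direction = rng.choice([-1.0, 1.0], size=k)
        base = np.empty(k)
        for j in range(k):
            # start levels that keep base + direction*delta inside [0, 1]
            ok = grid[(grid + direction[j] * delta >= -1e-12)
                      & (grid + direction[j] * delta <= 1.0 + 1e-12)]
            base[j] = rng.choice(ok)
        order = rng.permutation(k)
        x = base.copy()
        rows_unit[row] = x
        row += 1
        for j in order:
            x = x.copy()
            x[j] = min(max(x[j] + direction[j] * delta, 0.0), 1.0)
            rows_unit[row] = x
            moved[row] = j
            signs[row] = direction[j]
            row += 1

    low, high = ranges[:, 0], ranges[:, 1]
    rows_phys = low + rows_unit * (high - low)
    return MorrisDesign(unit_points=rows_unit, physical_points=rows_phys,
                        moved_factor=moved, step_sign=signs, k=k, r=r, p=p,
                        delta=delta, ranges=ranges, seed=seed)


def elementary_effects(design: MorrisDesign, y: np.ndarray) -> np.ndarray:
    """(r, k) elementary effects from outputs evaluated at the design rows.

    Rows with non-finite outputs invalidate their whole trajectory (the
    count of dropped trajectories is reported on the returned array as
    ``.dropped``); more than 20% dropped is refused.
    """
    y = np.asarray(y, float)
    if y.shape != (design.n_rows,):
        raise ValueError(
            f"need one output per design row ({design.n_rows}), got {y.shape}")
    k, r, delta = design.k, design.r, design.delta
    ee = np.full((r, k), np.nan)
    dropped = 0
    for t in range(r):
        block = slice(t * (k + 1), (t + 1) * (k + 1))
        yb = y[block]
        if not np.all(np.isfinite(yb)):
            dropped += 1
            continue
        for step in range(1, k + 1):
            i = t * (k + 1) + step
            j = design.moved_factor[i]
            ee[t, j] = (y[i] - y[i - 1]) / (design.step_sign[i] * delta)
    if dropped > 0.2 * r:
        raise ValueError(
            f"{dropped}/{r} trajectories dropped for non-finite outputs")
    ee = ee[np.all(np.isfinite(ee), axis=1)]
    return ee


@dataclass(frozen=True)
class MorrisResult:
    """Per-factor screening summary."""

    mu: np.ndarray
    mu_star: np.ndarray
    sigma: np.ndarray
    rank_score: np.ndarray          # B = sqrt(mu*^2 + sigma^2)
    polarity: list[str]             # "+", "-" or "+-" for mu == 0
    normalized_mu_star: np.ndarray
    normalized_rank_score: np.ndarray
    category: list[str]
    rank: np.ndarray                # 1 = most influential by B
    r: int
    factor_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = self.factor_names or [f"x{i}" for i in range(len(self.mu))]
        return pd.DataFrame({
            "factor": names, "mu": self.mu, "mu_star": self.mu_star,
            "sigma": self.sigma, "rank_score": self.rank_score,
            "normalized_mu_star": self.normalized_mu_star,
            "normalized_rank_score": self.normalized_rank_score,
            "polarity": self.polarity, "category": self.category,
            "rank": self.rank,
        })


def morris_summary(ee: np.ndarray, factor_names: list[str] | None = None,
                   category_threshold: float = 0.1) -> MorrisResult:
    """Summarize an (r, k) EE sample per factor.

    sigma is the sample standard deviation (divisor r-1).  Categories use the
    normalized scores: negligible (low mu*, low sigma), linear-additive
    (high mu*, low sigma), nonlinear/interacting (high sigma).
    """
    ee = np.asarray(ee, float)
    r, k = ee.shape
    if r < 2:
        raise ValueError("need at least 2 trajectories for sigma")
    mu = ee.mean(axis=0)
    mu_star = np.abs(ee).mean(axis=0)
    sigma = ee.std(axis=0, ddof=1)
    b = np.sqrt(mu_star ** 2 + sigma ** 2)
    polarity = ["+" if m > 0 else "-" if m < 0 else "+-" for m in mu]

    def _norm(v: np.ndarray) -> np.ndarray:
        # degenerate spread (e.g. a single factor): every value is the max
        if np.ptp(v) == 0:
            return np.where(v > 0, 1.0, 0.0)
        return normalize_scores(v)

    norm_mu_star = _norm(mu_star)
    norm_b = _norm(b)
    norm_sigma = _norm(sigma) if np.ptp(sigma) > 0 else np.zeros(k)
    category = []
    for zm, zs in zip(norm_mu_star, norm_sigma):
        if zs >= category_threshold:
            category.append(CATEGORY_NONLINEAR)
        elif zm >= category_threshold:
            category.append(CATEGORY_LINEAR)
        else:
            category.append(CATEGORY_NEGLIGIBLE)
    # rank by B; ties broken by mu*, then by registry order (determinism)
    order = np.lexsort((np.arange(k), -mu_star, -b))
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(1, k + 1)
    return MorrisResult(mu=mu, mu_star=mu_star, sigma=sigma, rank_score=b,
                        polarity=polarity, normalized_mu_star=norm_mu_star,
                        normalized_rank_score=norm_b, category=category,
                        rank=rank, r=r, factor_names=list(factor_names or []))


def normalize_scores(values: np.ndarray) -> np.ndarray:
    """Min-max normalization onto [0, 1]."""
    v = np.asarray(values, float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("normalization undefined: all values equal")
    return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class ScreeningReport:
    influential: list[str]          # normalized mu* >= threshold
    forwarded: list[str]            # top_k by rank score B, for the variance stage
    threshold: float
    top_k: int
    table: pd.DataFrame


def screen_influential(result: MorrisResult, threshold: float = 0.1,
                       top_k: int = 10) -> ScreeningReport:
    """Influential set {normalized mu* >= threshold} (inclusive) and the
    top_k factors by rank score B forwarded to the variance-based stage."""
    names = result.factor_names or [f"x{i}" for i in range(len(result.mu))]
    names = list(names)
    influential = [n for n, z in zip(names, result.normalized_mu_star)
                   if z >= threshold]
    order = np.argsort(result.rank)
    forwarded = [names[i] for i in order[:top_k]]
    table = result.to_frame()
    table["selected"] = table["factor"].isin(influential)
    table["forwarded"] = table["factor"].isin(forwarded)
    return ScreeningReport(influential=influential, forwarded=forwarded,
                           threshold=threshold, top_k=top_k, table=table)
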