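"""Monte-Carlo uncertainty propagation with GUM-style reporting.

Each influential parameter is assigned a probability density (uniform over
its literature range unless better information exists; normal and triangular
shapes are supported), pseudo-random samples are propagated through the
model, and each output's distribution is summarized by its mean, combined
standard uncertainty U_c (the sample standard deviation) and expanded
uncertainty U_e = k * U_c with coverage factor k = 1.96 for a 95% coverage
interval.

Standard uncertainties of the input densities follow the half-width rules:
uniform a/sqrt(3), triangular a/sqrt(6), normal from samples with divisor
n-1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .parameters import ParameterRegistry, ParameterVector
from .model import SteadyStateError

__all__ = [
    "PdfSpec",
    "UncertaintyResult",
    "std_from_pdf",
    "sample_pdf",
    "mc_propagate",
    "expanded_uncertainty",
    "load_pdf_specs_csv",
    "COVERAGE_FACTOR_95",
]

COVERAGE_FACTOR_95 = 1.96


@dataclass(frozen=True)
class PdfSpec:
    """Distribution assigned to one parameter for the uncertainty stage."""

    code: str
    shape: str                       # uniform | normal | triangular
    center: float
    half_width: float | None = None  # a, for uniform/triangular
    sigma: float | None = None       # for normal
    samples: tuple[float, ...] | None = None   # alternative normal source
    source: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("uniform", "normal", "triangular"):
            raise ValueError(f"{self.code}: unknown pdf shape {self.shape!r}")
        if self.shape in ("uniform", "triangular"):
            if self.half_width is None or self.half_width <= 0:
                raise ValueError(f"{self.code}: half-width a must be > 0")
        else:
            if self.sigma is None and (self.samples is None or len(self.samples) < 2):
                raise ValueError(
                    f"{self.code}: normal pdf needs sigma or >=2 samples")

    @classmethod
    def uniform_range(cls, code: str, low: float, high: float,
                      source: str = "") -> "PdfSpec":
        return cls(code=code, shape="uniform", center=0.5 * (low + high),
                   half_width=0.5 * (high - low), source=source)


def std_from_pdf(spec: PdfSpec) -> float:
    """Standard uncertainty of one input density.

    uniform: a/sqrt(3); triangular: a/sqrt(6); normal: given sigma or the
    sample standard deviation (divisor n-1).
    """
    if spec.shape == "uniform":
        return spec.half_width / np.sqrt(3.0)
    if spec.shape == "triangular":
        return spec.half_width / np.sqrt(6.0)
    if spec.sigma is not None:
        if spec.sigma <= 0:
            raise ValueError(f"{spec.code}: sigma must be > 0")
        return float(spec.sigma)
    return float(np.std(spec.samples, ddof=1))


def sample_pdf(spec: PdfSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.shape == "uniform":
        return rng.uniform(spec.center - spec.half_width,
                           spec.center + spec.half_width, size=n)
    if spec.shape == "triangular":
        return rng.triangular(spec.center - spec.half_width, spec.center,
                              spec.center + spec.half_width, size=n)
    return rng.normal(spec.center, std_from_pdf(spec), size=n)


def expanded_uncertainty(u_c: float, k: float = COVERAGE_FACTOR_95) -> float:
    """U_e = k * U_c (exact identity)."""
    if u_c < 0:
        raise ValueError("combined standard uncertainty must be >= 0")
    return k * u_c


@dataclass(frozen=True)
class UncertaintyResult:
    """Per-output Monte-Carlo summary."""

    samples: Mapping[str, np.ndarray]
    mean: Mapping[str, float]
    u_combined: Mapping[str, float]
    u_expanded: Mapping[str, float]
    coverage_factor: float
    n: int
    seed: int
    input_std: Mapping[str, float] = field(default_factory=dict)
    n_failures: int = 0

    def histogram(self, output: str, bins: int = 50):
        """(counts, edges) histogram export for distribution plots."""
        return np.histogram(self.samples[output], bins=bins)


def mc_propagate(
    evaluator: Callable[[ParameterVector], np.ndarray],
    specs: Sequence[PdfSpec],
    registry: ParameterRegistry,
    base: ParameterVector | None = None,
    n: int = 100_000,
    seed: int = 0,
    coverage_factor: float = COVERAGE_FACTOR_95,
    output_names: Sequence[str] = ("BOD", "TN", "TSS"),
    max_failure_rate: float = 0.01,
) -> UncertaintyResult:
    """Propagate the input densities through the model.

    Parameters without a density stay pinned at ``base`` (the calibrated
    vector).  Sampled values are clipped to the registry bounds so the
    parameter-vector invariants hold.  A solver failure rate above
    ``max_failure_rate`` aborts with diagnostics.
    """
    if not specs:
        raise ValueError("no pdf specs given")
    base = base if base is not None else registry.defaults()
    rng = np.random.default_rng(seed)
    draws = {s.code: sample_pdf(s, n, rng) for s in specs}
    for code, vals in draws.items():
        spec = registry[code]
        np.clip(vals, spec.low, spec.high, out=vals)

    out = np.empty((n, len(output_names)))
    failures = 0
    codes = [s.code for s in specs]
    for i in range(n):
        params = base.with_values({c: draws[c][i] for c in codes})
        try:
            out[i] = evaluator(params)
        except SteadyStateError:
            out[i] = np.nan
            failures += 1
            if failures > max_failure_rate * n:
                raise RuntimeError(
                    f"evaluator failed on {failures}/{i + 1} samples "
                    f"(> {max_failure_rate:.0%} allowed)")
    ok = np.all(np.isfinite(out), axis=1)
    out = out[ok]

    samples = {name: out[:, j].copy() for j, name in enumerate(output_names)}
    mean = {k: float(np.mean(v)) for k, v in samples.items()}
    u_c = {k: float(np.std(v, ddof=1)) for k, v in samples.items()}
    u_e = {k: expanded_uncertainty(v, coverage_factor) for k, v in u_c.items()}
    return UncertaintyResult(
        samples=samples, mean=mean, u_combined=u_c, u_expanded=u_e,
        coverage_factor=coverage_factor, n=n, seed=seed,
        input_std={s.code: std_from_pdf(s) for s in specs},
        n_failures=failures)


def load_pdf_specs_csv(path: str | Path) -> list[PdfSpec]:
    """PDF spec file: CSV with columns code, shape, low, high, center, source."""
    specs = []
    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.DictReader(fh), start=2):
            try:
                low, high = float(row["low"]), float(row["high"])
                center = float(row["center"]) if row.get("center") else 0.5 * (low + high)
                shape = row["shape"] or "uniform"
                specs.append(PdfSpec(
                    code=row["code"], shape=shape, center=center,
                    half_width=0.5 * (high - low) if shape != "normal" else None,
                    sigma=0.5 * (high - low) if shape == "normal" else None,
                    source=row.get("source", "")))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed pdf row at line {ln}: {exc}") from exc
    return specs
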