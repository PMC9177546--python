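"""Kinetic and stoichiometric parameter registry.

Every tunable biokinetic quantity of the reduced IFAS model is declared as a
:class:`ParameterSpec` carrying a short code (``X52`` style, following the
vendor convention of numbering the kinetic/stoichiometric library), a default
value, a screening range and a probability-density shape used by the
uncertainty stage.  A :class:`ParameterVector` is a complete assignment of
values to every registry entry and is the single currency the sensitivity,
calibration and uncertainty stages trade in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ParameterSpec",
    "ParameterRegistry",
    "ParameterVector",
    "default_registry",
    "load_registry_csv",
    "write_registry_csv",
]

_PDF_SHAPES = ("uniform", "normal", "triangular")
_KINDS = ("kinetic", "stoichiometric", "padding")


@dataclass(frozen=True)
class ParameterSpec:
    """One registry entry.

    ``low``/``high`` bound both the screening design and the calibration box;
    ``pdf`` is the distribution shape assigned when the parameter is carried
    into the uncertainty stage (uniform unless literature says otherwise).
    """

    code: str
    name: str
    units: str
    kind: str
    default: float
    low: float
    high: float
    pdf: str = "uniform"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"{self.code}: kind must be one of {_KINDS}")
        if self.pdf not in _PDF_SHAPES:
            raise ValueError(f"{self.code}: pdf must be one of {_PDF_SHAPES}")
        if not (self.low <= self.default <= self.high):
            raise ValueError(
                f"{self.code}: default {self.default} outside [{self.low}, {self.high}]"
            )
        if self.pdf in ("uniform", "triangular") and self.half_width <= 0:
            raise ValueError(f"{self.code}: zero-width range for {self.pdf} pdf")

    @property
    def half_width(self) -> float:
        """Half-width a = (high - low)/2 of the declared range."""
        return 0.5 * (self.high - self.low)

    @property
    def center(self) -> float:
        return 0.5 * (self.high + self.low)


class ParameterRegistry:
    """Ordered, code-unique collection of :class:`ParameterSpec`."""

    def __init__(self, specs: Iterable[ParameterSpec]):
        self._specs = list(specs)
        codes = [s.code for s in self._specs]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate parameter codes: {dupes}")
        self._by_code = {s.code: s for s in self._specs}

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> ParameterSpec:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown parameter code {code!r}") from None

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self._specs]

    def subset(self, codes: Iterable[str]) -> "ParameterRegistry":
        return ParameterRegistry(self[c] for c in codes)

    def defaults(self) -> "ParameterVector":
        return ParameterVector(self, {s.code: s.default for s in self._specs})

    def bounds(self) -> list[tuple[float, float]]:
        return [(s.low, s.high) for s in self._specs]


class ParameterVector(Mapping[str, float]):
    """A complete point in parameter space, validated against its registry."""

    def __init__(self, registry: ParameterRegistry, values: Mapping[str, float]):
        missing = set(registry.codes) - set(values)
        if missing:
            raise ValueError(f"incomplete parameter vector; missing {sorted(missing)}")
        extra = set(values) - set(registry.codes)
        if extra:
            raise ValueError(f"unknown parameter codes {sorted(extra)}")
        for code, v in values.items():
            spec = registry[code]
            if not (spec.low - 1e-12 <= v <= spec.high + 1e-12):
                raise ValueError(
                    f"{code}={v} outside bounds [{spec.low}, {spec.high}]"
                )
        self.registry = registry
        self._values = {c: float(values[c]) for c in registry.codes}

    def __getitem__(self, code: str) -> float:
        return self._values[code]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def replace(self, **updates: float) -> "ParameterVector":
        vals = dict(self._values)
        vals.update(updates)
        return ParameterVector(self.registry, vals)

    def with_values(self, updates: Mapping[str, float]) -> "ParameterVector":
        vals = dict(self._values)
        vals.update(updates)
        return ParameterVector(self.registry, vals)


def _pm50(default: float) -> tuple[float, float]:
    return 0.5 * default, 1.5 * default


def _spec(code, name, units, kind, default, low=None, high=None, pdf="uniform"):
    if low is None or high is None:
        low, high = _pm50(default)
    return ParameterSpec(code, name, units, kind, default, low, high, pdf)


# Real inputs of the reduced model.  The seven headline parameters keep their
# vendor codes; defaults for the headline set follow the published registry
# (yields 0.666 / 0.533, decay 0.62 1/d, nitrite denitrification factor 0.48).
_MODEL_SPECS = [
    _spec("X52", "Aerobic heterotrophic yield on soluble substrate", "mgCOD/mgCOD",
          "stoichiometric", 0.666),
    _spec("X53", "Anoxic heterotrophic yield on soluble substrate", "mgCOD/mgCOD",
          "stoichiometric", 0.533),
    # bounds widened beyond +-50% to cover the low end of the literature range
    _spec("X16", "Aerobic heterotrophic decay rate", "1/d", "kinetic", 0.62,
          low=0.23, high=0.93),
    _spec("X12", "Reduction factor for denitrification on nitrite-N", "-", "kinetic", 0.48),
    _spec("X15", "Oxygen inhibition coefficient for denitrification", "mgO2/L",
          "kinetic", 0.2),
    _spec("X61", "Unbiodegradable fraction from cell decay", "-", "stoichiometric", 0.08),
    _spec("X27", "Maximum growth rate for nitrite oxidizer", "1/d", "kinetic", 0.7),
    _spec("X1", "Maximum heterotrophic growth rate", "1/d", "kinetic", 4.0),
    _spec("X2", "Half-saturation for readily biodegradable substrate", "mgCOD/L",
          "kinetic", 10.0),
    _spec("X3", "Oxygen half-saturation for heterotrophs", "mgO2/L", "kinetic", 0.2),
    _spec("X11", "Reduction factor for denitrification on nitrate-N", "-", "kinetic", 0.48),
    _spec("X13", "Nitrate half-saturation for denitrification", "mgN/L", "kinetic", 0.5),
    _spec("X14", "Nitrite half-saturation for denitrification", "mgN/L", "kinetic", 0.5),
    _spec("X21", "Maximum growth rate for ammonia oxidizer", "1/d", "kinetic", 0.9),
    _spec("X22", "Ammonia half-saturation for ammonia oxidizer", "mgN/L", "kinetic", 0.7),
    _spec("X23", "Oxygen half-saturation for nitrifiers", "mgO2/L", "kinetic", 0.4),
    _spec("X24", "Ammonia oxidizer yield", "mgCOD/mgN", "stoichiometric", 0.18),
    _spec("X26", "Nitrite oxidizer yield", "mgCOD/mgN", "stoichiometric", 0.06),
    _spec("X28", "Nitrite half-saturation for nitrite oxidizer", "mgN/L", "kinetic", 0.5),
    _spec("X17", "Ammonia oxidizer decay rate", "1/d", "kinetic", 0.15),
    _spec("X18", "Nitrite oxidizer decay rate", "1/d", "kinetic", 0.15),
    _spec("X31", "Maximum specific hydrolysis rate", "mgCOD/mgCOD/d", "kinetic", 3.0),
    _spec("X32", "Hydrolysis half-saturation", "mgCOD/mgCOD", "kinetic", 0.1),
    _spec("X33", "Ammonification rate", "m3/gCOD/d", "kinetic", 0.08),
    _spec("X41", "Nitrogen content of biomass", "mgN/mgCOD", "stoichiometric", 0.086),
    _spec("X42", "Nitrogen content of endogenous products", "mgN/mgCOD",
          "stoichiometric", 0.06),
    _spec("X43", "Biofilm attachment rate", "1/d", "kinetic", 0.5),
    _spec("X44", "Biofilm detachment rate", "1/d", "kinetic", 0.05),
]

#: Codes consumed by the reduced process model.
MODEL_CODES = tuple(s.code for s in _MODEL_SPECS)

#: Headline parameters carried through calibration and uncertainty.
HEADLINE_CODES = ("X52", "X53", "X16", "X12")


def default_registry(n_total: int = 68) -> ParameterRegistry:
    """Bundled registry: 28 active inputs of the reduced model padded with
    inert placeholder entries up to ``n_total`` (default 68, the size of the
    full vendor library screened in the source study, whose complete listing
    is not public).  Padding entries carry ``kind='padding'`` and have no
    effect on the model, so screening ranks them at the bottom by
    construction.
    """
    specs = list(_MODEL_SPECS)
    if n_total < len(specs):
        raise ValueError(f"n_total must be >= {len(specs)}")
    used = {int(s.code[1:]) for s in specs}
    i = 1
    while len(specs) < n_total:
        while i in used:
            i += 1
        used.add(i)
        specs.append(
            _spec(f"X{i}", f"Registry padding parameter {i} (inert placeholder)",
                  "-", "padding", 1.0)
        )
    return ParameterRegistry(specs)


_CSV_FIELDS = ["code", "name", "units", "kind", "default", "low", "high", "pdf"]


def write_registry_csv(registry: ParameterRegistry, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for s in registry:
            w.writerow({
                "code": s.code, "name": s.name, "units": s.units, "kind": s.kind,
                "default": repr(s.default), "low": repr(s.low), "high": repr(s.high),
                "pdf": s.pdf,
            })


def load_registry_csv(path: str | Path) -> ParameterRegistry:
    specs = []
    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.DictReader(fh), start=2):
            try:
                specs.append(ParameterSpec(
                    code=row["code"], name=row["name"], units=row["units"],
                    kind=row["kind"], default=float(row["default"]),
                    low=float(row["low"]), high=float(row["high"]),
                    pdf=row["pdf"] or "uniform",
                ))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed registry row at line {ln}: {exc}") from exc
    return ParameterRegistry(specs)
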