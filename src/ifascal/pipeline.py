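"""End-to-end calibration workflow.

Stage order: Morris screen of the full registry (per output) -> top-10 per
output forwarded to the Sobol stage -> union of Sobol-influential parameters
(total-order index >= 0.05) calibrated jointly by Nelder-Mead against the
observed effluent -> Monte-Carlo uncertainty of the influential parameters
at the calibrated point -> re-run under the alternative oxygen regimes for
validation.  Every stage consumes the single evaluator contract
``parameter vector -> (BOD, TN, TSS)`` and derives its randomness from one
master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    CompositeMeasurements,
    EffluentEvaluator,
    FractionationSettings,
    PlantConfig,
    fractionate_influent,
)
from .morris import (
    MorrisResult,
    ScreeningReport,
    elementary_effects,
    morris_summary,
    sample_morris_design,
    screen_influential,
)
from .neldermead import CalibrationResult, calibrate
from .parameters import ParameterRegistry, load_registry_csv
from .sobol import (
    SobolInfluenceReport,
    SobolResult,
    bootstrap_ci,
    flag_influential_sobol,
    saltelli_sample,
)
from .synthetic import SyntheticObservation, generate_synthetic_observation
from .uncertainty import (
    PdfSpec,
    UncertaintyResult,
    load_pdf_specs_csv,
    mc_propagate,
)

__all__ = ["RunConfig", "FixtureSet", "PipelineReport", "load_fixtures",
           "build_evaluator", "run_pipeline", "validate_regimes",
           "export_reports", "REGIMES", "OUTPUTS"]

log = logging.getLogger("ifascal")

REGIMES = ("calibration", "do05", "do45")
OUTPUTS = ("BOD", "TN", "TSS")
_DATA = resources.files("ifascal") / "data"


@dataclass
class RunConfig:
    """Paths and stage settings for one pipeline run."""

    characterization: dict = field(default_factory=lambda: {
        r: str(_DATA / f"characterization_{r}.csv") for r in REGIMES})
    plant: dict = field(default_factory=lambda: {
        r: str(_DATA / f"plant_{r}.yaml") for r in REGIMES})
    registry_path: str = str(_DATA / "registry.csv")
    pdf_specs_path: str = str(_DATA / "pdf_specs.csv")
    # Morris stage
    morris_r: int = 100
    morris_p: int = 4
    morris_range_rel: float = 0.5        # +-50% of default
    morris_threshold: float = 0.1
    top_k: int = 10
    # Sobol stage
    sobol_n: int = 1024
    sobol_second_order: bool = True
    sobol_threshold: float = 0.05
    bootstrap_reps: int = 200
    # calibration stage
    nm_tol_x: float = 1e-8
    nm_max_iter: int = 2000
    # uncertainty stage
    mc_n: int = 10_000
    # synthetic observation
    use_synthetic_observation: bool = True
    noise_rel: float = 0.02
    # misc
    seed: int = 1
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("morris_threshold", "sobol_threshold"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        for r in REGIMES:
            for path in (self.characterization[r], self.plant[r]):
                if not Path(path).exists():
                    raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class FixtureSet:
    influent: Mapping[str, CompositeMeasurements]
    effluent: Mapping[str, CompositeMeasurements]
    plant: Mapping[str, PlantConfig]
    registry: ParameterRegistry


def _read_characterization(path: str | Path) -> dict[str, CompositeMeasurements]:
    df = pd.read_csv(path)
    required = {"determinand", "stream", "value", "spread", "units"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    out = {}
    for stream, grp in df.groupby("stream"):
        vals, spreads = {}, {}
        for i, row in grp.iterrows():
            name = str(row["determinand"]).strip().lower()
            try:
                vals[name] = float(row["value"])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed row {i + 2} ({row['determinand']})") from exc
            if pd.notna(row["spread"]):
                spreads[name] = float(row["spread"])
        try:
            out[stream] = CompositeMeasurements(
                cod=vals["cod"], bod=vals["bod"], tss=vals["tss"],
                nh3=vals["nh3"], tkn=vals["tkn"], tn=vals["tn"],
                spreads=spreads)
        except KeyError as exc:
            raise ValueError(f"{path}: missing determinand {exc} "
                             f"for stream {stream!r}") from exc
    return out


def load_fixtures(config: RunConfig) -> FixtureSet:
    """Characterization tables, plant configs per regime, and the registry."""
    influent, effluent, plant = {}, {}, {}
    for regime in REGIMES:
        streams = _read_characterization(config.characterization[regime])
        influent[regime] = streams["influent"]
        effluent[regime] = streams["effluent"]
        with open(config.plant[regime]) as fh:
            raw = yaml.safe_load(fh)
        plant[regime] = PlantConfig(**{k: v for k, v in raw.items()})
    registry = load_registry_csv(config.registry_path)
    return FixtureSet(influent=influent, effluent=effluent, plant=plant,
                      registry=registry)


def build_evaluator(fixtures: FixtureSet, regime: str = "calibration",
                    fractions: FractionationSettings = FractionationSettings(),
                    ) -> EffluentEvaluator:
    state, _ = fractionate_influent(fixtures.influent[regime], fractions,
                                    fixtures.plant[regime])
    return EffluentEvaluator(state, fixtures.plant[regime], fixtures.registry)


@dataclass
class PipelineReport:
    config: RunConfig
    fixtures: FixtureSet
    observation: SyntheticObservation | None
    targets: dict[str, float]
    morris: dict[str, MorrisResult]
    screening: dict[str, ScreeningReport]
    sobol: dict[str, SobolResult]
    sobol_flags: dict[str, SobolInfluenceReport]
    influential: list[str]                   # union across outputs
    calibration: CalibrationResult
    deviations: dict[str, float]             # |model - observed| per output
    uncertainty: UncertaintyResult
    validation: pd.DataFrame
    evaluation_counts: dict[str, int]
    seeds: dict[str, int]


def _stage_seed(master: int, offset: int) -> int:
    return (master * 1009 + offset) % (2 ** 31 - 1)


def run_pipeline(config: RunConfig) -> PipelineReport:
    fixtures = load_fixtures(config)
    registry = fixtures.registry
    evaluator = build_evaluator(fixtures)
    counts: dict[str, int] = {}
    seeds = {name: _stage_seed(config.seed, i) for i, name in enumerate(
        ("observation", "morris", "sobol", "bootstrap", "mc"))}

    # observed effluent: synthetic (known truth) or the bundled pilot values
    observation = None
    if config.use_synthetic_observation:
        observation = generate_synthetic_observation(
            evaluator, registry, noise_rel=config.noise_rel,
            seed=seeds["observation"])
        targets = observation.targets
    else:
        eff = fixtures.effluent["calibration"]
        targets = {"BOD": eff.bod, "TN": eff.tn, "TSS": eff.tss}
    log.info("calibration targets: %s", targets)

    # ---- Morris screen over the full registry --------------------------------
    codes = registry.codes
    k = len(codes)
    ranges = np.array([
        [s.default - config.morris_range_rel * abs(s.default),
         s.default + config.morris_range_rel * abs(s.default)]
        for s in registry])
    design = sample_morris_design(k=k, r=config.morris_r, ranges=ranges,
                                  p=config.morris_p, seed=seeds["morris"])
    n0 = evaluator.n_evaluations
    y = evaluator.evaluate_matrix(design.physical_points, codes)
    counts["morris"] = evaluator.n_evaluations - n0
    log.info("morris: %d evaluations (r(k+1) = %d)", counts["morris"],
             config.morris_r * (k + 1))

    morris_results, screening = {}, {}
    for j, out in enumerate(OUTPUTS):
        ee = elementary_effects(design, y[:, j])
        res = morris_summary(ee, factor_names=codes)
        morris_results[out] = res
        screening[out] = screen_influential(res, config.morris_threshold,
                                            config.top_k)
        log.info("morris %s: influential %s", out, screening[out].influential)

    # ---- Sobol decomposition on the forwarded subsets ------------------------
    sobol_results, sobol_flags = {}, {}
    for j, out in enumerate(OUTPUTS):
        sub = screening[out].forwarded
        specs = [registry[c] for c in sub]
        des = saltelli_sample(specs, n=config.sobol_n,
                              second_order=config.sobol_second_order,
                              seed=seeds["sobol"])
        n0 = evaluator.n_evaluations
        ys = evaluator.evaluate_matrix(des.points, sub)
        counts[f"sobol_{out}"] = evaluator.n_evaluations - n0
        log.info("sobol %s: %d evaluations (n(2k+2) = %d)", out,
                 counts[f"sobol_{out}"],
                 config.sobol_n * (2 * len(sub) + 2))
        res = bootstrap_ci(des, ys[:, j], reps=config.bootstrap_reps,
                           seed=seeds["bootstrap"])
        sobol_results[out] = res
        sobol_flags[out] = flag_influential_sobol(res, config.sobol_threshold)
        log.info("sobol %s: influential %s", out, sobol_flags[out].influential)

    influential: list[str] = []
    for out in OUTPUTS:                      # registry order, no duplicates
        for c in sobol_flags[out].influential:
            if c not in influential:
                influential.append(c)
    influential.sort(key=codes.index)
    if not influential:
        raise RuntimeError("no parameter reached the Sobol influence threshold")

    # ---- joint Nelder-Mead estimation ----------------------------------------
    eff_spreads = fixtures.effluent["calibration"].spreads
    sigmas = {out: eff_spreads[out.lower()] for out in OUTPUTS
              if out.lower() in eff_spreads}
    n0 = evaluator.n_evaluations
    calib = calibrate(evaluator, targets, influential, registry,
                      sigmas=sigmas or None, tol_x=config.nm_tol_x,
                      max_iter=config.nm_max_iter)
    counts["calibration"] = evaluator.n_evaluations - n0
    log.info("calibration: %d evaluations, objective %.3e (%s)",
             counts["calibration"], calib.fun, calib.termination)
    calibrated = registry.defaults().with_values(calib.estimated)
    deviations = {out: abs(calib.achieved[out] - targets[out])
                  for out in OUTPUTS}

    # ---- Monte-Carlo uncertainty at the calibrated point ---------------------
    pdf_by_code = {s.code: s for s in load_pdf_specs_csv(config.pdf_specs_path)}
    pdf_specs = []
    for c in influential:
        if c in pdf_by_code:
            pdf_specs.append(pdf_by_code[c])
        else:                                # conservative fallback
            s = registry[c]
            pdf_specs.append(PdfSpec.uniform_range(
                c, 0.5 * s.default, 1.5 * s.default,
                source="no literature range bundled; +-50% of default"))
    n0 = evaluator.n_evaluations
    uncertainty = mc_propagate(evaluator, pdf_specs, registry, base=calibrated,
                               n=config.mc_n, seed=seeds["mc"])
    counts["uncertainty"] = evaluator.n_evaluations - n0
    log.info("uncertainty: %d evaluations, U_c %s", counts["uncertainty"],
             {k_: round(v, 3) for k_, v in uncertainty.u_combined.items()})

    # ---- validation under the alternative oxygen regimes ---------------------
    validation = validate_regimes(calibrated, fixtures)

    return PipelineReport(
        config=config, fixtures=fixtures, observation=observation,
        targets=dict(targets), morris=morris_results, screening=screening,
        sobol=sobol_results, sobol_flags=sobol_flags, influential=influential,
        calibration=calib, deviations=deviations, uncertainty=uncertainty,
        validation=validation, evaluation_counts=counts, seeds=seeds)


def validate_regimes(calibrated, fixtures: FixtureSet,
                     regimes: tuple[str, ...] = REGIMES) -> pd.DataFrame:
    """Run the calibrated model under each regime's influent and operations;
    tabulate predictions against the reported effluent."""
    rows = []
    for regime in regimes:
        ev = build_evaluator(fixtures, regime)
        pred = ev(calibrated)
        eff = fixtures.effluent[regime]
        reported = {"BOD": eff.bod, "TN": eff.tn, "TSS": eff.tss}
        for j, out in enumerate(OUTPUTS):
            rows.append({
                "regime": regime, "output": out,
                "do_mg_l": fixtures.plant[regime].do_mg_l,
                "predicted": float(pred[j]), "reported": reported[out],
                "abs_deviation": abs(float(pred[j]) - reported[out]),
            })
    return pd.DataFrame(rows)


def export_reports(report: PipelineReport, outdir: str | Path) -> list[Path]:
    """Write the deterministic file set: per-stage CSVs, distribution data,
    and a JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    for out in OUTPUTS:
        res = report.morris[out]
        tab = report.screening[out].table
        save_csv(tab, f"morris_{out.lower()}.csv")
        save_csv(pd.DataFrame({
            "factor": res.factor_names, "mu_star": res.mu_star,
            "sigma": res.sigma}), f"morris_plot_{out.lower()}.csv")
        save_csv(report.sobol_flags[out].table, f"sobol_{out.lower()}.csv")
        if report.sobol_flags[out].pairwise is not None:
            p = outdir / f"sobol_s2_{out.lower()}.csv"
            report.sobol_flags[out].pairwise.to_csv(p, float_format="%.10g")
            written.append(p)

    # polarity of influential factors across outputs (screening-table shape)
    codes = sorted({c for out in OUTPUTS
                    for c in report.screening[out].influential},
                   key=report.fixtures.registry.codes.index)
    pol_rows = []
    for c in codes:
        row = {"code": c, "name": report.fixtures.registry[c].name}
        for out in OUTPUTS:
            res = report.morris[out]
            i = res.factor_names.index(c)
            row[out] = (res.polarity[i]
                        if c in report.screening[out].influential else "")
        pol_rows.append(row)
    save_csv(pd.DataFrame(pol_rows), "morris_polarity.csv")

    cal = report.calibration.to_frame()
    cal.insert(1, "name", [report.fixtures.registry[c].name for c in cal["code"]])
    cal.insert(2, "units", [report.fixtures.registry[c].units for c in cal["code"]])
    save_csv(cal, "calibration.csv")
    save_csv(pd.DataFrame({"iteration": np.arange(len(report.calibration.trace)),
                           "best_objective": report.calibration.trace}),
             "calibration_trace.csv")
    save_csv(pd.DataFrame([
        {"output": out, "observed": report.targets[out],
         "model": report.calibration.achieved[out],
         "abs_deviation": report.deviations[out]} for out in OUTPUTS]),
        "deviation.csv")

    unc = report.uncertainty
    for out in OUTPUTS:
        save_csv(pd.DataFrame({out: unc.samples[out]}),
                 f"uncertainty_samples_{out.lower()}.csv")
        counts, edges = unc.histogram(out)
        save_csv(pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                               "count": counts}),
                 f"uncertainty_hist_{out.lower()}.csv")
    save_csv(report.validation, "validation.csv")

    manifest = {
        "version": __version__,
        "master_seed": report.config.seed,
        "stage_seeds": report.seeds,
        "thresholds": {"morris": report.config.morris_threshold,
                       "sobol": report.config.sobol_threshold},
        "settings": {
            "morris_r": report.config.morris_r,
            "morris_p": report.config.morris_p,
            "top_k": report.config.top_k,
            "sobol_n": report.config.sobol_n,
            "bootstrap_reps": report.config.bootstrap_reps,
            "mc_n": report.config.mc_n,
            "nm_tol_x": report.config.nm_tol_x,
            "noise_rel": report.config.noise_rel,
        },
        "estimators": {"S1": "Saltelli-2010", "ST": "Jansen",
                       "S2": "Saltelli cross-matrix"},
        "influential": report.influential,
        "evaluation_counts": report.evaluation_counts,
        "uncertainty": {
            out: {"mean": unc.mean[out], "U_c": unc.u_combined[out],
                  "U_e": unc.u_expanded[out], "k": unc.coverage_factor}
            for out in OUTPUTS},
    }
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(p)
    return written
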