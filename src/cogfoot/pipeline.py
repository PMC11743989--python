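"""End-to-end orchestration: generate/load -> preprocess -> fit -> footprint.

One horseshoe model is fitted per (outcome x ATC level), including the
PCA-cognition composite; each model gets its own chain with a seed derived
from the base seed and a stable hash of the model label, so runs are
reproducible and models independent.  Artifacts (coefficient tables, top-k
tables, footprint tables, preprocessing report, run log) are written under
the configured output directory; coefficient and footprint CSVs are
byte-identical across re-runs with the same configuration.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atc import aggregate_level4, prevalence_filter
from .cohort import Cohort, generate_cohort
from .footprint import (
    PopulationStrata,
    binary_footprint,
    default_uk_strata,
    footprint_table,
    medication_footprint,
    select_reportable,
)
from .horseshoe import (
    HorseshoeConfig,
    fit_linear_horseshoe,
    fit_logistic_horseshoe,
    summarize_fit,
    top_k,
)
from .preprocess import normalize_outcome, pca_composite, build_design
from .scenario import ScenarioSpec

logger = logging.getLogger(__name__)

PCA_OUTCOME = "PCA_cognition"

_KNOWN_KEYS = {
    "seed", "outdir", "input", "outcomes", "pca_cognition", "atc_levels",
    "covariates", "horseshoe", "population", "top_k", "log_level",
}


class ConfigError(ValueError):
    """Configuration file fails validation; message lists every problem."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; message is prefixed with the stage name."""


@dataclass
class OutcomeConfig:
    name: str
    kind: str = "continuous"
    larger_is_worse: bool = False


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    mode: str = "synthetic"  # "synthetic" | "cohort"
    scenario: ScenarioSpec | None = None
    cohort_path: Path | None = None
    medication_cols: list[str] = field(default_factory=list)
    covariate_cols: list[str] = field(default_factory=list)
    outcomes: list[OutcomeConfig] = field(default_factory=list)
    pca_enabled: bool = True
    pca_tests: list[str] = field(default_factory=list)
    atc_levels: tuple[int, ...] = (4, 5)
    covariates: list[str] | None = None
    horseshoe: dict[str, Any] = field(default_factory=dict)
    strata_csv: Path | None = None
    population_total: float = 24_600_000.0
    top_k: int = 10
    log_level: str = "INFO"


@dataclass
class ReportTable:
    """Per (outcome x ATC level) results plus run metadata."""

    outcome: str
    atc_level: int
    coefficients: pd.DataFrame
    top: pd.DataFrame
    footprints: pd.DataFrame
    r2: float
    seed: int
    metadata: dict = field(default_factory=dict)


def validate_config(path: str | Path) -> RunConfig:
    """Parse and schema-check a YAML/JSON run configuration."""
    path = Path(path)
    raw = path.read_text()
    d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    unknown = set(d) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    if "seed" not in d:
        errors.append("missing required key: seed")
    if "outdir" not in d:
        errors.append("missing required key: outdir")

    inp = d.get("input", {})
    mode = inp.get("mode", "synthetic")
    scenario = None
    cohort_path = None
    if mode == "synthetic":
        sc = inp.get("scenario")
        try:
            if isinstance(sc, str):
                scenario = ScenarioSpec.load(Path(path).parent / sc)
            elif isinstance(sc, dict):
                sc = dict(sc)
                sc.setdefault("seed", d.get("seed", 0))
                scenario = ScenarioSpec.from_dict(sc)
            elif sc is None:
                errors.append("input.scenario required in synthetic mode")
        except Exception as exc:  # noqa: BLE001 - collected for the report
            errors.append(f"input.scenario: {exc}")
    elif mode == "cohort":
        cp = inp.get("cohort_path")
        if cp is None:
            errors.append("input.cohort_path required in cohort mode")
        else:
            cohort_path = Path(path).parent / cp
            if not cohort_path.exists():
                errors.append(f"input.cohort_path does not exist: {cohort_path}")
    else:
        errors.append(f"input.mode must be 'synthetic' or 'cohort', got {mode!r}")

    levels = tuple(d.get("atc_levels", (4, 5)))
    if not levels or any(lv not in (4, 5) for lv in levels):
        errors.append(f"atc_levels must be a non-empty subset of [4, 5]: {levels}")

    outcomes = [OutcomeConfig(**o) for o in d.get("outcomes", [])]
    if mode == "synthetic" and scenario is not None and not outcomes:
        outcomes = [
            OutcomeConfig(o.name, o.kind, not o.larger_is_better)
            for o in scenario.outcomes
        ]
    if not outcomes and not errors:
        errors.append("at least one outcome is required")

    hs = d.get("horseshoe", {})
    try:
        HorseshoeConfig(**{**hs, "seed": 0})
    except (TypeError, ValueError) as exc:
        errors.append(f"horseshoe: {exc}")

    pop = d.get("population", {})
    strata_csv = None
    if "strata_csv" in pop:
        strata_csv = Path(path).parent / pop["strata_csv"]
        if not strata_csv.exists():
            errors.append(f"population.strata_csv does not exist: {strata_csv}")

    pca = d.get("pca_cognition", {})

    if errors:
        raise ConfigError(
            f"invalid configuration {path}:\n  - " + "\n  - ".join(errors)
        )
    return RunConfig(
        seed=int(d["seed"]),
        outdir=Path(d["outdir"]),
        mode=mode,
        scenario=scenario,
        cohort_path=cohort_path,
        medication_cols=list(inp.get("medication_cols", [])),
        covariate_cols=list(inp.get("covariate_cols", [])),
        outcomes=outcomes,
        pca_enabled=bool(pca.get("enabled", True)),
        pca_tests=list(pca.get("tests", [])),
        atc_levels=levels,
        covariates=d.get("covariates"),
        horseshoe=hs,
        strata_csv=strata_csv,
        population_total=float(pop.get("total", 24_600_000.0)),
        top_k=int(d.get("top_k", 10)),
        log_level=str(d.get("log_level", "INFO")),
    )


def model_seed(base_seed: int, outcome: str, level: int) -> int:
    """Stable per-model chain seed below 2^31."""
    h = zlib.crc32(f"{outcome}:L{level}".encode())
    return (int(base_seed) + h) % (2**31 - 1)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _obtain_cohort(cfg: RunConfig) -> Cohort:
    if cfg.mode == "synthetic":
        assert cfg.scenario is not None
        return generate_cohort(cfg.scenario)
    outcome_names = [o.name for o in cfg.outcomes]
    return Cohort.from_csv(
        cfg.cohort_path, cfg.medication_cols, cfg.covariate_cols, outcome_names
    )


@_stage("preprocess")
def _normalized_outcomes(cfg: RunConfig, cohort: Cohort) -> dict:
    out = {}
    for oc in cfg.outcomes:
        out[oc.name] = normalize_outcome(
            cohort.data[oc.name],
            larger_is_worse=oc.larger_is_worse,
            kind=oc.kind,
            name=oc.name,
        )
    return out


def run_pipeline(cfg: RunConfig) -> dict[tuple[str, int], ReportTable]:
    """Execute the full analysis; returns one report per (outcome, level)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cogfoot")
    root.addHandler(handler)
    root.setLevel(cfg.log_level.upper())
    try:
        return _run(cfg, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, outdir: Path) -> dict[tuple[str, int], ReportTable]:
    if not cfg.outcomes and cfg.scenario is not None:
        cfg.outcomes = [
            OutcomeConfig(o.name, o.kind, not o.larger_is_better)
            for o in cfg.scenario.outcomes
        ]
    if not cfg.outcomes:
        raise PipelineError("[config] at least one outcome is required")
    cohort = _obtain_cohort(cfg)
    logger.info("cohort: n=%d, %d medications", cohort.n, len(cohort.medication_cols))

    outcomes = _normalized_outcomes(cfg, cohort)

    report: dict[str, Any] = {"version": __version__, "seed": cfg.seed}

    # PCA-cognition composite over the continuous tests
    if cfg.pca_enabled:
        tests = cfg.pca_tests or [
            oc.name for oc in cfg.outcomes if oc.kind == "continuous"
        ]
        if len(tests) >= 2:
            try:
                battery = pd.DataFrame(
                    {t: outcomes[t].values for t in tests}
                )
                comp = pca_composite(battery)
            except Exception as exc:
                raise PipelineError(f"[preprocess] PCA-cognition: {exc}") from exc
            from .preprocess import OutcomeVector

            outcomes[PCA_OUTCOME] = OutcomeVector(
                comp.values, "continuous", False, PCA_OUTCOME
            )
            report["pca_cognition"] = {
                "tests": comp.test_names,
                "loadings": [round(float(v), 6) for v in comp.loadings],
                "explained_variance_fraction": round(
                    comp.explained_variance_fraction, 6
                ),
            }

    # exposures and prevalence filtering per ATC level
    exposures5 = cohort.exposures()
    level_exposures = {}
    retained = {}
    for lv in sorted(cfg.atc_levels):
        exp = exposures5 if lv == 5 else aggregate_level4(exposures5)
        level_exposures[lv] = exp
        retained[lv] = prevalence_filter(exp)
        logger.info(
            "ATC level %d: %d/%d codes pass the 1%% prevalence filter",
            lv, len(retained[lv]), exp.shape[1],
        )
    report["retained_codes"] = {str(lv): retained[lv] for lv in retained}

    model_kinds = {name: ov.kind for name, ov in outcomes.items()}
    reports: dict[tuple[str, int], ReportTable] = {}
    per_outcome_n: dict[str, int] = {}

    for name, ov in outcomes.items():
        for lv in sorted(cfg.atc_levels):
            label = f"{name} / ATC level {lv}"
            codes = retained[lv]
            try:
                design, y = build_design(
                    cohort, codes, ov,
                    covariates=cfg.covariates,
                    atc_level=lv,
                    exposures=level_exposures[lv],
                )
            except Exception as exc:
                raise PipelineError(f"[design] {label}: {exc}") from exc
            per_outcome_n[name] = design.n
            seed = model_seed(cfg.seed, name, lv)
            hs = HorseshoeConfig(**{**cfg.horseshoe, "seed": seed})
            try:
                if model_kinds[name] == "binary":
                    fit = fit_logistic_horseshoe(design, y, hs)
                else:
                    fit = fit_linear_horseshoe(design, y, hs)
            except Exception as exc:
                raise PipelineError(f"[fit] {label}: {exc}") from exc
            fit.outcome_name, fit.atc_level = name, lv
            logger.info(
                "%s: fitted n=%d p=%d (min ESS %.0f)",
                label, design.n, design.p, fit.diagnostics["min_ess"],
            )

            try:
                summary = summarize_fit(fit, design, y)
                selected = top_k(fit, cfg.top_k)
                top_table = (
                    summary.table.set_index("name")
                    .loc[selected]
                    .reset_index()
                )
                strata = _strata_for(cfg, cohort, codes)
                fps = []
                for code in codes:
                    if model_kinds[name] == "binary":
                        fps.append(
                            binary_footprint(fit, design, strata, code, name)
                        )
                    else:
                        j = design.column(code)
                        raw_draws = fit.beta[:, j] / design.columns[j].sd
                        fps.append(
                            medication_footprint(raw_draws, strata, code, name)
                        )
                fp_all = footprint_table(fps)
                fp_rep = footprint_table(select_reportable(fps))
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[footprint] {label}: {exc}") from exc

            stem = f"{name}_L{lv}"
            summary.to_csv(outdir / f"coefficients_{stem}.csv")
            top_out = top_table.copy()
            top_out.insert(0, "outcome", name)
            top_out.insert(1, "atc_level", lv)
            top_out.to_csv(
                outdir / f"top{cfg.top_k}_{stem}.csv",
                index=False, float_format="%.6g",
            )
            fp_all.to_csv(
                outdir / f"footprints_{stem}.csv",
                index=False, float_format="%.6g",
            )
            (outdir / f"footprints_{stem}.json").write_text(
                fp_rep.to_json(orient="records", indent=2, double_precision=6)
            )
            reports[(name, lv)] = ReportTable(
                outcome=name,
                atc_level=lv,
                coefficients=summary.table,
                top=top_table,
                footprints=fp_all,
                r2=summary.r2,
                seed=seed,
                metadata={"n": design.n, "p": design.p},
            )

    report["per_outcome_n"] = per_outcome_n
    (outdir / "preprocessing_report.json").write_text(
        json.dumps(report, indent=2)
    )
    import datetime

    (outdir / "run_metadata.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "seed": cfg.seed,
                "timestamp": datetime.datetime.now().isoformat(),
                "models": [f"{n}_L{lv}" for n, lv in reports],
            },
            indent=2,
        )
    )
    return reports


def _strata_for(
    cfg: RunConfig, cohort: Cohort, codes: list[str]
) -> PopulationStrata:
    if cfg.strata_csv is not None:
        return PopulationStrata.from_csv(cfg.strata_csv)
    counts = default_uk_strata([], total=cfg.population_total).table
    data = cohort.data.copy()
    for code in codes:
        if code not in data.columns:
            # level-4 aggregate: attach for prevalence estimation
            from .atc import aggregate_level4 as _agg

            agg = _agg(cohort.exposures())
            for c in agg.columns:
                if c not in data.columns:
                    data[c] = agg[c]
            break
    return PopulationStrata.from_cohort_prevalence(
        data, codes, counts[["age_lo", "age_hi", "sex", "N"]]
    )
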