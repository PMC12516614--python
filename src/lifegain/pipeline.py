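"""End-to-end analysis pipeline with file artifacts and a manifest.

Stages: cohort (load or simulate) -> exposure derivation + eligibility
cascade -> prevalence tabulation -> rate-table preparation (with old-age
cause projection) -> weighted Cox hazard ratios -> partitioned life tables,
gains, Monte Carlo intervals -> age-by-cause decomposition.  Every stage
writes plain CSV/JSON artifacts into the run directory; ``manifest.json``
records the resolved configuration, seed, per-stage timings and a SHA-256
checksum of every output, so a rerun with the same configuration and seed
reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cox import DEFAULT_COVARIATES, WeightedCoxModel
from .exposure import GROUP_LABELS, apply_exclusions, derive_exposure
from .model import LifeExpectancyModel
from .rates import RateTable, extrapolate_cause_rates, read_rate_table
from .simulate import SimulationConfig, generate_cohort, generate_rate_table, tabulate_prevalence

logger = logging.getLogger(__name__)

#: Machine-readable error codes by pipeline stage.
STAGE_ERRORS = {
    "cohort": 10,
    "exposure": 11,
    "rates": 12,
    "hazards": 13,
    "lifetable": 14,
    "decomposition": 15,
    "report": 16,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage
        self.code = STAGE_ERRORS.get(stage, 1)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``simulation`` (synthetic cohort + Gompertz rates) or explicit
    input paths must be provided; ``hazards_path`` short-circuits the Cox
    stage with externally supplied estimates.
    """

    outdir: str = "lifegain_run"
    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    rates_path: str | None = None
    hazards_path: str | None = None
    exposure_source: str = "recalls"
    covariates: tuple = DEFAULT_COVARIATES
    robust: bool = True
    causes: tuple = ("all", "cvd", "cancer")
    project_rates: bool = True
    last_observed_age: int = 84
    projection_causes: tuple = ("cvd",)
    age_range: tuple = (50, 100)
    radix: float = 100_000.0
    mc_runs: int = 1000
    seed: int = 0
    subgroups: tuple = ()
    reference: str = "none"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = d.pop("simulation", None)
        if sim is not None:
            sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim = SimulationConfig(
                **{
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in sim.items()
                    if k in sim_fields
                }
            )
        cfg_fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d.items()
            if k in cfg_fields
        }
        return cls(simulation=sim, **kwargs)


def _plain(obj):
    """YAML-safe plain types: tuples -> lists, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _prepare_rates(config: RunConfig, outdir: Path) -> RateTable:
    if config.rates_path is not None:
        rt = read_rate_table(config.rates_path)
    elif config.simulation is not None:
        rt = generate_rate_table(
            config.simulation.baseline_gompertz,
            config.simulation.cause_mix,
            age_range=config.age_range,
        )
        # National cause-specific data stop at last_observed_age; blank the
        # older cause rates so the projection stage is exercised end-to-end.
        if config.project_rates:
            df = rt.df
            for cause in config.projection_causes:
                df.loc[df["age"] > config.last_observed_age, f"m_{cause}"] = np.nan
            rt = RateTable(df)
    else:
        raise StageError("rates", "neither rates_path nor simulation provided")

    projections = []
    if config.project_rates:
        needs = [
            c
            for c in config.projection_causes
            if rt.df.loc[rt.df["age"] > config.last_observed_age, f"m_{c}"].isna().any()
        ]
        if needs:
            rt, models = extrapolate_cause_rates(
                rt,
                last_observed_age=config.last_observed_age,
                target_max_age=config.age_range[1],
                causes=tuple(needs),
            )
            projections = [m.to_dict() for m in models]
    rt.to_csv(outdir / "rates.csv")
    _write_json(outdir / "rate_projection.json", projections)
    return rt


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory.

    Any stage failure raises :class:`StageError` carrying the stage name
    and a machine-readable error code.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc

        return _T()

    with stage("cohort"):
        if config.cohort_path is not None:
            cohort = pd.read_csv(config.cohort_path, comment="#")
        elif config.simulation is not None:
            cohort = generate_cohort(config.simulation)
        else:
            raise StageError("cohort", "neither cohort_path nor simulation provided")
        with open(outdir / "cohort.csv", "w") as fh:
            fh.write(f"# seed={config.seed}\n")
            cohort.to_csv(fh, index=False)

    with stage("exposure"):
        cohort = derive_exposure(cohort, source=config.exposure_source)
        eligible, log = apply_exclusions(cohort)
        _write_json(outdir / "exclusion_log.json", log)
        eligible.to_csv(outdir / "cohort_eligible.csv", index=False)
        prevalence = tabulate_prevalence(eligible)
        prevalence.to_csv(outdir / "prevalence.csv")
        logger.info(
            "exposure stage: %d -> %d eligible", log["n_initial"], log["n_eligible"]
        )

    with stage("rates"):
        rate_table = _prepare_rates(config, outdir)

    with stage("hazards"):
        if config.hazards_path is not None:
            hazards = pd.read_csv(config.hazards_path, comment="#")
        else:
            parts = []
            for cause in config.causes:
                res = WeightedCoxModel(
                    eligible,
                    cause=cause,
                    covariates=config.covariates,
                    reference=config.reference,
                    robust=config.robust,
                ).fit()
                parts.append(res.hazard_estimates)
            hazards = pd.concat(parts, ignore_index=True)
        hazards.to_csv(outdir / "hazards.csv", index=False)

    with stage("lifetable"):
        model = LifeExpectancyModel(
            rate_table,
            hazards,
            prevalence,
            reference=config.reference,
            age_range=config.age_range,
            radix=config.radix,
        )
        results = model.fit(n_runs=config.mc_runs, seed=config.seed)
        for g, t in results.life_tables.items():
            t.to_csv(outdir / f"lifetable_{g}.csv", index=False)
        results.gains.to_csv(outdir / "gains.csv", index=False)
        _write_json(
            outdir / "mc_intervals.json",
            {
                kind: {g: iv.to_dict() for g, iv in d.items()}
                for kind, d in results.intervals.items()
            },
        )

    with stage("decomposition"):
        decomp_summaries = {}
        for g in GROUP_LABELS:
            if g == config.reference or g not in results.life_tables:
                continue
            d = results.decompose(g)
            d.to_csv(outdir / f"decomposition_{g}.csv")
            decomp_summaries[g] = results.decomposition_summary(g).to_dict("records")

    with stage("report"):
        summary = {
            "seed": config.seed,
            "n_eligible": int(len(eligible)),
            "e50": {g: float(v) for g, v in results.e50.items()},
            "gains": results.gains.to_dict("records"),
            "decomposition": decomp_summaries,
        }
        if config.subgroups:
            summary["subgroups"] = _run_subgroups(config, eligible, rate_table, outdir)
        _write_json(outdir / "summary.json", summary)

    files = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "timings": timings,
        "files": {name: _sha256(outdir / name) for name in files},
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir


def _run_subgroups(config, eligible, rate_table, outdir: Path) -> dict:
    out = {}
    for var in config.subgroups:
        levels = sorted(pd.unique(eligible[var].astype(str)))
        if var == "race":
            levels = [l for l in levels if l != "other"]
        for lev in levels:
            sub = eligible[eligible[var].astype(str) == lev]
            try:
                rt = rate_table.select(**{var: lev}) if var in rate_table.keys else rate_table
                covs = tuple(c for c in config.covariates if c != var)
                model = LifeExpectancyModel.from_cohort(
                    sub, rt, covariates=covs, causes=config.causes,
                    reference=config.reference, age_range=config.age_range,
                    radix=config.radix,
                )
                res = model.fit(n_runs=config.mc_runs, seed=config.seed)
                res.gains.to_csv(outdir / f"gains_{var}_{lev}.csv", index=False)
                out[f"{var}={lev}"] = {
                    "e50": {g: float(v) for g, v in res.e50.items()},
                    "gains": res.gains.to_dict("records"),
                }
            except ValueError as err:
                logger.warning("subgroup %s=%s skipped: %s", var, lev, err)
                out[f"{var}={lev}"] = {"skipped": str(err)}
    return out


REQUIRED_ARTIFACTS = (
    "summary.json",
    "gains.csv",
    "hazards.csv",
    "manifest.json",
)


def summarize(run_dir) -> str:
    """Human-readable report of a completed run directory."""
    run_dir = Path(run_dir)
    missing = [f for f in REQUIRED_ARTIFACTS if not (run_dir / f).exists()]
    if missing:
        raise StageError("report", f"incomplete run, missing artifacts: {missing}")
    summary = json.loads((run_dir / "summary.json").read_text())
    gains = pd.read_csv(run_dir / "gains.csv")
    lines = [
        f"lifegain run: {run_dir}",
        f"seed: {summary['seed']}    eligible participants: {summary['n_eligible']}",
        "=" * 62,
        f"{'group':<12}{'e50':>8}{'95% CI':>18}{'gain':>8}{'95% CI':>16}",
    ]
    for _, r in gains.iterrows():
        ci_e = f"({r['e50_lo']:.2f}, {r['e50_hi']:.2f})"
        ci_g = f"({r['gain_lo']:.2f}, {r['gain_hi']:.2f})"
        lines.append(
            f"{r['group']:<12}{r['e50']:>8.2f}{ci_e:>18}{r['gain']:>8.2f}{ci_g:>16}"
        )
    lines.append("-" * 62)
    for g, rows in summary.get("decomposition", {}).items():
        parts = ", ".join(
            f"{r['cause']} {r['years']:+.3f}y ({r['percent']:.1f}%)"
            for r in rows
            if r["percent"] is not None and np.isfinite(r["percent"])
        )
        lines.append(f"gain {g}: {parts}")
    for name, block in summary.get("subgroups", {}).items():
        lines.append("-" * 62)
        if "skipped" in block:
            lines.append(f"subgroup {name}: skipped ({block['skipped']})")
            continue
        lines.append(f"subgroup {name}:")
        for r in block["gains"]:
            lines.append(
                f"  {r['group']:<12}e50 {r['e50']:>7.2f}   gain {r['gain']:>6.2f} "
                f"({r['gain_lo']:.2f}, {r['gain_hi']:.2f})"
            )
    return "\n".join(lines)
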