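"""Config-driven end-to-end runs: simulate -> model -> assess -> report.

A run covers diseases x sexes x survey years.  For each stratum the stages
are: obtain inputs (synthetic world or CSV files), interpolate to single
ages, derive case fatality, invert the prevalence ODE with and without the
secular incidence trend, bootstrap the modeled incidence, compute
completeness ratios against the observed registry rates on reporting age
groups, and finally run between-year one-sided increase tests and write the
report.  All randomness flows from one root seed through named
sub-streams, so a run is reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .backcalc import StratumInputs, model_incidence
from .completeness import (
    CompletenessEntry,
    CompletenessReport,
    Stratum,
    build_report,
    completeness_ratio,
    incidence_mortality_ratio,
)
from .illness_death import TrendSpec
from .synthetic import SyntheticWorld, emit_model_inputs, emit_surveillance, make_world
from .tables import (
    AgeBand,
    Measure,
    RateTable,
    StandardPopulation,
    age_standardize,
    read_rate_table,
    write_rate_table,
)
from .uncertainty import BootstrapSpec, bootstrap_incidence

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

DEFAULT_TRENDS = {
    "ami": {"male": -0.02, "female": -0.02},
    "stroke": {"male": 0.03, "female": 0.02},
}
DEFAULT_AGE_GROUPS: list[tuple[int, int | None]] = [(0, 30), (30, 60), (60, None)]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and stratum."""


@dataclass
class DiseaseConfig:
    name: str
    preset: str | None = None  # synthetic preset; None => file inputs
    trend: dict[str, float] = field(default_factory=dict)
    rho: dict[str, object] = field(default_factory=dict)  # per-sex scalar or {year: value}
    inputs_dir: str | None = None
    params: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    diseases: dict[str, DiseaseConfig]
    sexes: list[str] = field(default_factory=lambda: ["male", "female"])
    years: list[int] = field(default_factory=lambda: [2007, 2010, 2015])
    base_year: int = 2000
    reference_year: int = 2015  # year at which preset hazard levels are anchored
    bootstrap_n: int = 100
    bootstrap_level: float = 0.95
    bootstrap_trended: bool = True
    noise: float = 0.0
    band_person_years: float = 1e7
    age_groups: list[tuple[int, int | None]] = field(
        default_factory=lambda: list(DEFAULT_AGE_GROUPS)
    )
    with_trend: bool = True
    outdir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        for dcfg in self.diseases.values():
            for delta in dcfg.trend.values():
                if delta <= -1:
                    raise ValueError("trend delta must exceed -1")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run configuration; keyword overrides win."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    diseases = {}
    for name, d in (raw.pop("diseases", None) or {}).items():
        d = dict(d or {})
        trend = d.pop("trend", None) or DEFAULT_TRENDS.get(name, {})
        diseases[name] = DiseaseConfig(
            name=name,
            preset=d.pop("preset", None),
            trend=trend,
            rho=d.pop("rho", {}) or {},
            inputs_dir=d.pop("inputs_dir", None),
            params=d.pop("params", {}) or {},
        )
    if not diseases:
        diseases = {
            "ami": DiseaseConfig("ami", preset="ami_like", trend=dict(DEFAULT_TRENDS["ami"])),
            "stroke": DiseaseConfig("stroke", preset="stroke_like", trend=dict(DEFAULT_TRENDS["stroke"])),
        }
    groups = raw.pop("age_groups", None)
    if groups is not None:
        raw["age_groups"] = [(int(lo), None if hi is None else int(hi)) for lo, hi in groups]
    return RunConfig(diseases=diseases, **raw)


def derive_seed(root: int, *labels) -> int:
    """Stable named sub-stream seed below 2**31."""
    tag = "/".join(str(x) for x in labels)
    return (int(root) * 2654435761 + zlib.crc32(tag.encode())) % (2**31 - 1)


def _resolve_rho(dcfg: DiseaseConfig, sex: str, year: int, default: float) -> float:
    val = dcfg.rho.get(sex)
    if val is None:
        return default
    if isinstance(val, dict):
        return float(val.get(year, val.get(str(year), default)))
    return float(val)


def _age_group_label(lo: int, hi: int | None) -> str:
    return f"{lo}+" if hi is None else f"{lo}-{hi - 1}"


def _rollup(bands, band_values, py, lo, hi):
    """Person-year-weighted mean of band rates over an age group."""
    sel = [
        k for k, b in enumerate(bands)
        if b.lo >= lo and (hi is None or (not b.open_ended and b.hi <= hi))
    ]
    if not sel:
        raise PipelineError(f"no bands inside age group [{lo}, {hi})")
    w = py[sel]
    vals = np.asarray(band_values)[..., sel]
    return vals @ w / w.sum(), sel


def _subset(table: RateTable, idx: list[int]) -> RateTable:
    pick = lambda a: None if a is None else a[idx]
    return RateTable(
        disease=table.disease, sex=table.sex, year=table.year, measure=table.measure,
        bands=[table.bands[k] for k in idx], values=table.values[idx],
        se=pick(table.se), ci_lo=pick(table.ci_lo), ci_hi=pick(table.ci_hi),
        count=pick(table.count), person_years=pick(table.person_years),
    )


def _stage(stage: str, stratum: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {stage} failed for {stratum}: {exc}") from exc
            return False

    return _Ctx()


def _load_file_inputs(dcfg: DiseaseConfig, sex: str, year: int):
    root = Path(dcfg.inputs_dir)
    paths = {}
    tables = {}
    required = {
        "prevalence": Measure.prevalence,
        "remission": Measure.remission,
        "csmr": Measure.csmr,
        "observed_incidence": Measure.incidence,
    }
    optional = {
        "relative_risk": Measure.relative_risk,
        "all_cause_mortality": Measure.all_cause_mortality,
    }
    for key, measure in {**required, **optional}.items():
        path = root / f"{dcfg.name}_{sex}_{year}_{key}.csv"
        if path.exists():
            tables[key] = read_rate_table(path, schema=measure)
            paths[key] = path
        elif key in required:
            raise FileNotFoundError(f"missing input file {path}")
    inputs = StratumInputs(
        prevalence=tables["prevalence"],
        remission=tables["remission"],
        csmr=tables["csmr"],
        relative_risk=tables.get("relative_risk"),
        all_cause_mortality=tables.get("all_cause_mortality"),
    )
    return inputs, tables["observed_incidence"], tables.get("csmr"), paths


def simulate_stratum(config: RunConfig, dcfg: DiseaseConfig, sex: str, year: int):
    """Build the synthetic world for one stratum and emit its input bundle."""
    preset = dcfg.preset or "custom"
    delta = dcfg.trend.get(sex, 0.0)
    # anchor hazard levels so current-year incidence follows the trend across surveys
    scale = (1.0 + delta) ** (year - config.reference_year)
    params = dict(dcfg.params)
    base = params.get("i50")
    if base is None:
        from .synthetic import _PRESETS  # preset level anchors

        base = _PRESETS["ami_like" if preset == "custom" else preset]["i50"]
    from .synthetic import SEXES

    params["i50"] = {s: base[s] * ((1.0 + dcfg.trend.get(s, 0.0)) ** (year - config.reference_year))
                     for s in base}
    params["trend_delta"] = {s: dcfg.trend.get(s, 0.0) for s in SEXES}
    default_rho = params.pop("rho", None)
    world_seed = derive_seed(config.seed, "world", dcfg.name, year)
    world = make_world(
        preset=preset, params=params, seed=world_seed,
        survey_year=year, base_year=config.base_year,
        band_person_years=config.band_person_years,
    )
    for s in world.reporting_fraction:
        world.reporting_fraction[s] = np.full(
            len(world.bands),
            _resolve_rho(dcfg, s, year, float(world.reporting_fraction[s][0])),
        )
    noise_rng = np.random.default_rng(derive_seed(config.seed, "noise", dcfg.name, sex, year))
    inputs = emit_model_inputs(
        world, sex, noise=config.noise, perturb=config.noise > 0, rng=noise_rng
    )
    observed, mortality = emit_surveillance(
        world, sex, seed=derive_seed(config.seed, "registry", dcfg.name, sex, year)
    )
    return world, inputs, observed, mortality


def run_pipeline(config: RunConfig) -> CompletenessReport:
    """Execute the full analysis and write artifacts under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries: list[CompletenessEntry] = []
    checksums: dict[str, str] = {}
    diagnostics = []
    standardized = []
    std_pop = StandardPopulation.who_world()
    for dname, dcfg in config.diseases.items():
        for sex in config.sexes:
            for year in config.years:
                stratum_id = f"{dname}/{sex}/{year}"
                with _stage("inputs", stratum_id):
                    if dcfg.preset is not None:
                        world, inputs, observed, mortality = simulate_stratum(
                            config, dcfg, sex, year
                        )
                    elif dcfg.inputs_dir is not None:
                        inputs, observed, mortality, paths = _load_file_inputs(dcfg, sex, year)
                        for key, path in paths.items():
                            checksums[f"{stratum_id}/{key}"] = hashlib.sha256(
                                path.read_bytes()
                            ).hexdigest()
                    else:
                        raise ValueError(f"disease {dname}: neither preset nor inputs_dir set")
                logger.info("inputs ready for %s", stratum_id)

                trend = TrendSpec(
                    delta=dcfg.trend.get(sex, 0.0), survey_year=year, base_year=config.base_year
                )
                branches = [("untrended", None)]
                if config.with_trend:
                    branches.append(("trended", trend))
                py = (
                    observed.person_years
                    if observed.person_years is not None
                    else np.ones(len(observed))
                )
                for label, br_trend in branches:
                    with _stage(f"model+bootstrap[{label}]", stratum_id):
                        if label == "trended" and not config.bootstrap_trended:
                            run = model_incidence(inputs, bands=observed.bands, trend=br_trend)
                            point, reps = run.incidence_bands.values, None
                        else:
                            boot = bootstrap_incidence(
                                inputs,
                                BootstrapSpec(
                                    n_iter=config.bootstrap_n,
                                    seed=derive_seed(config.seed, "boot", stratum_id, label),
                                    level=config.bootstrap_level,
                                ),
                                bands=observed.bands,
                                trend=br_trend,
                            )
                            point, reps = boot.point, boot.replicates
                    logger.info("modeled %s incidence for %s", label, stratum_id)
                    with _stage(f"assess[{label}]", stratum_id):
                        groups = list(config.age_groups) + [(0, None)]
                        for lo, hi in groups:
                            ag = "total" if (lo, hi) == (0, None) else _age_group_label(lo, hi)
                            mod_rate, sel = _rollup(observed.bands, point, py, lo, hi)
                            obs_count = observed.count[sel].sum()
                            obs_py = py[sel].sum()
                            obs_rate = obs_count / obs_py
                            var_obs = obs_count / obs_py**2
                            if reps is not None and len(reps) > 1:
                                rep_roll, _ = _rollup(observed.bands, reps, py, lo, hi)
                                var_mod = float(np.var(rep_roll, ddof=1))
                            else:
                                var_mod = 0.0
                            entries.append(
                                completeness_ratio(
                                    obs_rate,
                                    float(mod_rate),
                                    var_observed=float(var_obs),
                                    var_modeled=var_mod,
                                    stratum=Stratum(dname, sex, year, ag),
                                    trended=(label == "trended"),
                                    level=config.bootstrap_level,
                                )
                            )
                    logger.info("assessed %s completeness for %s", label, stratum_id)
                with _stage("diagnostics", stratum_id):
                    # zero-death bands (young ages) carry no ratio information
                    keep = [k for k, v in enumerate(mortality.values) if v > 0]
                    diag = incidence_mortality_ratio(
                        _subset(observed, keep), _subset(mortality, keep)
                    )
                    diag.insert(0, "disease", dname)
                    diag.insert(1, "sex", sex)
                    diag.insert(2, "year", year)
                    diagnostics.append(diag)
                    row = {"disease": dname, "sex": sex, "year": year}
                    for series, table_vals in (
                        ("observed", observed.values),
                        ("modeled_trended", point),
                    ):
                        try:
                            std = age_standardize(
                                RateTable(
                                    disease=dname, sex=sex, year=year,
                                    measure=Measure.incidence,
                                    bands=list(observed.bands), values=np.asarray(table_vals),
                                ),
                                std_pop,
                            )
                            row[f"{series}_per_100k"] = std.value * 1e5
                        except ValueError:
                            row[f"{series}_per_100k"] = None
                    standardized.append(row)

    year_pairs = [(a, b) for a in config.years for b in config.years if a < b]
    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "input_checksums": checksums,
    }
    report = build_report(entries, year_pairs=year_pairs, metadata=metadata, outdir=outdir)
    if diagnostics:
        import pandas as pd

        pd.concat(diagnostics, ignore_index=True).to_csv(
            outdir / "incidence_mortality_ratio.csv", index=False
        )
        pd.DataFrame(standardized).to_csv(outdir / "standardized_rates.csv", index=False)
    logger.info("report written to %s", outdir)
    return report


def _config_dict(config: RunConfig) -> dict:
    out = {
        k: getattr(config, k)
        for k in (
            "sexes", "years", "base_year", "reference_year", "bootstrap_n",
            "bootstrap_level", "bootstrap_trended", "noise", "band_person_years",
            "with_trend", "seed",
        )
    }
    out["age_groups"] = [list(g) for g in config.age_groups]
    out["diseases"] = {
        name: {
            "preset": d.preset,
            "trend": d.trend,
            "rho": d.rho,
            "inputs_dir": d.inputs_dir,
            "params": {k: v for k, v in d.params.items() if not isinstance(v, np.ndarray)},
        }
        for name, d in config.diseases.items()
    }
    return json.loads(json.dumps(out, default=float))


def simulate_to_csv(config: RunConfig, outdir: str | Path) -> list[Path]:
    """Write the synthetic input bundle (CSV) plus ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    truth = {}
    for dname, dcfg in config.diseases.items():
        if dcfg.preset is None:
            continue
        for sex in config.sexes:
            for year in config.years:
                world, inputs, observed, mortality = simulate_stratum(config, dcfg, sex, year)
                named = {
                    "prevalence": inputs.prevalence,
                    "remission": inputs.remission,
                    "csmr": inputs.csmr,
                    "relative_risk": inputs.relative_risk,
                    "all_cause_mortality": inputs.all_cause_mortality,
                    "observed_incidence": observed,
                    "observed_mortality": mortality,
                }
                for key, table in named.items():
                    if table is None:
                        continue
                    path = outdir / f"{dname}_{sex}_{year}_{key}.csv"
                    write_rate_table(table, path)
                    written.append(path)
                truth[f"{dname}/{sex}/{year}"] = {
                    "reporting_fraction": world.reporting_fraction[sex].tolist(),
                    "bands": [b.label() for b in world.bands],
                    "trend_delta": world.trend[sex].delta,
                }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    written.append(outdir / "ground_truth.json")
    return written
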