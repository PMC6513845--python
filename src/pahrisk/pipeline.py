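"""End-to-end pipeline: configuration, population I/O, orchestration, and
publication-style table outputs.

``run_pipeline`` executes every stage on one dataset: TEQ summaries by
season and annually, ring-class composition, diagnostic-ratio source
screening, Monte-Carlo daily intake (median and IQR per stratum x season),
95th-percentile ILCR with risk bands, partial-correlation sensitivity, and
the two-dimensional uncertainty envelope.  All outputs are CSV plus one JSON
manifest recording the seed, a config hash and the package version, from
which a run is exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .congeners import (
    SEASON_LABELS,
    PopulationStratum,
    apply_detection_policy,
    read_congener_table,
    write_congener_table,
)
from .distributions import LognormalSpec, NormalSpec, UniformSpec, fit_lognormal
from .risk import (
    DEFAULT_CF_MG_PER_PG,
    PopulationGroup,
    RiskModel,
    default_population_groups,
)
from .sensitivity import two_dim_mca
from .synthetic import default_city_profiles, generate_congener_table
from .teq import (
    RatioThresholds,
    TEFTable,
    classify_source,
    compute_teq,
    default_ratio_thresholds,
    diagnostic_ratios,
    nisbet_lagoy_tefs,
    ring_class_fractions,
    summarize_teq,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "run_from_manifest",
    "load_population_config",
    "write_population_config",
    "PipelineError",
]

log = logging.getLogger("pahrisk")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


# ---------------------------------------------------------------------------
# Population config I/O
# ---------------------------------------------------------------------------

def _spec_to_dict(bw) -> dict | float:
    if isinstance(bw, NormalSpec):
        return {"mean": bw.mean, "sd": bw.sd, "lower": bw.lower, "upper": bw.upper}
    return float(bw)


def write_population_config(groups: dict[PopulationStratum, PopulationGroup], path) -> None:
    """Serialize population groups to the YAML exposure-factor format."""
    entries = []
    for st, g in sorted(groups.items(), key=lambda kv: (kv[0].city, kv[0].age_group, kv[0].gender)):
        entries.append(
            {
                "city": st.city,
                "age_group": st.age_group,
                "gender": st.gender,
                "ir_m3_day": g.ir_m3_day,
                "et": {"mean": g.et.mean, "sd": g.et.sd},
                "bw_kg": _spec_to_dict(g.bw_kg),
                "ed_years": g.ed_years,
                "ef_days_year": g.ef_days_year,
                "at_hours": g.at_hours,
                "cf_mg_per_pg": g.cf_mg_per_pg,
                "csf": {"gm": g.csf.gm, "gsd": g.csf.gsd},
            }
        )
    Path(path).write_text(yaml.safe_dump({"populations": entries}, sort_keys=False))


def load_population_config(path) -> dict[PopulationStratum, PopulationGroup]:
    """Load a YAML/JSON exposure-factor config into PopulationGroups."""
    raw = yaml.safe_load(Path(path).read_text())
    if not raw or "populations" not in raw:
        raise PipelineError(f"population config {path}: missing 'populations' key")
    groups = {}
    for e in raw["populations"]:
        st = PopulationStratum(e["city"], e["age_group"], e["gender"])
        bw = e["bw_kg"]
        if isinstance(bw, dict):
            bw = NormalSpec(
                bw["mean"], bw["sd"], lower=bw.get("lower", 0.0), upper=bw.get("upper", float("inf"))
            )
        csf = e.get("csf", {"gm": 3.14, "gsd": 1.80})
        groups[st] = PopulationGroup(
            stratum=st,
            ir_m3_day=float(e["ir_m3_day"]),
            et=NormalSpec(float(e["et"]["mean"]), float(e["et"]["sd"]), lower=0.0, upper=24.0),
            bw_kg=bw,
            ed_years=float(e["ed_years"]),
            ef_days_year=float(e["ef_days_year"]),
            at_hours=float(e["at_hours"]),
            cf_mg_per_pg=float(e.get("cf_mg_per_pg", DEFAULT_CF_MG_PER_PG)),
            csf=LognormalSpec(mu=float(np.log(csf["gm"])), sigma=float(np.log(csf["gsd"]))),
        )
    return groups


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``congener_table`` (a CSV path) or ``synthetic=True``
    must supply concentrations; the population config is mandatory — either
    a YAML path or the literal string 'defaults' to opt in to the documented
    placeholder exposure factors.
    """

    out_dir: str
    population: str = ""
    congener_table: str | None = None
    synthetic: bool = False
    n_days_per_season: int = 30
    tef_table: str | None = None
    dba_tef: float = 1.0
    ratio_thresholds: str | None = None
    below_detection_policy: str = "half_lod"
    n_inner: int = 10_000
    n_outer: int = 100
    seed: int = 0
    sensitivity_transform: str = "none"
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.n_inner < 100:
            raise ValueError("n_inner must be >= 100")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an integer")

    def validate_paths(self) -> None:
        if not self.population:
            raise PipelineError(
                "stage[config]: no population exposure-factor config supplied; "
                "pass a YAML path or the literal 'defaults'"
            )
        for label, p in (("population", self.population), ("congener_table", self.congener_table),
                         ("tef_table", self.tef_table), ("ratio_thresholds", self.ratio_thresholds)):
            if p and p != "defaults" and not Path(p).exists():
                raise PipelineError(f"stage[config]: {label} path does not exist: {p}")
        if not self.synthetic and not self.congener_table:
            raise PipelineError(
                "stage[config]: supply a congener_table CSV or set synthetic=true"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stratum_seed(master: int, *labels) -> int:
    """Deterministic per-stratum integer seed below 2^31."""
    key = zlib.crc32("/".join(str(x) for x in labels).encode())
    ss = np.random.SeedSequence(int(master), spawn_key=(key,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a mapping of output name -> written path.  Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- stage: concentrations -------------------------------------------
    try:
        if config.congener_table:
            table = read_congener_table(config.congener_table)
        else:
            profiles = default_city_profiles()
            table = pd.concat(
                [
                    generate_congener_table(
                        p, config.n_days_per_season, _stratum_seed(config.seed, "table", c)
                    )
                    for c, p in sorted(profiles.items())
                ],
                ignore_index=True,
            )
        table = apply_detection_policy(table, config.below_detection_policy)
    except Exception as exc:
        raise PipelineError(f"stage[concentrations]: {exc}") from exc
    log.info("concentrations: %d rows, %d samples", len(table), table["sample_id"].nunique())
    outputs["congener_table"] = out_dir / "congener_table.csv"
    write_congener_table(table, outputs["congener_table"])

    # --- stage: TEQ -------------------------------------------------------
    try:
        tefs = (
            TEFTable.from_csv(config.tef_table)
            if config.tef_table
            else nisbet_lagoy_tefs(dba_tef=config.dba_tef)
        )
        teq = compute_teq(table, tefs)
        teq_summary = pd.concat(
            [summarize_teq(teq, by=("city", "season")), summarize_teq(teq, by="annual")],
            ignore_index=True,
        )
    except Exception as exc:
        raise PipelineError(f"stage[teq]: {exc}") from exc
    outputs["teq_summary"] = out_dir / "teq_summary.csv"
    teq_summary.to_csv(outputs["teq_summary"], index=False)

    # --- stage: composition & sources ------------------------------------
    try:
        rings = ring_class_fractions(table, by=("city", "season"))
        thresholds = (
            RatioThresholds.from_csv(config.ratio_thresholds)
            if config.ratio_thresholds
            else default_ratio_thresholds()
        )
        ratios = diagnostic_ratios(table, by="city")
        sources = classify_source(ratios, thresholds)
        source_table = ratios.merge(sources, on="city")
    except Exception as exc:
        raise PipelineError(f"stage[sources]: {exc}") from exc
    outputs["ring_fractions"] = out_dir / "ring_fractions.csv"
    rings.to_csv(outputs["ring_fractions"], index=False)
    outputs["sources"] = out_dir / "sources.csv"
    source_table.to_csv(outputs["sources"], index=False)

    # --- stage: population -----------------------------------------------
    try:
        groups = (
            default_population_groups()
            if config.population == "defaults"
            else load_population_config(config.population)
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage[population]: {exc}") from exc

    # --- stage: DI / ILCR simulations ------------------------------------
    di_rows, ilcr_rows, sens_rows, unc_rows = [], [], [], []
    cities_with_groups = sorted({st.city for st in groups})
    for city in cities_with_groups:
        city_teq = teq[teq["city"] == city]
        if city_teq.empty:
            log.warning("no TEQ samples for city %s; skipping", city)
            continue
        specs: dict[str, LognormalSpec] = {}
        for season in SEASON_LABELS:
            vals = city_teq.loc[city_teq["season"] == season, "teq_ng_m3"]
            if len(vals) >= 2 and (vals > 0).all():
                specs[season] = fit_lognormal(vals, method="mle")
        specs["annual"] = fit_lognormal(city_teq["teq_ng_m3"], method="mle")

        for st in sorted((s for s in groups if s.city == city),
                         key=lambda s: (s.age_group, s.gender)):
            group = groups[st]
            sseed = _stratum_seed(config.seed, "risk", st.city, st.age_group, st.gender)
            try:
                for period, spec in specs.items():
                    res = RiskModel(spec, group).fit(config.n_inner, sseed).as_kind("di")
                    di_rows.append(
                        {"city": st.city, "age_group": st.age_group, "gender": st.gender,
                         "period": period, "di_median_ng_day": res.median,
                         "di_iqr_ng_day": res.iqr, "di_q1": res.q1, "di_q3": res.q3}
                    )
                annual = RiskModel(specs["annual"], group).fit(config.n_inner, sseed)
                ilcr_rows.append(
                    {"city": st.city, "age_group": st.age_group, "gender": st.gender,
                     "ilcr_p95": annual.p95, "ilcr_median": annual.median,
                     "risk_band": annual.classify().value}
                )
                sens = annual.sensitivity(transform=config.sensitivity_transform)
                for name, coef in sens.coefficients.items():
                    sens_rows.append(
                        {"city": st.city, "age_group": st.age_group, "gender": st.gender,
                         "input": name, "partial_correlation": coef}
                    )
                env = two_dim_mca(
                    specs["annual"], group, UniformSpec(2.0, 4.0),
                    n_outer=config.n_outer, n_inner=config.n_inner, seed=sseed,
                )
                lo, hi = env.ci
                unc_rows.append(
                    {"city": st.city, "age_group": st.age_group, "gender": st.gender,
                     "ilcr_p95_ci_lo": lo, "ilcr_p95_ci_hi": hi, "ci_width": hi - lo}
                )
            except Exception as exc:
                raise PipelineError(
                    f"stage[risk]: {st.city}/{st.age_group}/{st.gender}: {exc}"
                ) from exc

    outputs["di_table"] = out_dir / "di_table.csv"
    pd.DataFrame(di_rows).to_csv(outputs["di_table"], index=False)
    outputs["ilcr_table"] = out_dir / "ilcr_table.csv"
    pd.DataFrame(ilcr_rows).to_csv(outputs["ilcr_table"], index=False)
    outputs["sensitivity"] = out_dir / "sensitivity.csv"
    pd.DataFrame(sens_rows).to_csv(outputs["sensitivity"], index=False)
    outputs["uncertainty"] = out_dir / "uncertainty.csv"
    pd.DataFrame(unc_rows).to_csv(outputs["uncertainty"], index=False)

    if config.make_figures:
        _write_figures(teq, groups, config, out_dir, outputs)

    manifest = {
        "package": "pahrisk",
        "version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "outputs": {k: str(v.name) for k, v in outputs.items()},
    }
    outputs["manifest"] = out_dir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %d outputs in %s", len(outputs), out_dir)
    return outputs


def _write_figures(teq, groups, config, out_dir, outputs) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for st in sorted(groups, key=lambda s: (s.city, s.age_group, s.gender)):
        if st.gender != "total":
            continue
        city_teq = teq.loc[teq["city"] == st.city, "teq_ng_m3"]
        if len(city_teq) < 2:
            continue
        spec = fit_lognormal(city_teq, method="mle")
        res = RiskModel(spec, groups[st]).fit(
            config.n_inner, _stratum_seed(config.seed, "fig", st.city, st.age_group)
        )
        ax = axes[0] if st.age_group == "adult" else axes[1]
        res.as_kind("di").plot_cumulative(ax=ax)
    axes[0].set_title("adults")
    axes[1].set_title("children")
    fig.tight_layout()
    path = out_dir / "di_cumulative.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    outputs["figure_di"] = path


def run_from_manifest(manifest_path) -> dict[str, Path]:
    """Re-run a pipeline exactly as recorded in a manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    return run_pipeline(RunConfig(**manifest["config"]))
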