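"""End-to-end study orchestration.

A run takes the three study inputs (measured or synthetic), applies the
irradiance quality control, integrates daily totals, summarizes the
microclimate by month, scores cross-environment and inside/outside
agreement with the Willmott index, compares chamber geometry between
environments with the routed test battery, tabulates the census
trajectories and tests the mortality contrast.  Every output table is a
tidy CSV with stable columns, and a manifest records the configuration
and seed of the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nest, qc, similarity, stats, synth

__all__ = ["RunConfig", "run_study", "write_outputs"]

CHAMBER_VARIABLES = ("depth_cm", "width_cm", "length_cm", "height_cm", "volume_cm3")
CENSUS_VARIABLES = (
    "eggs",
    "larvae",
    "pupae",
    "workers_small_medium",
    "queen_mass_mg",
    "fungus_biomass_mg",
)

#: per-variable routing overrides: chamber dimensions pass through the
#: normality gate; volume is forced nonparametric (median comparison);
#: counts would likewise be nonparametric.
DEFAULT_ROUTING = {"volume_cm3": "nonparametric"}


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    outdir: str | None = None
    seed: int = 0
    latitude: float = -22.85
    alpha: float = 0.05
    min_coverage: float = 0.0  # drop days with lower accepted-sample fraction
    radius_rule: str = "mean"
    days_per_month: int = 30
    overwrite: bool = False
    routing: dict = field(default_factory=lambda: dict(DEFAULT_ROUTING))
    paths: dict = field(default_factory=dict)
    synthetic: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mode == "files":
            for key in ("irradiance", "temperatures", "nests"):
                if key not in self.paths:
                    raise ValueError(f"file mode requires a path for {key!r}")
                if not Path(self.paths[key]).exists():
                    raise FileNotFoundError(self.paths[key])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw:
            syn = raw.pop("synthetic")
            cloud = synth.CloudParams(**syn.pop("cloud", {}))
            raw["synthetic"] = synth.SyntheticConfig(cloud=cloud, **syn)
        return cls(**raw)


def _read_inputs(config: RunConfig) -> dict:
    if config.mode == "synthetic":
        study = synth.simulate_study(config.synthetic, config.seed)
        study["mortality_from"] = "generator"
        return study
    irr = qc.read_irradiance_csv(config.paths["irradiance"])
    temps = pd.read_csv(config.paths["temperatures"], parse_dates=["timestamp"])
    for col in ("site", "timestamp", "external_c", "internal_c"):
        if col not in temps.columns:
            raise ValueError(
                f"{config.paths['temperatures']}: missing column {col!r}; expected "
                "schema site,timestamp,external_c,internal_c"
            )
    nests = pd.read_csv(config.paths["nests"])
    for col in ("environment", "month", "width_cm", "length_cm", "height_cm", "queen_alive"):
        if col not in nests.columns:
            raise ValueError(f"{config.paths['nests']}: missing column {col!r}")
    census = None
    if "census" in config.paths:
        census = pd.read_csv(config.paths["census"])
    return {
        "irradiance": irr,
        "temperatures": temps,
        "nests": nests,
        "census": census,
        "start_date": irr["timestamp"].min().date(),
    }


def _monthly_microclimate(temps, daily, start, days_per_month):
    temps = temps.copy()
    temps["month"] = synth.study_month(temps["timestamp"].dt.date, start, days_per_month)
    long = temps.melt(
        id_vars=["site", "month"],
        value_vars=["external_c", "internal_c"],
        var_name="variable",
        value_name="value",
    )
    long["variable"] = long["variable"].map(
        {"external_c": "external_temperature_c", "internal_c": "internal_temperature_c"}
    )
    temp_summary = qc.monthly_summary(long, "value", by=("site", "variable"))

    d = daily.copy()
    d["variable"] = "daily_irradiation_mj_m2"
    irr_summary = qc.monthly_summary(d, "mj_m2", by=("site", "variable"))
    out = pd.concat([temp_summary, irr_summary], ignore_index=True)
    return out.sort_values(["site", "variable", "month"]).reset_index(drop=True)


def _willmott_tables(temps, daily, start, days_per_month):
    frames = []
    # cross-environment agreement (sunny series scored against shaded)
    t = temps.pivot_table(
        index="timestamp", columns="site", values=["external_c", "internal_c"]
    )
    t.columns = [f"{var}_{site}" for var, site in t.columns]
    t = t.dropna().reset_index()
    t["month"] = synth.study_month(t["timestamp"].dt.date, start, days_per_month)
    for var, label in (
        ("external_c", "external temperature: sunny vs shaded"),
        ("internal_c", "internal temperature: sunny vs shaded"),
    ):
        frames.append(
            similarity.monthly_willmott(
                t, f"{var}_sunny", f"{var}_shaded", pair_label=label
            )
        )

    d = daily.pivot_table(index="date", columns="site", values="mj_m2").dropna()
    d = d.reset_index()
    d["month"] = synth.study_month(d["date"], start, days_per_month)
    frames.append(
        similarity.monthly_willmott(
            d, "sunny", "shaded", pair_label="daily irradiation: sunny vs shaded"
        )
    )

    # inside vs outside within each environment (outside is the reference)
    temps = temps.copy()
    temps["month"] = synth.study_month(temps["timestamp"].dt.date, start, days_per_month)
    for site, grp in temps.groupby("site"):
        frames.append(
            similarity.monthly_willmott(
                grp,
                "internal_c",
                "external_c",
                pair_label=f"internal vs external temperature ({site})",
            )
        )
    return pd.concat(frames, ignore_index=True)


def _route_variable(values, variable, routing, alpha):
    forced = routing.get(variable)
    if forced in ("parametric", "nonparametric"):
        return forced, None
    route, gate = stats.normality_gate(values, alpha=alpha)
    return route, gate


def _format_letters(letters: dict) -> str:
    return "|".join(f"{g}={letters[g]}" for g in sorted(letters))


def _chamber_analysis(nests_vol, routing, alpha):
    test_rows, summary_rows = [], []
    for variable in CHAMBER_VARIABLES:
        values = nests_vol[variable].to_numpy(float)
        route, gate = _route_variable(values, variable, routing, alpha)
        gate_p = gate.p_value if gate is not None else np.nan

        if route == "parametric":
            res = stats.two_way_anova_tukey(
                nests_vol, variable, "environment", "month", alpha=alpha
            )
            letters = res["letters"]["environment"]
            for term, tr in res["anova"].items():
                test_rows.append(
                    {
                        "variable": variable,
                        "route": route,
                        "method": tr.method,
                        "term": term,
                        "statistic": tr.statistic,
                        "df": tr.df,
                        "p_value": tr.p_value,
                        "p_adjusted": np.nan,
                        "shapiro_p": gate_p,
                        "letters": _format_letters(letters) if term == "environment" else "",
                    }
                )
        else:
            srh = stats.scheirer_ray_hare(nests_vol, variable, "environment", "month")
            dunn, letters = stats.dunn_test(
                nests_vol[variable], nests_vol["environment"], p_adjust="fdr", alpha=alpha
            )
            env_pair = dunn.iloc[0]
            for _, row in srh[srh["H"].notna()].iterrows():
                is_env = row["term"] == "environment"
                test_rows.append(
                    {
                        "variable": variable,
                        "route": route,
                        "method": "Scheirer-Ray-Hare",
                        "term": row["term"],
                        "statistic": row["H"],
                        "df": row["df"],
                        "p_value": row["p_value"],
                        "p_adjusted": env_pair["p_adjusted"] if is_env else np.nan,
                        "shapiro_p": gate_p,
                        "letters": _format_letters(letters) if is_env else "",
                    }
                )

        for env, grp in nests_vol.groupby("environment"):
            summary_rows.append(
                {
                    "variable": variable,
                    "environment": env,
                    "mean": grp[variable].mean(),
                    "sd": grp[variable].std(),
                    "median": grp[variable].median(),
                    "n": len(grp),
                    "letter": letters.get(env, ""),
                    "method": "Tukey" if route == "parametric" else "Dunn",
                }
            )
    return pd.DataFrame(test_rows), pd.DataFrame(summary_rows)


def _census_trajectories(census):
    long = census.melt(
        id_vars=["environment", "month"],
        value_vars=[v for v in CENSUS_VARIABLES if v in census.columns],
        var_name="variable",
        value_name="value",
    )
    out = (
        long.groupby(["variable", "environment", "month"], sort=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def _mortality_tests(nests, alpha):
    counts = nests.groupby("environment")["queen_alive"].agg(["size", "sum"])
    table = stats.MortalityTable(
        deaths_sunny=int(counts.loc["sunny", "size"] - counts.loc["sunny", "sum"]),
        n_sunny=int(counts.loc["sunny", "size"]),
        deaths_shaded=int(counts.loc["shaded", "size"] - counts.loc["shaded", "sum"]),
        n_shaded=int(counts.loc["shaded", "size"]),
    )
    p_sunny, p_shaded = table.proportions
    rows = []
    for cc in (False, True):
        tr = stats.equal_proportions_test(table, continuity_correction=cc)
        rows.append(
            {
                "method": tr.method,
                "statistic": tr.statistic,
                "df": tr.df,
                "p_value": tr.p_value,
                "mortality_sunny": p_sunny,
                "mortality_shaded": p_shaded,
                "n_sunny": table.n_sunny,
                "n_shaded": table.n_shaded,
                "significant": tr.p_value < alpha,
            }
        )
    return pd.DataFrame(rows), table


def run_study(config: RunConfig) -> dict:
    """Run the full analysis chain and return the report tables.

    Returns a dict of DataFrames: qc_audit, daily_irradiation,
    monthly_microclimate, willmott_monthly, chamber_tests,
    chamber_summary, census_trajectories (when census data exist),
    mortality_test, nests.  If ``config.outdir`` is set the tables are
    also written as CSV with a JSON run manifest.
    """
    inputs = _read_inputs(config)
    start = inputs["start_date"]

    qc_df = qc.qc_series(inputs["irradiance"], config.latitude)
    audit_cols = ["site", "timestamp", "component", "value_wm2", "limit_wm2", "reason"]
    audit = qc_df.loc[~qc_df["accepted"], audit_cols].reset_index(drop=True)

    daily = qc.daily_table(qc_df)
    daily = daily[daily["coverage"] >= config.min_coverage].reset_index(drop=True)
    daily["month"] = synth.study_month(daily["date"], start, config.days_per_month)

    microclimate = _monthly_microclimate(
        inputs["temperatures"], daily, start, config.days_per_month
    )
    willmott = _willmott_tables(
        inputs["temperatures"], daily, start, config.days_per_month
    )

    nests_vol = nest.add_chamber_volume(inputs["nests"], rule=config.radius_rule)
    chamber_tests, chamber_summary = _chamber_analysis(
        nests_vol, config.routing, config.alpha
    )

    mortality_df, mortality_table = _mortality_tests(inputs["nests"], config.alpha)

    results = {
        "qc_audit": audit,
        "daily_irradiation": daily,
        "monthly_microclimate": microclimate,
        "willmott_monthly": willmott,
        "chamber_tests": chamber_tests,
        "chamber_summary": chamber_summary,
        "mortality_test": mortality_df,
        "nests": nests_vol,
    }
    if inputs.get("census") is not None and len(inputs["census"]):
        results["census_trajectories"] = _census_trajectories(inputs["census"])
        results["census"] = inputs["census"]
    results["_mortality_table"] = mortality_table

    if config.outdir is not None:
        write_outputs(config.outdir, results, config)
    return results


def write_outputs(outdir, results: dict, config: RunConfig) -> None:
    """Write the report tables and a run manifest; refuse to clobber.

    An existing manifest means a previous run lives here; it is only
    overwritten when ``config.overwrite`` is set.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace the run"
        )
    for name, frame in results.items():
        if name.startswith("_") or not isinstance(frame, pd.DataFrame):
            continue
        frame.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    manifest = {
        "config": _jsonable(asdict(config)),
        "radius_rule": config.radius_rule,
        "tables": sorted(
            name for name, f in results.items()
            if isinstance(f, pd.DataFrame) and not name.startswith("_")
        ),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
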