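"""End-to-end analysis: measurement tables in, rate/significance report out.

Reads tidy CSV measurement tables (one delta13C reading per row), groups
them into replicate sets, and for every layer computes three label-uptake
rates with their significance:

==================  ==========  ==============================
rate                fraction    comparison (sample vs baseline)
==================  ==========  ==============================
gross-fixation      organic     living vs poisoned control
biogenic            inorganic   living vs poisoned control
abiogenic           inorganic   poisoned vs negative control
==================  ==========  ==============================

Each comparison gets a pooled-bootstrap p-value and the analytic
machine-noise probability; rates come from the two-endmember mass balance
applied to the replicate means.  Optionally a station chemistry table is
speciated and given calcite saturation states, and a lithification
scenario is projected.  Everything is seeded and reproducible: the same
inputs, config and seed give byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import carbonate, projection, stats
from .isotopes import delta_to_fraction, percent_new_carbon, rate_per_day, R_VPDB

__all__ = [
    "SCHEMA_VERSION",
    "MEASUREMENT_COLUMNS",
    "SchemaError",
    "AnalysisConfig",
    "AnalysisReport",
    "read_measurements",
    "read_chemistry",
    "run_full_analysis",
    "write_report",
    "load_config",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
MEASUREMENT_COLUMNS = ("sample_id", "layer", "fraction", "treatment", "delta13c_permil")
VALID_TREATMENTS = ("negative", "poisoned", "living")
VALID_FRACTIONS = ("organic", "inorganic")

#: (mode, fraction, sample treatment, baseline treatment)
RATE_COMPARISONS = (
    ("gross-fixation", "organic", "living", "poisoned"),
    ("biogenic", "inorganic", "living", "poisoned"),
    ("abiogenic", "inorganic", "poisoned", "negative"),
)


class SchemaError(ValueError):
    """A measurement or chemistry table violates the expected schema."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Run configuration; defaults mirror the studied experiment."""

    label_delta: float = 2000.0
    duration_hours: float = 24.0
    n_resamples: int = 1000
    seed: int = 0
    machine_sigma: float = 0.1
    constant_set: str = "freshwater"
    salinity: float | None = None
    ionic_strength: float = 0.0
    reference_ratio: float = R_VPDB
    scenario: projection.ProjectionScenario = field(
        default_factory=projection.ProjectionScenario
    )


@dataclass(frozen=True)
class AnalysisReport:
    """Structured results of one full analysis run."""

    rates: pd.DataFrame
    chemistry: pd.DataFrame | None
    projection: dict[str, float]
    config: AnalysisConfig
    seed: int


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a TOML or YAML file.

    Scenario parameters live in a ``[scenario]`` table/mapping; all keys
    are optional and default to the study values.
    """
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    elif path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(path.read_text()) or {}
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    scenario_kwargs = raw.pop("scenario", {})
    known = {f.name for f in dataclasses.fields(AnalysisConfig)} - {"scenario"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(
        scenario=projection.ProjectionScenario(**scenario_kwargs), **raw
    )


def read_measurements(path: str | Path, schema_version: str = SCHEMA_VERSION) -> pd.DataFrame:
    """Read and validate a measurement CSV.

    Requires columns ``sample_id, layer, fraction, treatment,
    delta13c_permil`` (extra columns pass through).  Rows with unknown
    treatments/fractions, non-numeric or sub-physical (< -1000 per mil)
    delta values raise :class:`SchemaError` naming the offending row.
    Replicate groups of two log a warning; singleton groups are allowed
    here and rejected later by the significance test.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    delta = pd.to_numeric(df["delta13c_permil"], errors="coerce")
    bad = df.index[delta.isna()]
    if len(bad):
        raise SchemaError(f"non-numeric delta13c_permil at row {bad[0] + 2}")
    df = df.assign(delta13c_permil=delta)
    low = df.index[df["delta13c_permil"] < -1000.0]
    if len(low):
        raise SchemaError(f"delta13c_permil below -1000 per mil at row {low[0] + 2}")
    bad_t = df.index[~df["treatment"].isin(VALID_TREATMENTS)]
    if len(bad_t):
        raise SchemaError(
            f"unknown treatment {df.loc[bad_t[0], 'treatment']!r} at row {bad_t[0] + 2}"
        )
    bad_f = df.index[~df["fraction"].isin(VALID_FRACTIONS)]
    if len(bad_f):
        raise SchemaError(
            f"unknown fraction {df.loc[bad_f[0], 'fraction']!r} at row {bad_f[0] + 2}"
        )
    sizes = df.groupby(["layer", "fraction", "treatment"]).size()
    for key, n in sizes.items():
        if n == 2:
            logger.warning("replicate group %s has only two samples", key)
    return df


def read_chemistry(path: str | Path) -> pd.DataFrame:
    """Read a station chemistry CSV with columns
    ``station, temperature_c, ph, tco2_mm, calcium_mm``."""
    df = pd.read_csv(path)
    required = ("station", "temperature_c", "ph", "tco2_mm", "calcium_mm")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _triplicate(group: pd.DataFrame) -> stats.TriplicateSet:
    row = group.iloc[0]
    return stats.TriplicateSet(
        group["delta13c_permil"].tolist(),
        layer=str(row["layer"]),
        fraction=str(row["fraction"]),
        treatment=str(row["treatment"]),
    )


def analyze_rates(measurements: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Per layer x comparison rate and significance table.

    Incomplete treatment groups leave that comparison's row out (with a
    warning) rather than aborting the run.  Bootstrap seeds are spawned
    deterministically per comparison from ``config.seed``.
    """
    f_label = delta_to_fraction(config.label_delta, config.reference_ratio)
    mv = stats.propagate_machine_sigma(config.machine_sigma)
    groups: dict[tuple[str, str, str], pd.DataFrame] = {
        key: g for key, g in measurements.groupby(["layer", "fraction", "treatment"])
    }
    layers = sorted(measurements["layer"].unique())
    root = np.random.SeedSequence(config.seed)
    streams = iter(root.spawn(len(layers) * len(RATE_COMPARISONS)))

    records = []
    for layer in layers:
        for mode, fraction, sample_t, baseline_t in RATE_COMPARISONS:
            ss = next(streams)
            sample_g = groups.get((layer, fraction, sample_t))
            baseline_g = groups.get((layer, fraction, baseline_t))
            if sample_g is None or baseline_g is None or len(sample_g) < 2 or len(baseline_g) < 2:
                logger.warning(
                    "layer %s %s: incomplete groups for %s rate; skipped",
                    layer, fraction, mode,
                )
                continue
            trip_s = _triplicate(sample_g)
            trip_b = _triplicate(baseline_g)
            boot = stats.bootstrap_p(
                trip_s,
                trip_b,
                n_resamples=config.n_resamples,
                rng=np.random.default_rng(ss),
            )
            f_sample = delta_to_fraction(trip_s.mean, config.reference_ratio)
            f_baseline = delta_to_fraction(trip_b.mean, config.reference_ratio)
            pct = percent_new_carbon(f_sample, f_baseline, f_label)
            rate = rate_per_day(pct, config.duration_hours)
            records.append(
                {
                    "layer": layer,
                    "fraction": fraction,
                    "mode": mode,
                    "n_sample": trip_s.n,
                    "n_baseline": trip_b.n,
                    "mean_sample_permil": trip_s.mean,
                    "sd_sample_permil": trip_s.sd,
                    "mean_baseline_permil": trip_b.mean,
                    "sd_baseline_permil": trip_b.sd,
                    "delta_avg_exp_permil": boot.delta_avg_exp,
                    "p_bootstrap": boot.p_value,
                    "p_machine": stats.machine_variability_prob(
                        boot.delta_avg_exp, mv.sigma_diff
                    ),
                    "percent_new": pct,
                    "rate_pct_per_day": rate,
                    "below_detection": pct < 0,
                }
            )
    return pd.DataFrame.from_records(records)


def analyze_chemistry(chemistry: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Speciation and calcite saturation state per station."""
    records = []
    for _, row in chemistry.iterrows():
        water = carbonate.WaterChemistry(
            temperature_c=row["temperature_c"],
            ph=row["ph"],
            tco2_mm=row["tco2_mm"],
            calcium_mm=row["calcium_mm"],
            station=str(row["station"]),
        )
        spec = carbonate.speciate(
            water, config.constant_set, config.salinity, config.ionic_strength
        )
        sat = carbonate.omega_calcite(
            water, config.constant_set, config.salinity, config.ionic_strength
        )
        records.append(
            {
                "station": water.station,
                "temperature_c": water.temperature_c,
                "ph": water.ph,
                "tco2_mm": water.tco2_mm,
                "calcium_mm": water.calcium_mm,
                "co2_aq_mm": spec.co2_aq_mm,
                "hco3_mm": spec.hco3_mm,
                "co3_mm": spec.co3_mm,
                "omega_calcite": sat.omega,
                "constant_set": sat.constants_used,
            }
        )
    return pd.DataFrame.from_records(records)


def run_full_analysis(
    measurements: pd.DataFrame,
    chemistry: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Rates + significance, optional station chemistry, and the
    lithification projection, under one seed."""
    config = config or AnalysisConfig()
    rates = analyze_rates(measurements, config)
    chem = analyze_chemistry(chemistry, config) if chemistry is not None else None
    carb_mass, daily = projection.carbonate_mass_and_flux(config.scenario)
    proj = {
        "carbonate_mass_g": carb_mass,
        "daily_mass_rate_g_per_day": daily,
        "years_full_lithification": projection.years_to_full_lithification(
            config.scenario.carbonate_rate_pct_per_day
        ),
        "years_to_target_wtpct": projection.years_to_target_wtpct(config.scenario),
    }
    return AnalysisReport(
        rates=rates, chemistry=chem, projection=proj, config=config, seed=config.seed
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj


def write_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report as CSV tables plus a JSON run log and text summary.

    Deterministic: the same report object always produces byte-identical
    files (floats via repr-shortest formatting).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["rates"] = out / "rates.csv"
    report.rates.to_csv(paths["rates"], index=False)
    if report.chemistry is not None:
        paths["chemistry"] = out / "chemistry.csv"
        report.chemistry.to_csv(paths["chemistry"], index=False)
    paths["projection"] = out / "projection.csv"
    pd.DataFrame([report.projection]).to_csv(paths["projection"], index=False)

    log = {
        "schema_version": SCHEMA_VERSION,
        "seed": report.seed,
        "config": _jsonable(report.config),
    }
    paths["log"] = out / "run_log.json"
    paths["log"].write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    lines = ["matlith analysis summary", "========================", ""]
    for _, r in report.rates.iterrows():
        flag = " (below detection)" if r["below_detection"] else ""
        lines.append(
            f"layer {r['layer']} {r['mode']:>14}: "
            f"{r['rate_pct_per_day']:+.4f} %/day  "
            f"p_boot={r['p_bootstrap']:.3f} p_machine={r['p_machine']:.3f}{flag}"
        )
    lines.append("")
    lines.append(
        f"projection: {report.projection['carbonate_mass_g']:.4f} g carbonate, "
        f"{report.projection['daily_mass_rate_g_per_day']:.3g} g/day, "
        f"{report.projection['years_full_lithification']:.0f} yr to lithify from zero, "
        f"{report.projection['years_to_target_wtpct']:.0f} yr to target wt%"
    )
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
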