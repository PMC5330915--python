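"""End-to-end orchestration: thermal stress, demography, and report bundles.

:func:`run_all` drives the stages against supplied delimited-text inputs
or, when none are given, against the synthetic study presets.  It emits a
deterministic report bundle (JSON plus delimited text) whose shape follows
the study's summary tables:

* a stress-series table and a thermal-event report per depth,
* a per-group live-area table (absolute cm² and % of the month-0 baseline
  at months 9, 58 and 89; one All/Unbleached/Bleached row triple per
  species),
* a rate / recovery / horizon report per group and period,
* a size-class bleaching-comparison table per species,
* a provenance block recording the configuration hash and seed.

Identical configuration and seed give byte-identical outputs; any stage
failure aborts with an error naming the stage and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography as dg
from . import synth, thermal

__all__ = ["RunConfig", "PipelineStageError", "run_all"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"{stage}: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Inputs, thresholds and method flags for a full pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    temperature_table: str | None = None  # delimited text; None -> synthetic
    colony_table: str | None = None  # delimited text; None -> synthetic presets
    window_days: int = 84
    accum_min_C: float = 1.0
    baseline_years: tuple[int, int] | None = None
    stress_hotspot_C: float = thermal.STRESS_HOTSPOT_C
    risk_dhw_Cweeks: float = thermal.RISK_DHW_CWEEKS
    method: str = "regression"  # regression | endpoint
    report_months: tuple[int, ...] = (9, 58, 89)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "baseline_years" in raw and raw["baseline_years"] is not None:
            raw["baseline_years"] = tuple(raw["baseline_years"])
        if "report_months" in raw:
            raw["report_months"] = tuple(raw["report_months"])
        return cls(**raw)

    def digest(self) -> str:
        """Configuration hash covering every analysis-relevant field."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # location does not affect the numbers
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits) if math.isfinite(obj) else obj
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True, default=str) + "\n")


def _thermal_stage(config: RunConfig, out: Path, written: list[Path]) -> dict:
    if config.temperature_table is not None:
        readings = thermal.read_temperature_table(config.temperature_table)
    else:
        readings = synth.simulate_temperature(seed=config.seed)
    daily = thermal.aggregate_daily(readings)
    stress, events, clims = thermal.analyze(
        daily,
        window_days=config.window_days,
        accum_min_C=config.accum_min_C,
        baseline_years=config.baseline_years,
        stress_hotspot_C=config.stress_hotspot_C,
        risk_dhw_Cweeks=config.risk_dhw_Cweeks,
    )
    p = out / "stress_series.csv"
    stress.assign(date=pd.DatetimeIndex(stress["date"]).strftime("%Y-%m-%d")).to_csv(
        p, index=False, float_format="%.6f"
    )
    written.append(p)
    report = {
        "climatology": {
            str(d): {"mmm_C": c.mmm_C, "monthly_mean_C": list(c.monthly_mean_C),
                     "baseline_years": list(c.baseline_years)}
            for d, c in clims.items()
        },
        "events": [
            {
                "depth_m": e.depth_m,
                "start_date": str(e.start_date),
                "end_date": str(e.end_date),
                "peak_hotspot_C": e.peak_hotspot_C,
                "peak_dhw_Cweeks": e.peak_dhw_Cweeks,
                "severity": e.severity,
            }
            for e in events
        ],
        "thresholds": {
            "stress_hotspot_C": config.stress_hotspot_C,
            "risk_dhw_Cweeks": config.risk_dhw_Cweeks,
            "window_days": config.window_days,
            "accum_min_C": config.accum_min_C,
        },
    }
    p = out / "thermal_events.json"
    _write_json(p, report)
    written.append(p)
    return report


def _live_area_table(table: pd.DataFrame, months) -> pd.DataFrame:
    rows = []
    for sp in sorted(table["species"].unique()):
        sub_sp = table[table["species"] == sp]
        cohorts = [("All", sub_sp)] + [
            (grp.capitalize(), sub_sp[sub_sp["group2005"] == grp])
            for grp in ("unbleached", "bleached")
        ]
        for label, sub in cohorts:
            if len(sub) == 0:
                continue
            row = {"species": sp, "status": label}
            base = sub[(sub["month"] == 0) & (sub["status"] != "lost")]
            row["live_area_month0_cm2"] = round(float(base["live_area_cm2"].sum()), 2)
            for m in months:
                cohort = dg._cohort(sub, m, 0)
                row[f"live_area_month{m}_cm2"] = round(
                    float(cohort.loc[cohort["month"] == m, "live_area_cm2"].sum()), 2
                )
                row[f"pct_of_baseline_month{m}"] = round(dg.percent_of_baseline(sub, m), 2)
            rows.append(row)
    return pd.DataFrame(rows)


def _rates_report(table: pd.DataFrame, config: RunConfig) -> dict:
    report: dict = {}
    periods = dg.DEFAULT_PERIODS
    for sp in sorted(table["species"].unique()):
        for grp in ("bleached", "unbleached"):
            sub = table[(table["species"] == sp) & (table["group2005"] == grp)]
            if len(sub) == 0:
                continue
            entry: dict = {"periods": {}}
            for period in periods:
                try:
                    est = dg.group_rate(sub, period, method=config.method)
                except dg.DemographyError:
                    continue
                entry["periods"][period.name] = {
                    "rate_pct_per_year": est.rate_pct_per_year,
                    "se_pct": est.se_pct,
                    "n_colonies": est.n_colonies,
                    "method": est.method,
                }
            try:
                change, se, n = dg.group_percent_change(sub, 0, 9)
                entry["response_mean_pct_change_0_9"] = {
                    "mean_pct": change, "se_pct": se, "n_colonies": n,
                }
            except dg.DemographyError:
                pass
            # recovery vertex from the group mean relative-area trajectory
            months, rels = [], []
            for m in sorted(sub["month"].unique()):
                if m > 58:
                    continue
                try:
                    rels.append(dg.percent_of_baseline(sub, int(m)))
                    months.append(int(m))
                except dg.DemographyError:
                    pass
            if len(months) >= 4:
                rec = dg.recovery_time(months, rels)
                entry["recovery"] = {
                    "t_star_months": rec.t_star_months,
                    "r_squared": rec.r_squared,
                    "extrapolated": rec.extrapolated,
                }
            # compound-interest horizon back to the 2005 baseline
            rec_rate = entry["periods"].get("recovery", {}).get("rate_pct_per_year")
            if rec_rate and rels:
                start = min(rels) / 100.0
                if rec_rate > 0 and 0 < start < 1:
                    hz = dg.horizon_years(start, rec_rate, 1.0)
                    entry["horizon_to_baseline"] = {
                        "years": hz.years,
                        "start_fraction": hz.start_fraction,
                        "annual_rate_pct": hz.annual_rate_pct,
                    }
            report.setdefault(sp, {})[grp] = entry
        # declining species: horizon to half the baseline from the mean
        # second-event rate of both groups
        sp_entry = report.get(sp, {})
        second = [
            g["periods"].get("second_event_response", {}).get("rate_pct_per_year")
            for g in sp_entry.values()
        ]
        second = [r for r in second if r is not None]
        if second and all(r < 0 for r in second):
            mean_rate = float(np.mean(second))
            hz = dg.horizon_years(1.0, mean_rate, 0.5)
            sp_entry["horizon_to_half_baseline"] = {
                "years": hz.years,
                "annual_rate_pct": mean_rate,
            }
    return report


def _size_class_table(table: pd.DataFrame) -> pd.DataFrame:
    sized = dg.assign_size_classes(table)
    base = sized[sized["month"] == 0]
    rows = []
    for sp, g in base.groupby("species"):
        large = g[g["size_class"] == "large"]
        small = g[g["size_class"] == "small"]
        if len(large) < 2 or len(small) < 2:
            continue
        row = {"species": sp, "n_large": len(large), "n_small": len(small)}
        for metric, col in (("BL", "frac_bleached"), ("PB", "frac_partial")):
            tt = dg.compare_size_classes(
                100 * large[col].to_numpy(), 100 * small[col].to_numpy()
            )
            row[f"{metric}_large_mean_pct"] = round(100 * float(large[col].mean()), 2)
            row[f"{metric}_small_mean_pct"] = round(100 * float(small[col].mean()), 2)
            row[f"{metric}_t"] = round(tt.t_stat, 4)
            row[f"{metric}_df"] = tt.df
            row[f"{metric}_p"] = float(f"{tt.p_value:.4g}")
            row[f"{metric}_significant"] = bool(tt.significant)
        rows.append(row)
    return pd.DataFrame(rows)


def _demography_stage(config: RunConfig, out: Path, written: list[Path]) -> dict:
    if config.colony_table is not None:
        table = dg.load_colony_table(config.colony_table)
    else:
        table = synth.simulate_study(seed=config.seed)
        p = out / "colony_table.csv"
        table.to_csv(p, index=False, float_format="%.6f")
        written.append(p)

    live = _live_area_table(table, config.report_months)
    p = out / "live_area_table.csv"
    live.to_csv(p, index=False)
    written.append(p)
    p = out / "live_area_table.json"
    _write_json(p, live.to_dict(orient="records"))
    written.append(p)

    rates = _rates_report(table, config)
    p = out / "rates_report.json"
    _write_json(p, rates)
    written.append(p)

    sizes = _size_class_table(table)
    p = out / "size_class_tests.csv"
    sizes.to_csv(p, index=False)
    written.append(p)
    p = out / "size_class_tests.json"
    _write_json(p, sizes.to_dict(orient="records"))
    written.append(p)
    return {"live_area_rows": len(live), "rate_groups": sum(len(v) for v in rates.values())}


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns a summary dict with the paths written.  On any stage failure a
    :class:`PipelineStageError` naming the stage is raised and partial
    outputs are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        try:
            _thermal_stage(config, out, written)
        except Exception as exc:
            raise PipelineStageError("thermal", exc) from exc
        try:
            _demography_stage(config, out, written)
        except Exception as exc:
            raise PipelineStageError("demography", exc) from exc
        cfg_payload = dataclasses.asdict(config)
        cfg_payload.pop("out_dir")  # keep reports location-independent
        provenance = {
            "config": cfg_payload,
            "config_sha256": config.digest(),
            "seed": config.seed,
            "outputs": sorted(p.name for p in written),
        }
        p = out / "provenance.json"
        _write_json(p, provenance)
        written.append(p)
    except PipelineStageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return {"out_dir": str(out), "files": sorted(str(p) for p in written)}
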