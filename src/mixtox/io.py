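"""CSV schema readers/writers and run configuration.

Units are fixed by schema and never auto-detected: concentrations in ug/kg,
consumed amounts in g, body weights in kg, doses and TRVs in ug/kg bw/d.
Files are UTF-8 CSV with a header row; decimal commas are rejected.  Row
errors are aggregated so one pass reports every offending line.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from mixtox.doseresponse import DoseResponseDataset
from mixtox.exposure import ConsumptionSurvey, FoodConversionTable
from mixtox.hazard import round_sig
from mixtox.risk import CombinedRiskMetric, TierDecision

__all__ = [
    "ValidationError",
    "RunConfig",
    "load_config",
    "read_individuals",
    "read_consumption",
    "read_survey",
    "read_conversion",
    "read_concentrations",
    "read_reference_points",
    "read_dose_response",
    "write_trv_table",
    "write_report",
]


class ValidationError(ValueError):
    """Schema validation failed; ``errors`` lists every offending row."""

    def __init__(self, path: str | Path, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(f"{path}: " + "; ".join(self.errors))


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(path, [f"missing columns {missing}"])
    for col in required:
        if df[col].dtype == object and df[col].astype(str).str.contains(
                r"^\s*-?\d+,\d+\s*$", regex=True).any():
            raise ValidationError(path, [f"column {col!r} uses a decimal comma"])
    return df


def read_individuals(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["individual_id", "body_weight_kg", "age_group"])
    errors = [f"row {i + 2}: nonpositive body weight"
              for i in df.index[pd.to_numeric(df["body_weight_kg"], errors="coerce") <= 0]]
    if errors:
        raise ValidationError(path, errors)
    return df


def read_consumption(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["individual_id", "day", "food_code", "amount_g"])
    amounts = pd.to_numeric(df["amount_g"], errors="coerce")
    errors = [f"row {i + 2}: bad amount" for i in df.index[amounts.isna() | (amounts < 0)]]
    if errors:
        raise ValidationError(path, errors)
    return df


def read_survey(individuals_path: str | Path, consumption_path: str | Path,
                n_survey_days: int | None = None) -> ConsumptionSurvey:
    return ConsumptionSurvey(
        individuals=read_individuals(individuals_path),
        records=read_consumption(consumption_path),
        n_survey_days=n_survey_days,
    )


def read_conversion(path: str | Path) -> FoodConversionTable:
    df = _read_csv(path, ["food_code", "sample_code", "proportion"])
    p = pd.to_numeric(df["proportion"], errors="coerce")
    errors = [f"row {i + 2}: proportion {df.loc[i, 'proportion']!r} outside (0, 1]"
              for i in df.index[p.isna() | (p <= 0) | (p > 1)]]
    if errors:
        raise ValidationError(path, errors)
    return FoodConversionTable(rows=df)


def read_concentrations(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["sample_code", "compound", "value_ug_per_kg", "censored",
                          "lod_ug_per_kg", "loq_ug_per_kg"])
    censored = df["censored"].astype(bool)
    value = pd.to_numeric(df["value_ug_per_kg"], errors="coerce")
    lod = pd.to_numeric(df["lod_ug_per_kg"], errors="coerce")
    loq = pd.to_numeric(df["loq_ug_per_kg"], errors="coerce")
    errors = []
    for i in df.index:
        if censored[i] and np.isnan(lod[i]) and np.isnan(loq[i]):
            errors.append(f"row {i + 2}: censored without LOD or LOQ")
        if not censored[i] and (np.isnan(value[i]) or value[i] < 0):
            errors.append(f"row {i + 2}: uncensored without a nonnegative value")
    if errors:
        raise ValidationError(path, errors)
    return df


def read_reference_points(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["compound", "group", "rp_value_ug_per_kg_bw_d", "rp_type",
                          "species", "duration_class", "extra_af", "is_critical",
                          "hbgv_ug_per_kg_bw_d"])
    rp = pd.to_numeric(df["rp_value_ug_per_kg_bw_d"], errors="coerce")
    errors = [f"row {i + 2}: nonpositive reference point"
              for i in df.index[rp.isna() | (rp <= 0)]]
    if errors:
        raise ValidationError(path, errors)
    return df


def read_dose_response(path: str | Path) -> list[DoseResponseDataset]:
    df = _read_csv(path, ["compound", "endpoint", "dose", "mean", "dispersion",
                          "dispersion_type", "n", "direction"])
    out = []
    for (compound, endpoint, direction), sub in df.groupby(
            ["compound", "endpoint", "direction"], sort=False):
        rows = list(zip(sub["dose"], sub["mean"], sub["dispersion"],
                        sub["dispersion_type"], sub["n"]))
        out.append(DoseResponseDataset.from_rows(compound, endpoint, rows, direction))
    return out


def write_dose_response(datasets: Sequence[DoseResponseDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for d, m, sd, n in zip(ds.dose, ds.mean, ds.sd, ds.n):
            rows.append((ds.compound, ds.endpoint, d, m, sd, "SD", int(n), ds.direction))
    pd.DataFrame(rows, columns=["compound", "endpoint", "dose", "mean", "dispersion",
                                "dispersion_type", "n", "direction"]
                 ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration for a tiered assessment run."""

    scenarios: list[str] = field(default_factory=lambda: ["LB", "UB"])
    percentiles: list[float] = field(default_factory=lambda: [50.0, 95.0])
    bootstrap: int = 100
    seed: int | None = None
    bmr: float = 0.10
    reference_policy: str = "auto-min-interval-ratio"  # or "fixed:<compound>"
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for p in self.percentiles:
            if not 0 < p < 100:
                raise ValueError(f"percentile {p} outside (0, 100)")
        if self.seed is None and (self.bootstrap or self.scenarios):
            raise ValueError("a seed is required whenever a stochastic stage is enabled")


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(path, [f"unknown config keys {sorted(unknown)}"])
    return RunConfig(**raw)


def write_trv_table(trvs: dict, path: str | Path) -> pd.DataFrame:
    """Write a TRV table mirroring the hazard-characterisation layout."""
    rows = []
    for (compound, group), trv in sorted(trvs.items()):
        rp = trv.rp
        rows.append({
            "compound": compound,
            "group": group,
            "rp_value_ug_per_kg_bw_d": rp.value if rp else np.nan,
            "rp_type": rp.rp_type if rp else "",
            "species": rp.species if rp else "",
            "duration_class": rp.duration_class if rp else "",
            "composed_af": trv.afs.composed if trv.afs else np.nan,
            "source": trv.source,
            "trv_ug_per_kg_bw_d": trv.value,
            "trv_reported": trv.reported,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def _metric_record(m: CombinedRiskMetric) -> dict[str, Any]:
    return {
        "group": m.group, "scenario": m.scenario, "percentile": m.percentile,
        "method": m.method, "value": m.value, "reported": m.reported,
        "reference_compound": m.reference_compound,
        "missing_compounds": list(m.missing_compounds),
    }


def write_report(
    metrics: Sequence[CombinedRiskMetric],
    trail: Sequence[TierDecision],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit CSV + JSON + a human-readable summary of a risk run.

    The CSV pairs LB and UB values per group/percentile/method the way the
    combined-risk tables are usually printed; JSON keeps full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = [_metric_record(m) for m in metrics]
    json_path = out / "risk_metrics.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump({
            "metrics": records,
            "trail": [dataclasses.asdict(t) if not isinstance(t, dict) else t
                      for t in _trail_records(trail)],
        }, fh, indent=2, default=str)

    csv_path = out / "risk_metrics.csv"
    if records:
        df = pd.DataFrame(records)
        wide = df.pivot_table(index=["group", "method", "percentile"],
                              columns="scenario", values="value",
                              aggfunc="first").reset_index()
        for scen in ("LB", "MB", "UB"):
            if scen in wide.columns:
                wide[scen] = wide[scen].map(lambda v: round_sig(v, 2))
        if "LB" in wide.columns and "UB" in wide.columns:
            wide["LB-UB"] = wide.apply(
                lambda r: f"({r['LB']}-{r['UB']})", axis=1)
        wide.to_csv(csv_path, index=False)
    else:
        pd.DataFrame(columns=["group", "method", "percentile"]).to_csv(csv_path, index=False)

    txt_path = out / "summary.txt"
    with open(txt_path, "w", encoding="utf-8") as fh:
        if not trail:
            fh.write("No tier decisions recorded.\n")
        for t in trail:
            status = "proceed to refinement" if t.proceed else "stop"
            fh.write(f"[{t.tier}] group {t.group}: max combined metric "
                     f"{round_sig(t.trigger, 2)} -> {status}"
                     + (f" ({t.note})" if t.note else "") + "\n")
    return {"json": json_path, "csv": csv_path, "summary": txt_path}


def _trail_records(trail: Sequence[TierDecision]) -> list[dict]:
    out = []
    for t in trail:
        out.append({
            "group": t.group, "tier": t.tier, "proceed": t.proceed,
            "trigger": t.trigger, "note": t.note,
            "metrics": [_metric_record(m) for m in t.metrics],
        })
    return out
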