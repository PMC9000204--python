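"""CSV / JSON input-output for calibration tables, cohorts and reports."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .olp import BiasEstimate, CalibrationSeries

__all__ = [
    "read_calibration_csv",
    "series_from_wide",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_bias_report",
    "read_bias_report",
]

COHORT_COLUMNS = ["subject_id", "group", "subtype", "age", "menopausal",
                  "creatinine", "he4_raw", "ca125", "hospital"]
COHORT_OPTIONAL = ["smoker", "ethnicity", "he4_adj", "he4_true"]


def series_from_wide(table: pd.DataFrame, reference_lab: str,
                     lab: str) -> CalibrationSeries:
    """Build one lab's CalibrationSeries from a wide calibration table."""
    return CalibrationSeries(
        sample_ids=tuple(table["sample_id"].astype(str)),
        reference=table[reference_lab].to_numpy(dtype=float),
        test=table[lab].to_numpy(dtype=float),
        lab_id=lab,
    )


def read_calibration_csv(path: str | Path,
                         reference_lab: str = "lab1") -> dict[str, CalibrationSeries]:
    """Read a calibration experiment CSV in wide or long dialect.

    Wide: columns ``sample_id, lab1, ..., labN`` (one value per cell).
    Long: columns ``sample_id, lab_id, replicate, value``; replicate
    readings are averaged per sample before pairing with the reference.
    Returns one CalibrationSeries per non-reference laboratory.
    """
    df = pd.read_csv(path)
    if {"lab_id", "value"} <= set(df.columns):  # long dialect
        wide = (df.pivot_table(index="sample_id", columns="lab_id",
                               values="value", aggfunc="mean")
                .reset_index())
    else:
        wide = df
    if reference_lab not in wide.columns:
        raise ValueError(f"reference lab {reference_lab!r} not found in {path}")
    labs = [c for c in wide.columns if c not in ("sample_id", reference_lab)]
    return {lab: series_from_wide(wide, reference_lab, lab) for lab in labs}


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; validates the required schema columns."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    df["menopausal"] = df["menopausal"].map(
        {"true": True, "false": False, True: True, False: False})
    return df


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to the canonical CSV schema (extra columns kept last)."""
    df = cohort.copy()
    extras = [c for c in COHORT_OPTIONAL if c in df.columns]
    df = df[COHORT_COLUMNS + extras]
    df = df.assign(menopausal=df["menopausal"].map({True: "true", False: "false"}))
    df.to_csv(path, index=False)


def write_bias_report(estimates: dict[str, BiasEstimate], path: str | Path,
                      classification: dict[str, str] | None = None) -> None:
    """Write per-lab bias estimates (and optional classification) as JSON."""
    payload = {lab: est.to_dict() for lab, est in estimates.items()}
    if classification is not None:
        payload = {"estimates": payload, "classification": classification}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_bias_report(path: str | Path) -> dict[str, BiasEstimate]:
    """Read a bias-report JSON back into BiasEstimate objects."""
    payload = json.loads(Path(path).read_text())
    entries = payload.get("estimates", payload)
    out = {}
    for lab, d in entries.items():
        out[lab] = BiasEstimate(
            lab_id=d["lab_id"], alpha=d["alpha"], beta=d["beta"],
            alpha_ci=tuple(d["alpha_ci"]), beta_ci=tuple(d["beta_ci"]),
            r=d["r"], n=d["n"], confidence=d.get("confidence", 0.95),
            ci_method=d.get("ci_method", "analytic"),
        )
    return out
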