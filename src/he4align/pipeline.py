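"""End-to-end study orchestration.

Reproduces the design of a multicenter diagnostic-accuracy study:

1. fit per-laboratory fixed/proportional biases on a shared calibration
   curve and harmonize raw HE4 onto the reference laboratory's scale;
2. screen the cohort for eligibility (age 18-70, plausible creatinine,
   unambiguous diagnosis, menopause consistent with age);
3. fit the two-stage covariate-adjusted ROC regression on the full cohort
   (creatinine + menopausal state, hospitals as bootstrap clusters);
4. within each menopause x age stratum and for each case/control contrast,
   derive the stratum's Youden cut-off for HE4, dichotomize HE4 (derived
   cut-off) and CA125 (fixed > 35 IU/mL), and compare the two dichotomous
   markers' AUCs with the paired DeLong test;
5. repeat the stratified comparisons on the sensitivity subset where the
   benign group is restricted to ovarian, annexal and peritoneal lesions
   and endometriosis.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import simulate
from .olp import BiasEstimate, classify_biases, fit_olp, harmonize
from .rocreg import RocRegression
from .roctools import auc_equality_test, dichotomize, youden_cutoff
from .simulate import (CalibrationSimConfig, CohortSimConfig,
                       SENSITIVITY_SUBTYPES, generate_calibration_experiment,
                       generate_cohort)

logger = logging.getLogger(__name__)

__all__ = [
    "apply_eligibility",
    "stratify",
    "run_contrast",
    "sensitivity_subset",
    "sample_size",
    "StudyConfig",
    "StudyReport",
    "run_study",
    "harmonize_cohort",
]

CA125_CUTOFF = 35.0

#: Eligibility rules in screening order; a record is logged under the first
#: rule it violates.
_ELIGIBILITY_RULES = (
    "creatinine_out_of_range",   # <= 0.3 or > 3 mg/dL
    "ambiguous_diagnosis",       # missing/unknown group label
    "missing_age",
    "premenopausal_over_55",
    "age_out_of_range",          # outside 18-70
)


def apply_eligibility(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Screen a cohort; return (eligible records, per-rule exclusion counts)."""
    df = records.copy()
    age = pd.to_numeric(df.get("age"), errors="coerce")
    creat = pd.to_numeric(df.get("creatinine"), errors="coerce")
    group = df.get("group", pd.Series("", index=df.index)).astype(str)
    meno = df.get("menopausal")

    conds = {
        "creatinine_out_of_range": creat.isna() | (creat <= 0.3) | (creat > 3.0),
        "ambiguous_diagnosis": ~group.isin(["malignant", "benign", "healthy"]),
        "missing_age": age.isna(),
        "premenopausal_over_55": (~meno.astype(bool).fillna(False)) & (age > 55),
        "age_out_of_range": (age < 18) | (age > 70),
    }
    reason = pd.Series("", index=df.index)
    for rule in _ELIGIBILITY_RULES:
        hit = conds[rule].fillna(False) & (reason == "")
        reason[hit] = rule
    log = {rule: int((reason == rule).sum()) for rule in _ELIGIBILITY_RULES}
    eligible = df[reason == ""].copy()
    logger.info("eligibility: %d in, %d retained, %d excluded",
                len(df), len(eligible), len(df) - len(eligible))
    return eligible, log


STRATA = ("pre_le40", "pre_gt40", "post_le60", "post_gt60")


def stratify(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition by menopause and age: pre <=40 / >40, post <=60 / >60."""
    meno = records["menopausal"].astype(bool)
    age = records["age"].astype(float)
    return {
        "pre_le40": records[~meno & (age <= 40)],
        "pre_gt40": records[~meno & (age > 40)],
        "post_le60": records[meno & (age <= 60)],
        "post_gt60": records[meno & (age > 60)],
    }


def _contrast_frame(records: pd.DataFrame, contrast: str) -> pd.DataFrame:
    if contrast == "malignant_vs_rest":
        return records
    if contrast == "malignant_vs_benign":
        return records[records["group"] != "healthy"]
    raise ValueError(f"unknown contrast {contrast!r}")


def run_contrast(records: pd.DataFrame, contrast: str,
                 marker: str = "he4_adj", rounding: str = "integer") -> dict:
    """Youden cut-off + dichotomous HE4 vs CA125 AUC comparison in a stratum.

    Returns a dict with the HE4 cut-off result, both dichotomous AUCs and
    the paired equality test, or ``{"skipped": reason}`` when a class is
    absent.
    """
    df = _contrast_frame(records, contrast)
    labels = (df["group"] == "malignant").to_numpy()
    if labels.all() or not labels.any():
        reason = "no controls in stratum" if labels.all() else "no cases in stratum"
        logger.warning("contrast %s skipped: %s", contrast, reason)
        return {"skipped": reason, "n": int(len(df))}

    he4 = df[marker].to_numpy(dtype=float)
    ca125 = df["ca125"].to_numpy(dtype=float)
    cut = youden_cutoff(he4, labels, rounding=rounding)
    he4_bin = dichotomize(he4, cut.cutoff)
    ca125_bin = dichotomize(ca125, CA125_CUTOFF)
    comparison = auc_equality_test(he4_bin, ca125_bin, labels)
    return {
        "n_cases": int(labels.sum()),
        "n_controls": int((~labels).sum()),
        "he4_cutoff": cut.to_dict(),
        "ca125_cutoff": CA125_CUTOFF,
        "comparison": comparison.to_dict(),
    }


def sensitivity_subset(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict benign diagnoses to ovarian/annexal/peritoneal lesions and
    endometriosis; malignant and healthy records pass through."""
    benign = records["group"] == "benign"
    subtype = records["subtype"].fillna("").astype(str)
    missing = benign & (subtype == "")
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} benign record(s) without subtype dropped "
            "from the sensitivity subset",
            stacklevel=2,
        )
    keep = ~benign | subtype.isin(SENSITIVITY_SUBTYPES)
    return records[keep & ~missing].copy()


def sample_size(prevalence: float, sensitivity: float, confidence: float,
                ci_halfwidth: float) -> int:
    """Subjects needed to estimate sensitivity to a given CI half-width.

    ``n_cases = ceil(z^2 Se (1 - Se) / d^2)`` with z the two-sided normal
    quantile; the total enrolls enough subjects that the expected number of
    cases at the given prevalence reaches ``n_cases``.
    """
    for name, v in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("confidence", confidence), ("ci_halfwidth", ci_halfwidth)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    n_cases = math.ceil(z * z * sensitivity * (1.0 - sensitivity)
                        / (ci_halfwidth * ci_halfwidth))
    return math.ceil(n_cases / prevalence)


def harmonize_cohort(cohort: pd.DataFrame, estimates: dict[str, BiasEstimate],
                     reference_lab: str, policy: str = "biased_only",
                     raw_col: str = "he4_raw", adj_col: str = "he4_adj",
                     hospital_col: str = "hospital") -> pd.DataFrame:
    """Add a harmonized-marker column mapped by each record's hospital.

    Reference-laboratory records are never transformed; other hospitals use
    their fitted bias-correction equation under the given policy.
    """
    df = cohort.copy()
    adj = df[raw_col].to_numpy(dtype=float).copy()
    for lab, sub in df.groupby(hospital_col):
        if lab == reference_lab:
            continue
        if lab not in estimates:
            raise KeyError(f"no bias estimate for hospital {lab!r}")
        adj[df[hospital_col] == lab] = harmonize(
            sub[raw_col].to_numpy(dtype=float), estimates[lab], policy=policy
        )
    df[adj_col] = adj
    return df


@dataclass
class StudyConfig:
    """Configuration of a full study run.

    Either file paths (``calibration_csv``, ``cohort_csv``) or simulation
    configs may supply the inputs; simulation configs are used when paths
    are None.
    """

    calibration_csv: str | None = None
    cohort_csv: str | None = None
    calibration_sim: CalibrationSimConfig | None = None
    cohort_sim: CohortSimConfig | None = None
    reference_lab: str = "lab1"
    policy: str = "biased_only"
    confidence: float = 0.95
    ci_method: str = "analytic"
    covariates: tuple[str, ...] = ("creatinine", "menopausal")
    cluster: str = "hospital"
    fpr_grid_size: int = 30
    n_boot: int = 50
    rounding: str = "integer"
    seed: int = 0


@dataclass
class StudyReport:
    """Structured results of a full study run."""

    n_input: int
    n_eligible: int
    exclusion_log: dict[str, int]
    bias_report: dict
    bias_classification: dict[str, str]
    roc_regression: dict
    stratified: dict
    sensitivity: dict

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "exclusion_log": self.exclusion_log,
            "bias_report": self.bias_report,
            "bias_classification": self.bias_classification,
            "roc_regression": self.roc_regression,
            "stratified": self.stratified,
            "sensitivity": self.sensitivity,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _stratified_comparisons(records: pd.DataFrame, rounding: str) -> dict:
    out: dict = {}
    for name, stratum in stratify(records).items():
        out[name] = {}
        for contrast in ("malignant_vs_rest", "malignant_vs_benign"):
            try:
                out[name][contrast] = run_contrast(stratum, contrast,
                                                   rounding=rounding)
            except ValueError as exc:
                out[name][contrast] = {"skipped": str(exc), "n": int(len(stratum))}
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline; deterministic given the config seed."""
    from . import io as _io  # local import to avoid a cycle

    # --- stage 1: calibration and bias estimation -------------------------
    calib_cfg = None
    if config.calibration_csv is not None:
        series_by_lab = _io.read_calibration_csv(config.calibration_csv,
                                                 reference_lab=config.reference_lab)
    else:
        calib_cfg = config.calibration_sim or CalibrationSimConfig(
            seed=config.seed)
        series_by_lab = generate_calibration_experiment(calib_cfg)
        series_by_lab = {lab: s for lab, s in series_by_lab.items()
                         if lab != config.reference_lab}

    estimates = {
        lab: fit_olp(s, confidence=config.confidence, ci_method=config.ci_method,
                     seed=config.seed)
        for lab, s in series_by_lab.items()
    }
    classification = classify_biases(list(estimates.values()),
                                     reference_lab=config.reference_lab)

    # --- stage 2: cohort, harmonization, eligibility ----------------------
    if config.cohort_csv is not None:
        cohort = _io.read_cohort_csv(config.cohort_csv)
    else:
        cohort_cfg = config.cohort_sim
        if cohort_cfg is None:
            # reuse the calibration sim's lab biases so the cohort's raw
            # HE4 is distorted by the same biases the pipeline estimates
            biases = ({lab: (a, b) for lab, (a, b, _) in calib_cfg.labs.items()}
                      if calib_cfg is not None
                      else simulate.table2_like_biases())
            cohort_cfg = CohortSimConfig(lab_biases=biases,
                                         hospitals=tuple(biases),
                                         seed=config.seed + 1)
        cohort = generate_cohort(cohort_cfg)

    cohort = harmonize_cohort(cohort, estimates, config.reference_lab,
                              policy=config.policy)
    eligible, excl_log = apply_eligibility(cohort)

    # --- stage 3: covariate-adjusted ROC regression -----------------------
    model = RocRegression.from_dataframe(
        eligible, marker="he4_adj", case_group="malignant",
        covariates=list(config.covariates), cluster=config.cluster,
        fpr_grid=np.arange(1, config.fpr_grid_size + 1)
        / (config.fpr_grid_size + 1.0),
    )
    roc_results = model.fit(n_boot=config.n_boot, seed=config.seed)

    # --- stages 4-5: stratified contrasts + sensitivity analysis ----------
    stratified = _stratified_comparisons(eligible, config.rounding)
    sensitivity = _stratified_comparisons(sensitivity_subset(eligible),
                                          config.rounding)

    return StudyReport(
        n_input=int(len(cohort)),
        n_eligible=int(len(eligible)),
        exclusion_log=excl_log,
        bias_report={lab: est.to_dict() for lab, est in estimates.items()},
        bias_classification=classification,
        roc_regression=roc_results.to_dict(),
        stratified=stratified,
        sensitivity=sensitivity,
    )
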