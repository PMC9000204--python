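"""Synthetic calibration experiments and study cohorts.

No individual-level data from the multicenter HE4 study is deposited, so the
package ships generators that emulate its two data structures:

* a *calibration experiment* — every laboratory measures the same dilution
  series, with a lab-specific fixed bias (alpha), proportional bias (beta)
  and multiplicative assay noise at the platform's coefficient of variation;
  duplicate readings are averaged per sample, as in routine practice;

* a *cohort* — subjects in three groups (malignant disease, benign
  gynecological disease, healthy) with group-specific age, menopausal
  status, creatinine and heavily right-skewed HE4/CA125 distributions
  (lognormal, moment-matched to published group means and SDs), assigned to
  hospitals whose laboratory biases distort the recorded raw HE4.

Bias injection uses the inverse of the harmonization map: a laboratory with
parameters (alpha, beta) records ``r = (true - alpha) / beta``, so the
correction ``alpha + beta * r`` recovers the truth by construction.  All
draws are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import PLATFORM_CVS
from .olp import CalibrationSeries

__all__ = [
    "CalibrationSimConfig",
    "CohortSimConfig",
    "generate_calibration_experiment",
    "generate_cohort",
    "lognormal_params_from_moments",
    "DEFAULT_TRUE_CURVE",
    "table2_like_biases",
    "default_calibration_labs",
]

#: Reference-laboratory ten-point HE4 dilution series (pmol/L) used as the
#: default ground truth of simulated calibration experiments.
DEFAULT_TRUE_CURVE = (1074.4, 574.9, 384.1, 322.4, 219.6, 186.5,
                      121.9, 88.9, 68.0, 30.3)

GROUPS = ("malignant", "benign", "healthy")

BENIGN_SUBTYPES = ("ovarian_lesion", "annexal_lesion", "peritoneal_lesion",
                   "endometriosis", "fibroma", "endometrial_polyp",
                   "hemorrhagic_corpus_luteum", "other")

#: Sensitivity-analysis subset: lesion types retained when the benign group
#: is restricted to the diagnoses most likely to be confused with cancer.
SENSITIVITY_SUBTYPES = frozenset(
    {"ovarian_lesion", "annexal_lesion", "peritoneal_lesion", "endometriosis"}
)


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal (log-mean, log-sd) matching given arithmetic mean and SD.

    mu = ln(mean^2 / sqrt(mean^2 + sd^2)), sigma = sqrt(ln(1 + sd^2/mean^2)).
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    m2 = mean * mean
    mu = np.log(m2 / np.sqrt(m2 + sd * sd))
    sigma = np.sqrt(np.log(1.0 + sd * sd / m2))
    return float(mu), float(sigma)


def table2_like_biases() -> dict[str, tuple[float, float]]:
    """Per-lab (alpha, beta) of the size seen in the six-lab calibration.

    lab1 is the unbiased reference; the remaining labs carry fixed and/or
    proportional biases comparable to those estimated from the shared
    dilution series.
    """
    return {
        "lab1": (0.0, 1.0),
        "lab2": (13.9, 1.09),
        "lab3": (21.2, 1.15),
        "lab4": (1.9, 1.08),
        "lab5": (33.3, 1.02),
        "lab6": (13.9, 1.04),
    }


def default_calibration_labs() -> dict[str, tuple[float, float, float]]:
    """Default simulated labs: (alpha, beta, cv) per laboratory.

    Biases are of the size estimated in the six-lab calibration, except that
    fixed biases are capped below the lowest dilution point (30.3 pmol/L) so
    the inverse bias map yields positive readings over the whole curve.
    """
    capped = dict(table2_like_biases())
    capped["lab5"] = (25.0, 1.02)
    return {lab: (a, b, PLATFORM_CVS[lab]) for lab, (a, b) in capped.items()}


@dataclass(frozen=True)
class CalibrationSimConfig:
    """Configuration of a simulated multi-laboratory calibration experiment.

    ``labs`` maps lab_id -> (alpha_true, beta_true, cv); ``cv`` is the
    multiplicative assay coefficient of variation per reading.
    """

    true_values: tuple = DEFAULT_TRUE_CURVE
    labs: dict[str, tuple[float, float, float]] = field(
        default_factory=default_calibration_labs
    )
    duplicates: int = 2
    reference_lab: str = "lab1"
    seed: int = 0

    def __post_init__(self):
        tv = np.asarray(self.true_values, dtype=float)
        if np.any(tv <= 0):
            raise ValueError("true_values must be strictly positive")
        for lab, (a, b, cv) in self.labs.items():
            if b <= 0:
                raise ValueError(f"{lab}: beta_true must be > 0")
            if cv < 0:
                raise ValueError(f"{lab}: cv must be >= 0")
        if self.duplicates < 1:
            raise ValueError("duplicates must be >= 1")


def generate_calibration_experiment(
    config: CalibrationSimConfig,
) -> dict[str, CalibrationSeries]:
    """Simulate each laboratory's readings of the shared dilution series.

    A lab with bias (alpha, beta) reads ``r = (true - alpha) / beta``; each
    of the ``duplicates`` readings is perturbed by multiplicative Gaussian
    noise ``1 + cv * z`` and the duplicates are averaged into the series.

    Every returned series pairs the lab's averaged readings against the
    *reference laboratory's* averaged readings — both axes carry measurement
    error, as in the real experiment and as OLP regression assumes.  If the
    reference lab is not among ``config.labs`` (or its cv is 0) the
    reference axis equals the design values.
    """
    rng = np.random.default_rng(config.seed)
    true = np.asarray(config.true_values, dtype=float)
    n = true.size
    ids = tuple(chr(ord("A") + i) if n <= 26 else f"S{i}" for i in range(n))

    def draw(alpha, beta, cv):
        base = (true - alpha) / beta
        if np.any(base <= 0):
            raise ValueError("injected bias drives readings non-positive")
        reps = base[:, None] * (1.0 + cv * rng.standard_normal((n, config.duplicates)))
        reps = np.maximum(reps, 1e-6)  # assay readings cannot be <= 0
        return reps

    readings = {}
    for lab, (alpha, beta, cv) in config.labs.items():
        try:
            readings[lab] = draw(alpha, beta, cv)
        except ValueError as exc:
            raise ValueError(f"{lab}: {exc}") from None
    ref = (readings[config.reference_lab].mean(axis=1)
           if config.reference_lab in readings else true)

    out: dict[str, CalibrationSeries] = {}
    for lab, reps in readings.items():
        out[lab] = CalibrationSeries(
            sample_ids=ids,
            reference=ref,
            test=reps.mean(axis=1),
            lab_id=lab,
            replicate_values=tuple(tuple(row) for row in reps),
        )
    return out


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of a synthetic three-group study cohort.

    Defaults emulate the published cohort structure: 627 malignant / 583
    benign / 299 healthy women, group-specific ages (truncated to the 18-70
    eligibility window), menopause proportions, creatinine, and lognormal
    HE4/CA125 moment-matched to the published group means and SDs.
    ``menopause_separation`` adds that many log-SDs to malignant
    post-menopausal log-HE4, making the marker more discriminating in the
    post-menopausal stratum.  ``lab_biases`` distorts raw HE4 by hospital
    (identity by default).  ``contaminate`` appends that many
    eligibility-violating records for filter testing.
    """

    group_sizes: tuple[int, int, int] = (627, 583, 299)
    menopause_props: tuple[float, float, float] = (0.754, 0.377, 0.482)
    age_params: tuple = ((59.4, 13.8), (47.3, 13.9), (46.6, 13.0))
    he4_moments: tuple = ((474.1, 1207.0), (59.7, 62.1), (45.7, 14.7))
    ca125_moments: tuple = ((610.4, 1500.0), (30.1, 65.9), (15.4, 11.9))
    creatinine_params: tuple = ((0.8, 0.2), (0.7, 0.2), (0.7, 0.1))
    menopause_separation: float = 0.5
    creatinine_effect: float = 0.0
    menopause_level_effect: float = 0.0
    hospitals: tuple[str, ...] = ("lab1", "lab2", "lab3", "lab4", "lab5", "lab6")
    lab_biases: dict[str, tuple[float, float]] | None = None
    benign_subtype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "ovarian_lesion": 0.30, "endometriosis": 0.20, "fibroma": 0.18,
            "annexal_lesion": 0.08, "peritoneal_lesion": 0.04,
            "endometrial_polyp": 0.10, "hemorrhagic_corpus_luteum": 0.06,
            "other": 0.04,
        }
    )
    contaminate: int = 0
    seed: int = 0

    def __post_init__(self):
        if any(s < 0 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 0")
        if any(not 0 <= p <= 1 for p in self.menopause_props):
            raise ValueError("menopause proportions must lie in [0, 1]")
        for m, s in list(self.he4_moments) + list(self.ca125_moments):
            if m <= 0 or s <= 0:
                raise ValueError("marker moments must be positive")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Draw a synthetic cohort; one row per subject.

    Columns: subject_id, group, subtype, age, menopausal, creatinine,
    he4_true (reference-scale), he4_raw (hospital-distorted), ca125,
    hospital.  Menopause is forced consistent with age (never below 40,
    always above 55) so generated records pass the eligibility screen.
    """
    rng = np.random.default_rng(config.seed)
    biases = config.lab_biases or {h: (0.0, 1.0) for h in config.hospitals}
    frames = []
    counter = 0
    for g_idx, group in enumerate(GROUPS):
        n = config.group_sizes[g_idx]
        if n == 0:
            continue
        age_mean, age_sd = config.age_params[g_idx]
        age = _truncated_normal(rng, age_mean, age_sd, 18.0, 70.0, n)
        meno = rng.random(n) < config.menopause_props[g_idx]
        meno = np.where(age < 40, False, np.where(age > 55, True, meno))
        cr_mean, cr_sd = config.creatinine_params[g_idx]
        creat = _truncated_normal(rng, cr_mean, cr_sd, 0.301, 3.0, n)

        mu_h, sg_h = lognormal_params_from_moments(*config.he4_moments[g_idx])
        log_he4 = mu_h + sg_h * rng.standard_normal(n)
        if group == "malignant" and config.menopause_separation:
            log_he4 = log_he4 + config.menopause_separation * sg_h * meno
        log_he4 = (log_he4
                   + config.menopause_level_effect * meno
                   + config.creatinine_effect * (creat - np.mean(creat)))
        he4_true = np.exp(log_he4)

        mu_c, sg_c = lognormal_params_from_moments(*config.ca125_moments[g_idx])
        ca125 = np.exp(mu_c + sg_c * rng.standard_normal(n))

        hospital = rng.choice(config.hospitals, size=n)
        alpha = np.array([biases[h][0] for h in hospital])
        beta = np.array([biases[h][1] for h in hospital])
        he4_raw = np.maximum((he4_true - alpha) / beta, 1e-6)

        if group == "benign":
            labels = list(config.benign_subtype_mix)
            probs = np.array(list(config.benign_subtype_mix.values()), dtype=float)
            subtype = rng.choice(labels, size=n, p=probs / probs.sum())
        elif group == "malignant":
            subtype = np.full(n, "ovarian_cancer")
        else:
            subtype = np.full(n, "")

        frames.append(pd.DataFrame({
            "subject_id": [f"S{counter + i:05d}" for i in range(n)],
            "group": group,
            "subtype": subtype,
            "age": np.round(age, 1),
            "menopausal": meno,
            "creatinine": np.round(creat, 3),
            "he4_true": he4_true,
            "he4_raw": he4_raw,
            "ca125": ca125,
            "hospital": hospital,
        }))
        counter += n

    df = pd.concat(frames, ignore_index=True)
    if config.contaminate:
        df = pd.concat([df, _contaminated_records(rng, config, counter)],
                       ignore_index=True)
    return df


def _contaminated_records(rng, config, start) -> pd.DataFrame:
    """Records that each violate exactly one eligibility rule."""
    n = config.contaminate
    violations = ["creatinine_low", "creatinine_high", "age_young", "age_old",
                  "premeno_over55", "missing_age", "missing_group"]
    rows = []
    for i in range(n):
        v = violations[i % len(violations)]
        row = {
            "subject_id": f"X{start + i:05d}", "group": "benign",
            "subtype": "other", "age": 45.0, "menopausal": True,
            "creatinine": 0.8, "he4_true": 50.0, "he4_raw": 50.0,
            "ca125": 20.0, "hospital": config.hospitals[0],
        }
        if v == "creatinine_low":
            row["creatinine"] = 0.25
        elif v == "creatinine_high":
            row["creatinine"] = 3.5
        elif v == "age_young":
            row["age"] = 16.0
        elif v == "age_old":
            row["age"] = 75.0
        elif v == "premeno_over55":
            row["age"], row["menopausal"] = 58.0, False
        elif v == "missing_age":
            row["age"] = np.nan
        elif v == "missing_group":
            row["group"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
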