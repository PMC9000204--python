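"""Empirical ROC curves, Youden cut-offs and the DeLong paired AUC test.

Positivity is strict ``>`` throughout (a value equal to the cut-off is
negative), matching the conventional CA125 rule "positive if > 35 IU/mL".
Ties between a case and a control count one half toward the AUC, so the
trapezoidal area equals the Mann-Whitney probability estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocCurve",
    "CutoffResult",
    "AucComparison",
    "empirical_roc",
    "youden_cutoff",
    "dichotomize",
    "auc_equality_test",
]


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.dtype == bool:
        is_case = labels
    else:
        uniq = set(np.unique(labels).tolist())
        if not uniq <= {"case", "control"}:
            raise ValueError("labels must be boolean or 'case'/'control'")
        is_case = labels == "case"
    cases = scores[is_case]
    controls = scores[~is_case]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both cases and controls must be present")
    return cases, controls


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: (fpr, tpr) over all observed thresholds."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, **kwargs)
        ax.plot([0, 1], [0, 1], ls=":", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        return ax


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal marker cut-off and its operating characteristics."""

    cutoff: float
    youden: float
    sensitivity: float
    specificity: float
    rounded: bool

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "youden": self.youden,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "rounded": self.rounded,
        }


@dataclass(frozen=True)
class AucComparison:
    """Paired comparison of two AUCs measured on the same subjects."""

    auc_a: float
    auc_b: float
    difference: float
    variance: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "auc_a": self.auc_a,
            "auc_b": self.auc_b,
            "difference": self.difference,
            "variance": self.variance,
            "p_value": self.p_value,
        }


def empirical_roc(scores, labels) -> RocCurve:
    """Empirical ROC over all unique observed thresholds, strict ">" rule.

    The curve starts at (0, 0) (threshold above every score) and ends at
    (1, 1); the AUC is the trapezoidal area, identical to the Mann-Whitney
    U statistic divided by ``n_cases * n_controls`` with ties counted half.
    """
    cases, controls = _split(scores, labels)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(np.mean(cases > t))
        fpr.append(np.mean(controls > t))
    # lowest point: everything positive
    tpr.append(1.0)
    fpr.append(1.0)
    fpr_arr = np.array(fpr)
    tpr_arr = np.array(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(
        thresholds=thresholds[::-1].copy(), fpr=fpr_arr, tpr=tpr_arr,
        auc=auc, n_cases=cases.size, n_controls=controls.size,
    )


def youden_cutoff(scores, labels, rounding: str = "integer") -> CutoffResult:
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Every observed score is evaluated as a strict ">" threshold; among
    equal-J thresholds the smallest is returned (it maximizes sensitivity).
    With ``rounding="integer"`` the selected cut-off is rounded to the
    nearest integer unit after maximization.
    """
    if rounding not in ("integer", "none"):
        raise ValueError(f"unknown rounding {rounding!r}")
    cases, controls = _split(scores, labels)
    thresholds = np.unique(np.concatenate([cases, controls]))
    sens = np.array([np.mean(cases > t) for t in thresholds])
    spec = np.array([np.mean(controls <= t) for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    cutoff = float(thresholds[best])
    rounded = rounding == "integer"
    if rounded:
        cutoff = float(round(cutoff))
    return CutoffResult(
        cutoff=cutoff, youden=float(j[best]),
        sensitivity=float(sens[best]), specificity=float(spec[best]),
        rounded=rounded,
    )


def dichotomize(values, cutoff: float) -> np.ndarray:
    """Binary positivity indicators: positive iff value > cutoff (strict)."""
    vals = np.asarray(values, dtype=float)
    return (vals > cutoff).astype(int)


def _placement_components(cases: np.ndarray, controls: np.ndarray):
    """DeLong structural components: per-case and per-control placements."""
    diff = cases[:, None] - controls[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)  # one per case
    v01 = psi.mean(axis=0)  # one per control
    return psi.mean(), v10, v01


def auc_equality_test(scores_a, scores_b, labels) -> AucComparison:
    """DeLong's paired test for equality of two AUCs on the same subjects.

    Both markers must be measured on the same cases and controls (paired
    design); the covariance between the two AUC estimators is accounted for
    through the empirical placement components.
    """
    cases_a, controls_a = _split(scores_a, labels)
    cases_b, controls_b = _split(scores_b, labels)
    m, n = cases_a.size, controls_a.size

    auc_a, v10_a, v01_a = _placement_components(cases_a, controls_a)
    auc_b, v10_b, v01_b = _placement_components(cases_b, controls_b)

    # covariance matrices of (auc_a, auc_b) from case and control components
    s10 = np.cov(np.vstack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = float(auc_a - auc_b)

    if var <= 0:
        if abs(diff) > 1e-12:
            raise ValueError(
                "zero variance of the AUC difference with a nonzero difference; "
                "the paired test is undefined"
            )
        warnings.warn("identical AUCs with zero variance; p-value set to 1",
                      stacklevel=2)
        return AucComparison(float(auc_a), float(auc_b), 0.0, 0.0, 1.0)

    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(float(auc_a), float(auc_b), diff, float(var), p)
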