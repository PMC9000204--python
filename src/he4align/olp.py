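"""Ordinary least product (geometric-mean) regression for method comparison.

Two laboratories measuring the same samples both do so with error, so an
ordinary least squares line of one on the other is biased toward zero slope.
OLP regression treats the axes symmetrically: it minimizes the sum over
samples of |vertical deviation| x |horizontal deviation|, giving slope
``beta = sign(S_xy) * sqrt(S_yy / S_xx)`` and intercept
``alpha = mean(y) - beta * mean(x)``.

With ``y`` the reference laboratory and ``x`` a test laboratory, the fitted
line ``y = alpha + beta * x`` reads directly as a bias-correction equation:
``alpha`` is the *fixed* (constant) bias and ``beta`` the *proportional*
bias of the test laboratory, and ``alpha + beta * v`` maps a test-lab
measurement ``v`` onto the reference scale.  A fixed bias is declared when
the confidence interval for ``alpha`` excludes 0; a proportional bias when
the interval for ``beta`` excludes 1.

Analytic confidence intervals follow Ludbrook's construction:
``B = t^2 (1 - r^2) / (n - 2)`` with ``t`` the two-sided Student critical
value on ``n - 2`` df, slope bounds ``beta * (sqrt(B + 1) -/+ sqrt(B))`` and
intercept bounds obtained by pairing the extreme slope with the means.  A
pairs bootstrap (percentile) is available as a robustness check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationSeries",
    "BiasEstimate",
    "OLPRegression",
    "fit_olp",
    "classify_biases",
    "harmonize",
]


@dataclass(frozen=True)
class CalibrationSeries:
    """Paired measurements of shared calibration samples by two laboratories.

    Parameters
    ----------
    sample_ids : labels of the shared samples.
    reference : concentrations measured by the reference laboratory (pmol/L).
    test : concentrations measured by the test laboratory (pmol/L).
    lab_id : identifier of the test laboratory.
    replicate_values : optional per-sample duplicate readings; when given,
        ``test`` must equal their per-sample means.
    """

    sample_ids: tuple
    reference: np.ndarray
    test: np.ndarray
    lab_id: str
    replicate_values: tuple | None = None

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if ref.shape != tst.shape or ref.ndim != 1:
            raise ValueError("reference and test must be 1-d arrays of equal length")
        if len(self.sample_ids) != ref.size:
            raise ValueError("sample_ids length does not match measurements")
        if ref.size < 3:
            raise ValueError(f"need at least 3 samples, got {ref.size}")
        for name, arr in (("reference", ref), ("test", tst)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr <= 0):
                raise ValueError(f"{name} contains non-positive concentrations")
        if self.replicate_values is not None:
            reps = tuple(tuple(float(v) for v in r) for r in self.replicate_values)
            object.__setattr__(self, "replicate_values", reps)
            if len(reps) != ref.size:
                raise ValueError("replicate_values length does not match samples")
            means = np.array([np.mean(r) for r in reps])
            if not np.allclose(means, tst, rtol=1e-9, atol=1e-9):
                raise ValueError("test values must equal per-sample replicate means")

    @property
    def n(self) -> int:
        return int(self.reference.size)


@dataclass(frozen=True)
class BiasEstimate:
    """Fitted fixed/proportional bias of one laboratory vs the reference."""

    lab_id: str
    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    r: float
    n: int
    confidence: float = 0.95
    ci_method: str = "analytic"

    @property
    def fixed_bias_significant(self) -> bool:
        lo, hi = self.alpha_ci
        return not (lo <= 0.0 <= hi)

    @property
    def proportional_bias_significant(self) -> bool:
        lo, hi = self.beta_ci
        return not (lo <= 1.0 <= hi)

    def predict(self, values: Sequence[float]) -> np.ndarray:
        """Map test-laboratory values onto the reference scale."""
        return self.alpha + self.beta * np.asarray(values, dtype=float)

    def to_dict(self) -> dict:
        return {
            "lab_id": self.lab_id,
            "alpha": self.alpha,
            "beta": self.beta,
            "alpha_ci": list(self.alpha_ci),
            "beta_ci": list(self.beta_ci),
            "r": self.r,
            "n": self.n,
            "confidence": self.confidence,
            "ci_method": self.ci_method,
            "fixed_bias_significant": self.fixed_bias_significant,
            "proportional_bias_significant": self.proportional_bias_significant,
        }

    def summary(self) -> str:
        lines = [
            f"OLP bias estimate: {self.lab_id} vs reference (n={self.n})",
            f"  fixed bias        alpha = {self.alpha:8.3f}  "
            f"{100 * self.confidence:.0f}% CI ({self.alpha_ci[0]:.3f}, {self.alpha_ci[1]:.3f})"
            f"  {'SIGNIFICANT' if self.fixed_bias_significant else 'ns'}",
            f"  proportional bias beta  = {self.beta:8.4f}  "
            f"{100 * self.confidence:.0f}% CI ({self.beta_ci[0]:.4f}, {self.beta_ci[1]:.4f})"
            f"  {'SIGNIFICANT' if self.proportional_bias_significant else 'ns'}",
            f"  Pearson r = {self.r:.4f}   CI method: {self.ci_method}",
        ]
        return "\n".join(lines)


def _olp_point(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Return (alpha, beta, r) of the OLP line y = alpha + beta * x."""
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    sxy = float(xd @ yd)
    beta = float(np.sign(sxy) if sxy != 0 else 1.0) * np.sqrt(syy / sxx)
    alpha = float(y.mean() - beta * x.mean())
    r = sxy / np.sqrt(sxx * syy)
    return alpha, float(beta), float(r)


class OLPRegression:
    """Ordinary least product regression model ``reference = alpha + beta * test``.

    Parameters
    ----------
    series : CalibrationSeries, or pass ``reference``/``test`` arrays directly.
    """

    def __init__(self, series: CalibrationSeries | None = None, *,
                 reference=None, test=None, lab_id: str = "test"):
        if series is None:
            if reference is None or test is None:
                raise ValueError("provide a CalibrationSeries or reference and test arrays")
            reference = np.asarray(reference, dtype=float)
            series = CalibrationSeries(
                sample_ids=tuple(range(len(reference))),
                reference=reference,
                test=np.asarray(test, dtype=float),
                lab_id=lab_id,
            )
        self.series = series

    def fit(self, confidence: float = 0.95, ci_method: str = "analytic",
            n_boot: int = 2000, seed: int | None = None) -> BiasEstimate:
        """Fit the OLP line and confidence intervals.

        ``ci_method`` is ``"analytic"`` (Ludbrook) or ``"bootstrap"``
        (pairs resampling, percentile intervals, ``n_boot`` replicates).
        """
        if not 0.0 < confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if ci_method not in ("analytic", "bootstrap"):
            raise ValueError(f"unknown ci_method {ci_method!r}")
        s = self.series
        x, y = s.test, s.reference
        if np.var(x) == 0:
            raise ValueError("test series has zero variance")
        if np.var(y) == 0:
            raise ValueError("reference series has zero variance")

        alpha, beta, r = _olp_point(x, y)
        if r <= 0:
            warnings.warn(
                f"lab {s.lab_id}: methods are non-positively correlated (r={r:.3f}); "
                "the fitted line is not a meaningful bias correction",
                stacklevel=2,
            )

        if ci_method == "analytic":
            alpha_ci, beta_ci = self._analytic_ci(x, y, beta, r, confidence)
        else:
            alpha_ci, beta_ci = self._bootstrap_ci(x, y, confidence, n_boot, seed)

        return BiasEstimate(
            lab_id=s.lab_id, alpha=alpha, beta=beta,
            alpha_ci=alpha_ci, beta_ci=beta_ci, r=r, n=s.n,
            confidence=confidence, ci_method=ci_method,
        )

    @staticmethod
    def _analytic_ci(x, y, beta, r, confidence):
        n = x.size
        t = stats.t.ppf(0.5 + confidence / 2.0, n - 2)
        B = t * t * (1.0 - r * r) / (n - 2)
        beta_lo = beta * (np.sqrt(B + 1.0) - np.sqrt(B))
        beta_hi = beta * (np.sqrt(B + 1.0) + np.sqrt(B))
        if beta < 0:
            beta_lo, beta_hi = beta_hi, beta_lo
        # extreme slopes paired with the means give the intercept bounds
        alpha_lo = float(y.mean() - beta_hi * x.mean())
        alpha_hi = float(y.mean() - beta_lo * x.mean())
        return (alpha_lo, alpha_hi), (float(beta_lo), float(beta_hi))

    @staticmethod
    def _bootstrap_ci(x, y, confidence, n_boot, seed):
        rng = np.random.default_rng(seed)
        n = x.size
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, yb = x[idx], y[idx]
        xd = xb - xb.mean(axis=1, keepdims=True)
        yd = yb - yb.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", xd, xd)
        syy = np.einsum("ij,ij->i", yd, yd)
        sxy = np.einsum("ij,ij->i", xd, yd)
        ok = (sxx > 0) & (syy > 0)
        sign = np.where(sxy[ok] != 0, np.sign(sxy[ok]), 1.0)
        betas = sign * np.sqrt(syy[ok] / sxx[ok])
        alphas = yb[ok].mean(axis=1) - betas * xb[ok].mean(axis=1)
        lo = 100 * (0.5 - confidence / 2.0)
        hi = 100 * (0.5 + confidence / 2.0)
        a_ci = np.percentile(alphas, [lo, hi])
        b_ci = np.percentile(betas, [lo, hi])
        return (float(a_ci[0]), float(a_ci[1])), (float(b_ci[0]), float(b_ci[1]))


def fit_olp(series: CalibrationSeries, confidence: float = 0.95,
            ci_method: str = "analytic", n_boot: int = 2000,
            seed: int | None = None) -> BiasEstimate:
    """Functional wrapper: fit OLP bias model for one laboratory."""
    return OLPRegression(series).fit(confidence=confidence, ci_method=ci_method,
                                     n_boot=n_boot, seed=seed)


def classify_biases(estimates: Sequence[BiasEstimate],
                    reference_lab: str | None = None) -> dict[str, str]:
    """Classify each laboratory as 'none', 'fixed', 'proportional' or 'both'.

    The classification is the CI-containment rule: 0 outside the intercept CI
    flags a fixed bias, 1 outside the slope CI flags a proportional bias.
    The reference laboratory, if listed, is always 'none'.
    """
    if not estimates:
        raise ValueError("estimates must be non-empty")
    out: dict[str, str] = {}
    if reference_lab is not None:
        out[reference_lab] = "none"
    for est in estimates:
        if est.lab_id == reference_lab:
            continue
        fixed = est.fixed_bias_significant
        prop = est.proportional_bias_significant
        out[est.lab_id] = {
            (False, False): "none",
            (True, False): "fixed",
            (False, True): "proportional",
            (True, True): "both",
        }[(fixed, prop)]
    return out


def harmonize(values: Sequence[float], estimate: BiasEstimate,
              policy: str = "biased_only") -> np.ndarray:
    """Map test-laboratory measurements onto the reference scale.

    policy:
      * ``biased_only`` — apply ``alpha + beta * v`` only when the laboratory
        shows a significant fixed or proportional bias; otherwise pass through.
      * ``always`` — apply the correction unconditionally.
      * ``never`` — pass values through unchanged.

    Negative corrected concentrations (possible for small values with a
    negative intercept) are clamped to zero with a warning.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
        raise ValueError("values must be finite and non-negative")
    if policy not in ("biased_only", "always", "never"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "never":
        return vals.copy()
    if policy == "biased_only" and not (
        estimate.fixed_bias_significant or estimate.proportional_bias_significant
    ):
        return vals.copy()
    adj = estimate.predict(vals)
    neg = adj < 0
    if np.any(neg):
        warnings.warn(
            f"lab {estimate.lab_id}: {int(neg.sum())} harmonized value(s) fell below "
            "zero and were clamped to 0 pmol/L",
            stacklevel=2,
        )
        adj = np.where(neg, 0.0, adj)
    return adj
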