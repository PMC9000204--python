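"""Covariate-adjusted parametric ROC regression (two-stage ROC-GLM).

The model asks two distinct questions about a diagnostic marker:

1. *Control model* (stage 1): which covariates shift the marker level among
   disease-free subjects?  An ordinary least squares fit of the marker on
   the covariates in the control stratum; its residuals define the
   covariate-adjusted reference distribution.

2. *ROC model* (stage 2): which covariates shift the marker's discriminatory
   accuracy?  Each case is reduced to its placement value
   ``PV_i = 1 - F0(y_i - x_i' theta)`` — the fraction of the
   covariate-matched control distribution exceeding it, estimated with the
   empirical CDF of stage-1 residuals.  Over a grid of false-positive rates
   ``u`` the exceedance indicators ``U_iu = 1{PV_i <= u}`` follow
   ``P(U_iu = 1) = Phi(gamma0 + gamma1 * Phi^-1(u) + beta' X_i)``, a probit
   GLM whose coefficients describe vertical shifts of the ROC curve on the
   probit scale.  The covariate-specific ROC curve and its binormal AUC,
   ``Phi((gamma0 + beta'X) / sqrt(1 + gamma1^2))``, follow in closed form.

Uncertainty is assessed by a cluster bootstrap: whole clusters (hospitals)
are resampled with replacement and the two-stage procedure refitted, giving
percentile intervals that respect within-hospital correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtr, ndtri
from scipy import integrate

logger = logging.getLogger(__name__)

__all__ = [
    "ControlModelFit",
    "RocRegressionFit",
    "RocRegression",
    "fit_control_model",
    "placement_values",
    "fit_roc_glm",
    "covariate_adjusted_auc",
    "cluster_bootstrap",
    "default_fpr_grid",
]


def default_fpr_grid(size: int = 30) -> np.ndarray:
    """Equally spaced FPR grid {1/(size+1), ..., size/(size+1)} in (0, 1)."""
    return np.arange(1, size + 1) / (size + 1.0)


@dataclass(frozen=True)
class ControlModelFit:
    """Stage-1 OLS fit of the marker on covariates among controls."""

    coefficients: pd.Series  # 'const' plus one entry per covariate
    residuals: np.ndarray
    covariate_names: tuple[str, ...]
    n_controls: int

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(covariates[list(self.covariate_names)].astype(float),
                            has_constant="add")
        return X.to_numpy() @ self.coefficients.to_numpy()


@dataclass(frozen=True)
class RocRegressionFit:
    """Stage-2 probit ROC-GLM coefficients and supporting quantities."""

    gamma0: float
    gamma1: float
    covariate_betas: pd.Series
    fpr_grid: np.ndarray
    placement_values: np.ndarray
    n_cases: int
    bootstrap_cis: dict[str, tuple[float, float]] | None = None
    n_bootstrap: int = 0

    @property
    def params(self) -> pd.Series:
        base = pd.Series({"gamma0": self.gamma0, "gamma1": self.gamma1})
        return pd.concat([base, self.covariate_betas])

    def roc(self, u, covariate_values=None) -> np.ndarray:
        """Covariate-specific ROC curve evaluated at FPR values ``u``."""
        u = np.asarray(u, dtype=float)
        shift = self._covariate_shift(covariate_values)
        return ndtr(self.gamma0 + self.gamma1 * ndtri(u) + shift)

    def auc(self, covariate_values=None) -> float:
        """Closed-form binormal AUC at the given covariate values."""
        if self.gamma1 <= 0:
            raise ValueError("closed-form AUC requires gamma1 > 0")
        shift = self._covariate_shift(covariate_values)
        return float(ndtr((self.gamma0 + shift) / np.sqrt(1.0 + self.gamma1 ** 2)))

    def _covariate_shift(self, covariate_values) -> float:
        if len(self.covariate_betas) == 0:
            return 0.0
        if covariate_values is None:
            raise ValueError("covariate_values required for a model with covariates")
        x = np.asarray(covariate_values, dtype=float)
        return float(self.covariate_betas.to_numpy() @ x)


def fit_control_model(controls: pd.DataFrame, marker: str,
                      covariates: list[str]) -> ControlModelFit:
    """OLS fit of ``marker`` on ``covariates`` in the control stratum."""
    if len(controls) < 10:
        raise ValueError(f"need at least 10 controls, got {len(controls)}")
    y = controls[marker].astype(float).to_numpy()
    X = sm.add_constant(controls[list(covariates)].astype(float), has_constant="add")
    cond = np.linalg.cond(X.to_numpy())
    if cond > 1e8:
        raise ValueError(
            f"collinear control-model design (condition number {cond:.3g}) "
            f"for covariates {list(covariates)}; drop one of the correlated terms"
        )
    res = sm.OLS(y, X).fit()
    return ControlModelFit(
        coefficients=pd.Series(res.params, index=X.columns),
        residuals=np.asarray(res.resid, dtype=float),
        covariate_names=tuple(covariates),
        n_controls=len(controls),
    )


def placement_values(cases: pd.DataFrame, control_fit: ControlModelFit,
                     marker: str) -> np.ndarray:
    """Covariate-adjusted placement values of the cases.

    ``PV_i`` is the fraction of control residuals strictly greater than the
    case's residual ``y_i - x_i' theta``: the proportion of comparable
    controls exceeding the case measurement.  A highly elevated case has a
    placement value near 0.
    """
    if control_fit.residuals.size < 10:
        raise ValueError("control fit must retain at least 10 residuals")
    pred = control_fit.predict(cases)
    case_resid = cases[marker].astype(float).to_numpy() - pred
    resid = np.sort(control_fit.residuals)
    # fraction of control residuals strictly greater than each case residual
    n0 = resid.size
    pv = 1.0 - np.searchsorted(resid, case_resid, side="right") / n0
    return pv


def fit_roc_glm(pv: np.ndarray, case_covariates: pd.DataFrame | None,
                fpr_grid: np.ndarray | None = None,
                n_controls: int | None = None,
                start_params: np.ndarray | None = None) -> RocRegressionFit:
    """Fit the probit ROC-GLM to placement-value exceedance indicators.

    Placement values of exactly 0 (or 1) are floored at ``1/(2 n0)`` (capped
    at ``1 - 1/(2 n0)``) only while building the binary response, so the
    indicator is not degenerate at the grid ends; reported placement values
    are unmodified.
    """
    pv = np.asarray(pv, dtype=float)
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("placement values must lie in [0, 1]")
    if fpr_grid is None:
        fpr_grid = default_fpr_grid()
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    if np.any((fpr_grid <= 0) | (fpr_grid >= 1)) or np.any(np.diff(fpr_grid) <= 0):
        raise ValueError("fpr_grid must be strictly increasing within (0, 1)")

    eps = 1.0 / (2.0 * n_controls) if n_controls else 1e-6
    pv_clip = np.clip(pv, eps, 1.0 - eps)
    if np.all(pv_clip <= fpr_grid[0]) or np.all(pv_clip > fpr_grid[-1]):
        raise ValueError(
            "degenerate placement values (all cases at one extreme); "
            "the ROC-GLM is separated — jitter the marker or add data"
        )

    n_cases = pv.size
    n_grid = fpr_grid.size
    # response: one row per (case, grid point)
    U = (pv_clip[:, None] <= fpr_grid[None, :]).astype(float).ravel()
    cols = {"gamma0": np.ones(n_cases * n_grid),
            "gamma1": np.tile(ndtri(fpr_grid), n_cases)}
    cov_names: tuple[str, ...] = ()
    if case_covariates is not None and case_covariates.shape[1] > 0:
        cov_names = tuple(case_covariates.columns)
        Xc = case_covariates.astype(float).to_numpy()
        for j, name in enumerate(cov_names):
            cols[name] = np.repeat(Xc[:, j], n_grid)
    X = pd.DataFrame(cols)

    model = sm.GLM(U, X, family=sm.families.Binomial(link=sm.families.links.Probit()))
    try:
        res = model.fit(maxiter=200, start_params=start_params)
    except Exception as exc:  # statsmodels raises PerfectSeparation or LinAlg errors
        raise RuntimeError(f"ROC-GLM failed to converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError("ROC-GLM did not converge within 200 iterations")

    params = pd.Series(res.params, index=X.columns)
    return RocRegressionFit(
        gamma0=float(params["gamma0"]),
        gamma1=float(params["gamma1"]),
        covariate_betas=params[list(cov_names)].astype(float),
        fpr_grid=fpr_grid,
        placement_values=pv,
        n_cases=n_cases,
    )


def covariate_adjusted_auc(fit: RocRegressionFit, covariate_values=None) -> float:
    """Binormal AUC ``Phi((gamma0 + beta'X) / sqrt(1 + gamma1^2))``."""
    return fit.auc(covariate_values)


def _auc_by_quadrature(fit: RocRegressionFit, covariate_values=None) -> float:
    """Numeric integral of the fitted ROC over (0, 1); cross-check oracle."""
    val, _ = integrate.quad(lambda u: fit.roc(u, covariate_values), 0.0, 1.0,
                            limit=200)
    return float(val)


def cluster_bootstrap(fit_procedure, records: pd.DataFrame, cluster_field: str,
                      n_reps: int, seed: int,
                      confidence: float = 0.95) -> dict:
    """Percentile CIs from a cluster bootstrap of a fitting procedure.

    ``fit_procedure(df) -> pd.Series`` maps a resampled cohort to a
    coefficient vector.  Each replicate draws clusters (e.g. hospitals) with
    replacement — as many as there are distinct clusters — and refits; the
    replicate RNG is derived deterministically from ``seed`` plus the
    replicate index.  Replicates where the procedure fails (e.g. a resample
    with no cases) are discarded and logged; more than 20% discarded is an
    error.
    """
    clusters = records[cluster_field].unique()
    if len(clusters) < 2:
        raise ValueError("cluster bootstrap requires at least 2 clusters")
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")

    groups = {c: records[records[cluster_field] == c] for c in clusters}
    estimates: list[pd.Series] = []
    discarded = 0
    for i in range(n_reps):
        # (seed, index) pair -> independent substream per replicate; adjacent
        # seeds do not share replicate streams
        rng = np.random.default_rng((int(seed), i))
        chosen = rng.choice(clusters, size=len(clusters), replace=True)
        sample = pd.concat([groups[c] for c in chosen], ignore_index=True)
        try:
            estimates.append(fit_procedure(sample))
        except (ValueError, RuntimeError) as exc:
            discarded += 1
            logger.warning("bootstrap replicate %d discarded: %s", i, exc)
    if discarded > 0.2 * n_reps:
        raise RuntimeError(
            f"{discarded}/{n_reps} bootstrap replicates discarded; "
            "the resampling design is too fragile for these data"
        )

    mat = pd.DataFrame(estimates)
    lo = 100 * (0.5 - confidence / 2.0)
    hi = 100 * (0.5 + confidence / 2.0)
    cis = {
        col: (float(np.percentile(mat[col], lo)), float(np.percentile(mat[col], hi)))
        for col in mat.columns
    }
    return {"cis": cis, "n_used": len(estimates), "n_discarded": discarded,
            "replicates": mat}


class RocRegression:
    """Two-stage covariate-adjusted ROC regression model.

    Parameters
    ----------
    data : cohort DataFrame, one row per subject.
    marker : column with the diagnostic marker (e.g. harmonized HE4).
    status : boolean column marking cases (diseased) vs controls.
    covariates : columns entering both the control model and the ROC model.
    cluster : column identifying bootstrap clusters (e.g. hospital); required
        for interval estimation.
    """

    def __init__(self, data: pd.DataFrame, marker: str, status: str,
                 covariates: list[str] | tuple[str, ...] = (),
                 cluster: str | None = None,
                 fpr_grid: np.ndarray | None = None):
        self.data = data
        self.marker = marker
        self.status = status
        self.covariates = list(covariates)
        self.cluster = cluster
        self.fpr_grid = (default_fpr_grid() if fpr_grid is None
                         else np.asarray(fpr_grid, dtype=float))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, *, marker: str,
                       case_group: str = "malignant", group: str = "group",
                       covariates=(), cluster: str | None = None,
                       fpr_grid=None) -> "RocRegression":
        """Build from a cohort table with a categorical group column."""
        df = data.copy()
        df["_is_case"] = df[group] == case_group
        return cls(df, marker=marker, status="_is_case", covariates=covariates,
                   cluster=cluster, fpr_grid=fpr_grid)

    def _two_stage(self, df: pd.DataFrame,
                   start_params=None) -> tuple[ControlModelFit, RocRegressionFit]:
        is_case = df[self.status].astype(bool)
        controls = df[~is_case]
        cases = df[is_case]
        if len(cases) == 0 or len(controls) == 0:
            raise ValueError("need both cases and controls")
        cfit = fit_control_model(controls, self.marker, self.covariates)
        pv = placement_values(cases, cfit, self.marker)
        X = cases[self.covariates] if self.covariates else None
        rfit = fit_roc_glm(pv, X, self.fpr_grid, n_controls=cfit.n_controls,
                           start_params=start_params)
        return cfit, rfit

    def fit(self, n_boot: int = 50, seed: int = 0) -> "RocRegressionResults":
        """Fit both stages; cluster-bootstrap CIs when a cluster is set."""
        cfit, rfit = self._two_stage(self.data)

        boot = None
        if self.cluster is not None and n_boot >= 2:
            start = rfit.params.to_numpy()  # warm-start bootstrap refits

            def proc(df: pd.DataFrame) -> pd.Series:
                _, r = self._two_stage(df, start_params=start)
                return r.params

            boot = cluster_bootstrap(proc, self.data, self.cluster,
                                     n_reps=n_boot, seed=seed)
            rfit = RocRegressionFit(
                gamma0=rfit.gamma0, gamma1=rfit.gamma1,
                covariate_betas=rfit.covariate_betas, fpr_grid=rfit.fpr_grid,
                placement_values=rfit.placement_values, n_cases=rfit.n_cases,
                bootstrap_cis=boot["cis"], n_bootstrap=boot["n_used"],
            )
        return RocRegressionResults(self, cfit, rfit, boot)


class RocRegressionResults:
    """Fitted two-stage ROC regression: estimates, intervals, diagnostics."""

    def __init__(self, model: RocRegression, control_fit: ControlModelFit,
                 roc_fit: RocRegressionFit, bootstrap: dict | None):
        self.model = model
        self.control_fit = control_fit
        self.roc_fit = roc_fit
        self.bootstrap = bootstrap

    @property
    def params(self) -> pd.Series:
        return self.roc_fit.params

    def auc(self, covariate_values=None) -> float:
        return self.roc_fit.auc(covariate_values)

    def roc(self, u, covariate_values=None) -> np.ndarray:
        return self.roc_fit.roc(u, covariate_values)

    def to_dict(self) -> dict:
        out = {
            "control_model": {
                "n": self.control_fit.n_controls,
                "coefficients": {k: float(v)
                                 for k, v in self.control_fit.coefficients.items()},
            },
            "roc_model": {
                "n_cases": self.roc_fit.n_cases,
                "gamma0": self.roc_fit.gamma0,
                "gamma1": self.roc_fit.gamma1,
                "covariate_betas": {k: float(v)
                                    for k, v in self.roc_fit.covariate_betas.items()},
                "n_bootstrap": self.roc_fit.n_bootstrap,
            },
        }
        if self.roc_fit.bootstrap_cis is not None:
            out["roc_model"]["bootstrap_cis"] = {
                k: list(v) for k, v in self.roc_fit.bootstrap_cis.items()
            }
        return out

    def summary(self) -> str:
        lines = [
            "Two-stage ROC regression",
            f"  stage 1 (control model, OLS, n = {self.control_fit.n_controls}):",
        ]
        for name, val in self.control_fit.coefficients.items():
            lines.append(f"    {name:<14s} {val:10.4f}")
        lines.append(
            f"  stage 2 (ROC-GLM, probit link, {self.roc_fit.n_cases} cases x "
            f"{self.roc_fit.fpr_grid.size} grid points):"
        )
        cis = self.roc_fit.bootstrap_cis or {}
        for name, val in self.params.items():
            if name in cis:
                lo, hi = cis[name]
                lines.append(f"    {name:<14s} {val:10.4f}  [{lo:.4f}, {hi:.4f}]"
                             f" ({self.roc_fit.n_bootstrap} cluster-bootstrap reps)")
            else:
                lines.append(f"    {name:<14s} {val:10.4f}")
        return "\n".join(lines)

    def plot_roc(self, covariate_values=None, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        u = np.linspace(0.001, 0.999, 200)
        ax.plot(u, self.roc(u, covariate_values), **kwargs)
        ax.plot([0, 1], [0, 1], ls=":", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        return ax
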