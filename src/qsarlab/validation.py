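"""Internal/external validation statistics and applicability-domain analysis.

All coefficient-of-determination style statistics here follow the QSAR
convention of referencing the *training-set mean activity*: the external
R^2_pred compares test-set squared prediction errors against the spread of
the test observations about the training mean, and the leave-one-out Q^2
uses the training mean in its denominator.  Callers can override the
reference mean where a different convention is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, SingularityError
from .regression import design_matrix, fit_ols, LinearModel

__all__ = [
    "InternalValidation",
    "ExternalValidation",
    "DescriptorDiagnostics",
    "DomainAssessment",
    "GoldenCriteria",
    "r_squared",
    "adjusted_r2",
    "q2_loo",
    "external_r2pred",
    "mean_effect",
    "vif",
    "correlation_matrix",
    "leverage",
    "warning_leverage",
    "williams_data",
    "evaluate_against_criteria",
    "DEFAULT_CRITERIA",
]

#: leverage within this of 1 marks a leave-one-out refit as singular
_LOO_TOL = 1e-10

#: VIF above this flags an unstable, collinear equation
VIF_UNSTABLE = 10.0


def _as_array(v) -> np.ndarray:
    return np.asarray(v, dtype=float)


def r_squared(y_obs, y_pred, ref_mean: float | None = None) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    ``ref_mean`` is the mean the total sum of squares is taken about; it
    defaults to the mean of ``y_obs`` but should be the *training* mean when
    scoring external predictions.
    """
    y_obs, y_pred = _as_array(y_obs), _as_array(y_pred)
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise ValueError("need two equal-length vectors of >= 2 points")
    if ref_mean is None:
        ref_mean = float(y_obs.mean())
    ss_res = float(((y_obs - y_pred) ** 2).sum())
    ss_tot = float(((y_obs - ref_mean) ** 2).sum())
    if ss_tot == 0:
        raise DomainError("zero total sum of squares; R^2 undefined")
    return 1.0 - ss_res / ss_tot


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel-adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise DomainError(f"adjusted R^2 needs n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def q2_loo(X: pd.DataFrame, y: pd.Series, support=None) -> float:
    """Leave-one-out cross-validated Q^2.

    Each compound is dropped, the equation refitted on the rest, and the
    held-out compound predicted.  For least squares the deleted residual has
    the closed form e_i / (1 - h_i), which this uses; it is algebraically
    identical to literally refitting n times.
    """
    if support is not None:
        X = X.loc[:, list(support)]
    y = y.reindex(X.index)
    n, p = X.shape
    if n < p + 3:
        raise ValueError(f"need at least {p + 3} compounds for LOO, got {n}")
    model, stats = fit_ols(X, y)
    yhat = model.predict(X)
    resid = (y - yhat).to_numpy()
    h = leverage(X).to_numpy()
    near_one = np.nonzero(1.0 - h <= _LOO_TOL)[0]
    if near_one.size:
        cid = X.index[near_one[0]]
        raise SingularityError(
            f"leave-one-out design singular when holding out compound {cid!r}"
        )
    press = float(((resid / (1.0 - h)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DomainError("constant activities; Q^2 undefined")
    return 1.0 - press / ss_tot


@dataclass(frozen=True)
class ExternalValidation:
    """Test-set predictivity about the training-mean activity."""

    y_mintrn: float
    ss_res: float
    ss_tot: float
    r2_pred: float
    n_test: int


def external_r2pred(y_obs_test, y_pred_test, y_mintrn: float) -> ExternalValidation:
    """External validation R^2_pred = 1 - SS_res / SS_tot.

    SS_res sums squared prediction errors over the test set; SS_tot sums
    squared deviations of the test observations from the *training* mean
    activity ``y_mintrn``.
    """
    y_obs, y_pred = _as_array(y_obs_test), _as_array(y_pred_test)
    if y_obs.size == 0 or y_obs.shape != y_pred.shape:
        raise ValueError("need non-empty, equal-length test vectors")
    if not np.isfinite(y_mintrn):
        raise DomainError("training mean must be finite")
    ss_res = float(((y_obs - y_pred) ** 2).sum())
    ss_tot = float(((y_obs - y_mintrn) ** 2).sum())
    if ss_tot == 0:
        raise DomainError("zero external total sum of squares")
    return ExternalValidation(
        y_mintrn=float(y_mintrn),
        ss_res=ss_res,
        ss_tot=ss_tot,
        r2_pred=1.0 - ss_res / ss_tot,
        n_test=int(y_obs.size),
    )


def mean_effect(model: LinearModel, D: pd.DataFrame) -> pd.Series:
    """Normalised signed contribution of each descriptor.

    ME_j = beta_j * sum_i D_ij / sum_m (beta_m * sum_i D_im); the values are
    signed and sum to one.  ``D`` is the compound set the column sums run
    over (training, test or all compounds — a reporting choice).
    """
    missing = [d for d in model.descriptor_names if d not in D.columns]
    if missing:
        raise KeyError(f"descriptor column(s) missing: {missing}")
    col_sums = D.loc[:, list(model.descriptor_names)].sum(axis=0).to_numpy()
    contrib = np.asarray(model.coefficients) * col_sums
    denom = contrib.sum()
    if abs(denom) < 1e-300:
        raise DomainError("mean-effect denominator is zero")
    return pd.Series(
        contrib / denom, index=list(model.descriptor_names), name="mean_effect"
    )


def vif(D: pd.DataFrame, support=None) -> pd.Series:
    """Variance inflation factor per descriptor, 1 / (1 - R_j^2).

    R_j^2 comes from regressing descriptor j on the other descriptors of the
    support (with intercept).  Perfectly collinear descriptors are reported
    as ``inf`` rather than raising.  Values above 10 flag instability.
    """
    if support is not None:
        D = D.loc[:, list(support)]
    names = list(D.columns)
    if len(names) < 2:
        raise ValueError("VIF needs at least two descriptors")
    if len(D) <= len(names):
        raise ValueError("VIF needs more compounds than descriptors")
    values = D.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(names):
        others = np.delete(values, j, axis=1)
        A = np.column_stack([np.ones(len(D)), others])
        yj = values[:, j]
        beta, _, _, _ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ beta
        sst = ((yj - yj.mean()) ** 2).sum()
        if sst == 0:
            raise DomainError(f"descriptor {name!r} has zero variance")
        r2_j = 1.0 - float(resid @ resid) / float(sst)
        out[name] = float("inf") if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return pd.Series(out, name="vif")


def correlation_matrix(D: pd.DataFrame, support=None) -> pd.DataFrame:
    """Pairwise Pearson correlations between descriptors; diagonal exactly 1."""
    if support is not None:
        D = D.loc[:, list(support)]
    if len(D) < 2:
        raise ValueError("correlation needs at least two compounds")
    sd = D.to_numpy(dtype=float).std(axis=0, ddof=0)
    zero = [c for c, s in zip(D.columns, sd) if s == 0]
    if zero:
        raise DomainError(f"zero-variance descriptor column(s): {zero}")
    corr = D.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def leverage(
    X_train: pd.DataFrame, X_query: pd.DataFrame | None = None, support=None
) -> pd.Series:
    """Hat-matrix leverage h_i = x_i (X^T X)^{-1} x_i^T, intercept included.

    With no ``X_query`` the training leverages are returned (each in [0, 1],
    summing to k+1); otherwise the same quadratic form is evaluated for the
    query rows, which may exceed 1 outside the training domain.
    """
    if support is not None:
        X_train = X_train.loc[:, list(support)]
    A = design_matrix(X_train)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise SingularityError("training design is rank deficient")
    xtx_inv = np.linalg.inv(A.T @ A)
    if X_query is None:
        B, index = A, X_train.index
    else:
        B = design_matrix(X_query, support=list(X_train.columns))
        index = X_query.index
    h = np.einsum("ij,jk,ik->i", B, xtx_inv, B)
    return pd.Series(h, index=index, name="leverage")


def warning_leverage(k: int, n: int) -> float:
    """Warning leverage h* = 3(k + 1)/n for k descriptors, n train compounds."""
    if n <= 0:
        raise DomainError(f"train size must be positive, got {n}")
    return 3.0 * (k + 1) / n


@dataclass
class DomainAssessment:
    """Williams-plot data: leverage vs standardised residual per compound."""

    table: pd.DataFrame  # columns: leverage, std_residual, outlier, high_leverage, in_domain
    warning_leverage: float
    see: float

    @property
    def outliers(self) -> list:
        return list(self.table.index[self.table["outlier"]])

    @property
    def high_leverage(self) -> list:
        return list(self.table.index[self.table["high_leverage"]])


def williams_data(
    leverages: pd.Series,
    residuals: pd.Series,
    see: float,
    h_star: float,
    residual_limit: float = 3.0,
) -> DomainAssessment:
    """Assemble the applicability-domain table behind a Williams plot.

    Standardised residual is residual / SEE.  A compound is an activity
    outlier when |std residual| exceeds ``residual_limit`` (3 by convention)
    and structurally outside the domain when its leverage *strictly* exceeds
    the warning leverage h*.
    """
    leverages = pd.Series(leverages)
    residuals = pd.Series(residuals).reindex(leverages.index)
    if residuals.isna().any():
        raise ValueError("residuals and leverages must share compound ids")
    if see == 0:
        if (residuals != 0).any():
            raise DomainError("SEE is zero but residuals are not")
        std_res = residuals * 0.0
    else:
        std_res = residuals / see
    table = pd.DataFrame(
        {
            "leverage": leverages,
            "std_residual": std_res,
            "outlier": std_res.abs() > residual_limit,
            "high_leverage": leverages > h_star,
        }
    )
    table["in_domain"] = ~(table["outlier"] | table["high_leverage"])
    return DomainAssessment(table=table, warning_leverage=h_star, see=see)


@dataclass(frozen=True)
class InternalValidation:
    """Training-set fit and robustness statistics."""

    r2: float
    r2_adj: float
    see: float
    q2_loo: float
    n_train: int
    n_descriptors: int


@dataclass(frozen=True)
class DescriptorDiagnostics:
    """Collinearity and influence diagnostics of a model's descriptors."""

    correlation: pd.DataFrame
    vif: pd.Series
    mean_effect: pd.Series

    @property
    def unstable(self) -> bool:
        return bool((self.vif > VIF_UNSTABLE).any())


#: recommended minimum quality thresholds for a QSAR equation
DEFAULT_CRITERIA = {
    "r2_min": 0.6,
    "q2_min": 0.5,
    "r2_q2_gap_max": 0.3,
    "n_test_min": 5,
    "r2_ext_min": 0.5,
    "p_max": 0.05,
}


@dataclass
class GoldenCriteria:
    """Verdicts against the recommended QSAR quality thresholds.

    The confidence-level criterion (p < 0.05) is carried for completeness
    but reported as not evaluated unless a p-value is supplied.
    """

    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_CRITERIA))
    verdicts: dict = field(default_factory=dict)
    not_evaluated: list = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return all(self.verdicts.values())


def evaluate_against_criteria(
    internal: InternalValidation,
    external: ExternalValidation,
    n_test: int | None = None,
    p_value: float | None = None,
    thresholds: dict | None = None,
) -> GoldenCriteria:
    """Judge a model against the recommended quality thresholds.

    Checks R^2 >= 0.6, Q^2 >= 0.5, R^2 - Q^2 < 0.3, n_test >= 5 and
    R^2_ext >= 0.5; the p-value criterion is evaluated only when a p-value
    is given.
    """
    th = dict(DEFAULT_CRITERIA)
    if thresholds:
        th.update(thresholds)
    if n_test is None:
        n_test = external.n_test
    crit = GoldenCriteria(thresholds=th)
    crit.verdicts = {
        "r2": internal.r2 >= th["r2_min"],
        "q2": internal.q2_loo >= th["q2_min"],
        "r2_q2_gap": (internal.r2 - internal.q2_loo) < th["r2_q2_gap_max"],
        "n_test": n_test >= th["n_test_min"],
        "r2_ext": external.r2_pred >= th["r2_ext_min"],
    }
    if p_value is not None:
        crit.verdicts["p_value"] = p_value < th["p_max"]
    else:
        crit.not_evaluated.append("p_value")
    return crit
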