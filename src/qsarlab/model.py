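"""Model/Results facade tying the regression, validation and domain layers
together.

:class:`QsarModel` is constructed from a descriptor matrix and an activity
vector (aligned by compound id) and its :meth:`QsarModel.fit` returns a
:class:`QsarResults` that carries the fitted equation, its statistics, and
methods for every downstream judgement — internal and external validation,
collinearity diagnostics, applicability domain and the recommended-criteria
verdict — plus a plain-text ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import validation as val
from .regression import FitStats, LinearModel, fit_ols

__all__ = ["QsarModel", "QsarResults"]


class QsarModel:
    """A multiple-linear-regression QSAR model specification.

    Parameters
    ----------
    y : pandas.Series
        Activities (pIC50) indexed by compound id.
    X : pandas.DataFrame
        Descriptor matrix indexed by compound id.  Only compounds present
        in both ``X`` and ``y`` are used; pairing is by id, never position.
    support : sequence of str, optional
        Descriptor columns to regress on; defaults to all columns of ``X``.
    """

    def __init__(self, y: pd.Series, X: pd.DataFrame, support=None):
        ids = [i for i in X.index if i in set(y.index)]
        if len(ids) < 3:
            raise ValueError("fewer than 3 compounds shared by X and y")
        self.support = list(support) if support is not None else list(X.columns)
        self.X = X.loc[ids, self.support].copy()
        self.y = y.loc[ids].astype(float)

    @classmethod
    def from_frames(cls, activities: pd.DataFrame, descriptors: pd.DataFrame,
                    support=None, activity_column: str = "pic50") -> "QsarModel":
        return cls(activities[activity_column], descriptors, support=support)

    def fit(self, name: str = "") -> "QsarResults":
        model, stats = fit_ols(self.X, self.y, name=name)
        return QsarResults(self, model, stats)


class QsarResults:
    """Fitted QSAR equation plus every validation view of it."""

    def __init__(self, spec: QsarModel, model: LinearModel, stats: FitStats):
        self.spec = spec
        self.model = model
        self.stats = stats
        self.fittedvalues = model.predict(spec.X)
        self.resid = spec.y - self.fittedvalues

    # -- convenience accessors ---------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"intercept": self.model.intercept,
             **dict(zip(self.model.descriptor_names, self.model.coefficients))}
        )

    @property
    def nobs(self) -> int:
        return self.stats.n_obs

    @property
    def train_mean(self) -> float:
        return float(self.spec.y.mean())

    # -- validation views ---------------------------------------------------
    def internal_validation(self) -> val.InternalValidation:
        """Training R^2, adjusted R^2, SEE and leave-one-out Q^2."""
        return val.InternalValidation(
            r2=self.stats.r2,
            r2_adj=val.adjusted_r2(self.stats.r2, self.stats.n_obs,
                                   self.stats.n_params),
            see=self.stats.see,
            q2_loo=val.q2_loo(self.spec.X, self.spec.y),
            n_train=self.stats.n_obs,
            n_descriptors=self.stats.n_params,
        )

    def external_validation(
        self, X_test: pd.DataFrame, y_test: pd.Series,
        y_mintrn: float | None = None,
    ) -> val.ExternalValidation:
        """Predict held-out compounds and score them about the training mean."""
        y_pred = self.model.predict(X_test)
        y_obs = y_test.reindex(X_test.index)
        if y_obs.isna().any():
            missing = list(y_obs.index[y_obs.isna()])
            raise ValueError(f"no activity for test compounds: {missing}")
        if y_mintrn is None:
            y_mintrn = self.train_mean
        return val.external_r2pred(y_obs, y_pred, y_mintrn)

    def diagnostics(self, D: pd.DataFrame | None = None) -> val.DescriptorDiagnostics:
        """Correlation matrix, VIF and mean effect of the model descriptors.

        ``D`` chooses the compound set the statistics run over (defaults to
        the training set).
        """
        D = self.spec.X if D is None else D.loc[:, list(self.model.descriptor_names)]
        return val.DescriptorDiagnostics(
            correlation=val.correlation_matrix(D),
            vif=val.vif(D),
            mean_effect=val.mean_effect(self.model, D),
        )

    def applicability_domain(
        self, X_query: pd.DataFrame | None = None,
        y_query: pd.Series | None = None,
    ) -> val.DomainAssessment:
        """Williams-plot assessment of training (and optional query) compounds.

        Query compounds contribute leverages via the training hat matrix;
        their residuals require ``y_query``.
        """
        h_star = val.warning_leverage(self.stats.n_params, self.stats.n_obs)
        h = val.leverage(self.spec.X)
        resid = self.resid
        if X_query is not None:
            hq = val.leverage(self.spec.X, X_query)
            h = pd.concat([h, hq])
            if y_query is not None:
                rq = y_query.reindex(X_query.index) - self.model.predict(X_query)
                resid = pd.concat([resid, rq])
            else:
                resid = resid.reindex(h.index)  # query residuals unknown -> NaN
                resid = resid.fillna(0.0)
        return val.williams_data(h, resid, self.stats.see, h_star)

    def criteria(
        self, external: val.ExternalValidation | None = None,
        internal: val.InternalValidation | None = None,
        p_value: float | None = None,
    ) -> val.GoldenCriteria:
        internal = internal or self.internal_validation()
        if external is None:
            raise ValueError("external validation required for the criteria check")
        return val.evaluate_against_criteria(internal, external, p_value=p_value)

    # -- reporting ----------------------------------------------------------
    def summary(self, internal: val.InternalValidation | None = None) -> str:
        """Plain-text summary table of the equation and its statistics."""
        try:
            internal = internal or self.internal_validation()
            q2 = f"{internal.q2_loo:10.4f}"
            r2a = f"{internal.r2_adj:10.4f}"
        except Exception:  # tiny designs where LOO/adjustment is undefined
            q2 = r2a = "       n/a"
        lines = [
            "QSAR ordinary least squares",
            "=" * 46,
            f"{'No. observations:':<26}{self.stats.n_obs:>10}",
            f"{'No. descriptors:':<26}{self.stats.n_params:>10}",
            f"{'R-squared:':<26}{self.stats.r2:10.4f}",
            f"{'Adj. R-squared:':<26}{r2a:>10}",
            f"{'Q2 (LOO):':<26}{q2:>10}",
            f"{'SEE:':<26}{self.stats.see:10.4f}",
            f"{'Train mean pIC50:':<26}{self.train_mean:10.4f}",
            "-" * 46,
            f"{'term':<16}{'coefficient':>15}",
        ]
        lines.append(f"{'intercept':<16}{self.model.intercept:>15.6f}")
        for d, c in zip(self.model.descriptor_names, self.model.coefficients):
            lines.append(f"{d:<16}{c:>15.6f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        eq = self.model.equation()
        return f"<QsarResults n={self.stats.n_obs} r2={self.stats.r2:.4f} {eq}>"
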