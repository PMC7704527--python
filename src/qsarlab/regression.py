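"""Ordinary least squares on named descriptor subsets.

The regression equations this package manipulates are small (three to five
descriptors) multiple linear regressions of pIC50 on molecular descriptors,
always with an intercept.  :class:`LinearModel` stores such an equation by
descriptor *name* so a model fitted on one table can score any other table
carrying the same columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SingularityError

__all__ = ["LinearModel", "FitStats", "fit_ols", "design_matrix"]


@dataclass(frozen=True)
class LinearModel:
    """A fitted (or published) linear QSAR equation.

    ``prediction = intercept + sum_j coefficients[j] * X[descriptor_names[j]]``
    """

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    name: str = ""

    def __post_init__(self):
        if len(self.descriptor_names) != len(self.coefficients):
            raise ValueError("one coefficient per descriptor required")
        vals = (*self.coefficients, self.intercept)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite model parameters")
        object.__setattr__(self, "descriptor_names", tuple(self.descriptor_names))
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def predict(self, rows: pd.DataFrame) -> pd.Series:
        """Score each row of ``rows``; columns are matched by name."""
        missing = [d for d in self.descriptor_names if d not in rows.columns]
        if missing:
            raise KeyError(f"descriptor column(s) missing from input: {missing}")
        X = rows.loc[:, list(self.descriptor_names)].to_numpy(dtype=float)
        yhat = X @ np.asarray(self.coefficients) + self.intercept
        return pd.Series(yhat, index=rows.index, name="y_pred")

    def equation(self, target: str = "pIC50", ndigits: int = 6) -> str:
        terms = [
            f"{c:+.{ndigits}g}*{d}"
            for d, c in zip(self.descriptor_names, self.coefficients)
        ]
        return f"{target} = " + " ".join(terms) + f" {self.intercept:+.{ndigits}g}"

    # -- JSON persistence (floats round-trip exactly via repr) --------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "descriptors": list(self.descriptor_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            descriptor_names=tuple(d["descriptors"]),
            coefficients=tuple(d["coefficients"]),
            intercept=float(d["intercept"]),
            name=d.get("name", ""),
        )

    @classmethod
    def from_json(cls, source) -> "LinearModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FitStats:
    """Training-fit summary of a least-squares equation.

    ``see`` is the standard error of estimate, sqrt(SSE / (N - P - 1)) with
    N training compounds and P descriptors.
    """

    sse: float
    see: float
    r2: float
    n_obs: int
    n_params: int
    y_mean: float = field(default=float("nan"))


def design_matrix(X: pd.DataFrame, support=None) -> np.ndarray:
    """Descriptor columns (optionally restricted to ``support``) plus an
    intercept column, as a dense array."""
    if support is not None:
        X = X.loc[:, list(support)]
    values = X.to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), values])


def _independent_columns(A: np.ndarray) -> list[int]:
    """Indices of a maximal independent column subset, scanning left to right."""
    keep: list[int] = []
    for j in range(A.shape[1]):
        trial = A[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return keep


def fit_ols(
    X: pd.DataFrame, y: pd.Series | np.ndarray, support=None, name: str = ""
) -> tuple[LinearModel, FitStats]:
    """Least-squares fit of activity on the given descriptor columns.

    ``X`` rows and ``y`` must be aligned (same length; if ``y`` is a Series
    its index is reindexed onto ``X``).  Raises
    :class:`~qsarlab.errors.SingularityError` naming the dependent columns
    when the design is rank deficient.
    """
    if support is not None:
        X = X.loc[:, list(support)]
    if isinstance(y, pd.Series):
        y = y.reindex(X.index)
        if y.isna().any():
            missing = list(y.index[y.isna()])
            raise ValueError(f"no activity for compounds: {missing}")
        y = y.to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit {p} descriptors, got {n}")

    A = design_matrix(X)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        keep = _independent_columns(A)
        bad = [
            X.columns[j - 1] for j in range(1, A.shape[1]) if j not in keep
        ]
        raise SingularityError(
            f"rank-deficient design; dependent descriptor column(s): {bad}"
        )

    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ beta
    resid = y - yhat
    sse = float(resid @ resid)
    dof = n - p - 1
    see = float(np.sqrt(sse / dof)) if dof > 0 else float("nan")
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0

    model = LinearModel(
        descriptor_names=tuple(X.columns),
        coefficients=tuple(beta[1:]),
        intercept=float(beta[0]),
        name=name,
    )
    stats = FitStats(
        sse=sse, see=see, r2=r2, n_obs=n, n_params=p, y_mean=float(y.mean())
    )
    return model, stats
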