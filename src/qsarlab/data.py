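"""Ingestion, conversion, pretreatment and splitting of QSAR tables.

A *descriptor matrix* is represented throughout the package as a
:class:`pandas.DataFrame` whose index holds compound identifiers and whose
columns hold named molecular descriptors (as exported by a descriptor
calculator such as PaDEL).  Activities travel as a :class:`pandas.Series` of
pIC50 values indexed by compound id.  Row order never carries meaning:
pairing of activities with descriptors is always done by id.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError

__all__ = [
    "CompoundRecord",
    "PretreatReport",
    "DataSplit",
    "ic50_to_pic50",
    "pic50_to_ic50",
    "read_compound_table",
    "activities_series",
    "read_descriptor_matrix",
    "pretreat",
    "kennard_stone",
]

#: |pic50 - (6 - log10(ic50))| above which a row stating both is rejected.
CONSISTENCY_TOL = 1e-6


def ic50_to_pic50(ic50):
    """Convert an IC50 in micromolar to pIC50 = -log10(IC50 * 1e-6).

    Accepts scalars or array-likes; strictly positive, finite input required.
    The identity simplifies to ``6 - log10(ic50)`` on the micromolar scale.
    """
    arr = np.asarray(ic50, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"IC50 must be finite and > 0 (in uM); got {ic50!r}")
    out = 6.0 - np.log10(arr)
    return float(out) if np.isscalar(ic50) or arr.ndim == 0 else out


def pic50_to_ic50(pic50):
    """Inverse of :func:`ic50_to_pic50`: IC50 in uM = 10**(6 - pIC50)."""
    arr = np.asarray(pic50, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"pIC50 must be finite; got {pic50!r}")
    out = np.power(10.0, 6.0 - arr)
    return float(out) if np.isscalar(pic50) or arr.ndim == 0 else out


@dataclass
class CompoundRecord:
    """One compound's identity and activity.

    At least one of ``ic50`` (uM) / ``pic50`` must be present; when both are
    given they must agree through the log conversion.
    """

    compound_id: str
    ic50: float | None = None
    pic50: float | None = None
    is_validation: bool | None = None

    def __post_init__(self):
        if self.ic50 is None and self.pic50 is None:
            raise ParseError(
                f"compound {self.compound_id!r}: no activity (IC50 or pIC50) given"
            )
        if self.ic50 is not None:
            if not (math.isfinite(self.ic50) and self.ic50 > 0):
                raise DomainError(
                    f"compound {self.compound_id!r}: IC50 must be finite and > 0, "
                    f"got {self.ic50}"
                )
            converted = ic50_to_pic50(self.ic50)
            if self.pic50 is None:
                self.pic50 = converted
            elif abs(self.pic50 - converted) > CONSISTENCY_TOL:
                raise ParseError(
                    f"compound {self.compound_id!r}: inconsistent activities "
                    f"(IC50 {self.ic50} uM implies pIC50 {converted:.6f}, "
                    f"table says {self.pic50})"
                )


def _read_csv(source) -> pd.DataFrame:
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        source = io.StringIO(str(source))
    try:
        return pd.read_csv(source)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"could not read CSV: {exc}") from exc


def read_compound_table(source) -> list[CompoundRecord]:
    """Read a compound activity CSV into validated :class:`CompoundRecord`\\ s.

    The table must carry a compound-id column (named ``compound_id``, ``name``
    or ``id``, case-insensitive; otherwise the first column) and at least one
    of ``ic50`` / ``pic50``.  IC50 is interpreted in micromolar and converted.
    """
    df = _read_csv(source)
    cols = {c.lower().strip(): c for c in df.columns}
    id_col = next(
        (cols[k] for k in ("compound_id", "name", "id") if k in cols), df.columns[0]
    )
    ic50_col = cols.get("ic50")
    pic50_col = cols.get("pic50")
    if ic50_col is None and pic50_col is None:
        raise ParseError("no IC50 or pIC50 column found")

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for row_idx, row in df.iterrows():
        cid = str(row[id_col]).strip()
        if cid in seen:
            raise ParseError(f"duplicate compound id {cid!r}", row=row_idx)
        seen.add(cid)

        def _num(col, row_idx=row_idx, cid=cid):
            if col is None:
                return None
            val = row[col]
            if pd.isna(val) or (isinstance(val, str) and not val.strip()):
                return None
            try:
                return float(val)
            except (TypeError, ValueError):
                raise ParseError(
                    f"row {row_idx} (compound {cid!r}), column {col!r}: "
                    f"unparsable numeric {val!r}",
                    row=row_idx,
                    column=col,
                ) from None

        try:
            records.append(
                CompoundRecord(cid, ic50=_num(ic50_col), pic50=_num(pic50_col))
            )
        except (ParseError, DomainError):
            raise
    return records


def activities_series(records: list[CompoundRecord]) -> pd.Series:
    """Collapse compound records to a pIC50 Series indexed by compound id."""
    return pd.Series(
        {r.compound_id: r.pic50 for r in records}, name="pic50", dtype=float
    )


def read_descriptor_matrix(source) -> pd.DataFrame:
    """Read a descriptor CSV (first column = compound id) into a DataFrame.

    Every descriptor cell must parse as a finite number; blanks, ``NA`` and
    ragged rows are rejected with the offending coordinates.
    """
    df = _read_csv(source)
    if df.shape[1] < 2:
        raise ParseError("descriptor table has no descriptor columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.map(lambda v: str(v).strip())
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate compound ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"duplicate descriptor names: {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            cid = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"non-numeric or missing value at compound {cid!r}, "
                f"descriptor {col!r}",
                row=cid,
                column=col,
            )
        df[col] = coerced.astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise ParseError("descriptor matrix contains non-finite values")
    return df


@dataclass
class PretreatReport:
    """What :func:`pretreat` removed and why."""

    removed_constant: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str]] = field(default_factory=list)
    n_kept: int = 0

    @property
    def removed(self) -> set[str]:
        return set(self.removed_constant) | {d for _, d in self.removed_correlated}


def pretreat(
    matrix: pd.DataFrame,
    variance_tol: float = 1e-8,
    corr_threshold: float = 0.99,
) -> tuple[pd.DataFrame, PretreatReport]:
    """Drop constant and highly inter-correlated descriptor columns.

    A column is *constant* when its (sample) variance is <= ``variance_tol``.
    Among surviving columns, scanning left to right, a column is dropped when
    its absolute Pearson correlation with an already-kept column is
    >= ``corr_threshold``; the earlier column is always the one kept.

    Returns the filtered matrix and a :class:`PretreatReport`.  Raises if no
    descriptor survives.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ParseError("empty descriptor matrix")
    report = PretreatReport()
    values = matrix.to_numpy(dtype=float)
    variances = values.var(axis=0, ddof=1) if len(matrix) > 1 else np.zeros(
        matrix.shape[1]
    )
    non_constant = []
    for j, name in enumerate(matrix.columns):
        if variances[j] <= variance_tol:
            report.removed_constant.append(name)
        else:
            non_constant.append(j)

    kept: list[int] = []
    for j in non_constant:
        dropped = False
        for k in kept:
            r = np.corrcoef(values[:, k], values[:, j])[0, 1]
            if abs(r) >= corr_threshold:
                report.removed_correlated.append(
                    (matrix.columns[k], matrix.columns[j])
                )
                dropped = True
                break
        if not dropped:
            kept.append(j)

    if not kept:
        raise ParseError("pretreatment removed every descriptor column")
    report.n_kept = len(kept)
    return matrix.iloc[:, kept].copy(), report


@dataclass
class DataSplit:
    """Calibration (train) / validation (test) compound ids."""

    train_ids: list[str]
    test_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, "train") for cid in self.train_ids]
        rows += [(cid, "test") for cid in self.test_ids]
        return pd.DataFrame(rows, columns=["compound_id", "set"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DataSplit":
        df = df.copy()
        df["set"] = df["set"].str.strip().str.lower()
        bad = set(df["set"]) - {"train", "test"}
        if bad:
            raise ParseError(f"unknown split labels: {sorted(bad)}")
        return cls(
            train_ids=[str(c) for c in df.loc[df["set"] == "train", "compound_id"]],
            test_ids=[str(c) for c in df.loc[df["set"] == "test", "compound_id"]],
        )


def kennard_stone(
    matrix: pd.DataFrame,
    n_train: int | None = None,
    train_fraction: float | None = None,
) -> DataSplit:
    """Kennard-Stone maximin split into calibration and validation sets.

    Descriptors are column-standardised (mean 0, variance 1, computed on the
    full set) before Euclidean distances.  The first two picks are a globally
    maximally distant pair; each later pick maximises its minimum distance to
    the compounds already selected.  Ties break toward the smallest input
    index, making the split deterministic.

    Exactly one of ``n_train`` / ``train_fraction`` must be given; the
    fraction convenience uses ``floor(fraction * N)``.
    """
    n = len(matrix)
    if (n_train is None) == (train_fraction is None):
        raise ValueError("give exactly one of n_train / train_fraction")
    if n_train is None:
        if not 0 < train_fraction <= 1:
            raise ValueError(f"train_fraction out of (0, 1]: {train_fraction}")
        n_train = int(math.floor(train_fraction * n))
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must be in [2, {n}], got {n_train}")

    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant columns contribute nothing to distance
    z = (values - mu) / sd

    # pairwise squared Euclidean distances
    sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)

    # seed pair: global maximum distance, lexicographically smallest indices
    iu = np.triu_indices(n, k=1)
    best = np.argmax(sq[iu])  # argmax over row-major upper triangle = lexi tie-break
    i0, j0 = int(iu[0][best]), int(iu[1][best])
    selected = [i0, j0]
    remaining = [i for i in range(n) if i not in (i0, j0)]

    min_d = np.minimum(sq[:, i0], sq[:, j0])
    while len(selected) < n_train:
        cand = max(remaining, key=lambda i: (min_d[i], -i))
        selected.append(cand)
        remaining.remove(cand)
        min_d = np.minimum(min_d, sq[:, cand])

    ids = list(matrix.index)
    train = [ids[i] for i in selected]
    test = [ids[i] for i in sorted(remaining)]
    return DataSplit(train_ids=train, test_ids=test)
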