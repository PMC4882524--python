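"""Trait tables, descriptive statistics and Pearson moment matrices.

The raw-data role in this pipeline is an individuals x variables table of
finite numeric trait/environment measurements (climate, topsoil nutrient
concentrations, leaf morphology, foliar nitrogen).  Every covariance-structure
fit downstream consumes only the second moments, so the table's sufficient
statistic is a :class:`CorrMatrix` — a symmetric correlation (or covariance)
matrix together with the sample size it was computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitTable",
    "SummaryStats",
    "CorrMatrix",
    "read_trait_table",
    "write_trait_table",
    "read_corr_matrix",
    "write_corr_matrix",
    "summarize",
    "pearson_matrix",
    "nearest_psd",
]


class TraitTableError(ValueError):
    """Malformed or invalid trait-table input."""


@dataclass(frozen=True)
class TraitTable:
    """Individuals x named numeric variables.

    Parameters
    ----------
    data
        DataFrame with one row per individual and one numeric column per
        variable.  Column names must be unique and all values finite.
    units
        Optional mapping variable -> unit label (purely descriptive).
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise TraitTableError(f"duplicate column names: {dupes}")
        if self.data.shape[0] < 3:
            raise TraitTableError(
                f"need at least 3 records, got {self.data.shape[0]}"
            )
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TraitTableError("non-numeric values in trait table")
        bad = ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise TraitTableError(
                f"non-finite value at row {i + 1}, column {cols[j]!r}"
            )

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class SummaryStats:
    """Per-variable mean, SE of the mean, min, max and CV (percent)."""

    table: pd.DataFrame  # index: variable; columns: mean, se, min, max, cv
    flags: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return self.table.to_json(orient="index", double_precision=12)


@dataclass(frozen=True)
class CorrMatrix:
    """Symmetric moment matrix with its sample size.

    ``values[i, j]`` is the correlation (default) or covariance between
    ``names[i]`` and ``names[j]``; ``n`` is the number of individuals the
    moments were computed from.  ``pvalues`` optionally carries the matching
    two-sided significance matrix.
    """

    names: tuple[str, ...]
    values: np.ndarray
    n: int
    is_correlation: bool = True
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        p = len(self.names)
        if v.shape != (p, p):
            raise TraitTableError(f"matrix shape {v.shape} != ({p}, {p})")
        if len(set(self.names)) != p:
            raise TraitTableError("duplicate variable names")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise TraitTableError("matrix not symmetric to 1e-12")
        if self.is_correlation:
            if not np.allclose(np.diag(v), 1.0, atol=1e-12):
                raise TraitTableError("correlation matrix diagonal must be 1")
            if np.any(np.abs(v) > 1 + 1e-12):
                raise TraitTableError("correlation entries must lie in [-1, 1]")
        if self.n < 2:
            raise TraitTableError(f"sample size n={self.n} too small")

    @property
    def p(self) -> int:
        return len(self.names)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())

    def submatrix(self, names: list[str] | tuple[str, ...]) -> "CorrMatrix":
        """Return the moment matrix restricted to ``names`` (in that order)."""
        missing = [v for v in names if v not in self.names]
        if missing:
            raise KeyError(f"variables not in matrix: {missing}")
        idx = [self.names.index(v) for v in names]
        pv = self.pvalues[np.ix_(idx, idx)] if self.pvalues is not None else None
        return CorrMatrix(
            names=tuple(names),
            values=self.values[np.ix_(idx, idx)],
            n=self.n,
            is_correlation=self.is_correlation,
            pvalues=pv,
        )


def read_trait_table(path, delimiter: str = ",") -> TraitTable:
    """Read a delimited trait table (header row, one record per row).

    Rejects duplicate columns, empty files, missing and non-numeric cells,
    naming the offending row/column where possible.
    """
    raw = pd.read_csv(path, delimiter=delimiter)
    if raw.shape[0] == 0:
        raise TraitTableError(f"{path}: no data rows")
    for col in raw.columns:
        series = pd.to_numeric(raw[col], errors="coerce")
        bad = series.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TraitTableError(
                f"{path}: non-numeric value {raw[col].iloc[row]!r} "
                f"at row {row + 1}, column {col!r}"
            )
        missing = series.isna()
        if missing.any():
            row = int(np.flatnonzero(missing)[0])
            raise TraitTableError(
                f"{path}: missing value at row {row + 1}, column {col!r}"
            )
        raw[col] = series.astype(float)
    return TraitTable(raw)


def write_trait_table(table: TraitTable, path, delimiter: str = ",") -> None:
    table.data.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def read_corr_matrix(path, n: int, is_correlation: bool = True) -> CorrMatrix:
    """Read a square moment matrix: names in header and first column."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise TraitTableError(f"{path}: row and column names differ")
    return CorrMatrix(
        names=tuple(df.columns),
        values=df.to_numpy(dtype=float),
        n=n,
        is_correlation=is_correlation,
    )


def write_corr_matrix(m: CorrMatrix, path) -> None:
    pd.DataFrame(m.values, index=m.names, columns=m.names).to_csv(
        path, float_format="%.12g"
    )


def summarize(data: TraitTable) -> SummaryStats:
    """Descriptive statistics per variable.

    mean is the arithmetic mean, SE = s/sqrt(n) with s the (n-1)-denominator
    sample standard deviation, CV = 100*s/mean (percent).  A zero-variance
    variable gets CV 0; a zero-mean variable gets CV NaN and a flag.
    """
    if data.n < 2:
        raise TraitTableError("summarize needs n >= 2")
    x = data.values()
    n = data.n
    mean = x.mean(axis=0)
    s = x.std(axis=0, ddof=1)
    se = s / np.sqrt(n)
    flags: dict[str, str] = {}
    cv = np.empty_like(mean)
    for j, name in enumerate(data.names):
        if s[j] == 0.0:
            cv[j] = 0.0
        elif mean[j] == 0.0:
            cv[j] = np.nan
            flags[name] = "CV undefined: mean is 0"
        else:
            cv[j] = 100.0 * s[j] / mean[j]
    table = pd.DataFrame(
        {
            "mean": mean,
            "se": se,
            "min": x.min(axis=0),
            "max": x.max(axis=0),
            "cv": cv,
        },
        index=pd.Index(data.names, name="variable"),
    )
    return SummaryStats(table=table, flags=flags)


def pearson_matrix(data: TraitTable) -> CorrMatrix:
    """Pairwise Pearson correlations with two-sided p-values.

    p-values come from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom;
    the diagonal is exactly 1 with p = 0.
    """
    x = data.values()
    n, p = x.shape
    sds = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0.0)
    if zero.size:
        raise TraitTableError(
            f"zero variance in variable(s): {[data.names[j] for j in zero]}"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals[np.isnan(pvals)] = 0.0  # |r| == 1
    np.fill_diagonal(pvals, 0.0)
    return CorrMatrix(
        names=tuple(data.names), values=r, n=n, is_correlation=True, pvalues=pvals
    )


def nearest_psd(m: CorrMatrix, floor: float = 1e-6) -> tuple[CorrMatrix, float]:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal.

    Printed correlation matrices rounded to two decimals can be indefinite;
    this repairs them minimally.  Returns the (possibly unchanged) matrix and
    the maximum absolute entry change.  Idempotent: a matrix whose smallest
    eigenvalue is already >= ``floor`` is returned unchanged.
    """
    vals = m.values
    if np.linalg.eigvalsh(vals).min() >= floor:
        return m, 0.0
    # rescaling to unit diagonal can nudge the spectrum back below the
    # floor, so clip-and-rescale is iterated to a fixed point (idempotence)
    fixed = vals
    for _ in range(200):
        w, v = np.linalg.eigh(fixed)
        if w.min() >= floor:
            break
        fixed = (v * np.clip(w, floor, None)) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        fixed = (fixed + fixed.T) / 2.0
        np.fill_diagonal(fixed, 1.0)
    delta = float(np.abs(fixed - vals).max())
    out = CorrMatrix(
        names=m.names, values=fixed, n=m.n, is_correlation=True, pvalues=m.pvalues
    )
    return out, delta
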