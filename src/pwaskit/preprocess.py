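"""Preprocessing: rank-based normalization, inclusion rule, KNN imputation.

The fixed pipeline order is: inclusion rule -> KNN imputation (covariates)
-> inverse-rank normal transform (protein signals) -> standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "inverse_normal_transform",
    "transform_proteins",
    "apply_inclusion_rule",
    "knn_impute",
    "standardize",
    "ImputationReport",
]

#: Blom rank offset used by the inverse-rank normal transform
BLOM_OFFSET = 3.0 / 8.0


@dataclass
class ImputationReport:
    """Bookkeeping for the inclusion rule and KNN imputation."""

    n_input: int
    n_retained: int
    n_dropped_below_threshold: int
    imputed_cells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_retained + self.n_dropped_below_threshold == self.n_input


def inverse_normal_transform(values) -> np.ndarray:
    """Blom inverse-rank normal transform of one column.

    Non-missing entries are replaced by ``Phi^-1((r - 3/8) / (m + 1/4))``
    where ``r`` is the (tie-averaged) rank among the ``m`` non-missing
    values; missing entries stay missing.  Requires at least two distinct
    non-missing values.
    """
    x = np.asarray(pd.Series(values, dtype=float))
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    m = int(obs.sum())
    if m < 2:
        raise ValueError("inverse normal transform needs >= 2 non-missing values")
    v = x[obs]
    if np.all(v == v[0]):
        raise ValueError(
            "all non-missing values identical; rank transform would be degenerate"
        )
    ranks = rankdata(v, method="average")
    out[obs] = norm.ppf((ranks - BLOM_OFFSET) / (m + 1.0 - 2.0 * BLOM_OFFSET))
    return out


def transform_proteins(proteins: pd.DataFrame) -> pd.DataFrame:
    """Apply the inverse-rank normal transform to every signal column."""
    out = proteins.copy()
    for col in out.columns:
        out[col] = inverse_normal_transform(out[col].to_numpy())
    return out


def apply_inclusion_rule(
    table: pd.DataFrame, min_measured_fraction: float = 0.4
) -> tuple[pd.DataFrame, ImputationReport]:
    """Drop individuals with too few measured covariates before imputation.

    An individual is retained when the fraction of covariate columns with
    an observed value is at least ``min_measured_fraction`` (inclusive;
    with 10 covariates, 4 measured of 10 is retained).
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("covariate table is empty")
    if not (0.0 < min_measured_fraction <= 1.0):
        raise ValueError("min_measured_fraction must lie in (0, 1]")
    frac = table.notna().sum(axis=1) / table.shape[1]
    keep = frac >= min_measured_fraction - 1e-12
    retained = table.loc[keep].copy()
    report = ImputationReport(
        n_input=len(table),
        n_retained=int(keep.sum()),
        n_dropped_below_threshold=int((~keep).sum()),
    )
    return retained, report


def _gower_distances(
    data: np.ndarray, row: np.ndarray, ranges: np.ndarray, is_numeric: np.ndarray
) -> np.ndarray:
    """Gower distance from one row to all rows, over mutually observed columns."""
    diff = np.abs(data - row)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(is_numeric, diff / ranges, (diff > 0).astype(float))
    observed = ~np.isnan(contrib)
    n_obs = observed.sum(axis=1)
    total = np.nansum(contrib, axis=1)
    with np.errstate(invalid="ignore"):
        dist = np.where(n_obs > 0, total / np.maximum(n_obs, 1), np.inf)
    return dist


def knn_impute(
    table: pd.DataFrame,
    roles: dict[str, str],
    k: int = 5,
    report: ImputationReport | None = None,
) -> pd.DataFrame:
    """Fill missing covariate cells from the k Gower-nearest individuals.

    Continuous and ordinal columns are imputed with the neighbor median,
    binary columns with the neighbor mode (lower category on ties).
    Observed cells are never altered.  ``roles`` maps each column to
    "continuous", "ordinal" or "binary".
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    unknown = set(table.columns) - set(roles)
    if unknown:
        raise ValueError(f"no role declared for columns: {sorted(unknown)}")
    bad = {c: r for c, r in roles.items() if c in table and r not in ("continuous", "ordinal", "binary")}
    if bad:
        raise ValueError(f"invalid roles: {bad}")

    cols = list(table.columns)
    data = table.to_numpy(dtype=float)
    n, p = data.shape
    all_missing = [c for i, c in enumerate(cols) if np.isnan(data[:, i]).all()]
    if all_missing:
        raise ValueError(f"covariates missing for every individual: {all_missing}")

    is_numeric = np.array([roles[c] in ("continuous", "ordinal") for c in cols])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ranges = np.nanmax(data, axis=0) - np.nanmin(data, axis=0)
    ranges[~is_numeric] = 1.0
    ranges[ranges == 0] = 1.0

    out = data.copy()
    missing_rows = np.flatnonzero(np.isnan(data).any(axis=1))
    imputed_counts = {c: 0 for c in cols}
    for i in missing_rows:
        dist = _gower_distances(data, data[i], ranges, is_numeric)
        dist[i] = np.inf
        for jcol in np.flatnonzero(np.isnan(data[i])):
            donors = np.flatnonzero(~np.isnan(data[:, jcol]) & np.isfinite(dist))
            if donors.size == 0:
                continue
            if donors.size < k:
                warnings.warn(
                    f"only {donors.size} donors available for row {i}, "
                    f"column {cols[jcol]!r} (k={k}); using all",
                    stacklevel=2,
                )
            order = donors[np.argsort(dist[donors], kind="stable")][:k]
            vals = data[order, jcol]
            if roles[cols[jcol]] == "binary":
                ones = (vals == 1).sum()
                zeros = len(vals) - ones
                out[i, jcol] = 1.0 if ones > zeros else 0.0
            else:
                out[i, jcol] = np.median(vals)
            imputed_counts[cols[jcol]] += 1
    if np.isnan(out).any():
        raise ValueError("imputation left missing cells (no donors for some columns)")
    if report is not None:
        report.imputed_cells = {c: v for c, v in imputed_counts.items() if v}
    return pd.DataFrame(out, index=table.index, columns=cols)


def standardize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Scale each column to mean 0 and unit sample variance (ddof=1)."""
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
        squeeze = True
    else:
        squeeze = False
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        if isinstance(matrix, pd.DataFrame):
            names = [str(matrix.columns[i]) for i in zero]
        else:
            names = [str(i) for i in zero]
        raise ValueError(f"zero-variance column(s): {names}")
    out = (values - values.mean(axis=0)) / sd
    if squeeze:
        out = out[:, 0]
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out
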