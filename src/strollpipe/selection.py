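"""Feature selection: redundancy pruning, sampling adequacy, standardization.

Three steps applied to a measurements × features table before PCA:

1. :func:`prune_correlated` — while any pair of features correlates above a
   threshold (|r| > 0.95 by default), drop the member with the highest
   summed absolute correlation to all remaining features, one at a time.
2. :func:`kmo` — the Kaiser-Meyer-Olkin sampling-adequacy index, overall and
   per feature, from the anti-image (partial) correlations; acceptability
   cut points are 0.7 overall and 0.5 per feature.
3. :func:`standardize` — column z-scores with stored means/SDs so external
   data can be transformed with the fitting parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConstantFeatureError, InvalidArgumentError

KMO_OVERALL_CUT = 0.7
KMO_FEATURE_CUT = 0.5


@dataclass
class SelectionReport:
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (name, reason)
    surviving: list[str] = field(default_factory=list)
    overall_kmo: float | None = None
    per_feature_kmo: pd.Series | None = None
    notes: list[str] = field(default_factory=list)


def _check_numeric(table: pd.DataFrame) -> None:
    bad = table.columns[table.isna().any()].tolist()
    if bad:
        raise InvalidArgumentError(f"missing values in columns: {bad}")


def prune_correlated(
    table: pd.DataFrame, threshold: float = 0.95
) -> tuple[pd.DataFrame, SelectionReport]:
    """Iteratively drop one member of every |r| > threshold feature pair.

    Absolute correlations are used (sign-agnostic redundancy). At each step,
    among the features involved in any violating pair, the one with the
    largest sum of absolute correlations to all current features is dropped
    and the matrix recomputed; ties break by column order.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise InvalidArgumentError("need at least 2 features and 3 rows")
    _check_numeric(table)
    report = SelectionReport()
    cur = table.copy()
    while cur.shape[1] >= 2:
        corr = cur.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        viol = corr.values > threshold
        if not viol.any():
            break
        involved = np.flatnonzero(viol.any(axis=0))
        sums = corr.values.sum(axis=1)
        drop_pos = involved[np.argmax(sums[involved])]  # argmax keeps first on ties
        name = cur.columns[drop_pos]
        report.dropped.append((name, f"corr_gt_{threshold}"))
        cur = cur.drop(columns=[name])
    report.surviving = list(cur.columns)
    return cur, report


@dataclass
class KmoResult:
    overall: float
    per_feature: pd.Series
    acceptable_overall: bool
    acceptable_features: pd.Series
    ridge_used: bool = False
    underdetermined: bool = False
    degenerate: bool = False


def kmo(table: pd.DataFrame) -> KmoResult:
    """Kaiser-Meyer-Olkin sampling adequacy, overall and per feature.

    Partial correlations come from the inverse correlation matrix
    (anti-image): ``p_jk = -S_jk / sqrt(S_jj S_kk)`` with ``S = R⁻¹``;
    ``KMO_j = Σ r²_jk / (Σ r²_jk + Σ p²_jk)`` over ``k ≠ j`` and the overall
    index sums over all off-diagonal pairs. A ridge of 1e-8 is added when
    the correlation matrix is singular (recorded in the result).
    """
    _check_numeric(table)
    x = table.to_numpy(dtype=float)
    r = np.corrcoef(x, rowvar=False)
    ridge = False
    try:
        s = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        s = np.linalg.inv(r + 1e-8 * np.eye(r.shape[0]))
        ridge = True
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    partial = -s / d
    np.fill_diagonal(partial, 0.0)
    r_off = r - np.eye(r.shape[0])
    r2 = r_off**2
    p2 = partial**2

    denom_j = r2.sum(axis=1) + p2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        kmo_j = np.where(denom_j > 1e-12, r2.sum(axis=1) / denom_j, np.nan)
    denom = r2.sum() + p2.sum()
    overall = r2.sum() / denom if denom > 1e-12 else np.nan
    per = pd.Series(kmo_j, index=table.columns, name="kmo")
    return KmoResult(
        overall=float(overall) if np.isfinite(overall) else np.nan,
        per_feature=per,
        acceptable_overall=bool(np.isfinite(overall) and overall > KMO_OVERALL_CUT),
        acceptable_features=per > KMO_FEATURE_CUT,
        ridge_used=ridge,
        underdetermined=table.shape[0] < table.shape[1],
        degenerate=not np.isfinite(overall) or bool(np.any(~np.isfinite(kmo_j))),
    )


@dataclass
class StandardizedTable:
    """Z-scored table with the fitting means/SDs stored for later projection."""

    data: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def transform(self, new: pd.DataFrame) -> pd.DataFrame:
        """Standardize external data with the STORED parameters (no refit)."""
        missing = [c for c in self.means.index if c not in new.columns]
        if missing:
            raise InvalidArgumentError(f"columns missing from external table: {missing}")
        cols = list(self.means.index)
        return (new[cols] - self.means) / self.sds


def standardize(table: pd.DataFrame) -> StandardizedTable:
    """Column z-scores (sample SD, n−1 denominator)."""
    _check_numeric(table)
    means = table.mean()
    sds = table.std(ddof=1)
    zero = sds.index[sds == 0].tolist()
    if zero:
        raise ConstantFeatureError(f"zero-variance feature(s): {zero}")
    return StandardizedTable(data=(table - means) / sds, means=means, sds=sds)
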