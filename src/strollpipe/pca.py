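"""PCA with Kaiser retention, component labelling, fixed-loading projection,
and the test-retest reliability panel (ICC(2,1), SEM, MDC, RMSE).

The PCA is an eigendecomposition of the feature correlation matrix (equal to
the covariance of z-scores); components with eigenvalue > 1 are retained
(Kaiser criterion). Each retained loading column is oriented so its
largest-magnitude entry is positive, and labels come from the feature whose
correlation with the component scores is highest — both conventions are
stored in the model so projections are reproducible bit for bit.

Reliability of externally projected test-retest scores uses the two-way
random-effects absolute-agreement single-measure intraclass correlation
ICC(2,1) with F-based 95% confidence bounds, the standard error of
measurement SEM = pooled SD × √(1 − ICC), the minimal detectable change
MDC = 1.96 × √2 × SEM, and the test-retest RMSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientPairsError, InvalidArgumentError, SchemaError
from .selection import StandardizedTable

KAISER_THRESHOLD = 1.0
NEAR_THRESHOLD_BAND = (0.95, 1.05)


@dataclass
class PcaModel:
    feature_names: list[str]
    means: pd.Series
    sds: pd.Series
    loadings: np.ndarray          # (p, k) retained eigenvectors, orthonormal columns
    eigenvalues: np.ndarray       # all p eigenvalues, non-increasing
    explained: np.ndarray         # fractions of total variance, all components
    labels: list[str] | None = None
    near_threshold: bool = False
    tie_notes: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[1]

    def save(self, path: str) -> None:
        payload = {
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained": self.explained.tolist(),
            "labels": self.labels,
            "conventions": {
                "sign": "largest-magnitude loading entry positive",
                "ties": "registry (column) order",
                "retention": "eigenvalue > 1 on the correlation matrix",
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "PcaModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=d["feature_names"],
            means=pd.Series(d["means"], index=d["feature_names"]),
            sds=pd.Series(d["sds"], index=d["feature_names"]),
            loadings=np.asarray(d["loadings"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            explained=np.asarray(d["explained"]),
            labels=d.get("labels"),
        )


def fit_pca(ztable: StandardizedTable) -> PcaModel:
    """Fit the correlation-matrix PCA and retain eigenvalue > 1 components."""
    z = ztable.data.to_numpy(dtype=float)
    n, p = z.shape
    r = (z.T @ z) / (n - 1)
    w, v = np.linalg.eigh(r)
    order = np.argsort(w)[::-1]
    w, v = np.maximum(w[order], 0.0), v[:, order]
    retained = w > KAISER_THRESHOLD
    if n <= int(retained.sum()):
        raise InvalidArgumentError("more retained components than rows")
    load = v[:, retained]
    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(load.shape[1]):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    near = bool(np.any((w >= NEAR_THRESHOLD_BAND[0]) & (w <= NEAR_THRESHOLD_BAND[1])))
    return PcaModel(
        feature_names=list(ztable.data.columns),
        means=ztable.means.copy(),
        sds=ztable.sds.copy(),
        loadings=load,
        eigenvalues=w,
        explained=w / w.sum(),
        near_threshold=near,
    )


def scores(model: PcaModel, ztable_data: pd.DataFrame) -> pd.DataFrame:
    s = ztable_data[model.feature_names].to_numpy(dtype=float) @ model.loadings
    cols = [f"PC{j}" for j in range(model.n_retained)]
    return pd.DataFrame(s, index=ztable_data.index, columns=cols)


def label_components(model: PcaModel, ztable: StandardizedTable) -> PcaModel:
    """Name each retained component after its highest-|r| feature."""
    sc = scores(model, ztable.data).to_numpy()
    z = ztable.data.to_numpy(dtype=float)
    labels = []
    for j in range(model.n_retained):
        with np.errstate(invalid="ignore"):
            rr = np.array([
                np.corrcoef(sc[:, j], z[:, i])[0, 1] for i in range(z.shape[1])
            ])
        rr = np.abs(np.nan_to_num(rr))
        best = int(np.argmax(rr))  # first (registry-order) winner on ties
        if np.count_nonzero(np.isclose(rr, rr[best], atol=1e-12)) > 1:
            model.tie_notes.append(
                f"PC{j}: label tie broken by registry order -> {model.feature_names[best]}")
        labels.append(model.feature_names[best])
    model.labels = labels
    return model


def project(model: PcaModel, external: pd.DataFrame,
            refit_standardization: bool = False) -> pd.DataFrame:
    """Project external data onto the fitted loadings (no refitting).

    External features are standardized with the model's stored means/SDs by
    default; ``refit_standardization=True`` re-estimates moments from the
    external table instead (the alternative reading of external z-scoring).
    """
    missing = [c for c in model.feature_names if c not in external.columns]
    if missing:
        raise SchemaError(f"external table missing features: {missing}")
    x = external[model.feature_names]
    if refit_standardization:
        z = (x - x.mean()) / x.std(ddof=1)
    else:
        z = (x - model.means) / model.sds
    return scores(model, z)


# ---------------------------------------------------------------------------
# reliability panel


@dataclass
class ComponentReliability:
    component: str
    icc: float
    ci_low: float
    ci_high: float
    sem: float
    mdc: float
    rmse: float
    band: str
    n_pairs: int


def _band(icc: float) -> str:
    if icc > 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def icc_2_1(test: np.ndarray, retest: np.ndarray, alpha: float = 0.05):
    """ICC(2,1) with F-based CI from the two-way ANOVA mean squares.

    ICC = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE)) with k = 2
    sessions and n subjects; the confidence bounds follow the standard
    F-distribution construction for the two-way random-effects
    absolute-agreement single-measure coefficient.
    """
    y = np.column_stack([test, retest]).astype(float)
    n, k = y.shape
    if n < 2:
        raise InsufficientPairsError("need at least 2 complete pairs")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((y - grand) ** 2).sum()
    sse = sst - ssr - ssc
    if sse <= 1e-10 * max(sst, 1.0):  # exact agreement up to cancellation error
        sse = 0.0
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        return 1.0 if mse == 0 else np.nan, (np.nan, np.nan)
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return 1.0, (1.0, 1.0)

    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isinf(a) or mse == 0:
        return float(icc), (1.0, 1.0)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper))


def reliability(
    test_scores: pd.DataFrame,
    retest_scores: pd.DataFrame,
    alpha: float = 0.05,
) -> list[ComponentReliability]:
    """Per-component test-retest panel from subject-paired score tables.

    Both tables must share the subject index and component columns. SEM uses
    the pooled session SD, ``sqrt((SD_test² + SD_retest²) / 2)``.
    """
    common = test_scores.index.intersection(retest_scores.index)
    if common.size < 2:
        raise InsufficientPairsError("fewer than 2 subjects with both sessions")
    out = []
    for comp in test_scores.columns:
        a = test_scores.loc[common, comp].to_numpy(dtype=float)
        b = retest_scores.loc[common, comp].to_numpy(dtype=float)
        icc, (lo, hi) = icc_2_1(a, b, alpha=alpha)
        pooled_sd = float(np.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0))
        sem = pooled_sd * float(np.sqrt(max(1.0 - icc, 0.0)))
        mdc = 1.96 * np.sqrt(2.0) * sem
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        out.append(
            ComponentReliability(
                component=str(comp), icc=icc, ci_low=lo, ci_high=hi,
                sem=sem, mdc=float(mdc), rmse=rmse, band=_band(icc),
                n_pairs=int(common.size),
            )
        )
    return out


def reliability_frame(panel: list[ComponentReliability]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in panel]).set_index("component")
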