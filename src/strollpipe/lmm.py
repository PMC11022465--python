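"""Linear mixed models: gait-speed baseline, confounder/modifier forward
selection over candidate components, model comparison and residual checks.

Each walking-ability outcome gets a random-intercept (per subject) model with
2MWT gait speed as the exposure. Candidate components are screened for
collinearity (|r| ≥ 0.9 against gait speed or an earlier candidate), then
visited in order: a candidate is a **confounder** when adding its main effect
changes the gait-speed coefficient by ≥ 10% relative to the gait-speed-only
model, and an **effect modifier** when the speed × candidate interaction has
Wald p < 0.05 (maximum-likelihood fit). Retained candidates accumulate into
the definitive model. Estimates are REML; AIC/BIC comparisons use ML refits
because REML likelihoods are not comparable across fixed-effect structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    InvalidArgumentError,
    InvalidComparisonError,
    UndefinedCorrelationError,
)

COLLINEARITY_R = 0.9
CONFOUNDER_CHANGE = 0.10
INTERACTION_ALPHA = 0.05


@dataclass
class LmmFit:
    outcome: str
    terms: list[str]                 # fixed-effect names incl. intercept
    params: pd.Series
    se: pd.Series
    ci: pd.DataFrame                 # columns lower, upper
    subject_var: float
    resid_var: float
    aic: float
    bic: float
    nrmse: float
    resid: np.ndarray
    fitted: np.ndarray
    n: int
    rows: pd.Index
    converged: bool
    boundary: bool                   # subject variance at (near) zero
    llf_ml: float


@dataclass
class TraceEntry:
    candidate: str
    pct_change: float | None
    confounder: bool
    interaction_p: float | None
    modifier: bool
    included: bool
    note: str = ""


@dataclass
class SelectionTrace:
    entries: list[TraceEntry] = field(default_factory=list)

    def retained(self) -> list[str]:
        return [e.candidate for e in self.entries if e.included]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def _design(df: pd.DataFrame, terms: list[str],
            interactions: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for t in terms:
        cols.append(df[t].to_numpy(dtype=float))
        names.append(t)
    for t in interactions:
        cols.append((df["gait_speed"] * df[t]).to_numpy(dtype=float))
        names.append(f"gait_speed:{t}")
    return np.column_stack(cols), names


def _fit(df, outcome, terms, interactions, reml=True):
    x, names = _design(df, terms, interactions)
    y = df[outcome].to_numpy(dtype=float)
    groups = df["subject_id"].to_numpy()
    model = sm.MixedLM(y, x, groups=groups)
    last_exc: Exception | None = None
    for method in ("bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, method=method)
                res.fe_params, res.bse_fe  # populate caches quietly
            return res, names
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise last_exc


def fit_model(
    df: pd.DataFrame,
    outcome: str,
    terms: list[str],
    interactions: list[str] | None = None,
) -> LmmFit:
    """Random-intercept model ``outcome ~ terms (+ speed×interactions)``.

    REML for the reported estimates; a parallel ML fit supplies the
    log-likelihood behind AIC/BIC. nRMSE is the root-mean-square residual
    divided by the observed outcome range.
    """
    interactions = interactions or []
    if df["subject_id"].nunique() < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    res, names = _fit(df, outcome, terms, interactions, reml=True)
    res_ml, _ = _fit(df, outcome, terms, interactions, reml=False)

    p = len(names)
    params = pd.Series(np.asarray(res.fe_params)[:p], index=names)
    se = pd.Series(np.asarray(res.bse_fe)[:p], index=names)
    ci = pd.DataFrame(
        {"lower": params - 1.96 * se, "upper": params + 1.96 * se}, index=names)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resid = np.asarray(res.resid)
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effect covariance: fall back to marginal residuals
        x, _ = _design(df, terms, interactions)
        resid = df[outcome].to_numpy(dtype=float) - x @ np.asarray(res.fe_params)[:p]
    y = df[outcome].to_numpy(dtype=float)
    rng_y = float(np.ptp(y))
    nrmse = float(np.sqrt(np.mean(resid**2)) / rng_y) if rng_y > 0 else np.nan
    subject_var = float(np.asarray(res.cov_re)[0, 0])
    k_params = p + 2  # fixed effects + subject variance + residual variance
    llf = float(res_ml.llf)
    n = len(df)
    return LmmFit(
        outcome=outcome,
        terms=names,
        params=params,
        se=se,
        ci=ci,
        subject_var=subject_var,
        resid_var=float(res.scale),
        aic=-2.0 * llf + 2.0 * k_params,
        bic=-2.0 * llf + np.log(n) * k_params,
        nrmse=nrmse,
        resid=resid,
        fitted=y - resid,
        n=n,
        rows=df.index,
        converged=bool(res.converged),
        boundary=subject_var < 1e-8,
        llf_ml=llf,
    )


def fit_base(df: pd.DataFrame, outcome: str) -> LmmFit:
    """The gait-speed-only model for one walking-ability outcome."""
    return fit_model(df, outcome, ["gait_speed"])


# ---------------------------------------------------------------------------
# screening and selection


def correlation_screen(
    df: pd.DataFrame, candidates: list[str], threshold: float = COLLINEARITY_R
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson matrix over speed + candidates; exclude collinear candidates.

    A candidate is excluded when |r| ≥ threshold against gait speed or
    against an earlier-indexed surviving candidate; gait speed itself is
    never excluded.
    """
    cols = ["gait_speed"] + list(candidates)
    for c in cols:
        if df[c].std(ddof=0) == 0:
            raise UndefinedCorrelationError(f"variable {c!r} is constant")
    corr = df[cols].corr()
    excluded: list[str] = []
    kept: list[str] = []
    for c in candidates:
        prior = ["gait_speed"] + kept
        if any(abs(corr.loc[c, p]) >= threshold for p in prior):
            excluded.append(c)
        else:
            kept.append(c)
    return corr, excluded


def forward_select(
    df: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    conf_threshold: float = CONFOUNDER_CHANGE,
    alpha: float = INTERACTION_ALPHA,
    reference: str = "base",
) -> tuple[LmmFit, SelectionTrace]:
    """Confounder / effect-modifier forward selection over candidates.

    Candidates are visited in the given order (callers pass descending
    explained variance). The confounder test compares the gait-speed
    coefficient against the gait-speed-only model by default
    (``reference="base"``) or against the accumulating working model
    (``reference="sequential"``). Returns the definitive fit and the full
    decision trace.
    """
    base = fit_base(df, outcome)
    base_coef = float(base.params["gait_speed"])
    working_main: list[str] = []
    working_int: list[str] = []
    trace = SelectionTrace()
    ref_coef = base_coef
    for cand in candidates:
        # change-in-estimate against the base model tests the candidate on
        # its own; the sequential variant tests it on top of the working model
        tst_main = working_main if reference == "sequential" else []
        tst_int = working_int if reference == "sequential" else []
        try:
            with_main = fit_model(df, outcome, ["gait_speed"] + tst_main + [cand],
                                  tst_int)
            new_coef = float(with_main.params["gait_speed"])
            pct = abs(new_coef - ref_coef) / abs(ref_coef) if ref_coef != 0 else np.inf
            is_conf = pct >= conf_threshold

            res_int, names_int = _fit(
                df, outcome, ["gait_speed"] + tst_main + [cand],
                tst_int + [cand], reml=False)
            j = names_int.index(f"gait_speed:{cand}")
            tval = float(np.asarray(res_int.fe_params)[j]
                         / np.asarray(res_int.bse_fe)[j])
            # Wald test against a t reference with residual df (the normal
            # reference is anti-conservative at moderate sample sizes)
            dof = max(len(df) - len(names_int), 1)
            p_int = float(2.0 * stats.t.sf(abs(tval), dof))
            is_mod = p_int < alpha
        except Exception as exc:  # non-convergence: record and continue
            trace.entries.append(TraceEntry(cand, None, False, None, False, False,
                                            note=f"indeterminate: {exc}"))
            continue
        included = is_conf or is_mod
        if included:
            working_main.append(cand)
            if is_mod:
                working_int.append(cand)
            if reference == "sequential":
                ref_coef = new_coef
        trace.entries.append(
            TraceEntry(cand, float(pct), bool(is_conf), p_int, bool(is_mod), included))
    definitive = fit_model(df, outcome, ["gait_speed"] + working_main, working_int)
    return definitive, trace


def compare(fits: dict[str, LmmFit]) -> pd.DataFrame:
    """nRMSE / AIC / BIC comparison table across fits on identical rows.

    AIC/BIC come from the maximum-likelihood refits stored in each fit
    (REML likelihoods are not comparable across fixed-effect structures).
    """
    rows = None
    for f in fits.values():
        if rows is None:
            rows = f.rows
        elif not rows.equals(f.rows):
            raise InvalidComparisonError("fits are not on identical rows")
    tab = pd.DataFrame(
        {name: {"nRMSE": f.nrmse, "AIC": f.aic, "BIC": f.bic, "n_fixed": len(f.terms)}
         for name, f in fits.items()}
    ).T
    tab.attrs["note"] = "AIC/BIC from ML refits; estimates from REML"
    return tab


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class DiagnosticSummary:
    skewness: float
    excess_kurtosis: float
    normality_stat: float
    normality_p: float
    normal_ok: bool
    hetero_slope: float
    hetero_p: float
    homoscedastic_ok: bool
    degenerate: bool = False


def diagnostics(fit: LmmFit, alpha: float = 0.05) -> DiagnosticSummary:
    """Residual normality and homoscedasticity screens.

    Normality via the D'Agostino-Pearson omnibus test; heteroscedasticity via
    the slope of |residual| against fitted values.
    """
    r = fit.resid
    if np.allclose(r, r[0]):
        return DiagnosticSummary(0.0, 0.0, np.nan, np.nan, False, np.nan, np.nan,
                                 False, degenerate=True)
    skew = float(stats.skew(r))
    kurt = float(stats.kurtosis(r))
    stat, p = stats.normaltest(r)
    if np.ptp(fit.fitted) == 0:
        # constant fitted values: heteroscedasticity is unassessable
        return DiagnosticSummary(skew, kurt, float(stat), float(p),
                                 bool(p >= alpha), np.nan, np.nan, True)
    reg = stats.linregress(fit.fitted, np.abs(r))
    return DiagnosticSummary(
        skewness=skew,
        excess_kurtosis=kurt,
        normality_stat=float(stat),
        normality_p=float(p),
        normal_ok=bool(p >= alpha),
        hetero_slope=float(reg.slope),
        hetero_p=float(reg.pvalue),
        homoscedastic_ok=bool(reg.pvalue >= alpha),
    )


def fit_report(fit: LmmFit) -> pd.DataFrame:
    """Coefficient table mirroring the standard mixed-model report layout."""
    tab = pd.DataFrame(
        {"Coeff": fit.params, "SE": fit.se,
         "CI_low": fit.ci["lower"], "CI_high": fit.ci["upper"]}
    )
    tab.attrs.update({"nRMSE": fit.nrmse, "AIC": fit.aic, "BIC": fit.bic,
                      "outcome": fit.outcome})
    return tab
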