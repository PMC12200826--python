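"""Contingency-table tests, logistic models and nested model comparison.

The model ladder mirrors the study design: per EEG channel,

    baseline:   insight ~ 1 + sleep stage
    full:       insight ~ 1 + sleep stage + slope
    slope-only: insight ~ 1 + slope

with sleep stage treatment-coded against Wake. Fits use IRLS maximum
likelihood (statsmodels); models are compared by AIC, likelihood-ratio
tests and adjusted McFadden R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

STAGE_LEVELS = ("Wake", "N1", "N2")  # treatment coding, Wake reference


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test -> (p, sample odds ratio).

    Two-sided p sums the hypergeometric point probabilities of all tables
    with the observed margins that are no more probable than the observed
    one (the R convention). A zero margin yields p = 1 by convention.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0, float("nan")
    odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(p), float(odds)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    k: int
    terms: list[str]
    reference: str = "Wake"
    separation: bool = False
    mcfadden_adjusted: float = float("nan")
    _design_terms: tuple = field(default_factory=tuple, repr=False)


def _design_matrix(
    n: int,
    stage: np.ndarray | None,
    slope: np.ndarray | None,
    reference: str,
) -> pd.DataFrame:
    cols = {"intercept": np.ones(n)}
    if stage is not None:
        stage = np.asarray(stage)
        levels = [g for g in STAGE_LEVELS if g != reference]
        seen = set(np.unique(stage))
        unknown = seen - set(STAGE_LEVELS)
        if unknown:
            raise ValueError(f"unknown stage labels {unknown}")
        for g in levels:
            cols[f"stage[{g}]"] = (stage == g).astype(float)
    if slope is not None:
        cols["slope"] = np.asarray(slope, dtype=float)
    return pd.DataFrame(cols)


def fit_logistic(
    outcome,
    stage=None,
    slope=None,
    reference: str = "Wake",
) -> GLMFit:
    """IRLS maximum-likelihood logistic fit of insight on the given terms.

    ``stage`` (categorical, treatment-coded against ``reference``) and
    ``slope`` (continuous) are each optional; omitting both fits the
    intercept-only null model. Complete separation is flagged rather than
    raised.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    X = _design_matrix(y.size, stage, slope, reference)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # separation is detected and flagged on the result instead
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-10)
    mu = res.predict(X)
    # diverging coefficients or a perfect 0/1 fit indicate (quasi-)separation
    separation = bool(
        np.any(np.abs(res.params) > 15.0) or np.all(np.abs(mu - y) < 1e-6)
    )
    k = X.shape[1]
    terms = [c for c in X.columns]
    return GLMFit(
        params=res.params,
        bse=res.bse,
        zvalues=res.params / res.bse,
        pvalues=pd.Series(
            2.0 * stats.norm.sf(np.abs(res.params / res.bse)), index=res.params.index
        ),
        loglik=float(res.llf),
        aic=float(-2.0 * res.llf + 2 * k),
        k=k,
        terms=terms,
        reference=reference,
        separation=separation,
        _design_terms=(stage is not None, slope is not None),
    )


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


def likelihood_ratio_test(fit_null: GLMFit, fit_full: GLMFit) -> LRTResult:
    """Deviance-difference test between two nested logistic fits."""
    if fit_full.k < fit_null.k or not set(fit_null.terms) <= set(fit_full.terms):
        raise ValueError("models are not nested (null terms must be a subset)")
    df = fit_full.k - fit_null.k
    chi2 = 2.0 * (fit_full.loglik - fit_null.loglik)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(chi2=float(chi2), df=df, p=p)


def mcfadden_adjusted_r2(fit: GLMFit, null_fit: GLMFit) -> float:
    """Adjusted McFadden pseudo-R²: 1 - (LL_fit - k_fit) / LL_null."""
    if null_fit.loglik == 0.0:
        raise ValueError("null model log-likelihood is zero")
    return float(1.0 - (fit.loglik - fit.k) / null_fit.loglik)


# ---------------------------------------------------------------------------
# model ladder across channels
# ---------------------------------------------------------------------------

def channelwise_model_comparison(
    slopes: pd.DataFrame,
    stage_labels: dict[str, str] | pd.Series,
    insight_labels: dict[str, bool] | pd.Series,
) -> pd.DataFrame:
    """Fit the three-model ladder per channel and tabulate the comparison.

    ``slopes`` is subjects x channels (spectral slope, -x). Rows with a
    missing slope are dropped per channel (count logged in the output).
    Returns one row per channel with AICs, LRT statistics and p-values,
    adjusted McFadden R²s and the minimal-AIC model name.
    """
    stage = pd.Series(stage_labels)
    insight = pd.Series(insight_labels).astype(float)
    rows = []
    for ch in slopes.columns:
        s = slopes[ch]
        ok = s.notna() & s.index.isin(stage.index) & s.index.isin(insight.index)
        ids = s.index[ok]
        y = insight.loc[ids].to_numpy()
        g = stage.loc[ids].to_numpy()
        x = s.loc[ids].to_numpy()
        null = fit_logistic(y)
        base = fit_logistic(y, stage=g)
        full = fit_logistic(y, stage=g, slope=x)
        slope_only = fit_logistic(y, slope=x)
        aics = {
            "baseline": base.aic, "full": full.aic, "slope_only": slope_only.aic
        }
        rows.append(
            {
                "channel": ch,
                "n": int(ok.sum()),
                "n_dropped": int((~ok).sum()),
                "aic_null": null.aic,
                "aic_baseline": base.aic,
                "aic_full": full.aic,
                "aic_slope_only": slope_only.aic,
                "lrt_full_vs_baseline_chi2": likelihood_ratio_test(base, full).chi2,
                "lrt_full_vs_baseline_p": likelihood_ratio_test(base, full).p,
                "lrt_full_vs_slope_chi2": likelihood_ratio_test(slope_only, full).chi2,
                "lrt_full_vs_slope_p": likelihood_ratio_test(slope_only, full).p,
                "beta_slope_full": float(full.params.get("slope", np.nan)),
                "beta_slope_only": float(slope_only.params.get("slope", np.nan)),
                "r2_baseline": mcfadden_adjusted_r2(base, null),
                "r2_full": mcfadden_adjusted_r2(full, null),
                "r2_slope_only": mcfadden_adjusted_r2(slope_only, null),
                "best_model": min(aics, key=aics.get),
            }
        )
    return pd.DataFrame(rows).set_index("channel")


# ---------------------------------------------------------------------------
# descriptive two-sample tests
# ---------------------------------------------------------------------------

def descriptive_tests(a, b, kind: str = "welch_t"):
    """Standard two-sided Welch t or two-sample Kolmogorov-Smirnov test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    if kind == "welch_t":
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            raise ValueError("degenerate (zero-variance) samples for Welch t")
        res = stats.ttest_ind(a, b, equal_var=False)
        return {"statistic": float(res.statistic), "df": float(res.df),
                "p": float(res.pvalue)}
    if kind == "ks_2sample":
        res = stats.ks_2samp(a, b)
        return {"statistic": float(res.statistic), "df": None,
                "p": float(res.pvalue)}
    raise ValueError(f"unknown test kind {kind!r}")
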