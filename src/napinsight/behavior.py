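"""Behavioural analysis: inclusion filters, sigmoid change-point model,
insight classification and switch-aligned performance summaries.

The change-point model is the four-parameter sigmoid

    y(t) = y_min + (y_max - y_min) / (1 + exp(-m * (t - t_s)))

fit by Bernoulli maximum likelihood to the binary correctness series on
the noisiest (5% coherence) trials, with a multi-start grid over the
switch centre t_s to avoid local optima. The fitted t_s (the sigmoid
midpoint) is interpreted as the trial of insight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core import EASY_COHERENCES, SessionData, Subject

LOW_COHERENCE = 0.05
INSIGHT_ACCURACY_CRITERION = 0.85
LEARNING_ACCURACY_CRITERION = 0.80
#: Last fully uncorrelated block: the colour rule starts mid block 4,
#: so block 3 is the latest block whose trials are all rule-free.
LEARNING_FILTER_BLOCK = 3
M_CAP = 10.0
_EPS = 1e-9


@dataclass
class SigmoidFit:
    y_min: float
    y_max: float
    m: float
    t_s: float
    loglik: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return sigmoid(np.asarray(t, dtype=float),
                       self.y_min, self.y_max, self.m, self.t_s)


@dataclass
class InsightLabel:
    subject_id: str
    is_insight: bool | None
    t_s: float | None
    excluded: bool = False
    reason: str = "none"  # "low-accuracy" | "pre-nap-insight" | "none"


def sigmoid(t: np.ndarray, y_min: float, y_max: float,
            m: float, t_s: float) -> np.ndarray:
    z = np.clip(-m * (t - t_s), -500.0, 500.0)
    return y_min + (y_max - y_min) / (1.0 + np.exp(z))


def _nll(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    y_min, dy, m, t_s = params
    p = sigmoid(t, y_min, min(y_min + dy, 1.0), m, t_s)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def fit_sigmoid(
    correct_series: np.ndarray,
    trial_positions: np.ndarray,
    grid_step: int = 10,
    n_refine: int = 5,
) -> SigmoidFit:
    """Maximum-likelihood sigmoid fit to a binary correctness series.

    Multi-start: candidate t_s values every ``grid_step`` trials across the
    fitted range are scored with heuristic remaining parameters (window
    means before/after the candidate, a small grid of slopes); the best
    ``n_refine`` candidates are polished with bounded L-BFGS-B. Ties
    between equally likely optima are broken towards the smallest t_s; the
    slope is capped at 10 per trial and probabilities bounded in [0, 1].
    """
    y = np.asarray(correct_series, dtype=float)
    t = np.asarray(trial_positions, dtype=float)
    if y.size != t.size:
        raise ValueError("series and positions must have equal length")
    if y.size < 30:
        raise ValueError("need at least 30 trials to fit the sigmoid")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]

    lo, hi = float(t[0]), float(t[-1])
    grid = np.arange(lo, hi + grid_step / 2.0, grid_step, dtype=float)
    m_grid = (0.02, 0.1, 0.3, 1.0, 5.0)
    cands: list[tuple[float, np.ndarray]] = []
    for ts0 in grid:
        pre = y[t < ts0]
        post = y[t >= ts0]
        a = float(np.mean(pre)) if pre.size else float(np.mean(y))
        bmax = float(np.mean(post)) if post.size else float(np.mean(y))
        a = float(np.clip(a, 0.0, 1.0))
        d = float(np.clip(bmax - a, 0.0, 1.0 - a))
        for m0 in m_grid:
            p0 = np.array([a, max(d, 0.01), m0, ts0])
            cands.append((_nll(p0, t, y), p0))
    cands.sort(key=lambda c: (c[0], c[1][3]))

    bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, M_CAP), (lo, hi)]
    best_nll, best_params, best_ok = cands[0][0], cands[0][1], False
    seen_ts: set[float] = set()
    for nll0, p0 in cands:
        if p0[3] in seen_ts:
            continue
        seen_ts.add(p0[3])
        if len(seen_ts) > n_refine:
            break
        res = minimize(_nll, p0, args=(t, y), method="L-BFGS-B",
                       bounds=bounds)
        if res.fun < best_nll - 1e-9 or (
            abs(res.fun - best_nll) <= 1e-9 and res.x[3] < best_params[3]
        ):
            best_nll, best_params, best_ok = float(res.fun), res.x, bool(res.success)
        elif not best_ok and res.success and abs(res.fun - best_nll) <= 1e-6:
            best_ok = True
    y_min, dy, m, t_s = best_params
    return SigmoidFit(
        y_min=float(y_min),
        y_max=float(min(y_min + dy, 1.0)),
        m=float(m),
        t_s=float(np.clip(t_s, lo, hi)),
        loglik=-best_nll,
        converged=bool(best_ok),
    )


def fit_session_sigmoid(session: SessionData) -> SigmoidFit:
    """Fit the change-point model to a session's 5%-coherence series."""
    sel = [tr for tr in session.trials
           if np.isclose(tr.coherence, LOW_COHERENCE) and not tr.instructed]
    return fit_sigmoid(
        np.array([tr.correct for tr in sel], dtype=float),
        np.array([tr.trial_index for tr in sel], dtype=float),
    )


# ---------------------------------------------------------------------------
# inclusion / classification
# ---------------------------------------------------------------------------

def apply_inclusion_filters(
    cohort: list[Subject],
    accuracy_threshold: float = LEARNING_ACCURACY_CRITERION,
    filter_block: int = LEARNING_FILTER_BLOCK,
) -> tuple[list[Subject], list[InsightLabel]]:
    """Apply the two pre-analysis exclusion rules.

    A subject is excluded ("low-accuracy") when accuracy on the three
    easiest coherence levels in the last uncorrelated block falls below
    80%, and ("pre-nap-insight") when the fitted switch centre lies before
    the nap boundary with criterion-level (>85%) performance on the
    noisiest trials of the pre-nap correlated phase. Returns the kept
    cohort and a per-subject exclusion log.
    """
    if not cohort:
        raise ValueError("empty cohort")
    kept: list[Subject] = []
    log: list[InsightLabel] = []
    for subj in cohort:
        s = subj.session
        easy_acc = np.nanmean([
            s.accuracy(coherence=c, blocks=[filter_block]) for c in EASY_COHERENCES
        ])
        if easy_acc < accuracy_threshold:
            log.append(InsightLabel(subj.subject_id, None, None, True, "low-accuracy"))
            continue
        fit = fit_session_sigmoid(s)
        pre_nap_acc = s.accuracy(
            coherence=LOW_COHERENCE,
            trial_range=(s.colour_onset_trial, s.nap_boundary_trial),
        )
        if (
            fit.t_s < s.nap_boundary_trial
            and not np.isnan(pre_nap_acc)
            and pre_nap_acc > INSIGHT_ACCURACY_CRITERION
        ):
            log.append(
                InsightLabel(subj.subject_id, None, None, True, "pre-nap-insight")
            )
            continue
        subj.truth["sigmoid_fit"] = fit
        kept.append(subj)
        log.append(InsightLabel(subj.subject_id, None, None, False, "none"))
    return kept, log


def classify_insight(session: SessionData, fit: SigmoidFit) -> InsightLabel:
    """Label a session as insight iff accuracy on 5%-coherence trials in
    the last pre-instruction block exceeds 85%; the switch point is the
    fitted sigmoid midpoint."""
    block = session.instruction_block - 1
    acc = session.accuracy(coherence=LOW_COHERENCE, blocks=[block])
    is_insight = bool(acc > INSIGHT_ACCURACY_CRITERION)
    return InsightLabel(
        subject_id=session.subject_id,
        is_insight=is_insight,
        t_s=float(fit.t_s) if is_insight else None,
    )


def label_cohort(kept: list[Subject]) -> list[InsightLabel]:
    """Classify every included subject, fitting the sigmoid if needed."""
    labels = []
    for subj in kept:
        fit = subj.truth.get("sigmoid_fit") or fit_session_sigmoid(subj.session)
        subj.truth["sigmoid_fit"] = fit
        labels.append(classify_insight(subj.session, fit))
    return labels


# ---------------------------------------------------------------------------
# switch-aligned summaries
# ---------------------------------------------------------------------------

@dataclass
class SwitchAlignedSummary:
    offsets: np.ndarray          # relative trial positions (t - t_s)
    accuracy: np.ndarray         # mean accuracy per offset bin
    pre_mean: float              # mean accuracy, window before the switch
    post_mean: float             # mean accuracy, window after the switch
    jump: float                  # post_mean - pre_mean
    n_subjects: int


def switch_aligned_summary(
    sessions: list[SessionData],
    labels: list[InsightLabel],
    window_trials: int = 15,
) -> SwitchAlignedSummary:
    """Align 5%-coherence accuracy to each insight subject's switch point.

    Alignment and windows run over the low-coherence trial *series*: the
    first 5%-coherence trial at or after t_s has offset 0, and the jump is
    the difference between the subject-mean accuracy in the
    ``window_trials`` series trials from offset 0 versus the
    ``window_trials`` series trials before it. Raises if no insight
    subject has data on both sides; a window reaching past the available
    trials is truncated.
    """
    by_id = {lb.subject_id: lb for lb in labels}
    pre_means, post_means = [], []
    rel_all, acc_all = [], []
    for s in sessions:
        lb = by_id.get(s.subject_id)
        if lb is None or not lb.is_insight or lb.t_s is None:
            continue
        sel = [tr for tr in s.trials
               if np.isclose(tr.coherence, LOW_COHERENCE) and not tr.instructed]
        positions = np.array([tr.trial_index for tr in sel], dtype=float)
        acc = np.array([tr.correct for tr in sel], dtype=float)
        k = int(np.searchsorted(positions, lb.t_s))
        pre = acc[max(0, k - window_trials) : k]
        post = acc[k : k + window_trials]
        if pre.size and post.size:
            pre_means.append(pre.mean())
            post_means.append(post.mean())
        rel_all.append(np.arange(acc.size) - k)
        acc_all.append(acc)
    if not pre_means:
        raise ValueError("no insight subjects with data in the alignment window")
    rel_cat = np.concatenate(rel_all)
    acc_cat = np.concatenate(acc_all)
    uniq = np.unique(rel_cat)
    curve = np.array([acc_cat[rel_cat == u].mean() for u in uniq])
    pre_mean = float(np.mean(pre_means))
    post_mean = float(np.mean(post_means))
    return SwitchAlignedSummary(
        offsets=uniq.astype(float),
        accuracy=curve,
        pre_mean=pre_mean,
        post_mean=post_mean,
        jump=post_mean - pre_mean,
        n_subjects=len(pre_means),
    )


def group_insight_table(labels: list[InsightLabel], groups: dict[str, str]):
    """Counts of insight / no-insight per vigilance group.

    ``groups`` maps subject id -> group label. Returns a pandas DataFrame
    with rows ordered N2, N1, Wake and columns [insight, no_insight].
    """
    import pandas as pd

    counts = {g: [0, 0] for g in ("N2", "N1", "Wake")}
    n_labelled = 0
    for lb in labels:
        if lb.excluded or lb.is_insight is None:
            continue
        g = groups.get(lb.subject_id)
        if g not in counts:
            raise ValueError(f"unknown group for subject {lb.subject_id}: {g!r}")
        counts[g][0 if lb.is_insight else 1] += 1
        n_labelled += 1
    if n_labelled == 0:
        raise ValueError("no labelled subjects to tabulate")
    return pd.DataFrame(
        counts, index=["insight", "no_insight"]
    ).T.loc[["N2", "N1", "Wake"]]
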