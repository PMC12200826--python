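"""Reported cohort counts of the nap-insight study the simulator emulates,
and the routine that recomputes the headline statistics from those counts.

The counts are the analysis inputs (insight / no-insight per vigilance
group); every statistic below is recomputed from them at call time — Fisher
tests, the logistic model ladder, the likelihood-ratio test and the Wald
test on the N2 contrast — and compared against the published values at
their printed precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import (
    fisher_exact_2x2,
    fit_logistic,
    likelihood_ratio_test,
)

#: (insight, no-insight) per vigilance group in the nap cohort (N=68).
STUDY_COUNTS = {"N2": (24, 4), "N1": (14, 8), "Wake": (10, 8)}

#: Insight counts for the whole post-nap cohort and the no-delay baseline
#: cohort from the predecessor study with the same task.
POST_NAP = (48, 20)
NO_DELAY_BASELINE = (49, 50)

#: N2 group after excluding members with under two minutes of N2 sleep.
N2_ADJUSTED = (21, 3)

#: Published values, with the number of printed decimals for comparison.
PRINTED = {
    "fisher_p_n2_vs_wake": (0.038, 3),
    "fisher_p_n1_vs_wake": (0.75, 2),
    "fisher_p_n1_vs_n2": (0.1, 1),
    "fisher_p_postnap_vs_baseline": (0.007, 3),
    "fisher_p_n2adj_vs_wake": (0.03, 2),
    "aic_null": (84.4, 1),
    "aic_stage": (82.5, 1),
    "lrt_chi2": (5.85, 2),
    "lrt_p": (0.05, 2),
    "beta_n2_vs_wake": (1.57, 2),
    "beta_n1_vs_wake": (0.34, 2),
    "wald_p_n2_vs_wake": (0.03, 2),
}


def _counts_to_outcome(counts: dict[str, tuple[int, int]]):
    y, g = [], []
    for group, (n_ins, n_no) in counts.items():
        y += [1] * n_ins + [0] * n_no
        g += [group] * (n_ins + n_no)
    return np.array(y, dtype=float), np.array(g)


def compute_headline_statistics(
    counts: dict[str, tuple[int, int]] | None = None,
    post_nap: tuple[int, int] = POST_NAP,
    baseline: tuple[int, int] = NO_DELAY_BASELINE,
    n2_adjusted: tuple[int, int] = N2_ADJUSTED,
) -> dict[str, float]:
    """Recompute every headline statistic from the contingency counts."""
    counts = dict(STUDY_COUNTS if counts is None else counts)
    if not counts:
        raise ValueError("empty counts fixture")
    n2, n1, w = counts["N2"], counts["N1"], counts["Wake"]
    out: dict[str, float] = {}
    out["fisher_p_n2_vs_wake"] = fisher_exact_2x2([n2, w])[0]
    out["fisher_p_n1_vs_wake"] = fisher_exact_2x2([n1, w])[0]
    out["fisher_p_n1_vs_n2"] = fisher_exact_2x2([n1, n2])[0]
    out["fisher_p_postnap_vs_baseline"] = fisher_exact_2x2([post_nap, baseline])[0]
    out["fisher_p_n2adj_vs_wake"] = fisher_exact_2x2([n2_adjusted, w])[0]

    y, g = _counts_to_outcome(counts)
    null = fit_logistic(y)
    stage = fit_logistic(y, stage=g)
    lrt = likelihood_ratio_test(null, stage)
    out["aic_null"] = null.aic
    out["aic_stage"] = stage.aic
    out["lrt_chi2"] = lrt.chi2
    out["lrt_p"] = lrt.p
    out["beta_n2_vs_wake"] = float(stage.params["stage[N2]"])
    out["beta_n1_vs_wake"] = float(stage.params["stage[N1]"])
    out["wald_p_n2_vs_wake"] = float(stage.pvalues["stage[N2]"])
    return out


def verify_printed_statistics(
    counts: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Compare recomputed statistics to published values at printed precision.

    Returns a table with columns computed / printed / passed; ``passed``
    means the computed value rounds to the printed one at its precision.
    """
    computed = compute_headline_statistics(counts)
    rows = []
    for name, (printed, ndigits) in PRINTED.items():
        value = computed[name]
        rows.append(
            {
                "statistic": name,
                "computed": value,
                "printed": printed,
                "passed": bool(round(value, ndigits) == printed),
            }
        )
    return pd.DataFrame(rows).set_index("statistic")
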