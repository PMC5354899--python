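"""Two-group differential-activation testing with FDR control.

Activity distributions are bounded in [0,1] and often skewed, so the default
test is the two-sided Wilcoxon rank-sum (Mann-Whitney U): exact when the
combined sample size is at most 20 and there are no ties, otherwise the
normal approximation with continuity and tie correction.  p-values are
Benjamini-Hochberg adjusted within each activity matrix, i.e. separately per
decomposition level.  An alternative two-sided t-test on logit-transformed
activities is available for users who prefer a parametric route.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ActivityMatrix

RESULT_COLUMNS = ("statistic", "p", "fdr", "direction",
                  "median_case", "median_control")


def _two_group_p(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 0.0, 1.0
    if method == "wilcoxon":
        n = len(x) + len(y)
        ties = len(np.unique(np.concatenate([x, y]))) < n
        how = "exact" if (n <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=how,
                                 use_continuity=True)
        return float(res.statistic), float(res.pvalue)
    if method == "logit_t":
        eps = 1e-6
        lx = np.log(np.clip(x, eps, 1 - eps) / (1 - np.clip(x, eps, 1 - eps)))
        ly = np.log(np.clip(y, eps, 1 - eps) / (1 - np.clip(y, eps, 1 - eps)))
        res = stats.ttest_ind(lx, ly)
        p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        return float(res.statistic), p
    raise ValueError(f"unknown test method {method!r}")


def compare_groups(
    acts: ActivityMatrix | pd.DataFrame,
    design: pd.Series,
    reference: str | None = None,
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-feature two-group comparison of activity values.

    ``design`` maps sample id to one of exactly two group labels;
    ``reference`` names the control group (defaults to the lexicographically
    smaller label).  Returns a DataFrame indexed by feature with columns
    statistic, p, fdr (Benjamini-Hochberg across the features of this
    matrix), direction ("UP" when the non-reference median exceeds the
    reference median, "DOWN" for the converse, missing on equal medians) and
    the two group medians.
    """
    vals = acts.values if isinstance(acts, ActivityMatrix) else acts
    design = pd.Series(design)
    labels = sorted(design.unique())
    if len(labels) != 2:
        raise ValueError(f"design must have exactly two groups, got {labels}")
    if reference is None:
        reference = labels[0]
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among group labels {labels}")
    case_label = labels[1] if reference == labels[0] else labels[0]
    missing = set(design.index) - set(vals.columns)
    if missing:
        raise ValueError(f"design samples absent from activity matrix: {sorted(missing)}")
    case_ids = design.index[design == case_label]
    ctrl_ids = design.index[design == reference]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each group needs at least 2 samples")

    case = vals[case_ids].to_numpy(dtype=float)
    ctrl = vals[ctrl_ids].to_numpy(dtype=float)
    records = []
    for i, feature in enumerate(vals.index):
        stat, p = _two_group_p(case[i], ctrl[i], method)
        med_case = float(np.median(case[i]))
        med_ctrl = float(np.median(ctrl[i]))
        if med_case > med_ctrl:
            direction = "UP"
        elif med_case < med_ctrl:
            direction = "DOWN"
        else:
            direction = pd.NA
        records.append((feature, stat, p, direction, med_case, med_ctrl))
    out = pd.DataFrame(
        records, columns=["feature", "statistic", "p", "direction",
                          "median_case", "median_control"],
    ).set_index("feature")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[list(RESULT_COLUMNS)]


def significant_features(results: pd.DataFrame, threshold: float) -> set[str]:
    """Features whose BH-adjusted p-value is strictly below ``threshold``."""
    if results.empty:
        raise ValueError("empty result table")
    return set(results.index[results["fdr"] < threshold])
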