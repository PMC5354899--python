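"""Survival stratification by circuit activity: extreme deciles, K-M, log-rank.

For each activity feature, the samples with the highest (or lowest) 10% of
activity are compared to the rest with the log-rank test on their
Kaplan-Meier curves; both sides are always tested and jointly
Benjamini-Hochberg corrected across all (feature, side) pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .profiles import ActivityMatrix

logger = logging.getLogger(__name__)


def read_survival_tsv(path) -> pd.DataFrame:
    """Read a survival table: columns sample, time, event (1=death, 0=censored)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    df = df.set_index("sample")[["time", "event"]].astype(float)
    _validate_records(df)
    return df


def _validate_records(records: pd.DataFrame) -> None:
    if (records["time"] < 0).any():
        raise ValueError("negative survival times")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")


def stratify_extreme(
    acts: ActivityMatrix | pd.DataFrame, feature: str,
    fraction: float = 0.1, side: str = "high",
) -> tuple[list[str], list[str]]:
    """Split samples into the extreme ``fraction`` for ``feature`` and the rest.

    The extreme set holds round(fraction*n) samples (round-half-up, minimum
    1); ties at the cut are broken by stable sample order, so the split is
    deterministic.  Raises on constant features, where stratification is
    meaningless.
    """
    vals = acts.values if isinstance(acts, ActivityMatrix) else acts
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    row = vals.loc[feature]
    if side not in ("high", "low"):
        raise ValueError(f"side must be 'high' or 'low', got {side!r}")
    x = row.to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError(f"feature {feature!r} is constant across samples")
    n = len(x)
    k = max(1, int(np.floor(fraction * n + 0.5)))
    key = -x if side == "high" else x
    order = np.argsort(key, kind="stable")
    extreme = [row.index[i] for i in order[:k]]
    rest = [row.index[i] for i in order[k:]]
    return extreme, rest


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve; columns time, survival.

    Censored times shrink the risk set without producing a step.
    """
    if records.empty:
        raise ValueError("no survival records")
    _validate_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    _validate_records(group_a)
    _validate_records(group_b)
    if group_a["event"].sum() + group_b["event"].sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(group_a["time"], group_b["time"],
                      event_observed_A=group_a["event"],
                      event_observed_B=group_b["event"])
    return float(res.test_statistic), float(res.p_value)


def _prognosis(extreme: pd.DataFrame, rest: pd.DataFrame) -> str:
    """'bad' iff the extreme stratum's K-M curve lies below the rest's at
    the pooled median follow-up time."""
    t_med = float(np.median(pd.concat([extreme, rest])["time"]))

    def s_at(rec: pd.DataFrame) -> float:
        kmf = KaplanMeierFitter().fit(rec["time"], rec["event"])
        return float(kmf.survival_function_at_times(t_med).iloc[0])

    return "bad" if s_at(extreme) < s_at(rest) else "good"


def survival_scan(
    acts: ActivityMatrix | pd.DataFrame,
    records: pd.DataFrame,
    fraction: float = 0.1,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Extreme-decile log-rank scan over every feature and both sides.

    Returns a table indexed by (feature, stratum in {high10, low10}) with the
    log-rank statistic, raw and BH-adjusted p (joint across all rows), the
    prognosis call for the extreme stratum, and a significance flag at
    ``threshold``.  Features that cannot be stratified (constant activity)
    are skipped with a warning.
    """
    vals = acts.values if isinstance(acts, ActivityMatrix) else acts
    _validate_records(records)
    shared = [s for s in vals.columns if s in records.index]
    if len(shared) < 10:
        raise ValueError("need at least 10 samples shared between activities "
                         "and survival records")
    sub = vals[shared]
    rec = records.loc[shared]
    rows = []
    for feature in sub.index:
        for side in ("high", "low"):
            try:
                extreme, rest = stratify_extreme(sub, feature, fraction, side)
            except ValueError as exc:
                logger.warning("feature %s (%s): %s; skipped", feature, side, exc)
                break
            a, b = rec.loc[extreme], rec.loc[rest]
            if a["event"].sum() + b["event"].sum() == 0:
                logger.warning("feature %s (%s): no events; skipped", feature, side)
                continue
            stat, p = logrank_test(a, b)
            rows.append({
                "feature": feature, "stratum": f"{side}10",
                "statistic": stat, "p": p,
                "prognosis": _prognosis(a, b),
                "n_extreme": len(extreme), "n_rest": len(rest),
            })
    if not rows:
        raise ValueError("no feature could be tested")
    out = pd.DataFrame(rows).set_index(["feature", "stratum"])
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["fdr"] < threshold
    return out


def plot_km(extreme: pd.DataFrame, rest: pd.DataFrame, ax=None, labels=("extreme", "rest")):
    """Step-curve K-M plot for the two strata (optional convenience)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for rec, label in zip((extreme, rest), labels):
        KaplanMeierFitter().fit(rec["time"], rec["event"], label=label).plot_survival_function(ax=ax)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    return ax
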