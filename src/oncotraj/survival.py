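"""Kaplan-Meier estimation, the log-rank test, and cutpoint selection.

The log-rank statistic is computed in-package (hypergeometric variance,
simultaneous-event tie convention) because the maximally selected cutpoint
search evaluates it at every candidate threshold; lifelines backs the KM
estimates and serves as an independent cross-check of the statistic in the
test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = ["km_estimate", "log_rank_test", "score_cutpoint_groups"]


def km_estimate(surv: pd.DataFrame, groups: pd.Series) -> dict:
    """Kaplan-Meier product-limit curve per group.

    Returns group -> DataFrame with columns time and survival (step values).
    """
    g = pd.Series(groups).reindex(surv.index)
    out = {}
    for label, idx in g.groupby(g).groups.items():
        sub = surv.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"group {label!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        out[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def _logrank_chi2_two(time, event, in_group1):
    """Vectorized two-group log-rank chi-square."""
    order = np.argsort(time, kind="stable")
    time, event, g1 = time[order], event[order], in_group1[order]
    ev_times = time[event == 1]
    ut = np.unique(ev_times)
    if ut.size == 0:
        return 0.0
    n = len(time)
    n1 = int(g1.sum())
    t1 = time[g1.astype(bool)]
    nj = n - np.searchsorted(time, ut, side="left")
    n1j = n1 - np.searchsorted(np.sort(t1, kind="stable"), ut, side="left")
    dj = np.searchsorted(ev_times, ut, side="right") - np.searchsorted(
        ev_times, ut, side="left"
    )
    ev1_times = time[(event == 1) & g1.astype(bool)]
    ev1_sorted = np.sort(ev1_times, kind="stable")
    d1j = np.searchsorted(ev1_sorted, ut, side="right") - np.searchsorted(
        ev1_sorted, ut, side="left"
    )
    frac = n1j / nj
    o_minus_e = float((d1j - dj * frac).sum())
    ok = nj > 1
    v = float(
        (dj[ok] * frac[ok] * (1.0 - frac[ok]) * (nj[ok] - dj[ok]) / (nj[ok] - 1.0)).sum()
    )
    if v <= 0:
        return 0.0
    return o_minus_e**2 / v


def _logrank_chi2(time, event, codes, k):
    """Standard k-group log-rank chi-square (hypergeometric variance)."""
    if k == 2:
        return _logrank_chi2_two(time, event, codes == 1)
    order = np.argsort(time, kind="stable")
    time, event, codes = time[order], event[order], codes[order]
    uniq_times = np.unique(time[event == 1])
    n_at_risk = np.zeros(k)
    # counts at risk computed per event time by suffix sums
    obs = np.zeros(k)
    exp = np.zeros(k)
    cov = np.zeros((k, k))
    for t in uniq_times:
        at_risk = time >= t
        nj = float(at_risk.sum())
        dead = (time == t) & (event == 1)
        dj = float(dead.sum())
        for g in range(k):
            n_at_risk[g] = float((at_risk & (codes == g)).sum())
        d_g = np.array([float((dead & (codes == g)).sum()) for g in range(k)])
        obs += d_g
        exp += dj * n_at_risk / nj
        if nj > 1:
            factor = dj * (nj - dj) / (nj - 1.0)
            for a in range(k):
                for b in range(k):
                    delta = 1.0 if a == b else 0.0
                    cov[a, b] += factor * (n_at_risk[a] / nj) * (
                        delta - n_at_risk[b] / nj
                    )
    z = (obs - exp)[: k - 1]
    v = cov[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(v) @ z)
    return chi2


def log_rank_test(surv: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Log-rank test across groups; returns (chi2, p) with k-1 df."""
    g = pd.Series(groups).reindex(surv.index)
    codes = pd.Categorical(g).codes.astype(int)
    k = int(codes.max()) + 1
    if k < 2:
        raise ValueError("need at least two groups")
    for label, cnt in g.value_counts().items():
        if cnt == 0:
            raise ValueError(f"group {label!r} has zero subjects")
    chi2 = _logrank_chi2(
        surv["time"].to_numpy(dtype=float),
        surv["event"].to_numpy(dtype=int),
        codes,
        k,
    )
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, p


def score_cutpoint_groups(
    scores: pd.Series, surv: pd.DataFrame, min_prop: float = 0.1
) -> tuple[float, pd.Series, float]:
    """Maximally selected log-rank split of a continuous score.

    Every distinct score is tried as a threshold (low: score <= cut, high:
    score > cut) subject to both groups holding at least ``min_prop`` of the
    subjects; the cut maximizing the log-rank chi-square wins.  The returned p
    is the raw log-rank p at the chosen cut and is selection-biased (no
    multiplicity correction), matching common 'automatic grouping' practice.
    """
    s = pd.Series(scores).reindex(surv.index)
    vals = np.sort(s.unique())
    if len(vals) < 2:
        raise ValueError("scores are constant; no valid cutpoint exists")
    n = len(s)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    sv = s.to_numpy()
    best = (-np.inf, None)
    for cut in vals[:-1]:
        high = sv > cut
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_prop * n:
            continue
        chi2 = _logrank_chi2(time, event, high.astype(int), 2)
        if chi2 > best[0]:
            best = (chi2, cut)
    if best[1] is None:
        raise ValueError("no cutpoint satisfies the min_prop constraint")
    chi2, cut = best
    groups = pd.Series(
        np.where(sv > cut, "high", "low"), index=s.index, name="group"
    )
    p = float(stats.chi2.sf(chi2, 1))
    return float(cut), groups, p
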