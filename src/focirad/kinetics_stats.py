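"""Statistics over per-nucleus focus counts: box summaries, rank tests,
time courses, focus-area growth curves.

Quantiles use linear interpolation between order statistics throughout
(numpy's default convention). Outliers follow the 1.5*IQR rule relative to
the 25th/75th percentiles. Group comparisons use the two-sided Mann-Whitney
rank-sum test, exact by enumeration for small tie-free samples, otherwise a
normal approximation with tie and continuity corrections; significance is
flagged at alpha = 0.05. Per-time-point p-values are reported without
multiplicity correction by default (a Holm option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
EXACT_MAX_COMBINATIONS = 100_000


@dataclass
class BoxSummary:
    """Five-number-plus summary used in focus-count box plots."""

    n: int
    mean: float
    median: float
    q25: float
    q75: float
    p5: float
    p95: float
    outliers: np.ndarray

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


def summarize(group) -> BoxSummary:
    """Box summary of one group of counts (n >= 1).

    Outliers are values outside [q25 - 1.5*IQR, q75 + 1.5*IQR].
    """
    x = np.asarray(group, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    p5, p95 = np.quantile(x, [0.05, 0.95])
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    return BoxSummary(
        n=int(x.size),
        mean=float(x.mean()),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        p5=float(p5),
        p95=float(p95),
        outliers=np.sort(x[(x < lo) | (x > hi)]),
    )


def compare_groups(a, b) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney comparison of two count groups.

    Returns ``(U, p, significant_at_0.05)`` where U is the statistic of the
    first group. The exact null distribution is used when the number of
    orderings C(n+m, n) is at most 1e5 and the pooled sample is tie-free;
    otherwise the normal approximation with midrank tie correction and
    continuity correction.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact_ok = (not has_ties) and comb(x.size + y.size, x.size) <= EXACT_MAX_COMBINATIONS
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = min(float(res.pvalue), 1.0)
    return float(res.statistic), p, p < ALPHA


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def time_course(
    records: pd.DataFrame,
    group_by: str = "treatment",
    *,
    holm_correction: bool = False,
) -> pd.DataFrame:
    """Per-(time, group) box summaries plus treated-vs-untreated p-values.

    ``records`` is a count-record table (columns ``t_pi_min``, ``dsb_count``
    and the grouping column). When the grouping column has exactly two
    levels, a Mann-Whitney p-value comparing them is attached per time
    point; the default applies no multiplicity correction, the usual
    convention in focus-kinetics studies.
    """
    if "t_pi_min" not in records or "dsb_count" not in records:
        raise ValueError("records must carry t_pi_min and dsb_count columns")
    rows = []
    times = np.sort(records["t_pi_min"].unique())
    groups = sorted(records[group_by].unique())
    for t in times:
        at_t = records[records["t_pi_min"] == t]
        for g in groups:
            counts = at_t.loc[at_t[group_by] == g, "dsb_count"].to_numpy()
            if counts.size == 0:
                continue
            s = summarize(counts)
            rows.append(
                {
                    "t_pi_min": t,
                    group_by: g,
                    "n": s.n,
                    "mean": s.mean,
                    "median": s.median,
                    "q25": s.q25,
                    "q75": s.q75,
                    "p5": s.p5,
                    "p95": s.p95,
                    "n_outliers": len(s.outliers),
                }
            )
    table = pd.DataFrame(rows)
    if len(groups) == 2:
        pvals = []
        for t in times:
            at_t = records[records["t_pi_min"] == t]
            ga = at_t.loc[at_t[group_by] == groups[0], "dsb_count"].to_numpy()
            gb = at_t.loc[at_t[group_by] == groups[1], "dsb_count"].to_numpy()
            if ga.size and gb.size:
                _, p, _ = compare_groups(ga, gb)
            else:
                p = np.nan
            pvals.append(p)
        pvals = np.asarray(pvals)
        if holm_correction:
            valid = ~np.isnan(pvals)
            adj = pvals.copy()
            adj[valid] = _holm(pvals[valid])
            pvals = adj
        pmap = dict(zip(times, pvals))
        table["p_value"] = table["t_pi_min"].map(pmap)
        table["significant"] = table["p_value"] < ALPHA
    return table


def mean_curve(records: pd.DataFrame, group_by: str = "treatment") -> pd.DataFrame:
    """Mean focus count per time point and group (the Fig-11-style curve)."""
    return (
        records.groupby(["t_pi_min", group_by])["dsb_count"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_count", "count": "n"})
    )


def focus_area_course(
    records: pd.DataFrame, group_by: str = "treatment"
) -> pd.DataFrame:
    """Pooled per-focus pixel areas per (time, group): mean and SE.

    The unit is pixels per focus (max-projection footprint).
    """
    if "focus_areas_px" not in records:
        raise ValueError("records must carry a focus_areas_px column")
    rows = []
    for (t, g), sub in records.groupby(["t_pi_min", group_by]):
        areas = np.concatenate(
            [np.asarray(a, dtype=float) for a in sub["focus_areas_px"]]
        ) if len(sub) else np.empty(0)
        if areas.size == 0:
            continue
        se = float(areas.std(ddof=1) / np.sqrt(areas.size)) if areas.size > 1 else 0.0
        rows.append(
            {
                "t_pi_min": t,
                group_by: g,
                "n_foci": int(areas.size),
                "mean_area_px": float(areas.mean()),
                "se_area_px": se,
            }
        )
    if not rows:
        raise ValueError("no focus areas present in records")
    return pd.DataFrame(rows).sort_values(["t_pi_min", group_by]).reset_index(drop=True)
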