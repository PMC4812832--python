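"""Trial statistics for behavior-change evaluation.

Per-user weekly medians of walking length and meal calories are classified
into positive / negative trends (longer walks or fewer meal calories from
week 1 to week 3 count as positive), the per-arm positive counts form a
2x2 table tested with Fisher's exact test, and group-level comparisons use
the Mann-Whitney U test (ordinal ratings) and the pooled two-sample t test
with Cohen's d (daily totals).

The Fisher p-value is computed by full hypergeometric enumeration (sum of
the probabilities of all tables with the observed margins whose point
probability does not exceed the observed table's), the convention used by
mainstream statistical software for the two-sided test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.stats import t as t_dist

from .synthetic_data import TrialData, metric_events

WEEK_DAYS = 7
N_WEEKS = 3

#: healthy direction of the week-1 -> week-3 change, per metric
METRIC_SIGN = {"walk_length_minutes": +1.0, "meal_kcal": -1.0}
METRIC_KIND = {"walk_length_minutes": "walk", "meal_kcal": "meal"}


@dataclass(frozen=True)
class TrendResult:
    user_id: str
    metric: str
    weekly_medians: tuple[float, float, float] | None
    direction: str | None  # positive | negative
    insufficient_data: bool

    @property
    def positive(self) -> bool:
        """Insufficient-data users count as non-positive."""
        return self.direction == "positive" and not self.insufficient_data


@dataclass(frozen=True)
class TrialTable:
    """2x2 counts: rows = (experimental, control), cols = (positive, non-positive)."""

    a: int  # experimental positive
    b: int  # experimental non-positive
    c: int  # control positive
    d: int  # control non-positive

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def as_list(self):
        return [[self.a, self.b], [self.c, self.d]]


def weekly_trend(events: pd.DataFrame, metric: str, user_id: str = "") -> TrendResult:
    """Classify one user's week-1 -> week-3 trend for a metric.

    ``events`` has columns day / kind / value with day 0 the first study
    day. The direction compares the week-3 and week-1 medians in the
    metric's healthy direction; a week with no events flags
    insufficient_data (no direction assigned).
    """
    if metric not in METRIC_SIGN:
        raise ValueError(f"unknown metric {metric!r}")
    if events["day"].max() < (N_WEEKS - 1) * WEEK_DAYS:
        raise ValueError("log must span 3 weeks")
    kind = METRIC_KIND[metric]
    sub = events[events["kind"] == kind]
    medians = []
    for w in range(N_WEEKS):
        vals = sub.loc[(sub["day"] >= w * WEEK_DAYS) & (sub["day"] < (w + 1) * WEEK_DAYS), "value"]
        medians.append(float(np.median(vals)) if len(vals) else np.nan)
    if any(np.isnan(m) for m in medians):
        return TrendResult(user_id, metric, None, None, True)
    change = (medians[2] - medians[0]) * METRIC_SIGN[metric]
    direction = "positive" if change > 0 else "negative"
    return TrendResult(user_id, metric, tuple(medians), direction, False)


def fisher_exact_2x2(table: TrialTable | list) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    All tables with the observed margins whose point probability is at
    most the observed one's contribute to the tail.
    """
    if isinstance(table, TrialTable):
        (a, b), (c, d) = table.as_list()
    else:
        (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or (b + d) == 0:
        raise ValueError("all margins must be positive")
    lo, hi = max(0, k - r2), min(k, r1)
    xs = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(xs, n, r1, k)
    p_obs = probs[a - lo]
    # small relative tolerance so equal-probability tables are included
    p = float(np.sum(probs[probs <= p_obs * (1.0 + 1e-9)]))
    return min(p, 1.0)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a_i, b_j) pairs with a_i > b_j (+ 0.5 ties)."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(
    sample_a, sample_b, exact_max_n: int = 12
) -> tuple[float, float, float]:
    """Mann-Whitney U with two-sided p and rank-biserial effect size.

    The p-value is exact (enumeration of all rank splits, respecting ties)
    for pooled n <= ``exact_max_n``, else a normal approximation with tie
    correction. Effect size is the rank-biserial correlation
    ``2U/(n_a n_b) - 1`` (0 for identical samples).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    u_obs = _u_statistic(a, b)
    mean_u = na * nb / 2.0
    effect = 2.0 * u_obs / (na * nb) - 1.0

    if na + nb <= exact_max_n:
        pooled = np.concatenate([a, b])
        idx = range(na + nb)
        count = 0
        total = comb(na + nb, na)
        obs_dev = abs(u_obs - mean_u)
        for pick in combinations(idx, na):
            mask = np.zeros(na + nb, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mean_u) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        # normal approximation with tie correction
        pooled = np.concatenate([a, b])
        n = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var_u = na * nb / 12.0 * (n + 1 - tie_term)
        if var_u == 0:
            return u_obs, 1.0, effect
        z = (abs(u_obs - mean_u) - 0.5) / sqrt(var_u)  # continuity corrected
        z = max(z, 0.0)
        p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    return u_obs, min(p, 1.0), effect


def two_sample_t(sample_a, sample_b) -> tuple[float, int, float, float]:
    """Pooled-variance two-sample t with Cohen's d.

    Returns (t, df, two-sided p, d) with df = n_a + n_b - 2. Degenerate
    zero-variance inputs: equal means give t = 0, d = 0; unequal means are
    an error (the statistic is undefined).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("both samples need n >= 2")
    df = na + nb - 2
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0, 0.0
        raise ValueError("zero pooled variance with unequal means")
    t = diff / sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    d = diff / sqrt(sp2)
    return float(t), df, p, float(d)


def group_summary(values) -> dict:
    v = np.asarray(values, dtype=float)
    return dict(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        q25=float(np.percentile(v, 25)),
        q50=float(np.percentile(v, 50)),
        q75=float(np.percentile(v, 75)),
    )


def analyze_trial(trial: TrialData, ratings: dict[str, list] | None = None) -> dict:
    """Full trial analysis.

    Returns per-user trends, 2x2 trend tables (insufficient-data users
    counted non-positive), the Fisher p per metric, week-1 -> week-3
    change summaries with the pooled t and Cohen's d, and, when rating
    vectors per arm are supplied, their Mann-Whitney comparison.
    """
    arms = trial.arms()
    if not arms["experimental"] or not arms["control"]:
        raise ValueError("both arms must contain at least one user")

    report: dict = {"trends": [], "tables": {}, "fisher_p": {}, "changes": {}}
    per_user_events = {u.profile.user_id: metric_events(u.data) for u in trial.users}

    for metric in METRIC_SIGN:
        counts = {}
        for arm_name, members in arms.items():
            pos = nonpos = 0
            for u in members:
                tr = weekly_trend(per_user_events[u.profile.user_id], metric, u.profile.user_id)
                report["trends"].append(tr)
                if tr.positive:
                    pos += 1
                else:
                    nonpos += 1
            counts[arm_name] = (pos, nonpos)
        table = TrialTable(*counts["experimental"], *counts["control"])
        report["tables"][metric] = table
        report["fisher_p"][metric] = fisher_exact_2x2(table)

        # week-1 -> week-3 change in per-user weekly medians, compared across arms
        changes = {}
        for arm_name, members in arms.items():
            vals = []
            for u in members:
                tr = next(
                    t for t in report["trends"]
                    if t.user_id == u.profile.user_id and t.metric == metric
                )
                if tr.weekly_medians is not None:
                    vals.append(tr.weekly_medians[2] - tr.weekly_medians[0])
            changes[arm_name] = vals
        summary = {arm: group_summary(v) for arm, v in changes.items() if v}
        if len(changes["experimental"]) >= 2 and len(changes["control"]) >= 2:
            t, df, p, d = two_sample_t(changes["experimental"], changes["control"])
            summary["t"] = t
            summary["df"] = df
            summary["p"] = p
            summary["cohens_d"] = d
        report["changes"][metric] = summary

    if ratings is not None:
        u, p, eff = mann_whitney_u(ratings["experimental"], ratings["control"])
        report["ratings"] = dict(
            U=u, p=p, rank_biserial=eff,
            experimental=group_summary(ratings["experimental"]),
            control=group_summary(ratings["control"]),
        )
    return report


def trends_tsv(report: dict) -> str:
    """Per-user trend table as TSV."""
    lines = ["user_id\tmetric\tweek1\tweek2\tweek3\tdirection\tinsufficient_data"]
    for tr in report["trends"]:
        med = tr.weekly_medians or (float("nan"),) * 3
        lines.append(
            f"{tr.user_id}\t{tr.metric}\t{med[0]:.2f}\t{med[1]:.2f}\t{med[2]:.2f}"
            f"\t{tr.direction or 'NA'}\t{tr.insufficient_data}"
        )
    return "\n".join(lines) + "\n"
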