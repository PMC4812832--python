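"""Exploit-explore suggestion generation over behavior clusters.

The engine treats each behavior cluster as an arm of a multi-armed bandit
whose payoff is energy balance. Each day it emits 10 activity and 10 food
suggestions at a fixed 9 + 1 exploit/explore split:

* exploit — the user's frequent behaviors, ranked by aggregate impact:
  weekly frequency x calories per instance for activities (descending
  burn), ascending per-instance calories for frequent meals and snacks;
* explore — a uniform draw from infrequent but demonstrated behaviors in
  the healthy calorie direction (above-median burn for activities,
  below-median intake for foods). Never-done behaviors are never suggested
  (if the user has done it, even rarely, the skills are assumed present);
* small change — frequent stationary episodes are converted into a
  prescription of a short walk per stationary hour, and the projected
  weekly burn of that change competes in the same exploit ranking.

As an infrequent behavior becomes frequent, recomputation moves it from
the explore pool to the exploit ranking; the engine learns from passive
frequency change only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .behavior_clustering import BehaviorCluster
from .energy import MetTable, activity_kcal

logger = logging.getLogger(__name__)

ACTIVITY_TYPES = ("trajectory", "manual_exercise_type")
FOOD_TYPES = ("meal", "snack")


@dataclass(frozen=True)
class EngineConfig:
    """Tunable parameters of the suggestion engine."""

    n_activity: int = 10
    n_food: int = 10
    exploit_fraction: float = 0.9
    frequent_min_count: int = 3  # occurrences per trailing 14 days
    small_change_walk_minutes: float = 3.0
    avoid_kcal_cutoff: dict = field(
        default_factory=lambda: {"lose": 500.0, "maintain": 700.0, "gain": float("inf")}
    )

    def __post_init__(self):
        if not 0.0 < self.exploit_fraction < 1.0:
            raise ValueError("exploit_fraction must be in (0, 1)")

    def n_exploit(self, n_slots: int) -> int:
        return int(np.floor(n_slots * self.exploit_fraction))


@dataclass(frozen=True)
class Suggestion:
    suggestion_id: str
    arm: str  # exploit | explore | small_change
    target_cluster_id: int
    category: str  # activity | food
    text: str
    projected_weekly_kcal: float
    rank: int  # 1-based within the daily batch


def score_activity_cluster(cluster: BehaviorCluster) -> float:
    """Aggregate weekly burn: weekly frequency x kcal per instance.

    The per-instance kcal stored on the cluster is already the MET-based
    expenditure for the user's body mass.
    """
    if cluster.cluster_type == "stationary_place":
        raise ValueError("stationary clusters are scored via small_change_for_stationary")
    return cluster.weekly_frequency * cluster.per_instance_calories


def small_change_for_stationary(
    cluster: BehaviorCluster,
    weight_kg: float,
    met_table: MetTable,
    config: EngineConfig,
) -> Suggestion:
    """Prescribe a short walk per stationary hour at this place.

    Projected weekly burn = weekly stationary hours x walking kcal of one
    ``small_change_walk_minutes`` bout; this competes with ordinary
    activity suggestions in the exploit ranking.
    """
    if cluster.cluster_type != "stationary_place":
        raise ValueError("small-change suggestions target stationary clusters")
    walk_kcal = activity_kcal("walking", config.small_change_walk_minutes, weight_kg, met_table)
    weekly_hours = cluster.weekly_frequency * cluster.per_instance_duration / 60.0
    minutes = int(config.small_change_walk_minutes)
    return Suggestion(
        suggestion_id=f"sc-{cluster.cluster_id}",
        arm="small_change",
        target_cluster_id=cluster.cluster_id,
        category="activity",
        text=(
            f"Add a {minutes}-minute walk for every hour you spend "
            f"stationary at this spot (~{weekly_hours:.1f} h/week)."
        ),
        projected_weekly_kcal=weekly_hours * walk_kcal,
        rank=0,
    )


def partition_exploit_explore(
    clusters: list[BehaviorCluster], config: EngineConfig
) -> tuple[list[BehaviorCluster], list[BehaviorCluster]]:
    """Split clusters into frequent (exploit) and infrequent-but-done (explore).

    Clusters with zero occurrences in the window are dropped entirely.
    """
    frequent = [c for c in clusters if c.frequency >= config.frequent_min_count]
    infrequent = [c for c in clusters if 1 <= c.frequency < config.frequent_min_count]
    return frequent, infrequent


def _exploit_text(c: BehaviorCluster, projected: float) -> str:
    if c.cluster_type in FOOD_TYPES:
        return (
            f"Continue choosing {c.label} (~{c.per_instance_calories:.0f} kcal, "
            f"{c.weekly_frequency:.1f}x/week)."
        )
    return (
        f"Keep up your {c.per_instance_duration:.0f}-min {c.label} "
        f"({c.weekly_frequency:.1f}x/week, ~{c.per_instance_calories:.0f} kcal each)."
    )


def _explore_text(c: BehaviorCluster) -> str:
    if c.cluster_type in FOOD_TYPES:
        return f"Try {c.label} again (~{c.per_instance_calories:.0f} kcal)."
    return (
        f"Try your occasional {c.per_instance_duration:.0f}-min {c.label} again "
        f"(~{c.per_instance_calories:.0f} kcal)."
    )


def generate_daily_batch(
    clusters: list[BehaviorCluster],
    category: str,
    *,
    weight_kg: float,
    met_table: MetTable,
    config: EngineConfig,
    rng: np.random.Generator,
) -> list[Suggestion]:
    """One day's ranked batch of suggestions for a category.

    Nine exploit slots are filled by the top frequent clusters (descending
    projected burn for activities, ascending per-instance kcal for foods);
    the tenth slot is a uniform draw from calorie-eligible infrequent
    clusters, backfilled from the exploit ranking when that pool is empty.
    Score ties go to the earlier-created cluster.
    """
    if category == "activity":
        n_slots = config.n_activity
        pool = [c for c in clusters if c.cluster_type in ACTIVITY_TYPES]
        stationary = [
            c
            for c in clusters
            if c.cluster_type == "stationary_place" and not c.meta.get("unlocated")
        ]
        all_kcal = [c.per_instance_calories for c in pool]
        median_kcal = float(np.median(all_kcal)) if all_kcal else 0.0
    elif category == "food":
        n_slots = config.n_food
        pool = [c for c in clusters if c.cluster_type in FOOD_TYPES]
        stationary = []
        all_kcal = [c.per_instance_calories for c in pool]
        median_kcal = float(np.median(all_kcal)) if all_kcal else 0.0
    else:
        raise ValueError(f"unknown category {category!r}")

    frequent, infrequent = partition_exploit_explore(pool, config)
    freq_stationary, _ = partition_exploit_explore(stationary, config)

    # build exploit candidates with projected impact
    candidates: list[Suggestion] = []
    for c in frequent:
        projected = score_activity_cluster(c)
        candidates.append(
            Suggestion(
                suggestion_id=f"ex-{c.cluster_id}",
                arm="exploit",
                target_cluster_id=c.cluster_id,
                category=category,
                text=_exploit_text(c, projected),
                projected_weekly_kcal=projected,
                rank=0,
            )
        )
    for c in freq_stationary:
        candidates.append(small_change_for_stationary(c, weight_kg, met_table, config))

    by_cluster = {c.cluster_id: c for c in pool + stationary}
    if category == "activity":
        # descending projected weekly burn
        candidates.sort(
            key=lambda s: (-s.projected_weekly_kcal, s.target_cluster_id)
        )
    else:
        # frequent low-calorie meals first
        candidates.sort(
            key=lambda s: (by_cluster[s.target_cluster_id].per_instance_calories, s.target_cluster_id)
        )

    n_exploit = min(config.n_exploit(n_slots), len(candidates))
    batch = candidates[:n_exploit]
    backfill = candidates[n_exploit:]

    # explore slot(s): uniform among calorie-eligible infrequent clusters
    n_explore_slots = n_slots - config.n_exploit(n_slots)
    if category == "activity":
        eligible = [c for c in infrequent if c.per_instance_calories >= median_kcal]
    else:
        eligible = [c for c in infrequent if c.per_instance_calories <= median_kcal]
    eligible = sorted(eligible, key=lambda c: c.cluster_id)

    def explore_suggestion(c: BehaviorCluster) -> Suggestion:
        return Suggestion(
            suggestion_id=f"xp-{c.cluster_id}",
            arm="explore",
            target_cluster_id=c.cluster_id,
            category=category,
            text=_explore_text(c),
            projected_weekly_kcal=score_activity_cluster(c),
            rank=0,
        )

    n_draw = min(n_explore_slots, len(eligible))
    drawn: set[int] = set()
    if n_draw:
        picks = rng.choice(len(eligible), size=n_draw, replace=False)
        for k in np.sort(picks):
            batch.append(explore_suggestion(eligible[int(k)]))
            drawn.add(eligible[int(k)].cluster_id)
    # backfill unfilled slots: leftover exploit ranking first, then the rest
    # of the infrequent pool (calorie-eligible first) so a user with ten
    # total candidates still receives a full batch
    missing = n_slots - len(batch)
    if missing > 0:
        batch.extend(backfill[:missing])
    missing = n_slots - len(batch)
    if missing > 0:
        leftovers = [c for c in eligible if c.cluster_id not in drawn]
        rest = sorted(
            (c for c in infrequent if c not in eligible),
            key=lambda c: (
                -c.per_instance_calories if category == "activity" else c.per_instance_calories,
                c.cluster_id,
            ),
        )
        for c in (leftovers + rest)[:missing]:
            batch.append(explore_suggestion(c))
    if len(batch) < n_slots:
        logger.info(
            "only %d %s suggestion candidates available for a batch of %d",
            len(batch), category, n_slots,
        )
    return [
        Suggestion(
            suggestion_id=s.suggestion_id,
            arm=s.arm,
            target_cluster_id=s.target_cluster_id,
            category=s.category,
            text=s.text,
            projected_weekly_kcal=s.projected_weekly_kcal,
            rank=r + 1,
        )
        for r, s in enumerate(batch[:n_slots])
    ]


def avoid_food_suggestions(
    clusters: list[BehaviorCluster], goal: str, config: EngineConfig
) -> list[Suggestion]:
    """Avoid/reduce framing for frequent high-calorie meal clusters.

    These render alongside the daily batch but never occupy its scored
    slots.
    """
    cutoff = config.avoid_kcal_cutoff.get(goal, float("inf"))
    frequent, _ = partition_exploit_explore(
        [c for c in clusters if c.cluster_type == "meal"], config
    )
    out = []
    for c in sorted(frequent, key=lambda c: -c.per_instance_calories):
        if c.per_instance_calories > cutoff:
            out.append(
                Suggestion(
                    suggestion_id=f"av-{c.cluster_id}",
                    arm="exploit",
                    target_cluster_id=c.cluster_id,
                    category="food",
                    text=(
                        f"Consider reducing {c.label} "
                        f"(~{c.per_instance_calories:.0f} kcal, "
                        f"{c.weekly_frequency:.1f}x/week)."
                    ),
                    projected_weekly_kcal=score_activity_cluster(c),
                    rank=0,
                )
            )
    return out


def load_generic_pool() -> list[str]:
    """The 42-entry control-arm pool (synthetic placeholder texts)."""
    text = (resources.files("habitcoach.data") / "generic_suggestions.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def draw_generic_suggestions(pool: list[str], n: int, rng: np.random.Generator) -> list[str]:
    """Uniform sample without replacement for the control arm."""
    if not pool:
        raise ValueError("generic pool is empty")
    n = min(n, len(pool))
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[int(i)] for i in idx]
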