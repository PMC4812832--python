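"""Repeated-behavior clustering of life-log events.

Three similarity notions, one per behavior family:

* stationary episodes cluster by place — single linkage under great-circle
  distance with a 150 m threshold (the working accuracy of indoor
  localization, so two episodes within that radius are indistinguishable);
* walks and runs cluster by trajectory — each GPS trace is resampled to a
  fixed number of arc-length-equidistant points and compared by the mean
  point-wise great-circle distance, with online leader clustering;
* food entries cluster by ingredient overlap — Jaccard similarity of the
  ingredient token sets, separately for meals and snacks.

Cluster frequency is the member count inside a trailing window (14 days by
default), which is what the suggestion engine ranks on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .energy import FoodTable
from .geo import haversine_m, polyline_length_m
from .lifelog import LifeEvent

TRAJECTORY_POINTS = 32
STATIONARY_RADIUS_M = 150.0
TRAJECTORY_THRESHOLD_M = 150.0
FOOD_SIMILARITY_THRESHOLD = 0.5
FREQUENCY_WINDOW_DAYS = 14.0
MEAL_KCAL_MIN = 250.0
MEAL_WINDOWS = ((7, 9), (12, 14), (18, 21))  # local-time hours


@dataclass
class BehaviorCluster:
    """A group of similar life-log events treated as one repeated behavior."""

    cluster_id: int
    cluster_type: str  # stationary_place | trajectory | manual_exercise_type | meal | snack
    member_event_ids: list[int]
    frequency: int  # occurrences in the trailing window
    representative: object  # (lat, lon), CanonicalTrajectory, or food_id
    per_instance_calories: float
    per_instance_duration: float  # minutes
    label: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def weekly_frequency(self) -> float:
        return self.frequency * 7.0 / FREQUENCY_WINDOW_DAYS


@dataclass(frozen=True)
class CanonicalTrajectory:
    """A trajectory resampled to m equidistant points along its arc."""

    points: np.ndarray  # (m, 2) lat/lon
    length_m: float

    @property
    def m(self) -> int:
        return len(self.points)


def resample_trajectory(trace: np.ndarray, m: int = TRAJECTORY_POINTS) -> CanonicalTrajectory:
    """Resample a lat/lon polyline to m points uniform in arc length.

    Endpoints are preserved exactly; interior points are linear
    interpolations along the polyline, so total length is preserved to
    within the corner-cutting of the resampling grid (<1% for traces whose
    vertices are denser than the grid).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 2 or trace.shape[0] < 2:
        raise ValueError("trace must be an (n>=2, 2) lat/lon array")
    seg = haversine_m(trace[:-1, 0], trace[:-1, 1], trace[1:, 0], trace[1:, 1])
    total = float(np.sum(seg))
    if total == 0.0:
        raise ValueError("all trace points identical; not a trajectory")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, m)
    lats = np.interp(targets, cum, trace[:, 0])
    lons = np.interp(targets, cum, trace[:, 1])
    pts = np.column_stack([lats, lons])
    return CanonicalTrajectory(points=pts, length_m=polyline_length_m(lats, lons))


def trajectory_distance(a: CanonicalTrajectory, b: CanonicalTrajectory) -> float:
    """Mean point-wise great-circle distance, start-to-start alignment.

    Direction-sensitive: a path and its reverse are far apart unless the
    path is symmetric.
    """
    if a.m != b.m:
        raise ValueError(f"point-count mismatch: {a.m} vs {b.m}")
    d = haversine_m(a.points[:, 0], a.points[:, 1], b.points[:, 0], b.points[:, 1])
    return float(np.mean(d))


def _event_location(ev: LifeEvent) -> tuple[float, float] | None:
    if ev.trace is None or len(ev.trace) == 0:
        return None
    tr = np.asarray(ev.trace, dtype=float)
    return float(np.median(tr[:, 0])), float(np.median(tr[:, 1]))


def _window_mask(events: list[LifeEvent], ids: list[int], window_days: float) -> int:
    now = max(ev.end for ev in events)
    cutoff = now - pd.Timedelta(days=window_days)
    return sum(1 for i in ids if events[i].end > cutoff)


def cluster_stationary(
    events: list[LifeEvent],
    radius_m: float = STATIONARY_RADIUS_M,
    window_days: float = FREQUENCY_WINDOW_DAYS,
    start_id: int = 0,
) -> list[BehaviorCluster]:
    """Single-linkage place clustering of stationary episodes.

    Any two episodes within ``radius_m`` of each other end up in the same
    cluster (possibly chained through intermediates). Episodes without a
    location go to one "unlocated" cluster that the suggestion stage skips.
    """
    locs: list[tuple[float, float]] = []
    located_ids: list[int] = []
    unlocated_ids: list[int] = []
    for i, ev in enumerate(events):
        loc = _event_location(ev)
        if loc is None:
            unlocated_ids.append(i)
        else:
            located_ids.append(i)
            locs.append(loc)

    clusters: list[BehaviorCluster] = []
    next_id = start_id
    if located_ids:
        pts = np.array(locs)
        if len(pts) == 1:
            assignment = np.array([1])
        else:
            n = len(pts)
            dm = np.zeros((n, n))
            for i in range(n):
                dm[i, i + 1 :] = haversine_m(
                    pts[i, 0], pts[i, 1], pts[i + 1 :, 0], pts[i + 1 :, 1]
                )
            dm = dm + dm.T
            Z = linkage(squareform(dm, checks=False), method="single")
            assignment = fcluster(Z, t=radius_m, criterion="distance")
        for grp in np.unique(assignment):
            ids = [located_ids[k] for k in np.flatnonzero(assignment == grp)]
            member_pts = pts[assignment == grp]
            rep = (float(member_pts[:, 0].mean()), float(member_pts[:, 1].mean()))
            clusters.append(
                BehaviorCluster(
                    cluster_id=next_id,
                    cluster_type="stationary_place",
                    member_event_ids=ids,
                    frequency=_window_mask(events, ids, window_days),
                    representative=rep,
                    per_instance_calories=float(np.mean([events[i].calories for i in ids])),
                    per_instance_duration=float(np.mean([events[i].duration_minutes for i in ids])),
                    label="stationary",
                )
            )
            next_id += 1
    if unlocated_ids:
        clusters.append(
            BehaviorCluster(
                cluster_id=next_id,
                cluster_type="stationary_place",
                member_event_ids=unlocated_ids,
                frequency=_window_mask(events, unlocated_ids, window_days),
                representative=None,
                per_instance_calories=float(np.mean([events[i].calories for i in unlocated_ids])),
                per_instance_duration=float(
                    np.mean([events[i].duration_minutes for i in unlocated_ids])
                ),
                label="stationary",
                meta={"unlocated": True},
            )
        )
    return clusters


def cluster_trajectories(
    events: list[LifeEvent],
    threshold_m: float = TRAJECTORY_THRESHOLD_M,
    window_days: float = FREQUENCY_WINDOW_DAYS,
    m: int = TRAJECTORY_POINTS,
    start_id: int = 0,
) -> list[BehaviorCluster]:
    """Leader clustering of walk/run traces in chronological order.

    Each event joins the nearest existing representative within
    ``threshold_m`` (ties go to the lowest cluster id) or founds a new
    cluster; the representative is the point-wise mean of member
    trajectories, re-resampled to stay canonical.
    """
    order = sorted(range(len(events)), key=lambda i: events[i].start)
    reps: list[CanonicalTrajectory] = []
    members: list[list[int]] = []
    canon: dict[int, CanonicalTrajectory] = {}
    for i in order:
        canon[i] = resample_trajectory(np.asarray(events[i].trace, dtype=float), m=m)
    for i in order:
        t = canon[i]
        best_j, best_d = -1, np.inf
        for j, rep in enumerate(reps):
            d = trajectory_distance(t, rep)
            if d < best_d:  # strict: earlier cluster wins ties
                best_j, best_d = j, d
        if best_j >= 0 and best_d <= threshold_m:
            members[best_j].append(i)
            stack = np.stack([canon[k].points for k in members[best_j]])
            mean_pts = stack.mean(axis=0)
            reps[best_j] = resample_trajectory(mean_pts, m=m)
        else:
            reps.append(t)
            members.append([i])

    clusters = []
    for j, ids in enumerate(members):
        label = events[ids[0]].label
        clusters.append(
            BehaviorCluster(
                cluster_id=start_id + j,
                cluster_type="trajectory",
                member_event_ids=ids,
                frequency=_window_mask(events, ids, window_days),
                representative=reps[j],
                per_instance_calories=float(np.mean([events[i].calories for i in ids])),
                per_instance_duration=float(np.mean([events[i].duration_minutes for i in ids])),
                label=label,
            )
        )
    return clusters


def cluster_manual(
    events: list[LifeEvent],
    window_days: float = FREQUENCY_WINDOW_DAYS,
    start_id: int = 0,
) -> list[BehaviorCluster]:
    """Group manually logged exercises by activity type."""
    by_type: dict[str, list[int]] = {}
    for i, ev in enumerate(events):
        by_type.setdefault(ev.label, []).append(i)
    clusters = []
    for j, (name, ids) in enumerate(sorted(by_type.items())):
        clusters.append(
            BehaviorCluster(
                cluster_id=start_id + j,
                cluster_type="manual_exercise_type",
                member_event_ids=ids,
                frequency=_window_mask(events, ids, window_days),
                representative=name,
                per_instance_calories=float(np.mean([events[i].calories for i in ids])),
                per_instance_duration=float(np.mean([events[i].duration_minutes for i in ids])),
                label=name,
            )
        )
    return clusters


def classify_meal_snack(ev: LifeEvent, kcal: float | None = None) -> str:
    """Meal if inside a canonical meal window (07-09, 12-14, 18-21 local) or
    >= 250 kcal; snack otherwise."""
    kcal = ev.calories if kcal is None else kcal
    hour = ev.start.hour
    in_window = any(lo <= hour < hi for lo, hi in MEAL_WINDOWS)
    return "meal" if in_window or kcal >= MEAL_KCAL_MIN else "snack"


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def cluster_foods(
    events: list[LifeEvent],
    food_table: FoodTable,
    similarity_threshold: float = FOOD_SIMILARITY_THRESHOLD,
    window_days: float = FREQUENCY_WINDOW_DAYS,
    start_id: int = 0,
) -> list[BehaviorCluster]:
    """Leader clustering of food events by ingredient Jaccard similarity.

    Events are first typed meal vs snack; clusters never mix the two. Each
    event joins the most similar existing representative of its type when
    similarity >= threshold, else founds a new cluster. The representative
    food item is the modal food_id among members (first-seen on ties).
    """
    for ev in events:
        if ev.label not in food_table:
            raise KeyError(f"unknown food_id {ev.label!r} in food events")
    order = sorted(range(len(events)), key=lambda i: events[i].start)
    reps: list[tuple[str, frozenset, str]] = []  # (food_id, ingredients, type)
    members: list[list[int]] = []
    for i in order:
        ev = events[i]
        ing = food_table[ev.label].ingredients
        mtype = classify_meal_snack(ev)
        best_j, best_s = -1, -1.0
        for j, (_, rep_ing, rep_type) in enumerate(reps):
            if rep_type != mtype:
                continue
            s = jaccard(ing, rep_ing)
            if s > best_s:  # strict: earlier cluster wins ties
                best_j, best_s = j, s
        if best_j >= 0 and best_s >= similarity_threshold:
            members[best_j].append(i)
            ids = members[best_j]
            counts: dict[str, int] = {}
            first_seen: dict[str, int] = {}
            for pos, k in enumerate(ids):
                fid = events[k].label
                counts[fid] = counts.get(fid, 0) + 1
                first_seen.setdefault(fid, pos)
            # modal food id; ties go to the earliest-seen item
            modal = max(counts, key=lambda fid: (counts[fid], -first_seen[fid]))
            reps[best_j] = (modal, food_table[modal].ingredients, mtype)
        else:
            reps.append((ev.label, ing, mtype))
            members.append([i])

    clusters = []
    for j, ids in enumerate(members):
        rep_id, _, mtype = reps[j]
        clusters.append(
            BehaviorCluster(
                cluster_id=start_id + j,
                cluster_type=mtype,
                member_event_ids=ids,
                frequency=_window_mask(events, ids, window_days),
                representative=rep_id,
                per_instance_calories=float(np.mean([events[i].calories for i in ids])),
                per_instance_duration=float(np.mean([events[i].duration_minutes for i in ids])),
                label=food_table[rep_id].name,
            )
        )
    return clusters


def cluster_lifelog(
    lifelog: list[LifeEvent],
    food_table: FoodTable,
    *,
    stationary_radius_m: float = STATIONARY_RADIUS_M,
    trajectory_threshold_m: float = TRAJECTORY_THRESHOLD_M,
    food_similarity_threshold: float = FOOD_SIMILARITY_THRESHOLD,
    window_days: float = FREQUENCY_WINDOW_DAYS,
) -> list[BehaviorCluster]:
    """Cluster a whole life log; cluster ids are unique across families.

    Member ids refer to positions in ``lifelog``. Mixed events are treated
    as trajectories when they carry a trace (a commute is a repeatable
    behavior), otherwise skipped.
    """
    stationary, moving, manual, food = [], [], [], []
    idx_stationary, idx_moving, idx_manual, idx_food = [], [], [], []
    for i, ev in enumerate(lifelog):
        if ev.kind == "food":
            food.append(ev)
            idx_food.append(i)
        elif ev.kind == "manual_exercise":
            manual.append(ev)
            idx_manual.append(i)
        elif ev.label == "stationary":
            stationary.append(ev)
            idx_stationary.append(i)
        elif ev.label in ("walking", "running") or ev.kind == "mixed":
            if ev.trace is not None and len(ev.trace) >= 2:
                moving.append(ev)
                idx_moving.append(i)

    def remap(clusters, idx):
        for c in clusters:
            c.member_event_ids = [idx[k] for k in c.member_event_ids]
        return clusters

    out: list[BehaviorCluster] = []
    if stationary:
        cs = cluster_stationary(stationary, stationary_radius_m, window_days, start_id=len(out))
        out += remap(cs, idx_stationary)
    if moving:
        cs = cluster_trajectories(
            moving, trajectory_threshold_m, window_days, start_id=len(out)
        )
        out += remap(cs, idx_moving)
    if manual:
        cs = cluster_manual(manual, window_days, start_id=len(out))
        out += remap(cs, idx_manual)
    if food:
        cs = cluster_foods(
            food, food_table, food_similarity_threshold, window_days, start_id=len(out)
        )
        out += remap(cs, idx_food)
    return out
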