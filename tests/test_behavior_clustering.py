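import numpy as np
import pandas as pd
import pytest

from habitcoach.behavior_clustering import (
    classify_meal_snack,
    cluster_foods,
    cluster_stationary,
    cluster_trajectories,
    jaccard,
    resample_trajectory,
    trajectory_distance,
)
from habitcoach.geo import haversine_m, offset_latlon, polyline_length_m
from habitcoach.lifelog import LifeEvent

T0 = pd.Timestamp("2024-01-01T10:00:00")


def _stat_event(lat, lon, start_min=0, dur=30):
    return LifeEvent(
        start=T0 + pd.Timedelta(minutes=start_min),
        end=T0 + pd.Timedelta(minutes=start_min + dur),
        kind="activity",
        label="stationary",
        trace=np.array([[lat, lon]] * 4),
    )


def _walk_event(trace, start_min=0, dur=30):
    return LifeEvent(
        start=T0 + pd.Timedelta(minutes=start_min),
        end=T0 + pd.Timedelta(minutes=start_min + dur),
        kind="activity",
        label="walking",
        trace=np.asarray(trace, dtype=float),
    )


def _line(lat0, lon0, north_m, n=16):
    dn = np.linspace(0.0, north_m, n)
    lat, lon = offset_latlon(lat0, lon0, dn, np.zeros(n))
    return np.column_stack([lat, lon])


class TestStationaryClustering:
    def test_points_111m_apart_share_cluster(self):
        # 0.001 deg latitude at the equator is ~111.2 m < 150 m
        events = [_stat_event(0.0, 0.0), _stat_event(0.001, 0.0, start_min=60)]
        assert haversine_m(0.0, 0.0, 0.001, 0.0) == pytest.approx(111.2, abs=0.5)
        clusters = cluster_stationary(events)
        assert len(clusters) == 1 and clusters[0].frequency == 2

    def test_distant_points_split(self):
        events = [_stat_event(0.0, 0.0), _stat_event(0.045, 0.0, start_min=60)]  # ~5 km
        assert len(cluster_stationary(events)) == 2

    def test_single_linkage_property(self, rng):
        # all pairwise-close events must land in one cluster
        lats = 40.0 + rng.uniform(0, 0.0008, 12)
        lons = -75.0 + rng.uniform(0, 0.0008, 12)
        events = [_stat_event(la, lo, start_min=40 * i) for i, (la, lo) in enumerate(zip(lats, lons))]
        clusters = cluster_stationary(events)
        assignment = {}
        for c in clusters:
            for m in c.member_event_ids:
                assignment[m] = c.cluster_id
        for i in range(12):
            for j in range(i + 1, 12):
                d = haversine_m(lats[i], lons[i], lats[j], lons[j])
                if d <= 150.0:
                    assert assignment[i] == assignment[j]

    def test_unlocated_events_quarantined(self):
        ev = LifeEvent(T0, T0 + pd.Timedelta(minutes=10), "activity", "stationary", trace=None)
        clusters = cluster_stationary([ev])
        assert clusters[0].meta.get("unlocated") is True

    def test_partition_property(self, rng):
        events = [
            _stat_event(40.0 + rng.uniform(0, 0.05), -75.0, start_min=30 * i) for i in range(10)
        ]
        clusters = cluster_stationary(events)
        seen = sorted(m for c in clusters for m in c.member_event_ids)
        assert seen == list(range(10))


class TestResampleTrajectory:
    def test_straight_segment_uniform_spacing(self):
        traj = resample_trajectory(_line(0.0, 0.0, 310.0), m=32)
        assert traj.m == 32
        d = haversine_m(
            traj.points[:-1, 0], traj.points[:-1, 1], traj.points[1:, 0], traj.points[1:, 1]
        )
        assert np.allclose(d, 10.0, rtol=0.01)

    def test_fixed_point(self):
        traj = resample_trajectory(_line(10.0, 20.0, 500.0), m=32)
        again = resample_trajectory(traj.points, m=32)
        np.testing.assert_allclose(again.points, traj.points, atol=1e-9)

    def test_zigzag_length_preserved_within_1pct(self):
        # ~1 km zig-zag: heading alternates +-15 deg from north every 100 m
        heading = np.deg2rad(15.0) * np.where(np.arange(10) % 2 == 0, 1, -1)
        dn = np.concatenate([[0.0], np.cumsum(100.0 * np.cos(heading))])
        de = np.concatenate([[0.0], np.cumsum(100.0 * np.sin(heading))])
        lat, lon = offset_latlon(45.0, 7.0, dn, de)
        trace = np.column_stack([lat, lon])
        orig = polyline_length_m(trace[:, 0], trace[:, 1])
        traj = resample_trajectory(trace, m=64)
        assert abs(traj.length_m - orig) / orig < 0.01

    def test_degenerate_trace_rejected(self):
        with pytest.raises(ValueError):
            resample_trajectory(np.array([[1.0, 2.0], [1.0, 2.0]]))


class TestTrajectoryDistance:
    def test_identity_and_symmetry(self, rng):
        a = resample_trajectory(_line(40.0, -75.0, 400.0))
        assert trajectory_distance(a, a) == 0.0
        jitter = _line(40.0, -75.0, 400.0) + rng.normal(0, 1e-5, (16, 2))
        b = resample_trajectory(jitter)
        assert trajectory_distance(a, b) == pytest.approx(trajectory_distance(b, a))

    def test_rigid_translation_distance(self):
        a = resample_trajectory(_line(0.0, 10.0, 600.0))
        shifted_lat, shifted_lon = offset_latlon(0.0, 10.0, np.zeros(16), np.full(16, 1000.0))
        b_pts = _line(0.0, 10.0, 600.0)
        b_pts[:, 1] = b_pts[:, 1] + (shifted_lon[0] - 10.0)
        b = resample_trajectory(b_pts)
        assert trajectory_distance(a, b) == pytest.approx(1000.0, rel=0.01)

    def test_point_count_mismatch(self):
        a = resample_trajectory(_line(0, 0, 100.0), m=32)
        b = resample_trajectory(_line(0, 0, 100.0), m=16)
        with pytest.raises(ValueError):
            trajectory_distance(a, b)


class TestTrajectoryClustering:
    def _noisy_commute(self, rng, n_events, reverse=False, noise=20.0, base_start=0):
        base = _line(40.0, -75.0, 1500.0, n=24)
        if reverse:
            base = base[::-1]
        events = []
        for i in range(n_events):
            dn = rng.normal(0, noise, 24)
            de = rng.normal(0, noise, 24)
            lat, lon = offset_latlon(0, 0, dn, de)
            tr = base + np.column_stack([lat, lon])
            events.append(_walk_event(tr, start_min=base_start + 120 * i))
        return events

    def test_noisy_repeats_form_one_cluster(self, rng):
        events = self._noisy_commute(rng, 15)
        clusters = cluster_trajectories(events)
        assert len(clusters) == 1
        assert clusters[0].frequency == 15

    def test_direction_sensitivity(self, rng):
        fwd = self._noisy_commute(rng, 5)
        back = self._noisy_commute(rng, 5, reverse=True, base_start=60)
        clusters = cluster_trajectories(fwd + back)
        assert len(clusters) == 2

    def test_distinct_routes_stay_apart(self, rng):
        commute = self._noisy_commute(rng, 6)
        # a second route 5 km away
        far = []
        for ev in self._noisy_commute(rng, 6, base_start=30):
            far.append(
                _walk_event(np.asarray(ev.trace) + np.array([0.045, 0.0]), start_min=len(far) * 97 + 15)
            )
        clusters = cluster_trajectories(commute + far)
        assert len(clusters) == 2
        sizes = sorted(c.frequency for c in clusters)
        assert sizes == [6, 6]


class TestFoodClustering:
    def _food(self, fid, start_min=0):
        return LifeEvent(
            start=T0 + pd.Timedelta(minutes=start_min),
            end=T0 + pd.Timedelta(minutes=start_min + 1),
            kind="food",
            label=fid,
            calories=500.0,
        )

    def test_similar_burgers_cluster_together(self, food_table):
        # {bun, beef patty, cheese, ketchup} vs {bun, beef patty, lettuce, tomato}
        a = food_table["F001"].ingredients
        b = food_table["F002"].ingredients
        assert jaccard(a, b) == pytest.approx(2 / 6)
        # construct the canonical 0.5 case: sets sharing 2 of 4 union tokens
        s1 = frozenset({"bun", "beef patty", "cheese"})
        s2 = frozenset({"bun", "beef patty", "lettuce"})
        assert jaccard(s1, s2) == pytest.approx(0.5)
        events = [self._food("F001"), self._food("F003", start_min=60)]  # share 3 of 5
        clusters = cluster_foods(events, food_table)
        assert len(clusters) == 1

    def test_identical_items_cluster(self, food_table):
        events = [self._food("F010"), self._food("F010", start_min=30)]
        clusters = cluster_foods(events, food_table)
        assert len(clusters) == 1 and clusters[0].frequency == 2

    def test_disjoint_ingredients_split(self, food_table):
        events = [self._food("F021"), self._food("F026", start_min=30)]
        assert len(cluster_foods(events, food_table)) == 2

    def test_meals_and_snacks_never_mix(self, food_table):
        lunch = self._food("F005", start_min=150)  # 12:30, meal window
        late = LifeEvent(
            start=pd.Timestamp("2024-01-01T15:30:00"),
            end=pd.Timestamp("2024-01-01T15:31:00"),
            kind="food",
            label="F005",
            calories=100.0,
        )
        clusters = cluster_foods([lunch, late], food_table)
        assert sorted(c.cluster_type for c in clusters) == ["meal", "snack"]

    def test_unknown_food_id_rejected(self, food_table):
        with pytest.raises(KeyError, match="F999"):
            cluster_foods([self._food("F999")], food_table)


class TestMealSnackRule:
    @pytest.mark.parametrize(
        "hour,kcal,expected",
        [(8, 100, "meal"), (13, 100, "meal"), (19, 100, "meal"),
         (15, 100, "snack"), (15, 300, "meal"), (10, 249, "snack")],
    )
    def test_windows_and_kcal_threshold(self, hour, kcal, expected):
        ev = LifeEvent(
            start=pd.Timestamp(f"2024-01-01T{hour:02d}:30:00"),
            end=pd.Timestamp(f"2024-01-01T{hour:02d}:31:00"),
            kind="food",
            label="F001",
            calories=kcal,
        )
        assert classify_meal_snack(ev) == expected


def test_synthetic_commute_recovery(sim_user, sim_lifelog, sim_clusters):
    """Planted trajectory ids are recovered at 20 m GPS noise (ARI >= 0.9)."""
    from sklearn.metrics import adjusted_rand_score

    truth_walks = [ev for ev in sim_user.ground_truth if ev.label == "walking"]
    tid = {ev.start: ev.trajectory_id for ev in truth_walks}
    found = {}
    for c in sim_clusters:
        if c.cluster_type == "trajectory":
            for mid in c.member_event_ids:
                found[sim_lifelog[mid].start] = c.cluster_id
    common = [k for k in found if k in tid]
    assert len(common) >= 20
    ari = adjusted_rand_score([tid[k] for k in common], [found[k] for k in common])
    assert ari >= 0.9
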