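from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

from habitcoach.behavior_clustering import BehaviorCluster
from habitcoach.suggestion_engine import (
    EngineConfig,
    draw_generic_suggestions,
    generate_daily_batch,
    load_generic_pool,
    partition_exploit_explore,
    score_activity_cluster,
    small_change_for_stationary,
)

CFG = EngineConfig()


def _cluster(cid, ctype, freq14, kcal, dur=30.0, label=""):
    return BehaviorCluster(
        cluster_id=cid,
        cluster_type=ctype,
        member_event_ids=list(range(freq14)),
        frequency=freq14,
        representative=None,
        per_instance_calories=kcal,
        per_instance_duration=dur,
        label=label or ctype,
    )


def _traj(cid, freq14, kcal, dur=30.0):
    return _cluster(cid, "trajectory", freq14, kcal, dur, "walking")


class TestScoring:
    def test_frequent_walk_outranks_rare_gym(self):
        # 30-min walk at 3.5 MET, 70 kg -> 122.5 kcal, 5x/week -> 612.5
        walk = _traj(0, 10, 122.5)  # 10 per 14 days = 5/week
        gym = _cluster(1, "manual_exercise_type", 2, 420.0, 60.0, "gym_workout")
        assert score_activity_cluster(walk) == pytest.approx(612.5)
        assert score_activity_cluster(gym) == pytest.approx(420.0)
        assert score_activity_cluster(walk) > score_activity_cluster(gym)

    def test_zero_frequency_zero_score_and_linearity(self):
        c = _traj(0, 0, 122.5)
        assert score_activity_cluster(c) == 0.0
        assert score_activity_cluster(_traj(0, 8, 100.0)) == pytest.approx(
            2 * score_activity_cluster(_traj(0, 4, 100.0))
        )

    def test_stationary_cluster_rejected(self):
        with pytest.raises(ValueError):
            score_activity_cluster(_cluster(0, "stationary_place", 5, 10.0))


class TestSmallChange:
    def test_office_small_change_outranks_weekly_gym(self, met_table):
        # 25 one-hour stationary episodes/week at 70 kg:
        # 25 h x (3.5 MET x 70 kg x 3/60 h) = 25 x 12.25 = 306.25 kcal/week
        office = _cluster(0, "stationary_place", 50, 0.0, dur=60.0)  # 50/14d = 25/wk
        s = small_change_for_stationary(office, 70.0, met_table, CFG)
        assert s.arm == "small_change"
        assert s.projected_weekly_kcal == pytest.approx(306.25)
        gym = _cluster(1, "manual_exercise_type", 2, 245.0, 60.0)
        assert s.projected_weekly_kcal > score_activity_cluster(gym)

    def test_zero_stationary_hours(self, met_table):
        c = _cluster(0, "stationary_place", 0, 0.0, dur=60.0)
        assert small_change_for_stationary(c, 70.0, met_table, CFG).projected_weekly_kcal == 0.0

    def test_prescribes_configured_minutes(self, met_table):
        c = _cluster(0, "stationary_place", 14, 0.0, dur=60.0)
        s = small_change_for_stationary(c, 70.0, met_table, CFG)
        assert "3-minute walk" in s.text


class TestPartition:
    def test_all_frequent_leaves_empty_explore(self):
        clusters = [_traj(i, 5, 100.0) for i in range(4)]
        frequent, infrequent = partition_exploit_explore(clusters, CFG)
        assert len(frequent) == 4 and infrequent == []

    def test_rare_gym_is_explore_candidate(self):
        gym = _cluster(0, "manual_exercise_type", 1, 420.0)
        frequent, infrequent = partition_exploit_explore([gym], CFG)
        assert infrequent == [gym] and frequent == []

    def test_never_done_behaviors_never_suggested(self):
        ghost = _traj(0, 0, 400.0)
        frequent, infrequent = partition_exploit_explore([ghost], CFG)
        assert frequent == [] and infrequent == []

    def test_crossing_threshold_migrates_explore_to_exploit(self):
        before = _cluster(0, "manual_exercise_type", 2, 420.0)
        _, inf_before = partition_exploit_explore([before], CFG)
        assert before in inf_before
        after = _cluster(0, "manual_exercise_type", 3, 420.0)
        freq_after, _ = partition_exploit_explore([after], CFG)
        assert after in freq_after


@pytest.fixture()
def rich_clusters():
    """15 frequent + 4 infrequent activity clusters."""
    frequent = [_traj(i, 6 + i % 5, 80.0 + 10 * i) for i in range(15)]
    infrequent = [_cluster(100 + i, "manual_exercise_type", 1 + i % 2, 300.0 + 50 * i)
                  for i in range(4)]
    return frequent + infrequent


class TestDailyBatch:
    def test_nine_exploit_one_explore(self, rich_clusters, met_table, rng):
        batch = generate_daily_batch(
            rich_clusters, "activity", weight_kg=70.0, met_table=met_table, config=CFG, rng=rng
        )
        arms = Counter(s.arm for s in batch)
        assert len(batch) == 10
        assert arms["exploit"] == 9 and arms["explore"] == 1
        assert sorted(s.rank for s in batch) == list(range(1, 11))

    def test_empty_explore_pool_backfills_exploit(self, met_table, rng):
        clusters = [_traj(i, 6, 80.0 + i) for i in range(12)]
        batch = generate_daily_batch(
            clusters, "activity", weight_kg=70.0, met_table=met_table, config=CFG, rng=rng
        )
        assert len(batch) == 10
        assert all(s.arm == "exploit" for s in batch)

    def test_seed_determinism(self, rich_clusters, met_table):
        a = generate_daily_batch(rich_clusters, "activity", weight_kg=70.0,
                                 met_table=met_table, config=CFG,
                                 rng=np.random.default_rng(7))
        b = generate_daily_batch(rich_clusters, "activity", weight_kg=70.0,
                                 met_table=met_table, config=CFG,
                                 rng=np.random.default_rng(7))
        assert a == b

    def test_top9_matches_bruteforce_sort_oracle(self, met_table, rng):
        clusters = [_traj(i, 4 + (i * 3) % 7, 50.0 + (i * 37) % 90) for i in range(12)]
        batch = generate_daily_batch(
            clusters, "activity", weight_kg=70.0, met_table=met_table, config=CFG, rng=rng
        )
        exploit_ids = [s.target_cluster_id for s in batch if s.arm == "exploit"][:9]
        oracle = sorted(
            clusters, key=lambda c: (-c.weekly_frequency * c.per_instance_calories, c.cluster_id)
        )[:9]
        assert exploit_ids == [c.cluster_id for c in oracle]

    def test_rank_monotone_in_frequency(self, met_table):
        def rank_of(freq):
            clusters = [_traj(0, freq, 100.0)] + [_traj(i, 6, 100.0) for i in range(1, 10)]
            batch = generate_daily_batch(
                clusters, "activity", weight_kg=70.0, met_table=met_table, config=CFG,
                rng=np.random.default_rng(0),
            )
            return next(s.rank for s in batch if s.target_cluster_id == 0)

        assert rank_of(10) <= rank_of(6) <= rank_of(4)

    def test_food_batch_prefers_low_calorie_frequent(self, met_table, rng):
        meals = [_cluster(i, "meal", 5, 300.0 + 40 * i, 1.0, f"meal{i}") for i in range(10)]
        snacks = [_cluster(100 + i, "snack", 1, 80.0 + 10 * i, 1.0, f"snack{i}") for i in range(3)]
        batch = generate_daily_batch(
            meals + snacks, "food", weight_kg=70.0, met_table=met_table, config=CFG, rng=rng
        )
        exploit = [s for s in batch if s.arm == "exploit"]
        kcals = [next(c for c in meals if c.cluster_id == s.target_cluster_id).per_instance_calories
                 for s in exploit]
        assert kcals == sorted(kcals)

    def test_explore_respects_calorie_direction(self, rich_clusters, met_table):
        all_kcal = [c.per_instance_calories
                    for c in rich_clusters if c.cluster_type != "stationary_place"]
        med = np.median(all_kcal)
        for seed in range(25):
            batch = generate_daily_batch(
                rich_clusters, "activity", weight_kg=70.0, met_table=met_table, config=CFG,
                rng=np.random.default_rng(seed),
            )
            for s in batch:
                if s.arm == "explore":
                    c = next(c for c in rich_clusters if c.cluster_id == s.target_cluster_id)
                    assert c.per_instance_calories >= med

    def test_sparse_candidates_emit_what_exists(self, met_table, rng):
        clusters = [_traj(0, 6, 100.0), _traj(1, 1, 200.0)]
        batch = generate_daily_batch(
            clusters, "activity", weight_kg=70.0, met_table=met_table, config=CFG, rng=rng
        )
        assert len(batch) == 2


class TestGenericPool:
    def test_pool_has_42_entries(self):
        assert len(load_generic_pool()) == 42

    def test_full_draw_is_permutation(self, rng):
        pool = load_generic_pool()
        drawn = draw_generic_suggestions(pool, 42, rng)
        assert sorted(drawn) == sorted(pool)

    def test_single_draws_uniform(self):
        pool = load_generic_pool()
        counts = Counter()
        for seed in range(2100):
            rng = np.random.default_rng(seed)
            counts[draw_generic_suggestions(pool, 1, rng)[0]] += 1
        observed = [counts[p] for p in pool]
        _, p = chisquare(observed)
        assert p > 0.001  # uniformity sanity check
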