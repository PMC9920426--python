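"""On-watch simulator: cycle arithmetic, pruning tiers, power budget and
the feedback learning loop."""

import numpy as np
import pytest

import falldet as fd
from falldet.classify import LabeledPoint
from falldet.data_model import ADL, FALL
from falldet.evaluate import DEPLOYED_SUBSET, build_feature_table
from falldet.features import feature_names
from falldet.online import (
    OnlineConfig,
    Stream,
    build_stream,
    power_budget,
    prune_dataset,
    run_detector,
)

COLS = feature_names(DEPLOYED_SUBSET)


def quiet_stream(seconds=60.0, rate=50.0):
    n = int(seconds * rate)
    return Stream(rate_hz=rate, samples=np.tile([0.0, 0.0, 9.81], (n, 1)))


def tiny_seed_dataset():
    return [
        LabeledPoint(np.zeros(12), ADL),
        LabeledPoint(np.full(12, 0.1), ADL),
        LabeledPoint(np.full(12, 100.0), FALL),
    ]


def table_to_points(table, provenance="seed-dataset"):
    return [
        LabeledPoint(row[COLS].to_numpy(dtype=float), row["label"], provenance)
        for _, row in table.iterrows()
    ]


class TestCycleArithmetic:
    @pytest.mark.parametrize("window_s,expected", [(6.0, 10), (9.0, 6)])
    def test_calls_per_minute_zero_dead_time(self, window_s, expected):
        cfg = OnlineConfig(window_s=window_s, detect_cost_s_per_point=0.0)
        log = run_detector(quiet_stream(60.0), tiny_seed_dataset(), cfg)
        assert log.n_calls == expected
        assert log.dead_time_total == 0.0

    def test_two_second_dead_time_gives_five_calls(self):
        # 3 points x 2/3 s each = 2 s per classification; cycle 11 s.
        cfg = OnlineConfig(window_s=9.0, detect_cost_s_per_point=2.0 / 3.0)
        log = run_detector(quiet_stream(60.0), tiny_seed_dataset(), cfg)
        assert log.n_calls == 5

    def test_sample_conservation(self):
        cfg = OnlineConfig(window_s=9.0, detect_cost_s_per_point=2.0 / 3.0)
        stream = quiet_stream(60.0)
        log = run_detector(stream, tiny_seed_dataset(), cfg)
        assert log.collected_samples + log.dropped_samples == stream.samples.shape[0]

    def test_empty_seed_dataset_rejected(self):
        with pytest.raises(ValueError, match="seed dataset"):
            run_detector(quiet_stream(10.0), [], OnlineConfig())

    def test_fall_wholly_inside_dead_time_is_missed(self):
        # One fall interval placed entirely within the dead zone.
        stream = Stream(
            rate_hz=50.0,
            samples=np.tile([0.0, 0.0, 9.81], (50 * 30, 1)),
            fall_intervals=((9.5, 10.5),),
        )
        cfg = OnlineConfig(window_s=9.0, detect_cost_s_per_point=2.0 / 3.0)
        log = run_detector(stream, tiny_seed_dataset(), cfg)
        assert log.missed_falls_in_dead_time == 1
        assert log.confusion.fn >= 1

    def test_negative_oracle_never_adds_falls(self, fall_recording):
        table = build_feature_table([fall_recording])
        stream = build_stream([fall_recording], idle_s=1.0, seed=0)
        seed_pts = tiny_seed_dataset()
        sizes = []

        def deny(time_s, truth):
            return ADL

        cfg = OnlineConfig(dataset_cap=50, detect_cost_s_per_point=0.0)
        log = run_detector(stream, seed_pts, cfg, oracle=deny)
        assert all(lab == ADL for _, lab in log.feedback)


class TestPrune:
    def test_under_cap_unchanged(self):
        data = tiny_seed_dataset()
        assert prune_dataset(data, cap=10) == data

    def test_pruning_episode_650_to_400(self):
        # 200 seed ADLs + 200 seed falls + 250 feedback points, cap 400:
        # all 200 seed ADLs and the 50 oldest seed falls go first; no
        # feedback point is touched.
        seed_adl = [LabeledPoint([float(i)], ADL) for i in range(200)]
        seed_fall = [LabeledPoint([float(i)], FALL) for i in range(200)]
        feedback = [
            LabeledPoint([float(i)], ADL, "user-feedback") for i in range(250)
        ]
        pruned = prune_dataset(seed_adl + seed_fall + feedback, cap=400)
        assert len(pruned) == 400
        assert not any(p in pruned for p in seed_adl)
        assert sum(p in pruned for p in seed_fall) == 150
        kept_falls = [p for p in pruned if p.label == FALL]
        assert kept_falls == seed_fall[50:]  # oldest removed first
        assert all(p in pruned for p in feedback)

    def test_all_feedback_overflow_removes_oldest(self):
        feedback = [
            LabeledPoint([float(i)], ADL if i % 2 else FALL, "user-feedback")
            for i in range(20)
        ]
        pruned = prune_dataset(feedback, cap=10)
        assert pruned == feedback[10:]

    def test_balance_ratio_respected(self):
        # Removing strictly by tier would strip every ADL; the balance
        # guard must keep the minority class represented.
        seed_adl = [LabeledPoint([float(i)], ADL) for i in range(30)]
        seed_fall = [LabeledPoint([float(i)], FALL) for i in range(170)]
        pruned = prune_dataset(seed_adl + seed_fall, cap=100, balance_ratio_max=3.0)
        n_adl = sum(p.label == ADL for p in pruned)
        n_fall = 100 - n_adl
        assert n_fall <= 3.0 * n_adl

    def test_cap_below_two_rejected(self):
        with pytest.raises(ValueError, match="cap"):
            prune_dataset(tiny_seed_dataset(), cap=1)

    def test_dataset_never_exceeds_cap_during_session(self, small_dataset):
        recs = [r for r in small_dataset if r.duration >= 9.0][:10]
        table = build_feature_table(recs)
        pts = table_to_points(table)[:60]
        stream = build_stream(recs[:5], idle_s=1.0, seed=0)
        cfg = OnlineConfig(dataset_cap=50, detect_cost_s_per_point=0.0)
        log = run_detector(stream, pts[:50], cfg)
        assert all(size <= 50 for _, size in log.dataset_size_series)


class TestPowerBudget:
    def test_field_observation_chain(self):
        out = power_budget(1.02, 34.0, 144.0)
        assert out == {
            "app_draw_w": 0.03,
            "baseline_draw_w": 0.007,
            "delta_w": 0.023,
            "daily_wh": 0.552,
        }

    def test_direct_arithmetic(self):
        out = power_budget(1.0, 50.0, 100.0)
        assert out == {
            "app_draw_w": 0.02,
            "baseline_draw_w": 0.01,
            "delta_w": 0.01,
            "daily_wh": 0.24,
        }

    def test_observed_not_below_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            power_budget(1.02, 144.0, 144.0)


@pytest.fixture(scope="module")
def learning_log():
    # Seed dataset knows falls and walks but has never seen claps; the
    # stream alternates claps (fall-confusable) with walks and the wearer
    # truthfully denies each false alarm.
    falls = [fd.generate_fall("F01", seed=i) for i in range(25)]
    walks = [fd.generate_adl("D01", seed=100 + i) for i in range(25)]
    pts = table_to_points(build_feature_table(falls + walks))
    mix = []
    for i in range(20):
        mix.append(fd.generate_adl("D10", seed=200 + i))
        mix.append(fd.generate_adl("D01", seed=300 + i))
    stream = build_stream(mix, idle_s=2.0, seed=1)
    return run_detector(stream, pts, OnlineConfig(dataset_cap=400))


class TestLearning:
    def test_false_positives_do_not_increase(self, learning_log):
        fps = learning_log.false_positives()
        t_end = learning_log.classifications[-1][0]
        first = sum(1 for t in fps if t <= t_end / 2)
        second = len(fps) - first
        assert second <= first

    def test_feedback_grows_dataset_with_adl_points(self, learning_log):
        assert learning_log.feedback
        assert all(lab == ADL for _, lab in learning_log.feedback)

    def test_simulator_matches_offline_classifier_when_dead_zone_vanishes(self):
        # With zero detect cost and no feedback learning, each simulator
        # window must classify exactly as the batch kNN on its features.
        recs = [fd.generate_fall("F02", seed=50 + i) for i in range(3)]
        seed_table = build_feature_table(
            [fd.generate_fall("F01", seed=i) for i in range(10)]
            + [fd.generate_adl("D01", seed=20 + i) for i in range(10)]
        )
        pts = table_to_points(seed_table)
        stream = build_stream(recs, idle_s=0.0, seed=0)
        cfg = OnlineConfig(detect_cost_s_per_point=0.0)

        def no_learning(time_s, truth):
            return truth

        log = run_detector(stream, list(pts), cfg, oracle=no_learning)
        # replicate each window offline (no learning -> dataset only grows
        # with truthful points; recompute with a frozen dataset instead)
        from falldet.features import StreamState, stream_finalize, stream_update
        from falldet.classify import knn_predict

        win_len = int(9.0 * 50)
        dataset = list(pts)
        pos = 0
        for t_end, truth, pred in log.classifications:
            state = StreamState()
            for i in range(pos, pos + win_len):
                stream_update(state, stream.samples[i])
            fv = stream_finalize(state)
            assert knn_predict(dataset, fv.values, k=3) == pred
            if pred == FALL:
                dataset.append(LabeledPoint(fv.values, truth, "user-feedback"))
                dataset = prune_dataset(dataset, 400)
            pos += win_len
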