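"""Sliding-window maps, temporal histories and burst lifetimes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aggtrap import cluster_kinetics as ck
from aggtrap.synthetic import ThreeStateModel, gen_three_state_stream

CFG = ck.SlidingWindowConfig()  # 1000-frame window, 25-frame step, 20 ms


def _locs(frames, x=0.5, y=0.5):
    frames = np.asarray(frames, dtype=int)
    return pd.DataFrame({"frame": frames, "x_um": x, "y_um": y})


class TestSlidingWindows:
    def test_frame_zero_event_covered_by_window_over_step_maps(self):
        maps = ck.sliding_window_maps(_locs([0] * 7), CFG, 0.5, 1.0, n_frames=2000)
        per_map = maps.sum(axis=(1, 2))
        assert (per_map > 0).sum() == CFG.window // CFG.step  # 40 maps
        assert (per_map[:40] == 7).all() and (per_map[40:] == 0).all()

    def test_empty_table_all_zero(self):
        maps = ck.sliding_window_maps(_locs([]), CFG, 0.5, 1.0, n_frames=500)
        assert maps.sum() == 0

    def test_interior_frames_counted_window_over_step_times(self):
        maps = ck.sliding_window_maps(_locs([1200, 1300]), CFG, 0.5, 1.0, n_frames=4000)
        assert maps.sum() == 2 * CFG.window // CFG.step

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ck.SlidingWindowConfig(window=10, step=25)


class TestTemporalHistory:
    def test_uniform_detections_follow_diagonal(self):
        rng = np.random.default_rng(0)
        frames = np.sort(rng.integers(0, 5000, 800))
        t, cum = ck.temporal_history(_locs(frames), {"cx": 0.5, "cy": 0.5, "r": 1.0})
        u = t / (5000 * 0.02)
        assert stats.kstest(u, "uniform").pvalue > 0.01
        assert np.all(np.diff(cum) >= 0) and cum[-1] == pytest.approx(1.0)

    def test_burst_gives_step_like_cdf(self):
        frames = np.arange(2500, 3000)
        t, cum = ck.temporal_history(_locs(frames), {"cx": 0.5, "cy": 0.5, "r": 1.0})
        assert t.min() >= 2500 * 0.02 and t.max() < 3000 * 0.02

    def test_empty_region_flagged_empty(self):
        t, cum = ck.temporal_history(_locs([1, 2, 3]), {"cx": 50.0, "cy": 50.0, "r": 0.1})
        assert len(t) == 0 and len(cum) == 0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        locs = _locs(rng.integers(0, 1000, 100))
        region = {"cx": 0.5, "cy": 0.5, "r": 1.0}
        t1, c1 = ck.temporal_history(locs, region)
        t2, c2 = ck.temporal_history(locs.sample(frac=1.0, random_state=2), region)
        assert np.array_equal(t1, t2) and np.array_equal(c1, c2)

    def test_polygon_region(self):
        locs = pd.DataFrame({"frame": [0, 1], "x_um": [0.5, 5.0], "y_um": [0.5, 5.0]})
        square = [(0, 0), (1, 0), (1, 1), (0, 1)]
        t, _ = ck.temporal_history(locs, square)
        assert len(t) == 1


class TestBurstLifetime:
    def test_lifetime_is_half_visible_span(self):
        # continuously occupied region: window timestamps span the acquisition
        frames = np.repeat(np.arange(0, 2000), 2)
        rec = ck.burst_lifetime(
            _locs(frames), {"cx": 0.5, "cy": 0.5, "r": 1.0}, CFG, n_frames=2000
        )
        assert rec.lifetime == pytest.approx((rec.t_disappear - rec.t_appear) / 2)
        span_s = 2000 * CFG.step / CFG.step * 0.02  # 40 s acquisition
        assert rec.lifetime == pytest.approx(span_s / 2, rel=0.05)

    def test_no_burst_returns_none(self):
        rec = ck.burst_lifetime(
            _locs([1, 2]), {"cx": 0.5, "cy": 0.5, "r": 1.0}, CFG,
            visibility_threshold=5, n_frames=2000,
        )
        assert rec is None

    def test_bursting_cluster_recovered_near_truth(self):
        model = ThreeStateModel(
            n_frames=6000, activation_rate=0.0, seed=3,
            cluster_sites=((5.0, 5.0),), cluster_episode_duration=15.0,
        )
        locs, truth = gen_three_state_stream(model)
        rec = ck.burst_lifetime(locs, {"cx": 5.0, "cy": 5.0, "r": 0.5}, CFG, n_frames=6000)
        # visible span ~ true duration + window span; lifetime = half of that
        expected = (15.0 + CFG.window * CFG.frame_interval) / 2
        assert rec.lifetime == pytest.approx(expected, abs=2.0)

    def test_stable_aggregate_lifetime_half_acquisition(self):
        model = ThreeStateModel(
            n_frames=6000, activation_rate=0.0, seed=4,
            aggregate_regions=((5.0, 5.0, 0.4),), aggregate_loc_rate=0.3,
        )
        locs, _ = gen_three_state_stream(model)
        rec = ck.burst_lifetime(locs, {"cx": 5.0, "cy": 5.0, "r": 0.5}, CFG, n_frames=6000)
        acq = 6000 * 0.02
        assert rec.lifetime == pytest.approx(acq / 2, rel=0.1)
        assert ck.classify_lifetime(rec, acq) == "stable"


def test_propose_regions_finds_dense_spot():
    rng = np.random.default_rng(5)
    bg = pd.DataFrame(
        {"frame": rng.integers(0, 100, 200), "x_um": rng.uniform(0, 10, 200),
         "y_um": rng.uniform(0, 10, 200)}
    )
    hot = pd.DataFrame({"frame": np.arange(300), "x_um": 3.1, "y_um": 7.2})
    regions = ck.propose_regions(pd.concat([bg, hot]), field_size=10.0)
    assert any(abs(r["cx"] - 3.1) < 0.5 and abs(r["cy"] - 7.2) < 0.5 for r in regions)
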