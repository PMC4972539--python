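"""MSD estimation, diffusion fitting, translocations, angles, mask splitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aggtrap import spt
from aggtrap.synthetic import ThreeStateModel, gen_brownian_tracks, gen_three_state_stream


def _track(x, y, tid=0):
    return pd.DataFrame({"track_id": tid, "frame": range(len(x)), "x_um": x, "y_um": y})


class TestMsd:
    def test_immobile_track_zero_msd(self):
        t = _track([1.0] * 8, [2.0] * 8)
        curve = spt.compute_msd(t, 4)
        assert np.allclose(curve.msd, 0.0)

    def test_ballistic_track_quadratic_msd(self):
        t = _track(np.arange(10) * 0.1, np.zeros(10))
        curve = spt.compute_msd(t, 4)
        assert curve.msd == pytest.approx((0.1 * curve.lags) ** 2)

    def test_lag_truncation_and_pair_counts(self):
        t = _track(np.arange(5) * 0.1, np.zeros(5))
        curve = spt.compute_msd(t, 100)
        assert list(curve.lags) == [1, 2, 3, 4]
        assert list(curve.n_pairs) == [4, 3, 2, 1]

    def test_ensemble_msd_matches_4_d_dt(self):
        d, dt = 1.0, 0.01
        tracks = gen_brownian_tracks(d, 1000, 20, dt, 0.0, seed=3)
        msd1 = np.array(
            [spt.compute_msd(tr, 1).msd[0] for _, tr in tracks.groupby("track_id")]
        )
        se = msd1.std(ddof=1) / np.sqrt(len(msd1))
        assert abs(msd1.mean() - 4 * d * dt) < 3 * se


class TestFitDiffusion:
    def test_noiseless_line_recovers_slope_over_4(self):
        lags = np.arange(1, 5)
        curve = spt.MsdCurve(0, lags, 4 * 1.0 * lags * 0.01, np.full(4, 10))
        est = spt.fit_diffusion(curve, 0.01, n_points=10)
        assert est.d == pytest.approx(1.0)
        assert est.r_squared == pytest.approx(1.0)
        assert est.accepted

    def test_immobile_clips_to_zero(self):
        t = _track([1.0] * 8, [2.0] * 8)
        est = spt.fit_diffusion(spt.compute_msd(t, 4), 0.01, n_points=8)
        assert est.d == 0.0

    def test_short_track_not_estimable(self):
        t = _track([0.0, 0.1, 0.2], [0.0, 0.0, 0.0])
        est = spt.fit_diffusion(spt.compute_msd(t, 4), 0.01, n_points=3)
        assert not est.accepted and np.isnan(est.d)

    @pytest.mark.parametrize("d", [0.05, 0.5, 5.0])
    def test_parameter_recovery_within_15_percent(self, d):
        tracks = gen_brownian_tracks(d, 1000, 20, 0.02, 0.03, seed=int(d * 100))
        est = spt.estimate_tracks(tracks, 0.02)
        med = est.loc[est["accepted"], "d"].median()
        assert med == pytest.approx(d, rel=0.15)


class TestHistograms:
    def test_identical_estimates_fill_single_bin(self):
        est = pd.DataFrame({"d": [1.0] * 5, "accepted": True})
        h = spt.diffusion_histogram(est)
        assert (h["count"] > 0).sum() == 1
        assert h["density"].sum() == pytest.approx(1.0)

    def test_empty_input_no_error(self):
        h = spt.diffusion_histogram(pd.DataFrame({"d": [], "accepted": []}))
        assert len(h) == 0

    def test_two_population_mixture_is_bimodal(self):
        slow = gen_brownian_tracks(0.05, 200, 20, 0.02, 0.0, seed=1)
        fast = gen_brownian_tracks(3.0, 800, 20, 0.02, 0.0, seed=2)
        fast["track_id"] += 1000
        est = spt.estimate_tracks(pd.concat([slow, fast]), 0.02)
        h = spt.diffusion_histogram(est)
        occupied = h[h["count"] > 0]
        slow_mass = occupied[occupied["log10_d"] < -0.6]["density"].sum()
        fast_mass = occupied[occupied["log10_d"] > -0.2]["density"].sum()
        assert slow_mass > 0.1 and fast_mass > 0.5

    def test_translocation_distances_exact_for_known_track(self):
        t = _track([0.0, 0.1, 0.3], np.zeros(3))
        d = spt.translocations(t)
        assert d == pytest.approx([0.1, 0.2])

    def test_brownian_translocations_are_rayleigh(self):
        d, dt = 1.0, 0.01
        tracks = gen_brownian_tracks(d, 500, 20, dt, 0.0, seed=4)
        dist = spt.translocations(tracks)
        stat = stats.kstest(dist, stats.rayleigh(scale=np.sqrt(2 * d * dt)).cdf)
        assert len(dist) >= 10_000
        assert stat.pvalue > 0.01

    def test_error_only_translocations_rayleigh_of_error(self):
        sd = 0.03
        tracks = gen_brownian_tracks(0.0, 500, 20, 0.01, sd, seed=5)
        dist = spt.translocations(tracks)
        stat = stats.kstest(dist, stats.rayleigh(scale=sd * np.sqrt(2)).cdf)
        assert stat.pvalue > 0.01


class TestJumpAngles:
    def test_collinear_and_reversal_conventions(self):
        fwd = spt.jump_angles(_track([0, 0.1, 0.2], [0, 0, 0]), min_jump=0.01)
        rev = spt.jump_angles(_track([0, 0.1, 0.0], [0, 0, 0]), min_jump=0.01)
        assert fwd == pytest.approx([0.0])
        assert rev == pytest.approx([180.0])

    def test_short_jumps_excluded(self):
        ang = spt.jump_angles(_track([0, 0.01, 0.02], [0, 0, 0]), min_jump=0.04)
        assert len(ang) == 0

    def test_brownian_angles_uniform(self):
        tracks = gen_brownian_tracks(1.0, 700, 20, 0.02, 0.0, seed=6)
        ang = spt.jump_angles(tracks)
        counts, _ = np.histogram(ang, bins=18, range=(0, 180))
        assert len(ang) >= 10_000
        assert stats.chisquare(counts).pvalue > 0.01


class TestMaskSplitting:
    def _tracks(self):
        rng = np.random.default_rng(7)
        return pd.DataFrame(
            {
                "track_id": np.repeat(np.arange(20), 5),
                "frame": np.tile(np.arange(5), 20),
                "x_um": rng.uniform(0, 10, 100),
                "y_um": rng.uniform(0, 10, 100),
            }
        )

    def test_empty_and_full_masks(self):
        tracks = self._tracks()
        empty = spt.AggregateMask(np.zeros((10, 10), dtype=bool), 1.0)
        full = spt.AggregateMask(np.ones((10, 10), dtype=bool), 1.0)
        in_a, out_a = spt.split_tracks_by_mask(tracks, empty)
        assert len(in_a) == 0 and len(out_a) == len(tracks)
        in_b, out_b = spt.split_tracks_by_mask(tracks, full)
        assert len(out_b) == 0 and len(in_b) == len(tracks)

    def test_partition_is_conservative(self):
        tracks = self._tracks()
        mask = spt.mask_from_regions([(5.0, 5.0, 2.0)], 10.0, 0.1)
        in_t, out_t = spt.split_tracks_by_mask(tracks, mask)
        assert in_t["track_id"].nunique() + out_t["track_id"].nunique() == 20
        assert len(in_t) + len(out_t) == len(tracks)

    def test_ground_truth_aggregate_tracks_assigned_in(self):
        model = ThreeStateModel(
            aggregate_regions=((5.0, 5.0, 1.5),), activation_rate=0.5,
            n_frames=400, seed=8, localization_error_sd=0.0,
        )
        locs, _ = gen_three_state_stream(model)
        locs["track_id"] = locs["molecule_id"]
        mask = spt.mask_from_regions(model.aggregate_regions, model.field_size, 0.05)
        in_t, out_t = spt.split_tracks_by_mask(locs, mask)
        agg_ids = set(locs.loc[locs["state_label"] == "aggregate", "track_id"])
        assert agg_ids and agg_ids <= set(in_t["track_id"])
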