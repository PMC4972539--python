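"""Geometry construction and walker correctness of the search simulator."""

import numpy as np
import pytest

from aggtrap.search import (
    PackingError,
    SearchSimConfig,
    build_geometry,
    diameter_for_volume_ratio,
    fold_of_delay,
    n_aggregates_for_volume_ratio,
    run_condition,
    run_walks,
    simulate_search,
    sweep,
    volume_ratio,
)

from oracles import naive_walk

TINY = SearchSimConfig(
    nucleus_diameter=20.0,
    n_targets=10,
    target_diameter=2.0,
    n_aggregates=1,
    aggregate_diameter=6.0,
    slowdown_factor=10.0,
    n_simulations=100,
    n_geometries=2,
    seed=0,
)


class TestGeometry:
    def test_no_aggregates(self):
        cfg = SearchSimConfig(n_aggregates=0, n_targets=100, seed=1)
        geom = build_geometry(cfg, np.random.default_rng(1))
        assert geom.n_aggregates == 0
        assert len(geom.target_centers) == 100

    def test_containment_and_separation(self):
        cfg = SearchSimConfig(n_aggregates=50, aggregate_diameter=30.0, n_targets=2000, seed=2)
        geom = build_geometry(cfg, np.random.default_rng(2))
        R, ra, rt = geom.nucleus_radius, geom.aggregate_radius, geom.target_radius
        ac, tc = geom.aggregate_centers, geom.target_centers
        assert np.all(np.linalg.norm(ac, axis=1) <= R - ra + 1e-9)
        assert np.all(np.linalg.norm(tc, axis=1) <= R - rt + 1e-9)
        # aggregates pairwise non-overlapping
        d = np.linalg.norm(ac[:, None] - ac[None], axis=2)
        d[np.diag_indices(len(ac))] = np.inf
        assert d.min() >= 2 * ra - 1e-9
        # targets outside aggregates
        dt = np.linalg.norm(tc[:, None] - ac[None], axis=2)
        assert dt.min() >= ra + rt - 1e-9

    def test_volume_ratio_formula_and_monte_carlo(self):
        cfg = SearchSimConfig(n_aggregates=100, aggregate_diameter=20.0, n_targets=10, seed=3)
        assert cfg.volume_ratio == pytest.approx(100 * 10**3 / 200**3)  # 1.25%
        geom = build_geometry(cfg, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        pts = rng.uniform(-200, 200, size=(400_000, 3))
        pts = pts[(pts**2).sum(axis=1) <= 200.0**2]
        d2 = ((pts[:, None, :] - geom.aggregate_centers[None]) ** 2).sum(axis=2)
        mc = (d2 <= geom.aggregate_radius**2).any(axis=1).mean()
        assert mc == pytest.approx(cfg.volume_ratio, abs=1e-3)

    def test_canonical_vr_helpers(self):
        d = diameter_for_volume_ratio(0.051, 100)
        assert d == pytest.approx(32.0, rel=0.01)
        assert n_aggregates_for_volume_ratio(0.051, 16.0) == 797
        assert volume_ratio(0, 20.0, 400.0) == 0.0

    def test_overdense_packing_rejected(self):
        with pytest.raises(ValueError):
            SearchSimConfig(n_aggregates=100, aggregate_diameter=80.0)  # VR = 0.8
        cfg = SearchSimConfig(n_aggregates=50, aggregate_diameter=80.0)  # VR = 0.4
        with pytest.raises(PackingError):
            build_geometry(cfg, np.random.default_rng(5))


class TestWalker:
    def test_walker_in_huge_target_terminates_immediately(self):
        cfg = SearchSimConfig(
            nucleus_diameter=20.0, n_targets=1, target_diameter=19.0,
            n_aggregates=0, n_simulations=1, seed=6,
        )
        geom = build_geometry(cfg, np.random.default_rng(6))
        geom.target_centers[:] = 0.0
        steps = run_walks(geom, cfg, 50, seed=6)
        # nearly every start is already inside the target; the rest sit in
        # the thin boundary shell and need only a handful of steps
        assert np.mean(steps == 0) > 0.8
        assert steps.max() < 50

    def test_reproducibility_identical_seed(self):
        a = run_condition(TINY)
        b = run_condition(TINY)
        assert np.array_equal(a, b)
        c = run_condition(TINY.replace(seed=1))
        assert not np.array_equal(a, c)

    def test_simulate_search_single_run(self):
        geom = build_geometry(TINY, np.random.default_rng(0))
        steps = simulate_search(geom, TINY, np.random.default_rng(0))
        assert steps >= 0

    @pytest.mark.parametrize("mode", ["accept", "speed"])
    def test_oracle_equivalence_tiny_geometry(self, mode):
        """Production engine agrees with an independent brute-force walker."""
        cfg = TINY.replace(slowdown_mode=mode)
        geom = build_geometry(cfg, np.random.default_rng(10))
        n = 10_000
        prod = run_walks(geom, cfg, n, seed=11)
        orac = naive_walk(geom, n, cfg.slowdown_factor, mode, np.random.default_rng(12))
        se = np.sqrt(prod.var(ddof=1) / n + orac.var(ddof=1) / n)
        assert abs(prod.mean() - orac.mean()) < 3 * se

    def test_inert_obstacles_do_not_delay(self):
        """With slowdown 1 the aggregates only exclude targets: fold ~ 1."""
        cfg = SearchSimConfig(
            n_aggregates=100, aggregate_diameter=32.0, slowdown_factor=1.0,
            n_simulations=400, n_geometries=4, seed=13,
        )
        res = fold_of_delay(cfg)
        assert 0.9 <= res.fold_of_delay <= 1.2

    def test_accept_mode_occupancy_scales_with_slowdown(self):
        """Inside-obstacle dwell time inflates ~slowdown-fold (oracle count)."""
        geom = build_geometry(TINY, np.random.default_rng(14))
        n = 4000
        _, in1 = naive_walk(geom, n, 1.0, "accept", np.random.default_rng(15),
                            record_inside=True)
        _, in10 = naive_walk(geom, n, 10.0, "accept", np.random.default_rng(16),
                             record_inside=True)
        ratio = in10.mean() / in1.mean()
        assert ratio == pytest.approx(10.0, rel=0.2)


class TestFoldOfDelay:
    def test_self_normalization_is_unity(self):
        cfg = SearchSimConfig(n_aggregates=0, n_simulations=300, n_geometries=3, seed=17)
        res = fold_of_delay(cfg)
        se = res.fold_of_delay * np.sqrt(
            (res.se_steps / res.mean_steps) ** 2
            + (res.control_se_steps / res.control_mean_steps) ** 2
        )
        assert abs(res.fold_of_delay - 1.0) < 3 * se
        assert res.fold_ci_low < 1.0 < res.fold_ci_high

    def test_sweep_shares_controls_and_reports_vr(self):
        cfgs = [
            SearchSimConfig(n_aggregates=n, aggregate_diameter=20.0,
                            n_simulations=100, n_geometries=2, seed=18)
            for n in (0, 100)
        ]
        df = sweep(cfgs)
        assert len(df) == 2
        assert df.loc[0, "volume_ratio"] == 0.0
        assert df.loc[1, "volume_ratio"] == pytest.approx(0.0125)
        assert df.loc[1, "control_mean_steps"] == df.loc[0, "control_mean_steps"]

    def test_fold_nondecreasing_in_obstacle_number(self):
        """More obstacle volume at fixed diameter delays the search more."""
        ctrl = run_condition(SearchSimConfig(n_aggregates=0, n_simulations=200,
                                             n_geometries=3, seed=19))
        means = []
        for n_agg in (100, 200, 400):
            cfg = SearchSimConfig(n_aggregates=n_agg, aggregate_diameter=20.0,
                                  n_simulations=200, n_geometries=3, seed=19)
            means.append(run_condition(cfg).mean())
        assert means[0] < means[1] < means[2]
        assert means[0] / ctrl.mean() > 1.1
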