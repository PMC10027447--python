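import math

import numpy as np
import pytest
from scipy.stats import norm

from doppelsim import (
    ModelConfig,
    PhysicalParams,
    build_viscosity_field,
    extract_experiment_stats,
    run_doppelganger,
    sample_lognormal_viscosity,
    simulate_track,
    stokes_einstein_diffusivity,
    viscosity_at,
    water_viscosity,
)
from doppelsim.doppelganger_sim import (
    DOMAIN_SIZE_PRESETS,
    _reflect,
    calibrate_model,
    drag_coefficient,
    measure_targets,
    step_sd,
)
from doppelsim.msd_analysis import (
    ensemble_average_msd,
    fit_power_law,
    time_averaged_msd,
)
from doppelsim.synthetic_experiment import SynthConfig, generate_experiment_stats

from conftest import make_cell, make_track

T30 = 303.15
ETA_W = water_viscosity(T30)


class TestPhysicalConstants:
    def test_water_viscosity_30C_one_sig_fig(self):
        assert round(ETA_W, 7) == pytest.approx(8e-7)

    def test_water_viscosity_20C(self):
        # direct evaluation of the empirical formula
        expected = 2.414e-8 * 10 ** (247.8 / (293.15 - 140))
        assert water_viscosity(293.15) == pytest.approx(expected)
        assert water_viscosity(293.15) == pytest.approx(1.00e-6, rel=0.005)

    def test_monotone_decreasing_in_T(self):
        temps = np.linspace(273, 373, 50)
        visc = [water_viscosity(t) for t in temps]
        assert np.all(np.diff(visc) < 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            water_viscosity(145.0)

    def test_drag_and_diffusivity_defaults(self):
        p = PhysicalParams()
        gamma = drag_coefficient(40 * ETA_W, p.R)
        assert gamma == pytest.approx(0.012, abs=5e-4)
        D = stokes_einstein_diffusivity(p, 40 * ETA_W)
        assert D == pytest.approx(350.0, rel=0.01)

    def test_doubling_eta_halves_D(self):
        p = PhysicalParams()
        assert stokes_einstein_diffusivity(p, 2 * ETA_W) == pytest.approx(
            stokes_einstein_diffusivity(p, ETA_W) / 2)

    def test_temperature_ratio(self):
        eta = 40 * ETA_W
        r = (stokes_einstein_diffusivity(PhysicalParams(T=293.15), eta)
             / stokes_einstein_diffusivity(PhysicalParams(T=303.15), eta))
        assert r == pytest.approx(293.15 / 303.15)
        assert r == pytest.approx(0.967, abs=5e-4)


class TestLognormalSampling:
    def test_zero_shape_degenerate(self):
        rng = np.random.default_rng(0)
        vals = sample_lognormal_viscosity(5e-6, 0.0, 100, rng, ETA_W)
        np.testing.assert_allclose(vals, 5e-6)

    def test_clipped_fraction_matches_normal_cdf(self):
        mu = 40 * ETA_W
        shape = 0.45
        rng = np.random.default_rng(1)
        vals = sample_lognormal_viscosity(mu, shape, 100_000, rng, ETA_W)
        expected = norm.cdf(math.log(1 / 40) / shape)  # ~Phi(-8.2) ~ 0
        assert np.mean(vals == ETA_W) == pytest.approx(expected, abs=1e-4)
        assert np.all(vals >= ETA_W)

    def test_sample_median_is_mu(self):
        mu = 40 * ETA_W
        rng = np.random.default_rng(2)
        vals = sample_lognormal_viscosity(mu, 0.85, 100_000, rng, ETA_W)
        assert np.median(vals) == pytest.approx(mu, rel=0.02)


class TestViscosityField:
    def test_degenerate_shapes_reduce_to_uniform(self):
        cell = make_cell()
        rng = np.random.default_rng(0)
        mu = 40 * ETA_W
        for model in ("spatial", "cellular", "combined"):
            cfg = ModelConfig(model=model, sigma_cell=0.0, sigma_spatial=0.0)
            f = build_viscosity_field(cell, cfg, mu, rng, ETA_W)
            for x, y in [(0, 0), (5000, 1500), (9999, 2999)]:
                assert viscosity_at(f, x, y) == pytest.approx(mu)

    def test_exact_tiling_no_remainder(self):
        cell = make_cell(L=10_000, W=3_000)
        f = build_viscosity_field(cell, ModelConfig(model="spatial"),
                                  40 * ETA_W, np.random.default_rng(3), ETA_W)
        assert f.grid.shape == (3, 10)

    def test_remainder_column(self):
        cell = make_cell(L=10_400, W=3_000)
        f = build_viscosity_field(cell, ModelConfig(model="spatial"),
                                  40 * ETA_W, np.random.default_rng(3), ETA_W)
        assert f.grid.shape == (3, 11)  # 10 full columns + 400 nm remainder
        # remainder column owns x in (10000, 10400]
        assert viscosity_at(f, 10_200, 500) == pytest.approx(f.grid[0, 10])

    def test_lambda_larger_than_cell_single_domain(self):
        cell = make_cell(L=800, W=500)
        f = build_viscosity_field(cell, ModelConfig(model="spatial",
                                                    domain_size_Lambda=1000),
                                  40 * ETA_W, np.random.default_rng(4), ETA_W)
        assert f.grid.shape == (1, 1)

    def test_lookup_conventions(self):
        cell = make_cell(L=3_000, W=2_000)
        f = build_viscosity_field(cell, ModelConfig(model="spatial"),
                                  40 * ETA_W, np.random.default_rng(5), ETA_W)
        assert viscosity_at(f, 1500, 500) == pytest.approx(f.grid[0, 1])
        # half-open convention: x exactly at Lambda belongs to domain 1
        assert viscosity_at(f, 1000.0, 0.0) == pytest.approx(f.grid[0, 1])
        with pytest.raises(ValueError):
            viscosity_at(f, -1.0, 0.0)

    def test_uniform_field_anywhere(self):
        f = build_viscosity_field(make_cell(), ModelConfig(model="uniform"),
                                  40 * ETA_W, np.random.default_rng(6), ETA_W)
        assert viscosity_at(f, 123.0, 456.0) == pytest.approx(40 * ETA_W)

    def test_floor_applied(self):
        cell = make_cell()
        cfg = ModelConfig(model="combined", sigma_cell=2.0, sigma_spatial=2.0)
        f = build_viscosity_field(cell, cfg, 2 * ETA_W,
                                  np.random.default_rng(7), ETA_W)
        assert np.all(f.grid >= ETA_W)


class TestReflection:
    def test_reflection_map_examples(self):
        # box [0, 10000] x [0, 3000]
        assert _reflect(np.array(-50.0), 10_000.0) == pytest.approx(50.0)
        assert _reflect(np.array(3_100.0), 3_000.0) == pytest.approx(2_900.0)
        assert _reflect(np.array(-3_100.0), 3_000.0) == pytest.approx(2_900.0)

    def test_reflection_against_fold_oracle(self):
        def oracle(v, extent):  # repeated single reflections
            while v < 0 or v > extent:
                v = -v if v < 0 else 2 * extent - v
            return v

        rng = np.random.default_rng(0)
        for v in rng.uniform(-25_000, 25_000, 200):
            assert _reflect(np.array(v), 3_000.0) == pytest.approx(
                oracle(v, 3_000.0))

    def test_positions_stay_in_box(self, small_ledger):
        for model in ("uniform", "combined"):
            ts = run_doppelganger(small_ledger, ModelConfig(
                model=model, domain_size_Lambda=300, seed=3))
            for tr in ts.tracks:
                cell = ts.cell(tr.cell_id)
                assert np.all(tr.positions[:, 0] >= 0)
                assert np.all(tr.positions[:, 0] <= cell.length_L)
                assert np.all(tr.positions[:, 1] >= 0)
                assert np.all(tr.positions[:, 1] <= cell.width_W)


class TestSimulateTrack:
    def test_single_step_variance(self):
        p = PhysicalParams()
        cell = make_cell(L=1e6, W=1e6)
        f = build_viscosity_field(cell, ModelConfig(model="uniform"),
                                  40 * ETA_W, np.random.default_rng(0), ETA_W)
        rng = np.random.default_rng(1)
        disp = np.array([
            np.diff(simulate_track(cell, f, 1, p, rng).positions, axis=0)[0]
            for _ in range(10_000)
        ])
        D = stokes_einstein_diffusivity(p, 40 * ETA_W)
        np.testing.assert_allclose(disp.var(axis=0), 2 * D * p.dt, rtol=0.05)

    def test_step_sd_formula(self):
        p = PhysicalParams()
        xi = step_sd(p, 40 * ETA_W)
        assert xi == pytest.approx(
            math.sqrt(2 * p.kT * p.dt / (6 * math.pi * 40 * ETA_W * p.R)))

    def test_returns_n_steps_plus_one(self):
        cell = make_cell()
        f = build_viscosity_field(cell, ModelConfig(model="uniform"),
                                  40 * ETA_W, np.random.default_rng(0), ETA_W)
        tr = simulate_track(cell, f, 9, PhysicalParams(),
                            np.random.default_rng(2))
        assert tr.n_points == 10

    def test_grid_and_uniform_agree_statistically(self):
        # degenerate grid (zero shape) must reproduce uniform MSD statistics
        p = PhysicalParams()
        cell = make_cell()
        rng = np.random.default_rng(3)
        f_uni = build_viscosity_field(cell, ModelConfig(model="uniform"),
                                      40 * ETA_W, rng, ETA_W)
        f_grid = build_viscosity_field(
            cell, ModelConfig(model="spatial", sigma_spatial=0.0),
            40 * ETA_W, rng, ETA_W)
        curves_u = [time_averaged_msd(simulate_track(cell, f_uni, 30, p,
                                                     np.random.default_rng(100 + i)), 7)
                    for i in range(300)]
        curves_g = [time_averaged_msd(simulate_track(cell, f_grid, 30, p,
                                                     np.random.default_rng(900 + i)), 7)
                    for i in range(300)]
        fu = fit_power_law(ensemble_average_msd(curves_u))
        fg = fit_power_law(ensemble_average_msd(curves_g))
        assert fg.d_app == pytest.approx(fu.d_app, rel=0.1)

    def test_long_track_free_space_parameter_recovery(self):
        # >= 1e4 points, box large enough that reflections never occur
        p = PhysicalParams()
        cell = make_cell(L=1e9, W=1e9)
        f = build_viscosity_field(cell, ModelConfig(model="uniform"),
                                  40 * ETA_W, np.random.default_rng(0), ETA_W)
        tr = simulate_track(cell, f, 10_000, p, np.random.default_rng(5))
        fit = fit_power_law(time_averaged_msd(tr, 7))
        D = stokes_einstein_diffusivity(p, 40 * ETA_W)
        assert fit.alpha == pytest.approx(1.0, abs=0.05)
        assert fit.d_app == pytest.approx(D, rel=0.1)


class TestRunDoppelganger:
    def test_fixed_point(self, small_ledger):
        ts = run_doppelganger(small_ledger, ModelConfig(model="combined", seed=1))
        assert extract_experiment_stats(ts) == small_ledger

    def test_fixed_point_random_ledgers(self):
        for seed in (11, 12, 13):
            stats = generate_experiment_stats(SynthConfig(n_cells=5, seed=seed))
            ts = run_doppelganger(stats, ModelConfig(model="spatial", seed=seed))
            assert extract_experiment_stats(ts) == stats

    def test_deterministic_given_seed(self, small_ledger):
        a = run_doppelganger(small_ledger, ModelConfig(model="combined", seed=8))
        b = run_doppelganger(small_ledger, ModelConfig(model="combined", seed=8))
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_different_seeds_differ(self, small_ledger):
        a = run_doppelganger(small_ledger, ModelConfig(model="uniform", seed=1))
        b = run_doppelganger(small_ledger, ModelConfig(model="uniform", seed=2))
        assert not np.allclose(a.tracks[0].positions, b.tracks[0].positions)

    def test_labels_copied(self, small_ledger):
        ts = run_doppelganger(small_ledger, ModelConfig(model="uniform", seed=1))
        for cell, entry in zip(ts.cells, small_ledger.cells):
            assert (cell.cell_id, cell.session_id, cell.day_id) == (
                entry.cell_id, entry.session_id, entry.day_id)
            assert cell.length_L == entry.length_L
            assert cell.width_W == 3_000.0

    def test_dt_mismatch_rejected(self, small_ledger):
        with pytest.raises(ValueError):
            run_doppelganger(small_ledger, ModelConfig(model="uniform"),
                             PhysicalParams(dt=5.0))

    def test_variance_monotone_in_shapes(self, small_ledger):
        # more spatial spread -> more track-wise variance;
        # more cellular spread -> more cell-wise variance
        def variances(sc, ss):
            cfg = ModelConfig(model="combined", sigma_cell=sc,
                              sigma_spatial=ss, seed=21)
            t = measure_targets(run_doppelganger(small_ledger, cfg))
            return t["track_var_log10_dapp"], t["cell_var_log10_dapp"]

        tv_lo, _ = variances(0.2, 0.2)
        tv_hi, _ = variances(0.2, 1.2)
        assert tv_hi > tv_lo
        _, cv_lo = variances(0.1, 0.5)
        _, cv_hi = variances(1.0, 0.5)
        assert cv_hi > cv_lo


class TestCalibration:
    def test_uniform_targets_recover_small_shapes(self, small_ledger):
        uni = run_doppelganger(small_ledger, ModelConfig(model="uniform", seed=30))
        targets = measure_targets(uni)
        res = calibrate_model(small_ledger, 1000.0, targets,
                              n_replicates=1, n_iter=4, seed=31)
        assert res.config.sigma_cell < 0.25
        assert res.config.sigma_spatial < 0.45

    def test_combined_self_consistency(self, small_ledger):
        truth = ModelConfig(model="combined", mean_visc_rel_water=40.0,
                            sigma_cell=0.45, sigma_spatial=0.85, seed=40)
        targets = measure_targets(run_doppelganger(small_ledger, truth))
        res = calibrate_model(small_ledger, 1000.0, targets,
                              n_replicates=1, n_iter=5, seed=41)
        assert res.config.mean_visc_rel_water == pytest.approx(40.0, rel=0.35)
        assert res.config.sigma_spatial == pytest.approx(0.85, abs=0.35)

    def test_beats_coarse_grid(self, small_ledger):
        from doppelsim.doppelganger_sim import _sim_targets

        truth = ModelConfig(model="combined", sigma_cell=0.45,
                            sigma_spatial=0.85, seed=50)
        targets = measure_targets(run_doppelganger(small_ledger, truth))
        res = calibrate_model(small_ledger, 1000.0, targets,
                              n_replicates=1, n_iter=5, seed=51)
        tgt = np.array([targets["median_log10_dapp"],
                        targets["track_var_log10_dapp"],
                        targets["cell_var_log10_dapp"]])
        p = PhysicalParams()
        for mean in (20.0, 40.0, 80.0):
            for sc in (0.1, 0.6):
                for ss in (0.3, 1.2):
                    cfg = ModelConfig(model="combined", mean_visc_rel_water=mean,
                                      sigma_cell=sc, sigma_spatial=ss, seed=51 + 1)
                    got, _ = _sim_targets(small_ledger, cfg, p, 1, 100.0, 7)
                    grid_loss = float((got - tgt) @ (got - tgt))
                    assert res.loss <= grid_loss + 1e-12


class TestPresets:
    def test_preset_table_shapes(self):
        assert set(DOMAIN_SIZE_PRESETS) == {100.0, 300.0, 600.0, 1000.0, 3000.0}
        for mean, sc, ss in DOMAIN_SIZE_PRESETS.values():
            assert mean > 0 and sc >= 0 and ss > 0
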