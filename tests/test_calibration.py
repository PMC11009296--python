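"""Error models, posterior construction, MAP and the test-case runner."""

import numpy as np
import pytest

from pvlnode.calibration import (
    TEST_CASES,
    ErrorModel,
    ObservationSet,
    build_error_model,
    hmc_sample,
    log_posterior,
    make_observation,
    map_estimate,
    run_test_case,
)
from pvlnode.parameters import ParameterVector
from pvlnode.traces import CHANNELS, PVTrace, SimulationDataset


@pytest.fixture(scope="module")
def calib_setup(tiny_surrogate):
    """Surrogate + self-consistent truth/observation for the T_LV case."""
    model, _, train_ds = tiny_surrogate
    sp = model.space
    truth = ParameterVector(sp, sp.from_unit(np.full(len(sp), 0.2)))
    obs = make_observation("T_LV", truth, model, source="surrogate")
    err = ErrorModel(np.full(8, 0.5), np.full(8, 1.0))
    return model, truth, obs, err


class TestObservationSet:
    def test_empty_mask_rejected(self, calib_setup):
        model, truth, obs, _ = calib_setup
        with pytest.raises(ValueError, match="mask"):
            ObservationSet((), obs.t, obs.observed[:, :0], obs.T_HB,
                           obs.AV_delay, obs.z0_physical, truth, obs.estimate)

    def test_unknown_channel_rejected(self, calib_setup):
        model, truth, obs, _ = calib_setup
        with pytest.raises(KeyError, match="unknown channels"):
            ObservationSet(("V_XX",), obs.t, obs.observed, obs.T_HB,
                           obs.AV_delay, obs.z0_physical, truth, obs.estimate)

    def test_timing_parameters_not_estimable(self, calib_setup):
        model, truth, obs, _ = calib_setup
        with pytest.raises(ValueError, match="timing"):
            ObservationSet(obs.mask, obs.t, obs.observed, obs.T_HB,
                           obs.AV_delay, obs.z0_physical, truth,
                           ("AV_delay",))

    def test_unknown_case_name(self, calib_setup):
        model, truth, _, _ = calib_setup
        with pytest.raises(KeyError, match="unknown test case"):
            make_observation("T_nope", truth, model)


class TestErrorModel:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            ErrorModel(np.zeros(8), np.ones(8))

    def test_variance_composition(self):
        em = ErrorModel(np.full(8, 3.0), np.full(8, 4.0))
        var = em.variance(np.array([0, 5]), n_samples=4)
        assert var.shape == (4, 2)
        assert np.allclose(var, 25.0)

    def test_homoscedastic_matches_rmse(self, tiny_surrogate):
        from pvlnode.training import predict_record

        model, _, train_ds = tiny_surrogate
        val = train_ds.subset(range(3))
        em = build_error_model(model, val, mode="homoscedastic")
        resid = np.stack([
            predict_record(model, th, tr).values - tr.values
            for th, tr in val.records
        ])
        want = np.maximum(np.sqrt(np.mean(resid**2, axis=(0, 1))), 1e-3)
        assert np.allclose(em.surrogate_std, want, rtol=1e-12)

    def test_scale_equivariance(self, tiny_surrogate):
        """Doubling every residual doubles the homoscedastic std."""
        from pvlnode.training import predict_record

        model, _, train_ds = tiny_surrogate
        val = train_ds.subset(range(3))
        em1 = build_error_model(model, val, mode="homoscedastic")
        # build a synthetic validation set whose residuals are doubled
        recs = []
        for th, tr in val.records:
            pred = predict_record(model, th, tr).values
            doubled = pred + 2.0 * (tr.values - pred)
            doubled[:, 4:] = np.maximum(doubled[:, 4:], 1e-3)
            recs.append((th, PVTrace(tr.t, doubled, tr.T_HB, tr.AV_delay)))
        em2 = build_error_model(model, SimulationDataset(val.space, recs),
                                mode="homoscedastic")
        big = em1.surrogate_std > 0.01  # away from the floor
        assert np.allclose(em2.surrogate_std[big], 2 * em1.surrogate_std[big],
                           rtol=0.02)

    def test_perfect_surrogate_hits_floor(self, tiny_surrogate):
        """Zero residuals leave the surrogate std at the configured floor."""
        from pvlnode.training import predict_record

        model, _, train_ds = tiny_surrogate
        recs = []
        for th, tr in train_ds.subset(range(2)).records:
            pred = predict_record(model, th, tr).values
            pred[:, 4:] = np.maximum(pred[:, 4:], 1e-3)
            recs.append((th, PVTrace(tr.t, pred, tr.T_HB, tr.AV_delay)))
        em = build_error_model(model, SimulationDataset(train_ds.space, recs),
                               mode="homoscedastic")
        assert np.allclose(em.surrogate_std, 1e-3)

    def test_time_varying_consistent_with_homoscedastic(self, tiny_surrogate):
        """RMS over phase of the smoothed std curve stays within 15% of the
        homoscedastic value."""
        model, _, train_ds = tiny_surrogate
        val = train_ds.subset(range(4))
        em_h = build_error_model(model, val, mode="homoscedastic")
        em_t = build_error_model(model, val, mode="time-varying")
        rms = np.sqrt(np.mean(em_t.surrogate_std**2, axis=0))
        big = em_h.surrogate_std > 0.01
        assert np.all(np.abs(rms[big] - em_h.surrogate_std[big])
                      <= 0.15 * em_h.surrogate_std[big])

    def test_empty_validation_rejected(self, tiny_surrogate):
        model, _, train_ds = tiny_surrogate
        with pytest.raises(ValueError, match="empty"):
            build_error_model(model, train_ds.subset([]), "homoscedastic")


class TestLogPosterior:
    def test_out_of_bounds_is_minus_inf_not_exception(self, calib_setup):
        model, truth, obs, err = calib_setup
        sub = model.space.subspace(obs.estimate)
        bad = sub.upper + 1.0
        assert log_posterior(bad, obs, model, err) == -np.inf

    def test_gradient_zero_at_self_consistent_truth(self, calib_setup):
        """Noiseless surrogate-generated data: the truth is a stationary
        point of the posterior."""
        model, truth, obs, err = calib_setup
        th = np.array([truth[p] for p in obs.estimate])
        lp, g = log_posterior(th, obs, model, err, with_grad=True)
        sub = model.space.subspace(obs.estimate)
        assert np.linalg.norm(g * sub.widths) < 1e-6

    def test_gradient_matches_finite_differences(self, calib_setup):
        model, truth, obs, err = calib_setup
        sub = model.space.subspace(obs.estimate)
        th = sub.from_unit(np.full(len(sub), -0.3))
        lp, g = log_posterior(th, obs, model, err, with_grad=True)
        for k in range(len(th)):
            e = np.zeros_like(th)
            e[k] = 1e-6 * sub.widths[k]
            num = (log_posterior(th + e, obs, model, err)
                   - log_posterior(th - e, obs, model, err)) / (2 * e[k])
            assert num == pytest.approx(g[k], rel=1e-4, abs=1e-8)

    def test_std_inflation_closed_form(self, calib_setup):
        """Doubling all stds rescales the data term exactly as the Gaussian
        algebra predicts."""
        model, truth, obs, err = calib_setup
        sub = model.space.subspace(obs.estimate)
        th = sub.from_unit(np.full(len(sub), 0.4))
        err2 = ErrorModel(2 * err.measurement_std, 2 * err.surrogate_std)
        lp1 = log_posterior(th, obs, model, err)
        lp2 = log_posterior(th, obs, model, err2)
        var = err.variance(obs.channel_idx, len(obs.t))
        n_terms = var.size
        const1 = 0.5 * np.sum(np.log(2 * np.pi * var))
        D = -2.0 * (lp1 + const1)            # sum of squared scaled residuals
        lp2_pred = -D / 8.0 - const1 - n_terms * np.log(2.0)
        assert lp2 == pytest.approx(lp2_pred, rel=1e-10)


class TestMapEstimate:
    def test_one_parameter_grid_scan_oracle(self, calib_setup):
        """MAP agrees with a dense brute-force scan of the posterior."""
        model, truth, obs, err = calib_setup
        obs1 = ObservationSet(obs.mask, obs.t, obs.observed, obs.T_HB,
                              obs.AV_delay, obs.z0_physical, truth,
                              ("R_sys_scale",))
        est = map_estimate(obs1, model, err, n_restarts=2, seed=0)
        i = model.space.index("R_sys_scale")
        grid = np.linspace(model.space.lower[i] + 1e-6,
                           model.space.upper[i] - 1e-6, 2001)
        vals = [log_posterior(np.array([g]), obs1, model, err) for g in grid]
        g_best = grid[int(np.argmax(vals))]
        cell = grid[1] - grid[0]
        assert abs(est.theta["R_sys_scale"] - g_best) <= cell

    def test_determinism(self, calib_setup):
        model, truth, obs, err = calib_setup
        a = map_estimate(obs, model, err, n_restarts=3, seed=4)
        b = map_estimate(obs, model, err, n_restarts=3, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_map_recovers_self_consistent_truth(self, calib_setup):
        model, truth, obs, err = calib_setup
        est = map_estimate(obs, model, err, n_restarts=4, seed=1)
        sub = model.space.subspace(obs.estimate)
        tvals = np.array([truth[p] for p in obs.estimate])
        assert np.all(np.abs(est.values - tvals) / sub.widths < 0.05)


class TestRunTestCase:
    def test_case_table_masks(self):
        assert TEST_CASES["T_LV"]["mask"] == ("V_LV",)
        assert len(TEST_CASES["T_LV"]["estimate"]) == 4
        assert set(TEST_CASES["T_all"]["mask"]) == set(CHANNELS)
        for case in TEST_CASES.values():
            assert not {"T_HB", "AV_delay"} & set(case["estimate"])

    def test_report_structure_and_consistency(self, calib_setup):
        model, truth, obs, err = calib_setup
        report = run_test_case("T_LV", truth, model, err, seed=3,
                               source="surrogate", n_restarts=2,
                               n_chains=2, n_warmup=120, n_samples=120)
        k = len(report.estimate)
        assert report.chains.shape == (2, 120, k)
        assert report.median.shape == (k,)
        assert np.all(report.iqr >= 0)
        assert np.all(report.median >= report.ci95[:, 0] - 1e-12)
        assert np.all(report.median <= report.ci95[:, 1] + 1e-12)
        df = report.summary_frame()
        assert list(df["parameter"]) == list(report.estimate)
        # MAP basin consistency: posterior at MAP >= posterior at median - 5
        lp_map = log_posterior(report.map_point.values, obs, model, err)
        lp_med = log_posterior(report.median, obs, model, err)
        assert lp_map >= lp_med - 5.0

    def test_report_save(self, calib_setup, tmp_path):
        model, truth, obs, err = calib_setup
        report = run_test_case("T_LV", truth, model, err, seed=5,
                               source="surrogate", n_restarts=1,
                               n_chains=2, n_warmup=60, n_samples=60)
        report.save(tmp_path / "rep")
        assert (tmp_path / "rep.csv").exists()
        assert (tmp_path / "rep.json").exists()
        draws = report.pairwise_draws()
        assert list(draws.columns) == list(report.estimate)
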