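"""Dataset pre-treatment, weighting, and the global least-squares fit."""

import numpy as np
import pytest

from thermosvd import (
    Dataset,
    DatasetKind,
    ExperimentMeta,
    FitOptions,
    FitProblem,
    ModelSpec,
    Scheme,
    SignalParams,
    ThermoParams,
    ValidationError,
    collate_kinetics,
    component_curves,
    dataset_weight,
    decompose,
    denormalize,
    f_ratio,
    fit_global,
    load_preset,
    make_state_spectra,
    normalize_dataset,
    reconstruct_fitted_spectra,
    residual_vector,
    simulate_kinetics,
    simulate_melt_curve,
    simulate_scan_spectra,
    state_fingerprints,
)


def _melt(spec):
    return simulate_melt_curve(spec)


def _svd_curves(spec, k):
    sm = simulate_scan_spectra(spec)
    res = decompose(sm)
    curves = component_curves(res, k)
    curves.meta.scan_rate = spec.scan_rate
    return res, curves


class TestNormalize:
    def test_range_and_inverse(self, two_state_spec):
        d = _melt(two_state_spec)
        nd = normalize_dataset(d)
        assert nd.y.min() == pytest.approx(0.0) and nd.y.max() == pytest.approx(1.0)
        back = denormalize(nd)
        assert np.allclose(back, d.y, rtol=0, atol=1e-12)

    def test_temperature_window(self, two_state_spec):
        d = _melt(two_state_spec)
        nd = normalize_dataset(d, t_range=(30.0, 70.0))
        assert nd.x.min() >= 30.0 and nd.x.max() <= 70.0
        assert nd.x.size < d.x.size

    def test_svd_columns_normalized_independently(self, three_state_spec):
        _, curves = _svd_curves(three_state_spec, 3)
        nd = normalize_dataset(curves)
        assert np.allclose(nd.y.min(axis=0), 0.0) and np.allclose(nd.y.max(axis=0), 1.0)
        assert np.allclose(denormalize(nd), curves.y, atol=1e-12)

    def test_wrong_kind_rejected(self):
        d = Dataset(DatasetKind.DSC, np.arange(5.0), np.arange(5.0),
                    ExperimentMeta(scan_rate=1.0))
        with pytest.raises(ValidationError):
            normalize_dataset(d)

    def test_zero_span_rejected(self):
        d = Dataset(DatasetKind.SPECTROSCOPY, np.arange(5.0), np.ones(5),
                    ExperimentMeta(scan_rate=1.0))
        with pytest.raises(ValidationError, match="span"):
            normalize_dataset(d)

    def test_no_transform_recorded_rejected(self, two_state_spec):
        with pytest.raises(ValidationError):
            denormalize(_melt(two_state_spec))


class TestCollateKinetics:
    def _traces(self):
        spec = load_preset("two_state_fluor", seed=5, noise_sd=0.0)
        spec.t_grid_s = np.linspace(0.0, 120.0, 40)
        spec.iso_temperatures = (48.0, 52.0)
        spec.thermo = ThermoParams(tm1=50.0, dh1=400.0, ea=200.0, tf=55.0)
        return spec, simulate_kinetics(spec)

    def test_free_mode_no_sharing(self):
        _, traces = self._traces()
        out = collate_kinetics(traces, "free")
        assert all(not getattr(d, "share_endpoint", False) for d in out)

    def test_shared_final_registers_tie(self):
        spec, traces = self._traces()
        out = collate_kinetics(traces, "shared_final")
        problem = FitProblem(out, spec.model, spec.thermo)
        assert problem.ties == {"ds1.a_D": "ds0.a_D"}
        assert not problem.params["ds1.a_D"].vary
        # the tie propagates values
        problem.params["ds0.a_D"].value = 0.123
        problem.set_free(problem.free_vector())
        assert problem.params["ds1.a_D"].value == 0.123

    def test_bad_mode_and_kind(self):
        _, traces = self._traces()
        with pytest.raises(ValueError):
            collate_kinetics(traces, "banana")
        melt = _melt(load_preset("two_state_fluor", seed=1, noise_sd=0.0))
        with pytest.raises(ValidationError):
            collate_kinetics([melt])


class TestWeights:
    def test_known_value(self):
        y = np.linspace(0.0, 1.0, 100)  # span 1, n 100
        d = Dataset(DatasetKind.SPECTROSCOPY, np.linspace(20, 90, 100), y,
                    ExperimentMeta(scan_rate=1.0))
        assert dataset_weight(d) == pytest.approx(0.01)

    def test_halving_span_quadruples_weight(self):
        x = np.linspace(20, 90, 50)
        d1 = Dataset(DatasetKind.SPECTROSCOPY, x, np.linspace(0, 2, 50),
                     ExperimentMeta(scan_rate=1.0))
        d2 = Dataset(DatasetKind.SPECTROSCOPY, x, np.linspace(0, 1, 50),
                     ExperimentMeta(scan_rate=1.0))
        assert dataset_weight(d2) == pytest.approx(4 * dataset_weight(d1))

    def test_constant_signal_rejected(self):
        d = Dataset(DatasetKind.SPECTROSCOPY, np.arange(5.0), np.full(5, 2.0),
                    ExperimentMeta(scan_rate=1.0))
        with pytest.raises(ValidationError):
            dataset_weight(d)

    def test_unit_invariance_of_weighted_residuals(self, two_state_model):
        """Rescaling a dataset's units leaves its weighted residual block unchanged."""
        spec = load_preset("two_state_fluor", seed=7, noise_sd=0.0)
        d = _melt(spec)
        big = Dataset(d.kind, d.x, 1000.0 * d.y, d.meta)
        init = ThermoParams(tm1=48.0, dh1=350.0)
        r_small = residual_vector(
            (p := FitProblem([d], two_state_model, init)).free_vector(), p
        )
        r_big = residual_vector(
            (q := FitProblem([big], two_state_model, init)).free_vector(), q
        )
        assert np.allclose(r_small, r_big, rtol=1e-9, atol=1e-12)

    def test_svd_components_weighted_per_column(self, three_state_spec):
        _, curves = _svd_curves(three_state_spec, 3)
        problem = FitProblem([curves], three_state_spec.model, three_state_spec.thermo)
        w = problem._weights[0]
        assert w.shape == (3,)
        # the small-span third component gets a larger weight than the first
        assert w[2] > w[0]
        # each weighted block is O(1): sqrt(w_k) * span_k == 1/sqrt(n)
        span = curves.y.max(axis=0) - curves.y.min(axis=0)
        assert np.allclose(np.sqrt(w) * span, 1.0 / np.sqrt(curves.y.shape[0]))


class TestResiduals:
    def test_truth_residuals_vanish_noise_free(self, two_state_model):
        spec = load_preset("two_state_fluor", seed=9, noise_sd=0.0)
        d = _melt(spec)
        problem = FitProblem([d], two_state_model, spec.thermo)
        # set true baselines (generator used a_N=1, a_D=0.3, zero slopes)
        problem.params["ds0.a_N"].value = 1.0
        problem.params["ds0.a_D"].value = 0.3
        r = residual_vector(problem.free_vector(), problem)
        assert np.max(np.abs(r)) < 1e-10

    def test_wssr_is_sum_of_squares(self, two_state_model):
        spec = load_preset("two_state_fluor", seed=9)
        d = _melt(spec)
        problem = FitProblem([d], two_state_model, ThermoParams(tm1=49.0, dh1=380.0))
        r = residual_vector(problem.free_vector(), problem)
        w = problem._weights[0][0]
        m = problem.model_curve(0)
        assert float(r @ r) == pytest.approx(float(np.sum(w * (m - d.y) ** 2)))

    def test_tm_order_penalty_active(self, three_state_spec):
        _, curves = _svd_curves(three_state_spec, 3)
        problem = FitProblem([curves], three_state_spec.model,
                             ThermoParams(tm1=47.5, dh1=350.0, tm2=52.5, dh2=420.0))
        x = problem.free_vector()
        r_ok = residual_vector(x, problem)
        assert r_ok[-1] == 0.0
        x_bad = x.copy()
        i1 = problem.free_names.index("tm1")
        i2 = problem.free_names.index("tm2")
        x_bad[i1], x_bad[i2] = 60.0, 40.0
        r_bad = residual_vector(x_bad, problem)
        assert r_bad[-1] == pytest.approx(10.0 * 20.0)


class TestFitGlobal:
    def test_noise_free_truth_init_wssr_tiny(self, two_state_model):
        spec = load_preset("two_state_fluor", seed=13, noise_sd=0.0)
        problem = FitProblem([_melt(spec)], two_state_model, spec.thermo)
        fit = fit_global(problem)
        assert fit.wssr < 1e-12
        assert fit.converged

    def test_recovers_truth_from_offset_start(self, two_state_model):
        spec = load_preset("two_state_fluor", seed=13, noise_sd=0.0)
        problem = FitProblem(
            [_melt(spec)], two_state_model, ThermoParams(tm1=46.0, dh1=300.0)
        )
        fit = fit_global(problem)
        assert fit.params["tm1"] == pytest.approx(50.0, abs=1e-4)
        assert fit.params["dh1"] == pytest.approx(400.0, rel=1e-4)
        assert fit.wssr <= fit.init_wssr

    def test_fixed_parameter_stays_fixed(self, two_state_model):
        spec = load_preset("two_state_fluor", seed=13, noise_sd=0.0)
        problem = FitProblem(
            [_melt(spec)], two_state_model, ThermoParams(tm1=48.0, dh1=400.0),
            fixed=("tm1",),
        )
        fit = fit_global(problem)
        assert fit.params["tm1"] == 48.0
        assert "tm1" not in fit.stderr

    def test_stderr_reported_for_free_params(self, two_state_model):
        spec = load_preset("two_state_fluor", seed=13)  # with noise
        problem = FitProblem(
            [_melt(spec)], two_state_model, ThermoParams(tm1=49.0, dh1=380.0)
        )
        fit = fit_global(problem)
        assert set(fit.stderr) == set(problem.free_names)
        assert all(np.isfinite(v) and v >= 0 for v in fit.stderr.values())
        # with 1% noise the truth should be within a few stderr
        assert abs(fit.params["tm1"] - 50.0) < 5 * fit.stderr["tm1"] + 1e-6

    def test_joint_melt_and_dsc_share_thermo(self, two_state_model):
        spec = load_preset("two_state_fluor", seed=21, noise_sd=0.0)
        from thermosvd import simulate_dsc
        spec.dsc_baselines = {"N": (0.0, 0.0), "D": (2.0, 0.0)}
        melt, dsc = _melt(spec), simulate_dsc(spec)
        problem = FitProblem(
            [melt, dsc], two_state_model, ThermoParams(tm1=47.0, dh1=340.0)
        )
        fit = fit_global(problem)
        assert fit.params["tm1"] == pytest.approx(50.0, abs=1e-3)
        assert fit.params["dh1"] == pytest.approx(400.0, rel=1e-3)
        assert len(fit.per_dataset_rmse) == 2

    def test_multi_start_deterministic(self, two_state_model):
        spec = load_preset("two_state_fluor", seed=17)
        fits = []
        for _ in range(2):
            problem = FitProblem(
                [_melt(spec)], two_state_model, ThermoParams(tm1=45.0, dh1=200.0),
                options=FitOptions(multi_start=3, seed=42),
            )
            fits.append(fit_global(problem))
        assert fits[0].params == fits[1].params
        assert fits[0].wssr == fits[1].wssr


@pytest.fixture(scope="module")
def three_state_fit():
    spec = load_preset("three_state_hidden_intermediate", seed=11, noise_sd=0.0)
    sm = simulate_scan_spectra(spec)
    res = decompose(sm)
    curves = component_curves(res, 3)
    curves.meta.scan_rate = spec.scan_rate
    problem = FitProblem([curves], spec.model, spec.thermo)
    fit = fit_global(problem)
    return spec, sm, res, fit


class TestSpectraFromFit:
    def test_reconstruction_matches_data_noise_free(self, three_state_fit):
        spec, sm, res, fit = three_state_fit
        xfit = reconstruct_fitted_spectra(fit, res)
        rel = np.linalg.norm(xfit - sm.intensities) / np.linalg.norm(sm.intensities)
        assert rel < 1e-6

    def test_fewer_components_reconstruct_worse(self, three_state_fit):
        spec, sm, res, fit = three_state_fit
        curves1 = component_curves(res, 2)
        curves1.meta.scan_rate = spec.scan_rate
        p1 = FitProblem([curves1], spec.model, spec.thermo)
        f1 = fit_global(p1)
        x1 = reconstruct_fitted_spectra(f1, res)
        x3 = reconstruct_fitted_spectra(fit, res)
        err = lambda x: np.linalg.norm(x - sm.intensities)
        assert err(x1) > err(x3)

    def test_fingerprints_match_true_state_spectra(self, three_state_fit):
        spec, sm, res, fit = three_state_fit
        F = state_fingerprints(fit, res)
        S_true = make_state_spectra(spec)
        assert F.shape == S_true.shape
        for j in range(S_true.shape[1]):
            cos = float(
                F[:, j] @ S_true[:, j]
                / (np.linalg.norm(F[:, j]) * np.linalg.norm(S_true[:, j]))
            )
            assert cos > 0.999

    def test_fraction_weighted_fingerprints_reproduce_fit(self, three_state_fit):
        spec, sm, res, fit = three_state_fit
        F = state_fingerprints(fit, res)
        fr = fit.fractions[0]
        xfit = reconstruct_fitted_spectra(fit, res)
        assert np.allclose(F @ fr.fractions.T, xfit, atol=1e-10)

    def test_no_svd_dataset_rejected(self, two_state_model):
        spec = load_preset("two_state_fluor", seed=3, noise_sd=0.0)
        problem = FitProblem([_melt(spec)], two_state_model, spec.thermo)
        fit = fit_global(problem)
        sm = simulate_scan_spectra(spec)
        res = decompose(sm)
        with pytest.raises(ValidationError):
            reconstruct_fitted_spectra(fit, res)


class TestFRatio:
    def test_large_when_extra_params_help(self):
        assert f_ratio(100.0, 4, 1.0, 8, 200) > 10

    def test_zero_when_no_improvement(self):
        assert f_ratio(1.0, 4, 1.0, 8, 200) == 0.0

    def test_degenerate_cases_inf(self):
        assert f_ratio(1.0, 8, 0.5, 4, 200) == np.inf  # not nested
        assert f_ratio(1.0, 4, 0.0, 8, 200) == np.inf  # perfect big model
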