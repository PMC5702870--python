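import math

import numpy as np
import pytest

from numpref import (
    GridSpec,
    HRFModel,
    TuningModel,
    build_default_design,
    fit_constrained,
    fit_grid,
    hrf_kernel,
    neural_prediction,
    predict_bold,
)
from numpref.features import FeatureTimecourse


def num_track(design, config="constant_area"):
    return FeatureTimecourse("numerosity", config, design.numerosities().astype(float), "log10")


class TestNeuralPrediction:
    def test_gaussian_values(self, design):
        tr = num_track(design)
        m = TuningModel(preferred=math.log10(4), width=0.3)
        resp = neural_prediction(m, tr)
        at4 = resp[design.numerosities() == 4]
        assert np.all(at4 == pytest.approx(1.0))
        shifted = TuningModel(preferred=math.log10(4) + 0.3, width=0.3)
        at4b = neural_prediction(shifted, tr)[design.numerosities() == 4]
        assert np.all(at4b == pytest.approx(math.exp(-0.5)))

    def test_wide_width_flattens_response(self, design):
        resp = neural_prediction(TuningModel(0.5, 1e6), num_track(design))
        assert np.ptp(resp) == pytest.approx(0.0, abs=1e-9)

    def test_undefined_steps_evoke_no_response(self, design):
        vals = design.numerosities().astype(float)
        vals[2] = np.nan
        tr = FeatureTimecourse("f", "c", vals, "log10")
        resp = neural_prediction(TuningModel(0.5, 0.3), tr)
        assert resp[2] == 0.0

    def test_nonpositive_on_log_axis_rejected(self, design):
        vals = design.numerosities().astype(float)
        vals[0] = -1.0
        tr = FeatureTimecourse("f", "c", vals, "log10")
        with pytest.raises(ValueError):
            neural_prediction(TuningModel(0.5, 0.3), tr)

    def test_axis_mismatch_rejected(self, design):
        tr = FeatureTimecourse("f", "c", design.numerosities().astype(float), "linear")
        with pytest.raises(ValueError):
            neural_prediction(TuningModel(0.5, 0.3, axis="log10"), tr)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            TuningModel(0.5, 0.0)


class TestHRF:
    def test_default_kernel_shape(self):
        k = hrf_kernel(HRFModel(), dt=0.1)
        t = np.arange(len(k)) * 0.1
        assert k[0] == 0.0
        assert k.max() == 1.0
        peak_t = t[np.argmax(k)]
        assert 4.0 <= peak_t <= 6.0
        trough = np.argmin(k)
        assert t[trough] > peak_t and k[trough] < 0.0
        assert np.trapezoid(k, t) > 0.0

    def test_large_ratio_removes_undershoot(self):
        k = hrf_kernel(HRFModel(ratio=1e9), dt=0.2)
        assert k.min() >= -1e-9

    @pytest.mark.parametrize(
        "kwargs", [dict(peak_dispersion=0.0), dict(ratio=-1.0), dict(duration=10.0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HRFModel(**kwargs)


class TestPredictBold:
    def test_flat_neural_gives_flat_bold(self):
        design = build_default_design(cycles=2)
        vals = np.full(design.n_samples, 5.0)
        tr = FeatureTimecourse("f", "c", vals, "linear")
        pred = predict_bold(TuningModel(5.0, 0.5, axis="linear"), tr, HRFModel(), design)
        assert np.ptp(pred) == 0.0

    def test_impulse_gives_shifted_kernel_in_linear_mode(self):
        design = build_default_design(cycles=4)  # 80 s > kernel duration
        vals = np.full(design.n_samples, 100.0)
        vals[0] = 1.0
        tr = FeatureTimecourse("f", "c", vals, "linear")
        pred = predict_bold(
            TuningModel(1.0, 1e-3, axis="linear"), tr, HRFModel(), design, mode="linear"
        )
        kernel = hrf_kernel(HRFModel(), design.sampling_interval)
        np.testing.assert_allclose(pred[: len(kernel)], kernel, atol=1e-12)

    def test_linearity_in_neural_response(self, design):
        tr = num_track(design)
        m = TuningModel(0.5, 0.4)
        base = predict_bold(m, tr, HRFModel(), design)
        # doubling the neural input doubles the convolution output
        from numpref.prf import convolve_design

        neural = neural_prediction(m, tr)
        doubled = convolve_design(2 * neural, hrf_kernel(HRFModel(), 2.0))
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-12)


class TestFitGrid:
    def test_exact_candidate_recovered(self):
        design = build_default_design(cycles=5)
        tr = num_track(design)
        grid = GridSpec.from_tracks(tr)
        truth = TuningModel(float(grid.preferred[13]), float(grid.widths[7]))
        observed = 2.5 * predict_bold(truth, tr, HRFModel(), design) + 1.0
        fit = fit_grid(observed, tr, design, grid=grid)
        assert fit.tuning.preferred == truth.preferred
        assert fit.tuning.width == truth.width
        assert fit.amplitude == pytest.approx(2.5)
        assert fit.baseline == pytest.approx(1.0)
        assert fit.r2 > 1 - 1e-9

    def test_pure_noise_explains_little(self):
        design = build_default_design(cycles=20)  # 200 time points
        tr = num_track(design)
        grid = GridSpec.from_tracks(tr)
        rng = np.random.default_rng(0)
        for _ in range(5):
            fit = fit_grid(rng.standard_normal(design.n_samples), tr, design, grid=grid)
            assert fit.r2 <= 0.2

    def test_constant_track_explains_nothing(self):
        design = build_default_design(cycles=3)
        tr = FeatureTimecourse("total_item_area", "constant_area",
                               np.full(design.n_samples, 0.064), "linear")
        observed = np.sin(np.arange(design.n_samples))
        fit = fit_grid(observed, tr, design)
        assert fit.r2 == 0.0
        assert fit.amplitude == 0.0

    def test_tie_break_prefers_smallest_width_then_preferred(self):
        design = build_default_design(cycles=2)
        tr = FeatureTimecourse("f", "c", np.full(design.n_samples, 2.0), "linear")
        grid = GridSpec(preferred=np.array([1.0, 2.0]), widths=np.array([0.1, 0.2]))
        fit = fit_grid(np.sin(np.arange(design.n_samples)), tr, design, grid=grid)
        # every candidate scores 0: the first in (width, preferred) order wins
        assert fit.tuning.width == 0.1
        assert fit.tuning.preferred == 1.0

    def test_zero_variance_observed_rejected(self, design):
        with pytest.raises(ValueError):
            fit_grid(np.ones(design.n_samples), num_track(design), design)

    def test_grid_refinement_never_decreases_r2(self):
        design = build_default_design(cycles=5)
        tr = num_track(design)
        rng = np.random.default_rng(3)
        observed = predict_bold(TuningModel(0.47, 0.33), tr, HRFModel(), design)
        observed = observed + 0.3 * rng.standard_normal(len(observed))
        coarse = GridSpec(np.linspace(0, 1.3, 10), np.geomspace(0.05, 3, 8))
        dense = GridSpec(
            np.unique(np.concatenate([coarse.preferred, np.linspace(0, 1.3, 40)])),
            np.unique(np.concatenate([coarse.widths, np.geomspace(0.05, 3, 30)])),
        )
        r2_coarse = fit_grid(observed, tr, design, grid=coarse).r2
        r2_dense = fit_grid(observed, tr, design, grid=dense).r2
        assert r2_dense >= r2_coarse - 1e-12


class TestFitConstrained:
    def _data(self, seed=0, flip=False):
        design = build_default_design(cycles=5)
        rng = np.random.default_rng(seed)
        tracks, observed = {}, {}
        for i, c in enumerate(("a", "b", "c")):
            vals = design.numerosities().astype(float)
            if flip and c == "c":
                vals = 21.0 - vals  # feature anti-correlated with numerosity here
            tracks[c] = FeatureTimecourse("f", c, vals, "log10")
            truth = TuningModel(0.6, 0.4)
            sig = predict_bold(truth, tracks["a" if not flip else c], HRFModel(), design)
            observed[c] = sig + 0.2 * rng.standard_normal(len(sig))
        return design, tracks, observed

    def test_identical_tracks_and_data_match_specific_fit(self):
        design, tracks, observed = self._data()
        same = observed["a"]
        observed = {c: same for c in tracks}
        grid = GridSpec.from_tracks(list(tracks.values()))
        cfit = fit_constrained(observed, tracks, design, grid=grid)
        specific = fit_grid(same, tracks["a"], design, grid=grid)
        assert cfit.tuning == specific.tuning
        for c in tracks:
            assert cfit.per_configuration[c][2] == pytest.approx(specific.r2, abs=1e-12)

    def test_constrained_bounded_by_specific(self):
        design, tracks, observed = self._data(seed=5, flip=True)
        grid = GridSpec.from_tracks(list(tracks.values()))
        cfit = fit_constrained(observed, tracks, design, grid=grid)
        for c in tracks:
            specific = fit_grid(observed[c], tracks[c], design, grid=grid)
            assert cfit.per_configuration[c][2] <= specific.r2 + 1e-10

    def test_sign_conflict_collapses_one_configuration(self):
        """Total item area rises with numerosity when item size is fixed but
        falls when total perimeter is fixed; a shared-parameter fit to
        numerosity-tuned responses must collapse in one of the regimes."""
        from numpref import default_configurations, predict_bold
        from numpref.features import analytic_timecourses

        design = build_default_design(cycles=5)
        cfgs = default_configurations()
        tracks = {
            c: analytic_timecourses(design, cfgs[c])["total_item_area"]
            for c in ("constant_item_size", "constant_perimeter")
        }
        rng = np.random.default_rng(1)
        sig = predict_bold(TuningModel(0.6, 0.3), num_track(design), HRFModel(), design)
        observed = {c: sig + 0.1 * rng.standard_normal(len(sig)) for c in tracks}
        grid = GridSpec.from_tracks(list(tracks.values()))
        cfit = fit_constrained(observed, tracks, design, grid=grid)
        collapse = []
        for c in tracks:
            specific = fit_grid(observed[c], tracks[c], design, grid=grid)
            assert specific.r2 > 0.8  # each regime alone is well predicted
            collapse.append(specific.r2 - cfit.per_configuration[c][2])
        assert max(collapse) > 0.5

    def test_needs_two_configurations(self, design):
        tr = num_track(design)
        with pytest.raises(ValueError):
            fit_constrained({"a": np.sin(np.arange(design.n_samples))}, {"a": tr}, design)
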