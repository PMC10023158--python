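"""Subtraction-algorithm tests: bootstrap deltas, instantaneous
integration, the sigmoid nonlinearity, and permutation consistency."""

import numpy as np
import pytest

from okretina.prediction import (
    ResponseDistributions, bootstrap_delta, fit_sigmoid,
    instantaneous_prediction, permutation_consistency,
    predict_bar_conditions, sigmoid,
)
from okretina.synthetic import SyntheticPopulationParams, make_population
from okretina.tuning import preferred_direction


def paper_structured_distributions(seed=0):
    """PD/ND response distributions from the default synthetic population."""
    cells = make_population(SyntheticPopulationParams(seed=seed))
    data = {}
    for cell in cells:
        resp = cell.response
        try:
            pd_deg = preferred_direction(resp)
        except ValueError:
            continue
        dirs = resp.directions
        pd_idx = int(np.argmin(np.abs((dirs - pd_deg + 180) % 360 - 180)))
        nd_idx = (pd_idx + 4) % 8
        for align, idx in (("PD", pd_idx), ("ND", nd_idx)):
            key = (cell.cell_type, align, cell.contrast)
            data.setdefault(key, []).append(resp.mean_response[idx])
    return ResponseDistributions({k: np.asarray(v) for k, v in data.items()})


class TestBootstrapDelta:
    def test_identical_arrays_delta_zero(self, rng):
        x = rng.gamma(3.0, 2.0, 40)
        res = bootstrap_delta(x, x.copy(), n_boot=2000, seed=0)
        # identical source arrays: delta is centered on 0 (within resampling
        # noise of the median) and the CI must straddle 0
        assert abs(res.delta_median) < 0.2 * x.std()
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_constant_arrays_exact_delta(self):
        res = bootstrap_delta(np.full(20, 10.0), np.full(20, 2.0),
                              n_boot=200, seed=0)
        assert res.delta_median == 8.0
        assert res.ci_low == res.ci_high == 8.0

    def test_seeded_reproducibility(self, rng):
        a = rng.poisson(12, 30).astype(float)
        b = rng.poisson(5, 30).astype(float)
        r1 = bootstrap_delta(a, b, n_boot=1000, seed=42)
        r2 = bootstrap_delta(a, b, n_boot=1000, seed=42)
        assert (r1.delta_median, r1.ci_low, r1.ci_high) == \
            (r2.delta_median, r2.ci_low, r2.ci_high)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bootstrap_delta(np.ones(3), np.ones(3), n_boot=0)
        with pytest.raises(ValueError):
            bootstrap_delta(np.array([]), np.ones(3))


class TestBarPredictions:
    def test_paper_structure_gives_all_orderings(self):
        dists = paper_structured_distributions(seed=2)
        res = predict_bar_conditions(dists, n_boot=1000, seed=0)
        assert all(res["orderings"].values())

    def test_identical_pairs_no_orderings(self, rng):
        x = rng.gamma(4.0, 3.0, 50)
        data = {(ct, al, co): x.copy()
                for ct in ("Superior", "Inferior")
                for al in ("PD", "ND") for co in ("high", "low")}
        res = predict_bar_conditions(ResponseDistributions(data),
                                     n_boot=500, seed=1)
        assert not any(res["orderings"].values())

    def test_equal_contrast_scales_break_contrast_orderings(self):
        """Degenerate control: both 'contrasts' identical → orderings that
        depend on a contrast difference fail."""
        p = SyntheticPopulationParams(
            contrast_scales={"high": 1.0, "low": 1.0},
            low_contrast_sharpening=1.0, seed=4)
        cells = make_population(p)
        data = {}
        for cell in cells:
            resp = cell.response
            pd_deg = preferred_direction(resp)
            dirs = resp.directions
            pd_idx = int(np.argmin(np.abs(
                (dirs - pd_deg + 180) % 360 - 180)))
            for align, idx in (("PD", pd_idx), ("ND", (pd_idx + 4) % 8)):
                data.setdefault((cell.cell_type, align, cell.contrast),
                                []).append(resp.mean_response[idx])
        dists = ResponseDistributions(
            {k: np.asarray(v) for k, v in data.items()})
        res = predict_bar_conditions(dists, n_boot=500, seed=0)
        d = {k: v.delta_median for k, v in res["deltas"].items()}
        # high and low now only differ by trial-noise resampling
        assert abs(d[("superior", "high")] - d[("superior", "low")]) < \
            0.5 * abs(d[("superior", "high")])

    def test_missing_distribution_errors(self):
        with pytest.raises(KeyError):
            predict_bar_conditions(ResponseDistributions(
                {("Superior", "PD", "high"): np.ones(5)}), n_boot=10)


class TestInstantaneous:
    def test_equal_rates_flat_position(self):
        t = np.arange(0, 15, 0.005)
        r = np.abs(np.sin(t))
        pred = instantaneous_prediction(t, r, r.copy())
        assert np.all(pred.predicted_position == 0)

    def test_constant_delta_ramps_linearly(self):
        t = np.arange(0, 15.005, 0.005)
        pred = instantaneous_prediction(t, np.full(t.size, 3.0),
                                        np.full(t.size, 2.0))
        assert pred.predicted_position[0] == 0.0
        assert pred.predicted_position[-1] == pytest.approx(15.0)

    def test_sinusoidal_delta_closes_cycle(self):
        t = np.arange(0, 15.005, 0.005)
        sup = 5.0 + 2.0 * np.sin(2 * np.pi * t / 15.0)
        pred = instantaneous_prediction(t, sup, np.full(t.size, 5.0))
        assert abs(pred.predicted_position[-1]) < 1e-9

    def test_linearity_in_scale(self, rng):
        t = np.arange(0, 5, 0.005)
        sup = rng.random(t.size) * 10
        inf = rng.random(t.size) * 10
        p1 = instantaneous_prediction(t, sup, inf)
        p3 = instantaneous_prediction(t, 3 * sup, 3 * inf)
        assert np.allclose(p3.predicted_position,
                           3 * p1.predicted_position)

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError):
            instantaneous_prediction(np.arange(5.0), np.ones(5), np.ones(4))


class TestSigmoid:
    PAPER_BAR_FIT = dict(vmin=-1.69, vmax=1.82, r50=4.93, m=0.022)

    def test_midpoint_at_r50(self):
        p = self.PAPER_BAR_FIT
        assert sigmoid(p["r50"], **p) == pytest.approx(
            (p["vmin"] + p["vmax"]) / 2)
        assert sigmoid(4.93, **p) == pytest.approx(0.065)

    def test_noiseless_exact_recovery(self):
        r = np.linspace(-30, 40, 25)
        v = sigmoid(r, **self.PAPER_BAR_FIT)
        fit = fit_sigmoid(r, v)
        assert fit.sse < 1e-8
        assert fit.r50 == pytest.approx(4.93, abs=1e-4)
        assert fit.m == pytest.approx(0.022, abs=1e-5)

    def test_monotone_increasing(self):
        p = self.PAPER_BAR_FIT
        r = np.linspace(-100, 100, 500)
        assert np.all(np.diff(sigmoid(r, **p)) > 0)

    def test_noisy_r50_recovery(self):
        """r50 recovered within 10% (of the probe range) under 10% noise."""
        truth = dict(vmin=-2.0, vmax=2.0, r50=5.0, m=0.05)
        r = np.linspace(-30, 40, 40)
        span = r.max() - r.min()
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = sigmoid(r, **truth) + rng.normal(
                0, 0.1 * (truth["vmax"] - truth["vmin"]), r.size)
            fit = fit_sigmoid(r, v)
            errs.append(abs(fit.r50 - truth["r50"]))
        assert np.median(errs) < 0.1 * span

    def test_origin_point_added(self):
        r = np.array([-8.0, -3.0, 6.0, 12.0])
        v = np.array([-1.0, -0.4, 0.9, 1.5])
        fit = fit_sigmoid(r, v, add_origin=True)
        assert np.isfinite(fit.sse)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_sigmoid(np.ones(3), np.ones(3))


class TestPermutations:
    def test_space_size_is_256(self):
        dists = paper_structured_distributions(seed=1)
        res = permutation_consistency(dists)
        assert res["n_total"] == 256

    def test_true_assignment_counted(self):
        dists = paper_structured_distributions(seed=1)
        res = permutation_consistency(dists)
        assert 1 <= res["n_consistent"] < res["n_total"]
        assert res["fraction"] == res["n_consistent"] / 256

    def test_trivial_predicates(self):
        dists = paper_structured_distributions(seed=1)
        assert permutation_consistency(
            dists, predicate=lambda d: True)["n_consistent"] == 256
        assert permutation_consistency(
            dists, predicate=lambda d: False)["n_consistent"] == 0
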