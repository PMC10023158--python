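"""Parallel-conductance model tests: Ohm's-law conversion, an independent
step-by-step Euler oracle, spiking/subthreshold consistency, threshold
calibration, and spike isolation on ground-truth fixtures."""

import numpy as np
import pytest

from okretina.conductance import (
    ConductanceSet, build_untuned_excitation, calibrate_threshold,
    current_to_conductance, isolate_subthreshold, proxy_spike_count,
    simulate, sweep_gain, vm_tuning_curve,
)
from okretina.synthetic import make_conductance_set


def naive_integrator(cset, idx, gain_ex=1.0, gain_in=1.0, spiking=True):
    """Independently coded reference: literal sample-by-sample Euler with
    threshold/pause/reset semantics."""
    g_in = cset.g_in[idx] * gain_in
    g_ex = cset.g_ex * gain_ex
    n_refr = int(round(cset.t_refr / cset.dt))
    vm = [cset.E_rest]
    spikes = 0
    k = 1
    n = len(g_ex)
    while k < n:
        v = vm[-1]
        dv = (cset.dt * 1e3 / cset.C) * (
            g_ex[k - 1] * (cset.E_ex - v) + g_in[k - 1] * (cset.E_in - v)
            + cset.G_rest * (cset.E_rest - v))
        v_new = v + dv
        if spiking and v_new >= cset.V_thresh:
            spikes += 1
            for _ in range(min(n_refr, n - k)):
                vm.append(cset.V_thresh)
            k += n_refr
            if k < n:
                vm.append(cset.E_rest)
                k += 1
        else:
            vm.append(v_new)
            k += 1
    return np.array(vm[:n]), spikes


class TestOhmsLaw:
    def test_zero_current_zero_conductance(self):
        g, n = current_to_conductance(np.zeros(10), -60.0, 0.0)
        assert np.all(g == 0) and n == 0

    def test_arithmetic(self):
        g, _ = current_to_conductance(np.array([-600.0]), -60.0, 0.0)
        assert g[0] == pytest.approx(10.0)

    def test_junction_cancels(self):
        i = np.array([120.0, -40.0, 500.0])
        g0, _ = current_to_conductance(i, 10.0, -70.0, junction_mV=0.0)
        g5, _ = current_to_conductance(i, 10.0, -70.0, junction_mV=5.0)
        assert np.allclose(g0, g5)

    def test_negative_values_floored_and_counted(self):
        g, n = current_to_conductance(np.array([100.0, -50.0]), 10.0, -70.0)
        assert n == 1 and g[1] == 0.0

    def test_equal_potentials_error(self):
        with pytest.raises(ZeroDivisionError):
            current_to_conductance(np.ones(3), -70.0, -70.0)


class TestUntunedExcitation:
    def test_identical_series_passthrough(self, rng):
        s = rng.random(50)
        assert np.allclose(build_untuned_excitation(np.tile(s, (8, 1))), s)

    def test_pointwise_max(self, rng):
        g = rng.random((8, 100))
        out = build_untuned_excitation(g)
        assert np.all(out >= g - 1e-15)
        assert np.allclose(out, g.max(axis=0))


class TestSimulate:
    def test_no_input_stays_at_rest(self):
        cset = ConductanceSet(dt=1e-3, g_in=np.zeros((8, 100)),
                              g_ex=np.zeros(100))
        tr = simulate(cset, 0.0, spiking=True)
        assert np.all(tr.vm == cset.E_rest) and tr.n_spikes == 0

    def test_constant_excitation_steady_state(self):
        g = 2.0
        cset = ConductanceSet(dt=1e-3, g_in=np.zeros((8, 3000)),
                              g_ex=np.full(3000, g))
        tr = simulate(cset, 0.0, spiking=False)
        expect = (g * cset.E_ex + cset.G_rest * cset.E_rest) / (
            g + cset.G_rest)
        assert tr.vm[-1] == pytest.approx(expect, abs=1e-6)

    def test_subthreshold_equals_spiking_below_threshold(self, default_cset):
        from dataclasses import replace
        high = replace(default_cset, V_thresh=0.0)
        for d in (0.0, 270.0):
            spk = simulate(high, d, spiking=True)
            sub = simulate(high, d, spiking=False)
            assert np.allclose(spk.vm, sub.vm)
            assert spk.n_spikes == 0

    def test_matches_naive_integrator(self, default_cset):
        for idx, d in enumerate(default_cset.directions):
            for spiking in (False, True):
                tr = simulate(default_cset, d, spiking=spiking)
                vm_ref, n_ref = naive_integrator(default_cset, idx,
                                                 spiking=spiking)
                assert np.abs(tr.vm - vm_ref).max() < 1e-9
                if spiking:
                    assert tr.n_spikes == n_ref

    def test_inhibition_only_never_depolarizes(self, rng):
        g_in = np.tile(rng.random(500) * 5.0, (8, 1))
        cset = ConductanceSet(dt=1e-3, g_in=g_in, g_ex=np.zeros(500),
                              E_in=-80.0)
        tr = simulate(cset, 0.0, spiking=False)
        assert np.all(tr.vm <= cset.E_rest + 1e-12)

    def test_halving_dt_changes_counts_by_at_most_one(self):
        c1 = make_conductance_set("Superior", dt=1e-3, seed=0)
        c2 = make_conductance_set("Superior", dt=0.5e-3, seed=0)
        for d in c1.directions:
            n1 = simulate(c1, d, spiking=True).n_spikes
            n2 = simulate(c2, d, spiking=True).n_spikes
            assert abs(n1 - n2) <= 1

    def test_depolarizing_injection_broadens_spike_tuning(self, default_cset):
        """Constant depolarizing current widens and de-sharpens spike tuning
        relative to hyperpolarizing current (current-injection analog)."""
        from okretina.tuning import (DirectionalResponse, DIRECTIONS_8,
                                     direction_selectivity_index,
                                     normalized_area)
        # current sized to shift resting vm by ±6 mV: ΔV = I / G_rest
        i_inj = 6.0 * default_cset.G_rest
        curves = {}
        for name, inj in (("depol", i_inj), ("hyper", -i_inj)):
            counts = [simulate(default_cset, d, i_inj_pA=inj,
                               spiking=True).n_spikes
                      for d in default_cset.directions]
            curves[name] = DirectionalResponse(DIRECTIONS_8,
                                               np.array(counts, float))
        assert normalized_area(curves["depol"]) > \
            normalized_area(curves["hyper"])
        assert direction_selectivity_index(curves["depol"]) < \
            direction_selectivity_index(curves["hyper"])


class TestProxy:
    def test_below_threshold_zero(self):
        tr = simulate(ConductanceSet(dt=1e-3, g_in=np.zeros((8, 10)),
                                     g_ex=np.zeros(10)), 0.0, spiking=False)
        assert proxy_spike_count(tr, -40.0) == 0.0

    def test_counts_samples_above(self, default_cset):
        tr = simulate(default_cset, 270.0, spiking=False)
        k = int(np.count_nonzero(tr.vm > -50.0))
        assert proxy_spike_count(tr, -50.0) == pytest.approx(k * 1e-3)

    def test_monotone_in_threshold(self, default_cset):
        tr = simulate(default_cset, 270.0, spiking=False)
        vals = [proxy_spike_count(tr, v) for v in (-52.0, -48.0, -44.0)]
        assert vals[0] >= vals[1] >= vals[2]


class TestSweep:
    def test_zero_gain_conventions(self, default_cset):
        df = sweep_gain(default_cset, [0.0], mode="excitation-only")
        row = df.iloc[0]
        assert row.pd_spikes == 0 and row.nd_spikes == 0
        assert row.dsi_spk == 1.0 and row.norm_area_spk == 0.0

    def test_area_nondecreasing_in_gain(self, default_cset):
        df = sweep_gain(default_cset, np.arange(0.0, 2.01, 0.25),
                        mode="excitation-only")
        assert np.all(np.diff(df.area_spk) >= 0)

    def test_empty_gain_list_errors(self, default_cset):
        with pytest.raises(ValueError):
            sweep_gain(default_cset, [])


class TestCalibration:
    def test_self_consistency_recovery(self, default_cset):
        from okretina.conductance import _spike_metrics_at_threshold
        known = -47.3
        dsi, na = _spike_metrics_at_threshold(default_cset, known, 1.0)
        recovered, boundary = calibrate_threshold(default_cset, dsi, na)
        assert abs(recovered - known) <= 0.1
        assert not boundary

    def test_extreme_targets_silence_null(self, default_cset):
        v, _ = calibrate_threshold(default_cset, target_dsi=1.0,
                                   target_norm_area=0.0)
        nd_peak = simulate(default_cset, 90.0, spiking=False).vm.max()
        assert v > nd_peak


class TestIsolation:
    @staticmethod
    def _with_spikes(times_s, dt=1e-4, dur=1.0, base=-55.0):
        t = np.arange(0.0, dur, dt)
        vm = base + 3.0 * np.sin(2 * np.pi * 1.0 * t)  # slow smooth drift
        wave = np.concatenate([np.linspace(0, 45, 8),
                               np.linspace(45, -5, 12),
                               np.linspace(-5, 0, 10)])
        for ts in times_s:
            i = int(round(ts / dt))
            vm[i:i + wave.size] += wave[:min(wave.size, vm.size - i)]
        return t, vm

    def test_clean_trace_untouched(self):
        t = np.arange(0.0, 0.5, 1e-4)
        vm = -55.0 + 2.0 * np.sin(2 * np.pi * t)
        spikes, clean = isolate_subthreshold(vm, 1e-4)
        assert spikes.size == 0
        assert np.array_equal(clean, vm)

    def test_recovers_inserted_spikes(self):
        times = [0.11, 0.34, 0.72]
        t, vm = self._with_spikes(times)
        spikes, clean = isolate_subthreshold(vm, 1e-4)
        assert spikes.size == 3
        # spike time = waveform peak, 7 samples after insertion onset
        assert np.allclose(spikes, np.asarray(times) + 7e-4, atol=2e-4)
        smooth = -55.0 + 3.0 * np.sin(2 * np.pi * 1.0 * t)
        assert np.abs(clean - smooth).max() < 2.0

    def test_merges_within_refractory(self):
        t, vm = self._with_spikes([0.300, 0.302])
        spikes, _ = isolate_subthreshold(vm, 1e-4, min_refractory=0.005)
        assert spikes.size == 1

    def test_nan_rejected(self):
        vm = np.full(100, -55.0)
        vm[3] = np.nan
        with pytest.raises(ValueError):
            isolate_subthreshold(vm, 1e-4)


class TestVmTuning:
    def test_flat_traces_zero_curve(self):
        traces = np.full((8, 100), -55.0)
        curve = vm_tuning_curve(traces, baseline=-55.0)
        assert np.all(curve.mean_response == 0)

    def test_offset_invariance(self, rng):
        traces = -55.0 + rng.random((8, 200)) * 5.0
        c0 = vm_tuning_curve(traces, baseline=-55.0)
        c1 = vm_tuning_curve(traces + 7.0, baseline=-48.0)
        assert np.allclose(c0.mean_response, c1.mean_response)

    def test_matches_subthreshold_simulation(self, default_cset):
        traces = np.stack([simulate(default_cset, d, spiking=False).vm
                           for d in default_cset.directions])
        curve = vm_tuning_curve(traces, baseline=default_cset.E_rest)
        for i, d in enumerate(default_cset.directions):
            peak = simulate(default_cset, d, spiking=False).vm.max()
            assert curve.mean_response[i] == pytest.approx(
                max(peak - default_cset.E_rest, 0.0))

    def test_repeats_averaged(self, rng):
        reps = -55.0 + rng.random((8, 5, 50)) * 3.0
        curve = vm_tuning_curve(reps, baseline=-55.0)
        manual = (reps.max(axis=2) + 55.0).mean(axis=1)
        assert np.allclose(curve.mean_response, manual)
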