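"""Feature extractors against closed forms, constructions and the simulator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fusiform.ephys.calibrate import measured_tail
from fusiform.ephys.features import (BoltzmannModel, FeatureError,
                                     average_spike, detect_spikes,
                                     firing_rate, fit_boltzmann,
                                     input_resistance, ramp_to_gv,
                                     resting_potential, sag_ratio,
                                     spike_parameters, subtract_traces,
                                     tail_current_amplitude,
                                     zd_sensitive_sag)
from fusiform.ephys.model import (CellParams, DrugState, Protocol, Segment,
                                  Trace, protocol_library, simulate)


def flat_trace(values, command=None, dt=0.025, mode="current_clamp"):
    v = np.asarray(values, dtype=float)
    cmd = np.zeros_like(v) if command is None else np.asarray(command, float)
    return Trace(time_ms=np.arange(v.size) * dt, signal=v, command=cmd,
                 mode=mode, dt_ms=dt)


def boltzmann(v, g_max, v_half, k):
    return g_max / (1.0 + np.exp(-(v - v_half) / k))


class TestSubtraction:
    def test_identical_traces_cancel(self):
        a = flat_trace(np.linspace(0, 5, 100))
        assert np.allclose(subtract_traces(a, a).signal, 0.0)

    def test_constant_offset_recovered(self):
        a = flat_trace(np.linspace(0, 5, 100))
        b = flat_trace(np.linspace(0, 5, 100) - 3.0)
        assert np.allclose(subtract_traces(a, b).signal, 3.0)

    def test_mismatched_protocols_rejected(self):
        a = flat_trace(np.zeros(50))
        b = flat_trace(np.zeros(50), command=np.ones(50))
        with pytest.raises(FeatureError):
            subtract_traces(a, b)

    def test_xe991_subtraction_isolates_kcnq(self, presets, protocols):
        cell = presets["control"]
        pre = simulate(cell, protocols["kcnq_deactivation"])
        post = simulate(cell, protocols["kcnq_deactivation"],
                        DrugState(xe991=True))
        diff = subtract_traces(pre, post)
        kcnq = pre.channel_currents["kcnq"]
        scale = np.abs(kcnq).max()
        assert np.abs(diff.signal - kcnq).max() < 0.01 * scale


class TestTailCurrent:
    def test_zero_trace_has_zero_tail(self, protocols):
        cmd = protocols["kcnq_deactivation"].command()
        tr = flat_trace(np.zeros_like(cmd), command=cmd, mode="voltage_clamp")
        assert tail_current_amplitude(tr) == 0.0

    def test_tail_calibrated_preset_hits_published_amplitude(self, presets):
        assert measured_tail(presets["control_tail"]) == pytest.approx(
            73.8, rel=0.01)

    def test_noise_exposed_tail_smaller_than_sham(self, presets):
        assert measured_tail(presets["noise_4d"]) < measured_tail(
            presets["control"])


class TestRampGV:
    def test_ohms_law_conversion(self):
        # constant 100 pA along the ramp: G at V = -35.5 is 100/50 = 2 nS
        cmd = np.concatenate([np.full(400, -80.0),
                              np.linspace(-80, 0, 3201)])
        tr = flat_trace(np.full_like(cmd, 100.0), command=cmd,
                        mode="voltage_clamp")
        gv = ramp_to_gv(tr)
        nearest = gv.iloc[(gv["v_mv"] + 35.5).abs().argmin()]
        assert nearest["g_ns"] == pytest.approx(100.0 / 50.0, rel=1e-3)

    def test_zero_current_gives_zero_conductance(self):
        cmd = np.concatenate([np.full(100, -80.0), np.linspace(-80, 0, 2000)])
        tr = flat_trace(np.zeros_like(cmd), command=cmd, mode="voltage_clamp")
        assert np.allclose(ramp_to_gv(tr)["g_ns"], 0.0)

    def test_guard_excludes_points_near_reversal(self):
        cmd = np.linspace(-100, 0, 5000)
        tr = flat_trace(np.ones_like(cmd), command=cmd, mode="voltage_clamp")
        gv = ramp_to_gv(tr, v_span=(-100.0, 0.0))
        assert (np.abs(gv["v_mv"] + 85.5) >= 5.0).all()
        assert gv.attrs["n_dropped"] > 0

    def test_simulator_ramp_inverts_conductance_model(self, presets, protocols):
        cell = presets["control"]
        pre = simulate(cell, protocols["gv_ramp"])
        post = simulate(cell, protocols["gv_ramp"], DrugState(xe991=True))
        gv = ramp_to_gv(subtract_traces(pre, post), tau_lag_ms=cell.tau)
        expected = cell.g_kcnq * np.asarray(cell.m_inf(gv["v_mv"]))
        rel = np.abs(gv["g_ns"].to_numpy() - expected) / expected
        assert rel.max() < 0.02


class TestBoltzmannFit:
    @pytest.mark.parametrize("params", [(39.1, -28.3, 6.0), (37.7, -20.3, 6.0)])
    def test_noiseless_recovery_to_three_sig_figs(self, params):
        v = np.linspace(-80, 0, 200)
        fit = BoltzmannModel().fit(v, boltzmann(v, *params))
        assert fit.converged_
        assert fit.g_max_ == pytest.approx(params[0], rel=1e-3)
        assert fit.v_half_ == pytest.approx(params[1], abs=0.05)
        assert fit.k_ == pytest.approx(params[2], rel=1e-3)

    def test_flat_curve_flagged_not_fitted(self):
        v = np.linspace(-80, 0, 50)
        fit = fit_boltzmann(pd.DataFrame({"v_mv": v, "g_ns": np.ones_like(v)}))
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(FeatureError):
            BoltzmannModel().fit(np.arange(5), np.arange(5))

    def test_unbiased_recovery_under_noise(self):
        # bias < 5% of each parameter at SNR 20 across replicates
        rng = np.random.default_rng(12)
        truth = (39.1, -28.3, 6.0)
        v = np.linspace(-80, 0, 120)
        clean = boltzmann(v, *truth)
        model = BoltzmannModel(v_half_starts=(-30.0,), k_starts=(6.0,))
        estimates = []
        for _ in range(200):
            noisy = clean + rng.normal(0, clean.max() / 20.0, v.size)
            fit = model.fit(v, noisy)
            if fit.converged_:
                estimates.append((fit.g_max_, fit.v_half_, fit.k_))
        est = np.mean(estimates, axis=0)
        assert len(estimates) >= 190
        assert abs(est[0] - truth[0]) < 0.05 * truth[0]
        assert abs(est[1] - truth[1]) < 0.05 * abs(truth[1])
        assert abs(est[2] - truth[2]) < 0.05 * truth[2]


class TestSag:
    def make_step_trace(self, baseline, peak_defl, ss_defl, offset=0.0):
        dt = 0.5
        n_pre, n_step, n_post = 400, 4000, 400
        v = np.full(n_pre + n_step + n_post, baseline + offset)
        # ramp to the peak, relax, then hold exactly at the steady level so
        # the final-window mean equals ss_defl by construction (dt=0.5 ms,
        # 100 ms window = 200 samples)
        step = np.concatenate([
            np.linspace(0, peak_defl, 50),
            np.linspace(peak_defl, ss_defl, n_step - 250),
            np.full(200, ss_defl)])
        v[n_pre:n_pre + n_step] -= step
        cmd = np.zeros_like(v)
        cmd[n_pre:n_pre + n_step] = -550.0
        return flat_trace(v, command=cmd, dt=dt)

    def test_hand_arithmetic(self):
        tr = self.make_step_trace(-75.0, 20.0, 17.0)
        m = sag_ratio(tr)
        assert m.sag_ratio == pytest.approx(15.0, abs=0.1)

    def test_no_sag_when_peak_equals_steady(self):
        tr = self.make_step_trace(-75.0, 20.0, 20.0)
        assert sag_ratio(tr).sag_ratio == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_vertical_offset(self):
        a = sag_ratio(self.make_step_trace(-75.0, 22.0, 18.0))
        b = sag_ratio(self.make_step_trace(-75.0, 22.0, 18.0, offset=7.0))
        assert a.sag_ratio == pytest.approx(b.sag_ratio)

    def test_depolarizing_step_rejected(self):
        tr = self.make_step_trace(-75.0, -10.0, -10.0)
        with pytest.raises(FeatureError):
            sag_ratio(tr)

    def test_non_tinnitus_preset_zd_sag(self, presets, protocols):
        cell = presets["non_tinnitus_7d"]
        pre = simulate(cell, protocols["sag_step"], DrugState(ttx=True))
        post = simulate(cell, protocols["sag_step"],
                        DrugState(ttx=True, zd7288=True))
        assert zd_sensitive_sag(pre, post) == pytest.approx(8.3, abs=1.0)

    def test_control_sag_measurement_components(self, control_sag_traces):
        pre, _ = control_sag_traces
        m = sag_ratio(pre)
        assert m.v_peak >= m.v_ss > 0
        assert m.baseline_mv == pytest.approx(-75.0, abs=0.5)


@pytest.fixture(scope="module")
def passive_family():
    cell = CellParams(g_kcnq=0.0, g_hcn=0.0, spike_on=False,
                      g_leak=10.0, e_leak=-65.0)
    return [simulate(cell, p) for p in protocol_library()["rin_family"]]


class TestInputResistance:
    def test_passive_cell_reads_inverse_leak(self, passive_family):
        m = input_resistance(passive_family)
        assert m.onset_mohm == pytest.approx(100.0, rel=0.01)
        assert m.steady_state_mohm == pytest.approx(100.0, rel=0.01)

    def test_scale_invariance(self, passive_family):
        m = input_resistance(passive_family)
        doubled = [Trace(time_ms=t.time_ms, signal=(t.signal + 65) * 2 - 65,
                         command=t.command * 2, mode=t.mode, dt_ms=t.dt_ms)
                   for t in passive_family]
        d = input_resistance(doubled, expected_steps=range(-120, 121, 40))
        assert d.onset_mohm == pytest.approx(m.onset_mohm, rel=1e-6)
        assert d.steady_state_mohm == pytest.approx(m.steady_state_mohm,
                                                    rel=1e-6)

    def test_missing_step_reported(self, passive_family):
        with pytest.raises(FeatureError, match="-60"):
            input_resistance(passive_family[1:])

    def test_hcn_lowers_steady_state_resistance(self, presets):
        family = [simulate(presets["control"], p, DrugState(ttx=True))
                  for p in protocol_library()["rin_family"]]
        m = input_resistance(family)
        assert m.steady_state_mohm < m.onset_mohm


class TestRestingPotential:
    def test_leak_only_cell_reads_e_leak(self):
        cell = CellParams(g_kcnq=0.0, g_hcn=0.0, spike_on=False, e_leak=-61.0)
        tr = simulate(cell, protocol_library(gap_free_s=2.0)["gap_free"],
                      DrugState(ttx=True))
        assert resting_potential(tr) == pytest.approx(-61.0, abs=0.01)

    def test_spiking_trace_violates_ttx_precondition(self, control_gap_free):
        with pytest.raises(FeatureError):
            resting_potential(control_gap_free)

    def test_noise_exposed_rmp_hyperpolarized(self, presets):
        gf = protocol_library(gap_free_s=2.0)["gap_free"]
        rmp = {name: resting_potential(
            simulate(presets[name], gf, DrugState(ttx=True)))
            for name in ("control", "noise_4d")}
        assert rmp["noise_4d"] < rmp["control"]

    def test_zd7288_hyperpolarizes_rmp(self, presets):
        gf = protocol_library(gap_free_s=2.0)["gap_free"]
        plain = resting_potential(simulate(presets["control"], gf,
                                           DrugState(ttx=True)))
        zd = resting_potential(simulate(presets["control"], gf,
                                        DrugState(ttx=True, zd7288=True)))
        assert zd < plain


class TestSpikes:
    def test_flat_trace_has_no_spikes(self):
        tr = flat_trace(np.full(40000, -65.0))
        assert firing_rate(tr) == 0.0

    def test_evenly_spaced_synthetic_spikes(self):
        dt = 0.025
        n = int(1000 / dt)
        v = np.full(n, -65.0)
        for k in range(10):
            i = int((50 + 100 * k) / dt)
            v[i:i + 40] = 10.0
        tr = flat_trace(v, dt=dt)
        spikes = detect_spikes(tr)
        assert spikes.size == 10
        assert firing_rate(tr) == pytest.approx(10.0, rel=0.01)

    def test_refractory_merges_double_crossings(self):
        dt = 0.025
        v = np.full(4000, -65.0)
        i = 1000
        v[i:i + 20] = 0.0
        v[i + 25:i + 45] = 0.0          # second crossing 0.625 ms later
        assert detect_spikes(flat_trace(v, dt=dt)).size == 1


def triangular_spike(dt=0.025, v_rest=-65.0, v_peak=5.0, thr_slope_at=-45.0):
    """Constructed spike with a known 10 V/s crossing and symmetric flanks.

    Rise: slow linear ramp (5 V/s) until ``thr_slope_at``, then fast ramp
    (200 V/s) to the peak; mirrored decay to a trough, then recovery.
    """
    slow = np.arange(v_rest, thr_slope_at, 5.0 * dt)
    fast = np.arange(thr_slope_at, v_peak, 200.0 * dt)
    down = np.arange(v_peak, -75.0, -200.0 * dt)
    tail = np.full(400, -75.0)
    lead = np.full(400, v_rest)
    v = np.concatenate([lead, slow, fast, down, tail])
    return flat_trace(v, dt=dt)


class TestSpikeParameters:
    def test_threshold_at_constructed_crossing(self):
        tr = triangular_spike()
        p = spike_parameters(tr.time_ms, tr.signal, smooth_cutoff_hz=1e9)
        assert p.threshold_mv == pytest.approx(-45.0, abs=1.0)

    def test_amplitude_from_peak_and_threshold(self):
        tr = triangular_spike()
        p = spike_parameters(tr.time_ms, tr.signal, smooth_cutoff_hz=1e9)
        assert p.amplitude_mv == pytest.approx(5.0 - p.threshold_mv, abs=0.5)
        assert p.fahp_mv == pytest.approx(p.threshold_mv - (-75.0), abs=0.5)

    def test_half_height_width_matches_construction(self):
        tr = triangular_spike()
        p = spike_parameters(tr.time_ms, tr.signal, smooth_cutoff_hz=1e9)
        half = p.threshold_mv + p.amplitude_mv / 2.0
        # symmetric 200 V/s flanks: width = 2 * (peak - half)/200 ms
        expected = 2.0 * (5.0 - half) / 200.0
        assert p.half_height_width_ms == pytest.approx(expected, abs=0.1)

    def test_average_spike_needs_twenty(self, presets):
        short = simulate(presets["control"],
                         protocol_library(gap_free_s=1.0)["gap_free"])
        with pytest.raises(FeatureError, match="found"):
            average_spike(short, n=20)

    def test_averaged_preset_spike_parameters(self, control_gap_free):
        t, avg = average_spike(control_gap_free, n=20)
        p = spike_parameters(t, avg)
        assert p.amplitude_mv > 20.0
        assert p.half_height_width_ms > 0
        assert p.max_depol_slope_vps > 10.0
        assert p.min_hyperpol_slope_vps < 0.0
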