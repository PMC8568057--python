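"""Surrogate neurons: resting behavior, clamp protocols, bath modulation,
spike detection and short-term-plasticity synapses."""

import numpy as np
import pytest

from neuromodnet.celltypes import default_modulation
from neuromodnet.cellmodel import (
    ClampProtocol,
    ClampSegment,
    TMSynapse,
    build_surrogate,
    deliver_synaptic_event,
    detect_spikes,
    rheobase,
    run_protocol,
)
from neuromodnet.engine import CellGroup, CellTypeSpec
from neuromodnet.modulation import ChannelSpec
from neuromodnet.morphology import Compartment, Morphology


class TestRestingBehavior:
    def test_spn_rests_hyperpolarized(self, dspn_rest_run):
        v_end = dspn_rest_run.soma_v_mv[-1]
        assert -85.0 <= v_end <= -75.0
        assert len(dspn_rest_run.spike_times_ms) == 0

    def test_fs_rests_less_hyperpolarized(self, fs_rest_run):
        v_end = fs_rest_run.soma_v_mv[-1]
        assert -75.0 <= v_end <= -65.0
        assert len(fs_rest_run.spike_times_ms) == 0

    def test_stationary_at_rest(self, dspn_rest_run):
        v = dspn_rest_run.soma_v_mv
        assert np.ptp(v) < 0.5  # no drift without input over 1 s

    def test_ispn_shares_spn_biophysics(self):
        m = build_surrogate("iSPN")
        r = run_protocol(m, ClampProtocol.current_step(100, 200, 0.0), 400.0, dt_ms=0.05)
        assert -85.0 <= r.soma_v_mv[-1] <= -75.0

    def test_unknown_cell_type_names_valid_ones(self):
        with pytest.raises(ValueError, match="dSPN, iSPN, FS"):
            build_surrogate("LTS")


class TestSpiking:
    def test_spn_regular_spiking_with_onset_delay(self, dspn_step_run):
        st = dspn_step_run.spike_times_ms
        assert len(st) >= 3
        isis = np.diff(st)
        assert np.std(isis) / np.mean(isis) < 0.2  # regular
        # the slow A-type current postpones the first spike relative to
        # strong drive
        strong = run_protocol(
            build_surrogate("dSPN"), ClampProtocol.current_step(200, 500, 500.0),
            800.0, dt_ms=0.05,
        )
        assert st[0] - 200.0 > strong.spike_times_ms[0] - 200.0

    def test_fs_outpaces_spn_at_twice_rheobase(self):
        rates = {}
        for ct in ("FS", "dSPN"):
            model = build_surrogate(ct)
            rheo = rheobase(model, hi_pa=1000.0, tol_pa=25.0)
            r = run_protocol(model, ClampProtocol.current_step(100, 500, 2.0 * rheo),
                             700.0, dt_ms=0.05)
            rates[ct] = len(r.spike_times_ms) / 0.5
        assert rates["FS"] > rates["dSPN"]
        assert rates["FS"] > 50.0  # fast-spiking under strong drive

    def test_voltage_bounded_under_strong_drive(self):
        r = run_protocol(build_surrogate("dSPN"),
                         ClampProtocol.current_step(50, 400, 800.0), 500.0, dt_ms=0.05)
        assert r.v_mv.min() > -120.0 and r.v_mv.max() < 80.0

    def test_determinism(self):
        p = ClampProtocol.current_step(100, 300, 250.0)
        r1 = run_protocol(build_surrogate("dSPN"), p, 500.0, dt_ms=0.05)
        r2 = run_protocol(build_surrogate("dSPN"), p, 500.0, dt_ms=0.05)
        np.testing.assert_array_equal(r1.v_mv, r2.v_mv)

    def test_dt_self_convergence(self):
        """Halving dt shifts early spike times by well under half a millisecond
        (phase drift accumulates over long spike trains, so compare the first
        few spikes where the per-spike discretization error is visible)."""
        p = ClampProtocol.current_step(50, 250, 300.0)
        spikes = {}
        for dt in (0.05, 0.025):
            r = run_protocol(build_surrogate("dSPN"), p, 350.0, dt_ms=dt)
            spikes[dt] = r.spike_times_ms
        assert len(spikes[0.05]) == len(spikes[0.025])
        assert np.max(np.abs(spikes[0.05][:5] - spikes[0.025][:5])) < 0.5


class TestPassiveOracle:
    """Single passive compartment against the closed-form RC step response."""

    def _passive_model(self):
        leak = ChannelSpec("leak", gbar=1e-4, e_rev=-70.0)
        morph = Morphology([Compartment("soma", 20.0, 20.0, -1)])
        ct = CellTypeSpec("passive", morph, ((leak, ("soma",)),), (), -70.0)
        return ct, morph

    def test_rc_step_response(self):
        ct, morph = self._passive_model()
        group = CellGroup(ct, 1)
        dt = 0.025
        group.prepare(dt)
        area = morph.areas_cm2[0]
        g_us = 1e-4 * area * 1e6
        c_nf = morph.capacitances_nf[0]
        tau_ms = c_nf / g_us
        i_na = 0.05  # 50 pA
        n = int(round(5 * tau_ms / dt))
        i_inj = np.full((1, 1), i_na)
        vs = np.empty(n)
        for k in range(n):
            group.step((k + 1) * dt, i_inj_na=i_inj)
            vs[k] = group.v[0, 0]
        t = (np.arange(n) + 1) * dt
        expected = -70.0 + (i_na / g_us) * (1.0 - np.exp(-t / tau_ms))
        assert np.max(np.abs(vs - expected)) < 0.05  # mV

    def test_ideal_voltage_clamp_current(self):
        ct, morph = self._passive_model()
        group = CellGroup(ct, 1)
        group.prepare(0.025)
        g_us = 1e-4 * morph.areas_cm2[0] * 1e6
        # hold 20 mV above rest; steady clamp current = g * dV
        for k in range(4000):
            group.step((k + 1) * 0.025, vclamp_cmd_mv=-50.0)
        assert group.v[0, 0] == -50.0
        assert group.last_clamp_current_na[0] == pytest.approx(g_us * 20.0, rel=1e-6)


class TestBathModulation:
    def test_empty_bath_is_control(self):
        p = ClampProtocol.current_step(100, 300, 215.0)
        m = build_surrogate("dSPN")
        m.apply_modulation({"DA": default_modulation("dSPN", "DA")})
        r0 = run_protocol(m, p, 500.0, dt_ms=0.05)
        rb = run_protocol(m, p, 500.0, dt_ms=0.05, bath={})
        np.testing.assert_array_equal(r0.v_mv, rb.v_mv)

    def test_neutral_max_mod_is_control_at_any_level(self):
        p = ClampProtocol.current_step(100, 300, 215.0)
        ctrl = run_protocol(build_surrogate("dSPN"), p, 500.0, dt_ms=0.05)
        m = build_surrogate("dSPN")
        m.apply_modulation({"DA": {"ion_channels": {
            "soma": [{"channel": "kir", "maxMod": 1.0},
                     {"channel": "naf", "maxMod": 1.0}],
            "dendrite": [{"channel": "kir", "maxMod": 1.0}]}}})
        rb = run_protocol(m, p, 500.0, dt_ms=0.05, bath={"DA": 1.0})
        np.testing.assert_array_equal(ctrl.v_mv, rb.v_mv)

    def test_depolarizing_set_adds_spikes(self):
        p = ClampProtocol.current_step(100, 400, 215.0)
        ctrl = run_protocol(build_surrogate("dSPN"), p, 600.0, dt_ms=0.05)
        m = build_surrogate("dSPN")
        m.apply_modulation({"DA": default_modulation("dSPN", "DA")})
        rb = run_protocol(m, p, 600.0, dt_ms=0.05, bath={"DA": 1.0})
        assert len(rb.spike_times_ms) > len(ctrl.spike_times_ms)

    def test_unknown_bath_modulator_lists_registered(self):
        m = build_surrogate("dSPN")
        m.apply_modulation({"DA": default_modulation("dSPN", "DA")})
        with pytest.raises(KeyError, match="DA"):
            run_protocol(m, ClampProtocol.current_step(10, 20, 0.0), 50.0,
                         dt_ms=0.05, bath={"5HT": 1.0})

    def test_bath_level_out_of_range_rejected(self):
        m = build_surrogate("dSPN")
        m.apply_modulation({"DA": default_modulation("dSPN", "DA")})
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            run_protocol(m, ClampProtocol.current_step(10, 20, 0.0), 50.0,
                         dt_ms=0.05, bath={"DA": 1.5})


class TestClampProtocol:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ClampProtocol("current", (ClampSegment(0, 100, 10.0),
                                      ClampSegment(50, 100, 20.0)))

    def test_segment_beyond_duration_rejected(self):
        p = ClampProtocol.current_step(100, 300, 50.0)
        with pytest.raises(ValueError, match="duration"):
            run_protocol(build_surrogate("dSPN"), p, 200.0, dt_ms=0.05)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ClampProtocol("dynamic", (ClampSegment(0, 10, 1.0),))


def _brute_force_spikes(v, dt, threshold=-10.0, dead=1.0):
    """Independent scan applying the identical crossing rule sample by sample."""
    out, t_last = [], -np.inf
    for i in range(1, len(v)):
        if v[i] >= threshold and v[i - 1] < threshold:
            t = (i + 1) * dt
            if t - t_last >= dead:
                out.append(t)
                t_last = t
    return out


class TestDetectSpikes:
    def test_flat_trace(self):
        assert detect_spikes(np.full(1000, -80.0), 0.1).size == 0

    def test_synthetic_peaks(self):
        dt = 0.1
        v = np.full(4000, -80.0)
        for k in range(4):
            v[500 + 800 * k : 510 + 800 * k] = 40.0
        assert detect_spikes(v, dt).size == 4

    def test_matches_brute_force_on_noise(self, rng):
        dt = 0.1
        v = -60.0 + 60.0 * np.sin(np.linspace(0, 40 * np.pi, 5000)) + rng.normal(0, 5, 5000)
        got = detect_spikes(v, dt)
        np.testing.assert_allclose(got, _brute_force_spikes(v, dt))

    def test_dead_time_suppresses_double_counts(self):
        dt = 0.1
        v = np.full(100, -80.0)
        v[10] = 0.0
        v[12] = -20.0  # drops below then re-crosses within 1 ms
        v[14] = 0.0
        assert detect_spikes(v, dt).size == 1


class TestTMSynapse:
    def test_first_event_amplitude(self):
        syn = TMSynapse(g_max_ns=2.0, u=0.4)
        assert deliver_synaptic_event(syn, 10.0) == pytest.approx(2.0 * 0.4)

    def test_paired_pulse_depression_closed_form(self):
        u, tau_rec, delta = 0.5, 200.0, 50.0
        syn = TMSynapse(g_max_ns=1.0, u=u, tau_rec_ms=tau_rec)
        a1 = syn.deliver(0.0)
        a2 = syn.deliver(delta)
        expected_ratio = 1.0 - u * np.exp(-delta / tau_rec)
        assert a2 / a1 == pytest.approx(expected_ratio, rel=1e-12)

    def test_facilitation_increases_second_amplitude(self):
        syn = TMSynapse(g_max_ns=1.0, u=0.1, tau_rec_ms=500.0, tau_fac_ms=300.0)
        a1 = syn.deliver(0.0)
        a2 = syn.deliver(20.0)
        assert a2 > a1

    def test_release_modulation_floor_warns(self, caplog):
        import logging

        syn = TMSynapse(g_max_ns=1.0, u=0.5)
        with caplog.at_level(logging.WARNING, logger="neuromodnet.cellmodel"):
            amp = syn.deliver(0.0, rel_factor=0.0)
        assert amp > 0.0  # clipped to the floor, not zero release probability
        assert any("clipping" in r.message for r in caplog.records)

    def test_amplitude_modulation_scales_peak(self):
        syn = TMSynapse(g_max_ns=1.0, u=0.5)
        assert syn.deliver(0.0, amp_factor=1.2) == pytest.approx(0.6)

    def test_conductance_waveform_peaks_at_event_amplitude(self):
        syn = TMSynapse(g_max_ns=2.0, u=1.0, tau_rise_ms=1.0, tau_decay_ms=10.0)
        peak = syn.deliver(5.0)
        t = np.linspace(0, 60, 6001)
        g = syn.conductance(t)
        assert g.max() == pytest.approx(peak, rel=1e-3)
        assert np.all(g[t <= 5.0] == 0.0)

    def test_event_times_must_increase(self):
        syn = TMSynapse(g_max_ns=1.0, u=0.5)
        syn.deliver(10.0)
        with pytest.raises(ValueError):
            syn.deliver(5.0)
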