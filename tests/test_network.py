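"""Network construction, external inputs, conc integration and both
neuromodulation engines."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromodnet.celltypes import default_modulation
from neuromodnet.network import (
    AdaptiveConfig,
    ConcState,
    ConnectionRule,
    NetworkRecipe,
    PlacedNetwork,
    ReplayConfig,
    build_external_inputs,
    build_network,
    connect_network,
    place_neurons,
    simulate_adaptive,
    simulate_replay,
    update_conc,
)
from neuromodnet.presets import desk_recipe, dspn_only_recipe, striatal_recipe
from neuromodnet.transient import LevelArray


class TestPlacement:
    def test_full_scale_composition_counts(self):
        pn = place_neurons(striatal_recipe(10_000), seed=1)
        assert pn.counts() == {"dSPN": 4950, "iSPN": 4950, "FS": 100}

    def test_empty_network(self):
        rec = NetworkRecipe(side_um=100.0, n_neurons=0, composition={"dSPN": 1.0})
        assert place_neurons(rec, seed=0).n == 0

    @given(n=st.integers(min_value=1, max_value=5000))
    @settings(max_examples=25, deadline=None)
    def test_counts_conserved_for_any_n(self, n):
        pn = place_neurons(striatal_recipe(n), seed=3)
        assert sum(pn.counts().values()) == n
        assert pn.positions_um.shape == (n, 3)

    def test_positions_inside_volume_and_deterministic(self):
        rec = desk_recipe(200, 250.0)
        a = place_neurons(rec, seed=9)
        b = place_neurons(rec, seed=9)
        c = place_neurons(rec, seed=10)
        assert a.positions_um.min() >= 0 and a.positions_um.max() <= 250.0
        np.testing.assert_array_equal(a.positions_um, b.positions_um)
        assert not np.array_equal(a.positions_um, c.positions_um)

    def test_integer_count_composition(self):
        rec = NetworkRecipe(side_um=100.0, n_neurons=7,
                            composition={"dSPN": 4, "iSPN": 3})
        assert place_neurons(rec, seed=0).counts() == {"dSPN": 4, "iSPN": 3}


class TestWiring:
    def _placed(self, n=15):
        rec = NetworkRecipe(side_um=100.0, n_neurons=n, composition={"dSPN": 1.0})
        return place_neurons(rec, seed=4)

    def test_p_zero_gives_no_connections(self):
        net = connect_network(self._placed(),
                              {("dSPN", "dSPN"): ConnectionRule(p=0.0)}, seed=1)
        assert len(net.connections) == 0

    def test_p_one_complete_digraph(self):
        net = connect_network(
            self._placed(5),
            {("dSPN", "dSPN"): ConnectionRule(p=1.0, cutoff_um=1e9)}, seed=1,
        )
        assert len(net.connections) == 20  # 5*4 ordered pairs, no self-connections
        assert np.all(net.connections.pre_gid != net.connections.post_gid)

    def test_count_within_three_sigma_of_binomial(self):
        # 15 neurons, all pairs eligible: n=210, p=0.1 -> mean 21, sd ~4.35
        for seed in range(5):
            net = connect_network(
                self._placed(15),
                {("dSPN", "dSPN"): ConnectionRule(p=0.1, cutoff_um=1e9)}, seed=seed,
            )
            assert abs(len(net.connections) - 21.0) <= 3.0 * np.sqrt(210 * 0.1 * 0.9)

    def test_cutoff_respected(self):
        net = connect_network(self._placed(30),
                              {("dSPN", "dSPN"): ConnectionRule(p=1.0, cutoff_um=30.0)},
                              seed=2)
        c = net.connections
        d = np.linalg.norm(
            net.positions_um[c.pre_gid] - net.positions_um[c.post_gid], axis=1
        )
        assert np.all(d <= 30.0)

    def test_unlisted_pair_gets_no_connections(self):
        rec = NetworkRecipe(side_um=100.0, n_neurons=10,
                            composition={"dSPN": 0.5, "iSPN": 0.5})
        net = connect_network(place_neurons(rec, 1),
                              {("dSPN", "iSPN"): ConnectionRule(p=1.0, cutoff_um=1e9)},
                              seed=1)
        types = np.array(net.types)
        assert set(types[net.connections.pre_gid]) == {"dSPN"}
        assert set(types[net.connections.post_gid]) == {"iSPN"}

    def test_json_round_trip(self, tmp_path):
        net = build_network(desk_recipe(100, 250.0), seed=5)
        p = tmp_path / "net.json"
        net.to_json(p)
        back = PlacedNetwork.from_json(p)
        assert back.counts() == net.counts()
        np.testing.assert_allclose(back.positions_um, net.positions_um)
        np.testing.assert_array_equal(back.connections.pre_gid, net.connections.pre_gid)


class TestExternalInputs:
    def _recipe(self, rate_bg, act=None):
        from neuromodnet.network import InputBlock

        block = dict(target_type="dSPN", n_synapses=1, background_rate_hz=rate_bg,
                     g_max_ns=1.0)
        if act:
            block.update(activation_start_ms=act[0], activation_duration_ms=act[1],
                         activation_rate_hz=act[2])
        return NetworkRecipe(side_um=100.0, n_neurons=1, composition={"dSPN": 1.0},
                             inputs=[InputBlock(**block)])

    def test_zero_rate_gives_no_events(self):
        rec = self._recipe(0.0)
        pn = place_neurons(rec, 0)
        (ext,) = build_external_inputs(rec, pn, 1000.0, 0.1, seed=1)
        assert ext.event_step.size == 0

    def test_poisson_count_oracle(self):
        # 10 Hz for 10 s -> 100 expected, sd 10
        rec = self._recipe(10.0)
        pn = place_neurons(rec, 0)
        for seed in range(5):
            (ext,) = build_external_inputs(rec, pn, 10_000.0, 0.1, seed=seed)
            assert abs(ext.event_step.size - 100) <= 30

    def test_activation_window_elevates_rate(self):
        rec = self._recipe(2.0, act=(1000.0, 500.0, 40.0))
        pn = place_neurons(rec, 0)
        (ext,) = build_external_inputs(rec, pn, 2000.0, 0.1, seed=3)
        t = ext.event_step * 0.1
        inside = np.count_nonzero((t >= 1000.0) & (t < 1500.0)) / 0.5
        outside = np.count_nonzero((t < 1000.0) | (t >= 1500.0)) / 1.5
        assert inside > outside

    def test_input_block_for_absent_type_rejected(self):
        rec = self._recipe(1.0)
        rec2 = NetworkRecipe(side_um=100.0, n_neurons=1, composition={"FS": 1.0},
                             inputs=rec.inputs)
        pn = place_neurons(rec2, 0)
        with pytest.raises(ValueError, match="dSPN"):
            build_external_inputs(rec2, pn, 100.0, 0.1, seed=0)


class TestConcIntegrator:
    def test_silent_input_stays_zero(self):
        st_ = ConcState(n=3, increment=0.1, tau_ms=100.0)
        for _ in range(100):
            update_conc(st_, 0, 1.0)
        assert np.all(st_.conc == 0.0) and np.all(st_.level == 0.0)

    def test_single_spike_peak_and_decay(self):
        st_ = ConcState(n=1, increment=0.2, tau_ms=50.0)
        update_conc(st_, 1, 1.0)
        assert st_.conc[0] == pytest.approx(0.2)
        update_conc(st_, 0, 1.0)
        assert st_.conc[0] == pytest.approx(0.2 * np.exp(-1.0 / 50.0))

    def test_regular_train_steady_state(self):
        # time-averaged conc -> A * f * tau for an unsaturated regular train
        A, tau, f, dt = 0.04, 200.0, 10.0, 0.1
        st_ = ConcState(n=1, increment=A, tau_ms=tau)
        period = 1000.0 / f
        vals = []
        next_spike = period
        for k in range(100_000):
            t = (k + 1) * dt
            c = 0
            while t >= next_spike - 1e-9:
                c += 1
                next_spike += period
            update_conc(st_, c, dt)
            vals.append(st_.conc[0])
        mean_tail = np.mean(vals[len(vals) // 2:])
        assert mean_tail == pytest.approx(A * f * tau / 1000.0, rel=0.02)

    def test_level_maps(self):
        st_ = ConcState(n=1, increment=2.0, tau_ms=100.0)
        update_conc(st_, 1, 1.0)
        assert st_.level[0] == 1.0  # hard min(1, conc)
        sat = ConcState(n=1, increment=2.0, tau_ms=100.0, map="saturating", k=1.0)
        update_conc(sat, 1, 1.0)
        assert sat.level[0] == pytest.approx(2.0 / 3.0)


@pytest.fixture(scope="module")
def small_net():
    return build_network(dspn_only_recipe(20, 150.0, activation=(300.0, 300.0)), seed=7)


class TestReplayEngine:
    DUR, DT = 700.0, 0.05

    def test_all_zero_levels_identical_to_control(self, small_net):
        ctrl = simulate_replay(small_net, None, self.DUR, self.DT, seed=11)
        arr = LevelArray(dt_ms=self.DT, values=np.zeros(int(self.DUR / self.DT)))
        rp = ReplayConfig(
            modulation={"dSPN": {"DA": default_modulation("dSPN", "DA")}},
            levels={"dSPN": {"DA": arr}},
        )
        mod = simulate_replay(small_net, rp, self.DUR, self.DT, seed=11)
        np.testing.assert_array_equal(ctrl.spike_times_ms, mod.spike_times_ms)
        np.testing.assert_array_equal(ctrl.spike_gids, mod.spike_gids)

    def test_neutral_modulation_file_never_changes_output(self, small_net, rng):
        """All-maxMod=1 modulation is spike-identical to control under an
        arbitrary level trajectory."""
        ctrl = simulate_replay(small_net, None, self.DUR, self.DT, seed=11)
        wild = LevelArray(dt_ms=self.DT,
                          values=rng.uniform(0, 1, int(self.DUR / self.DT)))
        neutral = {"ion_channels": {
            "soma": [{"channel": "kir", "maxMod": 1.0},
                     {"channel": "naf", "maxMod": 1.0},
                     {"channel": "kas", "maxMod": 1.0}],
            "dendrite": [{"channel": "kir", "maxMod": 1.0}]},
            "receptors": {"AMPA": {"maxMod": 1.0, "release_mod": 1.0}}}
        rp = ReplayConfig(modulation={"dSPN": {"DA": neutral}},
                          levels={"dSPN": {"DA": wild}})
        mod = simulate_replay(small_net, rp, self.DUR, self.DT, seed=11)
        np.testing.assert_array_equal(ctrl.spike_times_ms, mod.spike_times_ms)
        np.testing.assert_array_equal(ctrl.spike_gids, mod.spike_gids)

    def test_seed_determinism_end_to_end(self):
        rec = dspn_only_recipe(15, 150.0, activation=(300.0, 300.0))
        r1 = simulate_replay(build_network(rec, 3), None, 600.0, 0.05, seed=21)
        r2 = simulate_replay(build_network(rec, 3), None, 600.0, 0.05, seed=21)
        r3 = simulate_replay(build_network(rec, 3), None, 600.0, 0.05, seed=22)
        np.testing.assert_array_equal(r1.spike_times_ms, r2.spike_times_ms)
        assert (r1.spike_times_ms.size != r3.spike_times_ms.size
                or not np.array_equal(r1.spike_times_ms, r3.spike_times_ms))

    def test_replay_for_absent_type_rejected(self, small_net):
        rp = ReplayConfig(modulation={"FS": {"DA": default_modulation("FS", "DA")}})
        with pytest.raises(ValueError, match="FS"):
            simulate_replay(small_net, rp, 100.0, 0.05, seed=1)

    def test_simultaneous_modulators_combine_multiplicatively(self):
        """On an isolated neuron, DA and ACh applied together equal a single
        modulator carrying the product factor (no network terms)."""
        from neuromodnet.cellmodel import ClampProtocol, build_surrogate, run_protocol

        proto = ClampProtocol.current_step(100.0, 400.0, 220.0)
        both = build_surrogate("dSPN")
        both.apply_modulation({
            "DA": {"ion_channels": {"soma": [{"channel": "kir", "maxMod": 0.7}]}},
            "ACh": {"ion_channels": {"soma": [{"channel": "kir", "maxMod": 0.8}]}},
        })
        r_both = run_protocol(both, proto, 600.0, dt_ms=0.05,
                              bath={"DA": 1.0, "ACh": 1.0})
        single = build_surrogate("dSPN")
        single.apply_modulation({
            "DA": {"ion_channels": {"soma": [{"channel": "kir",
                                              "maxMod": 0.7 * 0.8}]}},
        })
        r_single = run_protocol(single, proto, 600.0, dt_ms=0.05, bath={"DA": 1.0})
        assert len(r_both.spike_times_ms) == len(r_single.spike_times_ms)
        np.testing.assert_allclose(r_both.soma_v_mv, r_single.soma_v_mv, atol=1e-6)


class TestAdaptiveEngine:
    DUR, DT = 600.0, 0.05

    def _config(self, **kw):
        base = dict(
            modulator="DA", target_type="dSPN",
            modulation=default_modulation("dSPN", "DA"),
            n_sources=2, rate_hz=5.0, conc_increment=0.05, conc_tau_ms=300.0,
        )
        base.update(kw)
        return AdaptiveConfig(**base)

    def test_zero_sources_identical_to_control(self, small_net):
        ctrl = simulate_replay(small_net, None, self.DUR, self.DT, seed=31)
        ada = simulate_adaptive(small_net, self._config(n_sources=0), self.DUR,
                                self.DT, seed=31)
        np.testing.assert_array_equal(ctrl.spike_times_ms, ada.spike_times_ms)
        np.testing.assert_array_equal(ctrl.spike_gids, ada.spike_gids)

    def test_higher_source_rate_never_lowers_level(self, small_net):
        lo = simulate_adaptive(small_net, self._config(rate_hz=3.0, source_kind="regular"),
                               self.DUR, self.DT, seed=33)
        hi = simulate_adaptive(small_net, self._config(rate_hz=30.0, source_kind="regular"),
                               self.DUR, self.DT, seed=33)
        key = ("dSPN", "DA")
        assert hi.level_traces[key].mean() > lo.level_traces[key].mean()

    def test_adaptive_replay_equivalence(self, small_net):
        """Feeding the recorded level traces back through replay reproduces
        the adaptive run's spikes."""
        ada = simulate_adaptive(small_net, self._config(rate_hz=20.0), self.DUR,
                                self.DT, seed=35)
        rp = ReplayConfig(
            modulation={"dSPN": {"DA": default_modulation("dSPN", "DA")}},
            per_neuron_levels={"dSPN": {"DA": ada.level_traces[("dSPN", "DA")]}},
        )
        rep = simulate_replay(small_net, rp, self.DUR, self.DT, seed=35)
        np.testing.assert_array_equal(ada.spike_gids, rep.spike_gids)
        assert ada.spike_times_ms.size == rep.spike_times_ms.size
        if ada.spike_times_ms.size:
            assert np.max(np.abs(ada.spike_times_ms - rep.spike_times_ms)) <= self.DT

    def test_missing_modulation_schema_rejected(self, small_net):
        with pytest.raises(ValueError, match="modulation"):
            simulate_adaptive(small_net, self._config(modulation=None), 100.0,
                              self.DT, seed=1)


class TestRecipeIO:
    def test_recipe_json_round_trip(self, tmp_path):
        rec = desk_recipe(120, 250.0)
        p = tmp_path / "recipe.json"
        rec.to_json(p)
        back = NetworkRecipe.from_json(p)
        assert back.counts() == rec.counts()
        assert back.connectivity.keys() == rec.connectivity.keys()
        assert len(back.inputs) == len(rec.inputs)

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError):
            NetworkRecipe(side_um=100.0, n_neurons=10,
                          composition={"dSPN": 0.6, "iSPN": 0.6})
        with pytest.raises(ValueError):
            NetworkRecipe(side_um=100.0, n_neurons=10, composition={"ChIN": 1.0})
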