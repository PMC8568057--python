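"""Ready-made recipes and scenario builders for the striatal-like surrogate circuit.

The full-scale composition (49.5 % dSPN, 49.5 % iSPN, 1 % FS -- 4950 + 4950 +
100 at N = 10,000) ships as :func:`striatal_recipe`; the desk-scale default
used throughout the examples and tests is the same composition at N = 400 in a
correspondingly smaller volume.  Connectivity is Bernoulli within a distance
cutoff with GABAergic synapses (SPN collaterals weak, FS perisomatic strong);
external drive is cortical-like Poisson input with an activation window.
"""

from __future__ import annotations


from .celltypes import default_modulation
from .network import ConnectionRule, InputBlock, NetworkRecipe, ReplayConfig
from .transient import TransientEvent, TransientSpec, build_transient

__all__ = [
    "striatal_recipe",
    "desk_recipe",
    "dspn_only_recipe",
    "spn_recipe",
    "da_burst_transient",
    "ach_transient",
    "replay_da_burst",
    "replay_tonic_ach",
    "CORTICAL_ACTIVATION",
]

#: Cortical activation window used by the desk-scale scenarios (ms).
CORTICAL_ACTIVATION = (700.0, 500.0)  # start, duration


def _inputs(types, start_ms, duration_ms, act_rate_hz=12.0, bg_rate_hz=1.0,
            n_synapses=150, g_max_ns=2.0):
    return [
        InputBlock(
            target_type=t,
            n_synapses=n_synapses,
            background_rate_hz=bg_rate_hz,
            activation_start_ms=start_ms,
            activation_duration_ms=duration_ms,
            activation_rate_hz=act_rate_hz,
            g_max_ns=g_max_ns,
        )
        for t in types
    ]


def _connectivity(cutoff_um):
    spn = ConnectionRule(p=0.2, cutoff_um=cutoff_um, g_max_ns=0.5, receptor="GABA",
                         u=0.4, tau_rec_ms=150.0)
    fs = ConnectionRule(p=0.6, cutoff_um=1.5 * cutoff_um, g_max_ns=2.0, receptor="GABA",
                        u=0.3, tau_rec_ms=100.0, compartment=0)
    rules = {}
    for pre in ("dSPN", "iSPN"):
        for post in ("dSPN", "iSPN"):
            rules[(pre, post)] = spn
    for post in ("dSPN", "iSPN"):
        rules[("FS", post)] = fs
    return rules


def striatal_recipe(
    n_neurons: int = 10_000,
    side_um: float = 1000.0,
    activation: tuple[float, float] = CORTICAL_ACTIVATION,
) -> NetworkRecipe:
    """Full-proportion striatal-like recipe: 49.5/49.5/1 % dSPN/iSPN/FS."""
    start, dur = activation
    return NetworkRecipe(
        side_um=side_um,
        n_neurons=n_neurons,
        composition={"dSPN": 0.495, "iSPN": 0.495, "FS": 0.01},
        connectivity=_connectivity(100.0),
        inputs=_inputs(("dSPN", "iSPN", "FS"), start, dur),
    )


def desk_recipe(n_neurons: int = 400, side_um: float = 300.0,
                activation: tuple[float, float] = CORTICAL_ACTIVATION) -> NetworkRecipe:
    """Desk-scale network with the full-scale proportions (default 400 neurons)."""
    return striatal_recipe(n_neurons=n_neurons, side_um=side_um, activation=activation)


def dspn_only_recipe(n_neurons: int = 40, side_um: float = 150.0,
                     activation: tuple[float, float] = CORTICAL_ACTIVATION) -> NetworkRecipe:
    """Small dSPN-only network (adaptive-mode and timing-sweep scenarios)."""
    start, dur = activation
    return NetworkRecipe(
        side_um=side_um,
        n_neurons=n_neurons,
        composition={"dSPN": 1.0},
        connectivity={("dSPN", "dSPN"): _connectivity(100.0)[("dSPN", "dSPN")]},
        inputs=_inputs(("dSPN",), start, dur),
    )


def spn_recipe(n_neurons: int = 60, side_um: float = 200.0,
               activation: tuple[float, float] = CORTICAL_ACTIVATION) -> NetworkRecipe:
    """SPN-only network (cholinergic pause-vs-tonic scenario)."""
    start, dur = activation
    return NetworkRecipe(
        side_um=side_um,
        n_neurons=n_neurons,
        composition={"dSPN": 0.5, "iSPN": 0.5},
        connectivity={k: v for k, v in _connectivity(100.0).items()
                      if "FS" not in k},
        inputs=_inputs(("dSPN", "iSPN"), start, dur),
    )


def da_burst_transient(onset_ms: float = 600.0, amplitude: float = 1.0,
                       tonic: float = 0.0) -> TransientSpec:
    """Phasic dopamine burst preceding/overlapping the cortical activation."""
    return TransientSpec(
        modulator="DA",
        tonic=tonic,
        events=(TransientEvent("burst", onset_ms, amplitude),),
    )


def ach_transient(kind: str | None, onset_ms: float = 600.0,
                  tonic: float = 0.5, amplitude: float = 0.5) -> TransientSpec:
    """Cholinergic transient: tonic 0.5 with a burst or pause deviation of 0.5.

    ``kind`` is ``"burst"``, ``"pause"`` or ``None`` (pure tonic).
    """
    events = () if kind is None else (TransientEvent(kind, onset_ms, amplitude),)
    return TransientSpec(modulator="ACh", tonic=tonic, events=events)


def replay_da_burst(duration_ms: float, dt_ms: float,
                    types=("dSPN", "iSPN", "FS"),
                    onset_ms: float = 600.0) -> ReplayConfig:
    """Replay config applying the default DA modulation with a burst transient."""
    arr = build_transient(da_burst_transient(onset_ms), duration_ms, dt_ms)
    return ReplayConfig(
        modulation={t: {"DA": default_modulation(t, "DA")} for t in types},
        levels={t: {"DA": arr} for t in types},
    )


def replay_tonic_ach(duration_ms: float, dt_ms: float, kind: str | None,
                     types=("dSPN", "iSPN"), onset_ms: float = 850.0) -> ReplayConfig:
    """Replay config for muscarinic modulation: tonic ACh with burst/pause."""
    arr = build_transient(ach_transient(kind, onset_ms), duration_ms, dt_ms)
    return ReplayConfig(
        modulation={t: {"ACh": default_modulation(t, "ACh")} for t in types},
        levels={t: {"ACh": arr} for t in types},
    )
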