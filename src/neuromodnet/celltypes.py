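"""Built-in surrogate neuron models for a striatal-like microcircuit.

Three ball-and-stick cell types stand in for the detailed, morphologically
reconstructed striatal models that full-scale simulations use:

``dSPN`` / ``iSPN``
    striatal-projection-neuron-like surrogates: hyperpolarized rest near
    -80 mV (set by an inward-rectifier potassium current), a slowly
    inactivating A-type current that delays the first spike, and regular
    spiking under suprathreshold current steps.  The two types share
    biophysics; they differ in their dopamine receptor complement (D1-like
    on dSPN -- excitability up; D2-like on iSPN -- excitability down).
``FS``
    fast-spiking-interneuron-like surrogate: rests near -70 mV and sustains
    high firing rates under strong drive, with fast delayed-rectifier
    kinetics; dopamine acts D1-like (depolarizing).

The channel kinetics are the package's own (Boltzmann steady states,
first-order gates); they meet the behavioural contract above but make no
claim to reproduce any published model's f-I curve.  The default modulation
target sets below are likewise surrogates for cell-type-specific receptor
maps: directions (which currents go up or down under DA/ACh) follow the
physiology, magnitudes are chosen to give robust, clearly visible effects.
"""

from __future__ import annotations

import numpy as np

from .engine import CellGroup, CellTypeSpec, ReceptorSpec
from .modulation import ChannelSpec, GateSpec
from .morphology import ball_and_stick

__all__ = [
    "CELL_TYPES",
    "make_cell_type",
    "make_cell_group",
    "default_modulation",
    "DEFAULT_MODULATION",
]

_AMPA = ReceptorSpec("AMPA", e_rev_mv=0.0, tau_rise_ms=0.3, tau_decay_ms=3.0)
_GABA = ReceptorSpec("GABA", e_rev_mv=-72.0, tau_rise_ms=0.5, tau_decay_ms=8.0)

_ALL = frozenset({"DA", "ACh"})


def _spn_channels() -> tuple:
    naf = ChannelSpec(
        "naf", gbar=0.25, e_rev=50.0,
        gates=(
            GateSpec(v_half=-38.0, slope=6.0, tau_base=0.1, exponent=3),
            GateSpec(v_half=-52.0, slope=-6.0, tau_base=0.3,
                     tau_amp=5.0, tau_v_half=-55.0, tau_width=15.0),
        ),
        modulated_by=_ALL,
    )
    kdr = ChannelSpec(
        "kdr", gbar=0.04, e_rev=-90.0,
        gates=(GateSpec(v_half=-25.0, slope=12.0, tau_base=3.0, exponent=2),),
        modulated_by=_ALL,
    )
    # slow-inactivating A-type: fast activation near threshold, slow (~250 ms)
    # inactivation -- postpones and spaces spikes from a hyperpolarized hold
    kas = ChannelSpec(
        "kas", gbar=0.008, e_rev=-90.0,
        gates=(
            GateSpec(v_half=-42.0, slope=8.0, tau_base=0.5, exponent=2),
            GateSpec(v_half=-60.0, slope=-10.0, tau_base=250.0),
        ),
        modulated_by=_ALL,
    )
    # inward rectifier: open at hyperpolarized potentials, sets the -80 mV rest
    kir = ChannelSpec(
        "kir", gbar=3e-4, e_rev=-90.0,
        gates=(GateSpec(v_half=-85.0, slope=-12.0, tau_base=1.0),),
        modulated_by=_ALL,
    )
    leak = ChannelSpec("leak", gbar=1e-4, e_rev=-70.0)
    return (
        (naf, ("soma", "axon")),
        (kdr, ("soma", "axon")),
        (kas, ("soma", "dendrite")),
        (kir, ("soma", "dendrite", "axon")),
        (leak, ("soma", "dendrite", "axon")),
    )


def _fs_channels() -> tuple:
    naf = ChannelSpec(
        "naf", gbar=0.2, e_rev=50.0,
        gates=(
            GateSpec(v_half=-38.0, slope=5.5, tau_base=0.05, exponent=3),
            GateSpec(v_half=-58.0, slope=-6.0, tau_base=0.3,
                     tau_amp=2.0, tau_v_half=-60.0, tau_width=15.0),
        ),
        modulated_by=_ALL,
    )
    kdr = ChannelSpec(
        "kdr", gbar=0.06, e_rev=-90.0,
        gates=(GateSpec(v_half=-27.0, slope=10.0, tau_base=0.8, exponent=2),),
        modulated_by=_ALL,
    )
    kir = ChannelSpec(
        "kir", gbar=1.5e-4, e_rev=-90.0,
        gates=(GateSpec(v_half=-75.0, slope=-16.0, tau_base=1.0),),
        modulated_by=_ALL,
    )
    leak = ChannelSpec("leak", gbar=1e-4, e_rev=-60.0)
    return (
        (naf, ("soma", "axon")),
        (kdr, ("soma", "axon")),
        (kir, ("soma", "dendrite", "axon")),
        (leak, ("soma", "dendrite", "axon")),
    )


def make_cell_type(name: str) -> CellTypeSpec:
    """Build a fresh surrogate cell-type spec for ``dSPN``, ``iSPN`` or ``FS``."""
    if name in ("dSPN", "iSPN"):
        return CellTypeSpec(
            name=name,
            morphology=ball_and_stick(),
            channels=_spn_channels(),
            receptors=(_AMPA, _GABA),
            v_init_mv=-80.0,
        )
    if name == "FS":
        return CellTypeSpec(
            name=name,
            morphology=ball_and_stick(),
            channels=_fs_channels(),
            receptors=(_AMPA, _GABA),
            v_init_mv=-70.0,
        )
    raise ValueError(f"unknown cell type {name!r}; valid types: dSPN, iSPN, FS")


CELL_TYPES = ("dSPN", "iSPN", "FS")

_REST_CACHE: dict[str, dict] = {}


def make_cell_group(name: str, n: int, settled: bool = True) -> CellGroup:
    """Create a batched group of ``n`` surrogate neurons of one type.

    With ``settled`` (default) the group starts from the cached unmodulated
    resting state (computed once per cell type by relaxing 2 s with no input),
    so runs are stationary from t=0.
    """
    ct = make_cell_type(name)
    group = CellGroup(ct, n)
    if settled:
        if name not in _REST_CACHE:
            probe = CellGroup(make_cell_type(name), 1)
            probe.settle(2000.0, dt_ms=0.5)
            _REST_CACHE[name] = probe.state_snapshot()
        snap = _REST_CACHE[name]
        group.load_snapshot(
            {
                "v": np.repeat(snap["v"], n, axis=0),
                "gates": [[np.repeat(x, n, axis=0) for x in ch] for ch in snap["gates"]],
            }
        )
    return group


#: Default modulation parameter sets per cell type, in the modulation-file
#: schema (see :mod:`neuromodnet.modcell`).  Directions: D1-like (dSPN, FS)
#: increases excitability / depolarizes (inward rectifier and A-type down,
#: sodium up); D2-like (iSPN) decreases excitability; muscarinic (SPNs)
#: increases excitability.
DEFAULT_MODULATION: dict[str, dict] = {
    "dSPN": {
        "DA": {
            "ion_channels": {
                "soma": [
                    {"channel": "kir", "maxMod": 0.7},
                    {"channel": "kas", "maxMod": 0.7},
                    {"channel": "naf", "maxMod": 1.25},
                ],
                "dendrite": [{"channel": "kir", "maxMod": 0.7}],
                "axon": [],
            },
            "receptors": {"AMPA": {"maxMod": 1.2, "release_mod": 1.1}},
        },
        "ACh": {
            "ion_channels": {
                "soma": [
                    {"channel": "kir", "maxMod": 0.8},
                    {"channel": "kas", "maxMod": 0.8},
                ],
                "dendrite": [{"channel": "kir", "maxMod": 0.8}],
                "axon": [],
            },
            "receptors": {},
        },
    },
    "iSPN": {
        "DA": {
            "ion_channels": {
                "soma": [
                    {"channel": "kir", "maxMod": 1.3},
                    {"channel": "kas", "maxMod": 1.3},
                    {"channel": "naf", "maxMod": 0.8},
                ],
                "dendrite": [{"channel": "kir", "maxMod": 1.3}],
                "axon": [],
            },
            "receptors": {"AMPA": {"maxMod": 0.9, "release_mod": 0.95}},
        },
        "ACh": {
            "ion_channels": {
                "soma": [
                    {"channel": "kir", "maxMod": 0.8},
                    {"channel": "kas", "maxMod": 0.8},
                ],
                "dendrite": [{"channel": "kir", "maxMod": 0.8}],
                "axon": [],
            },
            "receptors": {},
        },
    },
    "FS": {
        "DA": {
            "ion_channels": {
                "soma": [
                    {"channel": "kir", "maxMod": 0.4},
                    {"channel": "naf", "maxMod": 1.2},
                ],
                "dendrite": [{"channel": "kir", "maxMod": 0.4}],
                "axon": [{"channel": "kir", "maxMod": 0.4}],
            },
            "receptors": {},
        },
    },
}


def default_modulation(cell_type: str, modulator: str) -> dict:
    """The built-in modulation parameter set for one (cell type, modulator)."""
    try:
        return DEFAULT_MODULATION[cell_type][modulator]
    except KeyError:
        raise KeyError(
            f"no default modulation for cell type {cell_type!r} and modulator "
            f"{modulator!r}"
        ) from None
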