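"""Phenomenological neuromodulation formalism and generic gated-channel mechanics.

A neuromodulator (identified by a short key such as ``"DA"`` for dopamine or
``"ACh"`` for acetylcholine) acts on a target quantity -- typically a maximal
conductance, a synaptic amplitude or a release probability -- by multiplication
with a dimensionless factor.  Each (target, modulator) pair carries three
parameters:

``maxMod``
    the modulation degree reached at full activation (``0.6`` means a 40 %
    reduction, ``1.4`` a 40 % increase),
``mod``
    an on/off activation flag (0 inactive, 1 fully active),
``level``
    the instantaneous modulation level in ``[0, 1]``, which may vary every
    time step of a simulation.

The factor applied to the target is linear in ``level``::

    f = 1 + mod * level * (maxMod - 1)

so ``f == maxMod`` at full modulation and ``f == 1`` whenever the modulator is
inactive or its level is zero.  Several modulators acting on the same target
combine multiplicatively (independent fractional effects).

The module also provides the small Hodgkin-Huxley-style kinetics toolbox
(Boltzmann steady states, first-order gate relaxation, ohmic channel currents)
that the surrogate neuron models are built from.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModulationState",
    "GateSpec",
    "ChannelSpec",
    "modulation_factor",
    "combine_factors",
    "gate_steady_state",
    "gate_time_constant",
    "step_gate",
    "channel_current",
]

logger = logging.getLogger(__name__)


def _clip_level(level: float) -> float:
    """Clamp a modulation level to [0, 1], warning (not raising) when outside."""
    if level < 0.0 or level > 1.0:
        logger.warning("modulation level %.4g outside [0, 1]; clipping", level)
        return min(1.0, max(0.0, level))
    return float(level)


@dataclass
class ModulationState:
    """Modulation triplet for one (target, modulator) pair.

    Parameters
    ----------
    max_mod : float
        Modulation degree at full activation; finite and >= 0 (a negative
        effective conductance is impossible by construction).
    mod : int
        Activation flag, 0 (inactive) or 1 (active).
    level : float
        Instantaneous level in [0, 1]; values outside are clipped with a
        logged warning.
    """

    max_mod: float = 1.0
    mod: int = 1
    level: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.max_mod) or self.max_mod < 0.0:
            raise ValueError(f"maxMod must be finite and >= 0, got {self.max_mod}")
        if self.mod not in (0, 1):
            raise ValueError(f"mod flag must be 0 or 1, got {self.mod}")
        self.level = _clip_level(self.level)

    def set_level(self, level: float) -> None:
        self.level = _clip_level(level)

    @property
    def factor(self) -> float:
        return modulation_factor(self)


def modulation_factor(state: ModulationState) -> float:
    """Multiplicative factor applied to the modulated target.

    ``1 + mod * level * (maxMod - 1)``: equals ``maxMod`` at full modulation
    (mod=1, level=1) and 1 whenever mod=0 or level=0.
    """
    return 1.0 + state.mod * state.level * (state.max_mod - 1.0)


def combine_factors(factors: Iterable[float]) -> float:
    """Combine factors from several modulators acting on one target.

    Independent fractional effects multiply; an empty collection yields the
    neutral factor 1.
    """
    out = 1.0
    for f in factors:
        if f < 0.0:
            raise ValueError(f"modulation factors must be >= 0, got {f}")
        out *= f
    return out


@dataclass(frozen=True)
class GateSpec:
    """First-order voltage-gated activation/inactivation variable.

    Steady state is a Boltzmann sigmoid ``1 / (1 + exp(-(V - v_half)/slope))``
    (negative ``slope`` for inactivation gates).  The time constant is
    ``tau_base`` plus an optional Gaussian bell centred on ``tau_v_half``:
    ``tau(V) = tau_base + tau_amp * exp(-((V - tau_v_half)/tau_width)^2)``.

    ``exponent`` is the power the gate enters the conductance product with
    (e.g. 3 for the classic m^3 sodium activation).
    """

    v_half: float
    slope: float
    tau_base: float
    tau_amp: float = 0.0
    tau_v_half: float = 0.0
    tau_width: float = 10.0
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.tau_base <= 0.0 or self.tau_amp < 0.0:
            raise ValueError("time constant must be positive (tau_base > 0, tau_amp >= 0)")
        if self.slope == 0.0:
            raise ValueError("Boltzmann slope must be nonzero")
        if self.exponent < 1 or int(self.exponent) != self.exponent:
            raise ValueError(f"gate exponent must be an integer >= 1, got {self.exponent}")


def gate_steady_state(v, spec: GateSpec):
    """Boltzmann steady-state activation at membrane potential ``v`` (mV)."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - spec.v_half) / spec.slope))


def gate_time_constant(v, spec: GateSpec):
    """Voltage-dependent gate time constant tau(V) in ms."""
    v = np.asarray(v, dtype=float)
    if spec.tau_amp == 0.0:
        return np.broadcast_to(np.float64(spec.tau_base), v.shape).copy()
    z = (v - spec.tau_v_half) / spec.tau_width
    return spec.tau_base + spec.tau_amp * np.exp(-z * z)


def step_gate(x, v, spec: GateSpec, dt: float):
    """Advance a gate by one exponential-Euler step of size ``dt`` ms.

    ``x' = x_inf + (x - x_inf) * exp(-dt / tau(V))`` -- exact for the
    first-order gate ODE at frozen voltage, hence unconditionally stable and
    confined to [0, 1] for x in [0, 1].
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    x_inf = gate_steady_state(v, spec)
    return x_inf + (np.asarray(x, dtype=float) - x_inf) * np.exp(-dt / gate_time_constant(v, spec))


@dataclass(frozen=True)
class ChannelSpec:
    """Ohmic voltage-gated channel: ``i = gbar * f * prod(gate^exp) * (V - e_rev)``.

    ``gbar`` is the maximal conductance density in S/cm^2, ``e_rev`` the
    reversal potential in mV, and ``modulated_by`` the set of neuromodulator
    keys this channel responds to.  With gbar in S/cm^2 and V in mV the current
    density comes out in mA/cm^2.
    """

    name: str
    gbar: float
    e_rev: float
    gates: tuple[GateSpec, ...] = ()
    modulated_by: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.gbar < 0.0:
            raise ValueError(f"gbar must be >= 0, got {self.gbar}")
        object.__setattr__(self, "gates", tuple(self.gates))
        object.__setattr__(self, "modulated_by", frozenset(self.modulated_by))

    def open_fraction(self, gate_values: Sequence) -> np.ndarray:
        if len(gate_values) != len(self.gates):
            raise ValueError(
                f"channel {self.name!r} has {len(self.gates)} gates, got {len(gate_values)} values"
            )
        out = np.ones_like(np.asarray(gate_values[0], dtype=float)) if gate_values else np.float64(1.0)
        for x, spec in zip(gate_values, self.gates):
            out = out * np.asarray(x, dtype=float) ** spec.exponent
        return out


def channel_current(v, gate_values: Sequence, spec: ChannelSpec, g_factor: float = 1.0):
    """Channel current density (mA/cm^2) at voltage ``v`` and the given gate state.

    ``g_factor`` is the combined modulation factor applied to the conductance;
    it must be >= 0 and scales the current linearly.
    """
    if g_factor < 0.0:
        raise ValueError(f"g_factor must be >= 0, got {g_factor}")
    if len(spec.gates) == 0:
        open_frac = 1.0
    else:
        open_frac = spec.open_fraction(gate_values)
    return spec.gbar * g_factor * open_frac * (np.asarray(v, dtype=float) - spec.e_rev)
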