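"""Single-cell surrogate models, clamp protocols and bath application.

A :class:`NeuronModel` wraps one surrogate neuron (a batched
:class:`~neuromodnet.engine.CellGroup` of size one) together with its
registered modulation targets.  ``run_protocol`` simulates a current- or
voltage-clamp protocol, optionally with a *bath application*: a constant
modulation level applied to every registered target of a modulator for the
whole run, emulating drug application in a recording chamber.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .celltypes import CELL_TYPES, make_cell_group
from .engine import CellGroup, SPIKE_DEAD_TIME_MS, SPIKE_THRESHOLD_MV

__all__ = [
    "ClampSegment",
    "ClampProtocol",
    "NeuronModel",
    "ProtocolResult",
    "build_surrogate",
    "run_protocol",
    "detect_spikes",
    "TMSynapse",
    "deliver_synaptic_event",
]

logger = logging.getLogger(__name__)

_U_FLOOR = 1e-6


@dataclass(frozen=True)
class ClampSegment:
    """One clamp segment: amplitude is pA (current mode) or mV (voltage mode)."""

    start_ms: float
    duration_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.start_ms < 0 or self.duration_ms <= 0:
            raise ValueError("segment must have start >= 0 and duration > 0")

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms


@dataclass(frozen=True)
class ClampProtocol:
    """Current- or voltage-clamp protocol attached to one compartment."""

    mode: str  # "current" | "voltage"
    segments: tuple[ClampSegment, ...]
    compartment: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("current", "voltage"):
            raise ValueError(f"clamp mode must be 'current' or 'voltage', got {self.mode!r}")
        segs = tuple(sorted(self.segments, key=lambda s: s.start_ms))
        for a, b in zip(segs, segs[1:]):
            if b.start_ms < a.end_ms:
                raise ValueError(
                    f"clamp segments overlap: [{a.start_ms}, {a.end_ms}) and "
                    f"[{b.start_ms}, {b.end_ms})"
                )
        object.__setattr__(self, "segments", segs)
        if self.mode == "voltage" and self.compartment != 0:
            raise ValueError("voltage clamp is somatic (compartment 0) only")

    def validate_duration(self, duration_ms: float) -> None:
        for s in self.segments:
            if s.end_ms > duration_ms:
                raise ValueError(
                    f"segment ending at {s.end_ms} ms exceeds simulation duration "
                    f"{duration_ms} ms"
                )

    @classmethod
    def current_step(cls, start_ms: float, duration_ms: float, amplitude_pa: float,
                     compartment: int = 0) -> "ClampProtocol":
        return cls("current", (ClampSegment(start_ms, duration_ms, amplitude_pa),),
                   compartment)

    @classmethod
    def from_dict(cls, d: dict) -> "ClampProtocol":
        segs = tuple(
            ClampSegment(float(s["start_ms"]), float(s["duration_ms"]),
                         float(s.get("amplitude_pA", s.get("command_mV", s.get("amplitude")))))
            for s in d["segments"]
        )
        return cls(d.get("mode", "current"), segs, int(d.get("compartment", 0)))


@dataclass
class ProtocolResult:
    """Voltage (and clamp-current) traces from one protocol run."""

    times_ms: np.ndarray
    v_mv: np.ndarray  # (n_steps, n_recorded)
    recorded_comps: tuple[int, ...]
    clamp_current_na: np.ndarray | None = None
    spike_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def soma_v_mv(self) -> np.ndarray:
        return self.v_mv[:, self.recorded_comps.index(0)]

    def to_text(self, path) -> None:
        """Columnar text trace: time_ms then one voltage column per compartment."""
        header = "time_ms " + " ".join(f"V{c}_mV" for c in self.recorded_comps)
        np.savetxt(path, np.column_stack([self.times_ms, self.v_mv]),
                   fmt="%.6f", header=header, comments="")


class NeuronModel:
    """One surrogate neuron with a per-target modulation registry.

    The registry is populated from modulation parameter sets in the
    modulation-file schema via :meth:`apply_modulation`; levels start at zero
    (no modulation) and are driven by bath application or replay.
    """

    def __init__(self, cell_type: str):
        if cell_type not in CELL_TYPES:
            raise ValueError(
                f"unknown cell type {cell_type!r}; valid types: {', '.join(CELL_TYPES)}"
            )
        self.cell_type = cell_type
        self.group: CellGroup = make_cell_group(cell_type, 1)
        self._rest = self.group.state_snapshot()
        self.synapses: list[tuple["TMSynapse", int]] = []

    @property
    def modulators(self) -> list[str]:
        return sorted(self.group.levels)

    def apply_modulation(self, modulation: dict, modulator: str | None = None,
                         mod: int = 1) -> None:
        """Register targets from a modulation parameter set.

        ``modulation`` is either ``{"<modulator>": {...}}`` (possibly several
        modulators) or, with ``modulator`` given, the inner
        ``{"ion_channels": ..., "receptors": ...}`` mapping.
        """
        items = {modulator: modulation} if modulator is not None else modulation
        for key, entry in items.items():
            for region, targets in entry.get("ion_channels", {}).items():
                for t in targets:
                    self.group.register_channel_modulation(
                        key, t["channel"], region, float(t["maxMod"]), mod=mod
                    )
            for receptor, t in entry.get("receptors", {}).items():
                self.group.register_receptor_modulation(
                    key, receptor, float(t.get("maxMod", 1.0)),
                    float(t.get("release_mod", 1.0)), mod=mod,
                )

    def reset(self) -> None:
        self.group.load_snapshot(self._rest)
        self.group.t_last_spike[:] = -np.inf

    def add_synapse(self, synapse: "TMSynapse", compartment: int = 0) -> None:
        self.synapses.append((synapse, compartment))


def build_surrogate(cell_type: str) -> NeuronModel:
    """Construct a built-in surrogate neuron (``dSPN``, ``iSPN`` or ``FS``)."""
    return NeuronModel(cell_type)


def run_group_protocol(
    group: CellGroup,
    protocol: ClampProtocol,
    duration_ms: float,
    dt_ms: float = 0.025,
    bath: dict[str, float] | None = None,
    record_comps: tuple[int, ...] = (0,),
) -> "GroupProtocolResult":
    """Run one clamp protocol on every instance of a batched cell group.

    All instances receive the same clamp; they may differ in registered
    modulation parameters (one candidate set per instance).  ``bath`` maps
    modulator keys to a constant level in [0, 1] held for the whole run.
    """
    protocol.validate_duration(duration_ms)
    group.prepare(dt_ms)

    bath = bath or {}
    for key, level in bath.items():
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"bath level for {key!r} must be in [0, 1], got {level}")
        group.set_level(key, level)  # raises listing registered keys if unknown
    for key in group.levels:
        if key not in bath:
            group.set_level(key, 0.0)

    n_steps = int(round(duration_ms / dt_ms))
    times = (np.arange(n_steps) + 1) * dt_ms
    rec_idx = list(record_comps)
    v_rec = np.empty((n_steps, group.n, len(rec_idx)))
    clamp_rec = np.zeros((n_steps, group.n)) if protocol.mode == "voltage" else None
    spike_times: list[list[float]] = [[] for _ in range(group.n)]

    i_inj = np.zeros((group.n, group.n_comp))
    comp = protocol.compartment
    for k in range(n_steps):
        t = times[k]
        seg_amp = None
        for s in protocol.segments:
            if s.start_ms <= t - dt_ms < s.end_ms:  # active during this step
                seg_amp = s.amplitude
                break
        if protocol.mode == "current":
            i_inj[:, comp] = 0.0 if seg_amp is None else seg_amp * 1e-3  # pA -> nA
            spiked = group.step(t, i_inj_na=i_inj)
        else:
            cmd = None if seg_amp is None else seg_amp
            spiked = group.step(t, vclamp_cmd_mv=cmd)
            if cmd is not None and group.last_clamp_current_na is not None:
                clamp_rec[k] = group.last_clamp_current_na
        for i in np.flatnonzero(spiked):
            spike_times[i].append(t)
        v_rec[k] = group.v[:, rec_idx]

    return GroupProtocolResult(
        times_ms=times,
        v_mv=v_rec,
        recorded_comps=tuple(record_comps),
        clamp_current_na=clamp_rec,
        spike_times_ms=[np.asarray(st) for st in spike_times],
    )


@dataclass
class GroupProtocolResult:
    """Traces and spikes for every instance of a batched protocol run."""

    times_ms: np.ndarray
    v_mv: np.ndarray  # (n_steps, n, n_recorded)
    recorded_comps: tuple[int, ...]
    clamp_current_na: np.ndarray | None
    spike_times_ms: list[np.ndarray]

    def instance(self, i: int) -> ProtocolResult:
        return ProtocolResult(
            times_ms=self.times_ms,
            v_mv=self.v_mv[:, i, :],
            recorded_comps=self.recorded_comps,
            clamp_current_na=None if self.clamp_current_na is None
            else self.clamp_current_na[:, i],
            spike_times_ms=self.spike_times_ms[i],
        )


def run_protocol(
    model: NeuronModel,
    protocol: ClampProtocol,
    duration_ms: float,
    dt_ms: float = 0.025,
    bath: dict[str, float] | None = None,
    record_comps: tuple[int, ...] = (0,),
) -> ProtocolResult:
    """Simulate one clamp protocol, optionally under bath-applied modulation.

    ``bath`` maps modulator keys to a constant level in [0, 1] applied to all
    registered targets of that modulator for the whole run.  An empty bath is
    trace-identical to the unmodulated control.
    """
    model.reset()
    res = run_group_protocol(
        model.group, protocol, duration_ms, dt_ms=dt_ms, bath=bath,
        record_comps=record_comps,
    )
    return res.instance(0)


def detect_spikes(
    v_mv: np.ndarray,
    dt_ms: float,
    threshold_mv: float = SPIKE_THRESHOLD_MV,
    dead_time_ms: float = SPIKE_DEAD_TIME_MS,
) -> np.ndarray:
    """Spike times (ms) from a uniformly sampled voltage trace.

    A spike is an upward crossing of ``threshold_mv`` at least
    ``dead_time_ms`` after the previous one; the time reported is that of the
    first suprathreshold sample.
    """
    v = np.asarray(v_mv, dtype=float)
    above = v >= threshold_mv
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = []
    t_last = -np.inf
    for idx in crossings:
        t = (idx + 1) * dt_ms
        if t - t_last >= dead_time_ms:
            times.append(t)
            t_last = t
    return np.asarray(times)


def rheobase(
    model: NeuronModel,
    lo_pa: float = 0.0,
    hi_pa: float = 2000.0,
    step_duration_ms: float = 500.0,
    tol_pa: float = 10.0,
    dt_ms: float = 0.05,
) -> float:
    """Minimal step-current amplitude (pA) eliciting at least one spike.

    Bisection on a single step protocol; raises if even ``hi_pa`` is
    subthreshold.
    """
    def spikes(amp: float) -> int:
        proto = ClampProtocol.current_step(50.0, step_duration_ms, amp)
        r = run_protocol(model, proto, 50.0 + step_duration_ms + 50.0, dt_ms=dt_ms)
        return len(r.spike_times_ms)

    if spikes(hi_pa) == 0:
        raise ValueError(f"no spikes up to {hi_pa} pA; cannot bracket rheobase")
    while hi_pa - lo_pa > tol_pa:
        mid = 0.5 * (lo_pa + hi_pa)
        if spikes(mid) > 0:
            hi_pa = mid
        else:
            lo_pa = mid
    return hi_pa


class TMSynapse:
    """Tsodyks-Markram short-term-plasticity synapse with modulation hooks.

    Release resources ``R`` recover toward 1 with ``tau_rec``; the utilization
    ``u`` jumps by ``U*(1-u)`` at each spike and decays with ``tau_fac``
    (``tau_fac=0`` disables facilitation, ``u == U``).  Modulation scales the
    amplitude (on ``g_max``) and the release probability (on ``U``, clipped to
    (0, 1]).
    """

    def __init__(
        self,
        g_max_ns: float,
        e_rev_mv: float = 0.0,
        tau_rise_ms: float = 0.3,
        tau_decay_ms: float = 3.0,
        u: float = 0.5,
        tau_rec_ms: float = 200.0,
        tau_fac_ms: float = 0.0,
    ):
        if not 0 < u <= 1:
            raise ValueError("release parameter U must be in (0, 1]")
        if g_max_ns < 0:
            raise ValueError("g_max must be >= 0")
        if not 0 < tau_rise_ms < tau_decay_ms:
            raise ValueError("need 0 < tau_rise < tau_decay")
        self.g_max_ns = g_max_ns
        self.e_rev_mv = e_rev_mv
        self.tau_rise_ms = tau_rise_ms
        self.tau_decay_ms = tau_decay_ms
        self.u_base = u
        self.tau_rec_ms = tau_rec_ms
        self.tau_fac_ms = tau_fac_ms
        self._r = 1.0
        self._u = 0.0 if tau_fac_ms > 0 else u
        self._t_last: float | None = None
        self.events: list[tuple[float, float]] = []  # (time, peak conductance nS)

    def reset(self) -> None:
        self._r = 1.0
        self._u = 0.0 if self.tau_fac_ms > 0 else self.u_base
        self._t_last = None
        self.events.clear()

    def deliver(self, t_ms: float, amp_factor: float = 1.0, rel_factor: float = 1.0) -> float:
        """Process a presynaptic spike; returns the event's peak conductance (nS)."""
        if self._t_last is not None:
            if t_ms <= self._t_last:
                raise ValueError("event times must be strictly increasing")
            dt = t_ms - self._t_last
            self._r = 1.0 - (1.0 - self._r) * np.exp(-dt / self.tau_rec_ms)
            if self.tau_fac_ms > 0:
                self._u *= np.exp(-dt / self.tau_fac_ms)
        u_eff = self.u_base * rel_factor
        if u_eff <= 0.0:
            logger.warning("release-probability modulation drove U to %.3g; clipping", u_eff)
            u_eff = _U_FLOOR
        u_eff = min(u_eff, 1.0)
        if self.tau_fac_ms > 0:
            self._u = self._u + u_eff * (1.0 - self._u)
            release = self._u * self._r
        else:
            self._u = u_eff
            release = u_eff * self._r
        self._r *= 1.0 - (self._u if self.tau_fac_ms > 0 else u_eff)
        self._t_last = t_ms
        peak = self.g_max_ns * amp_factor * release
        self.events.append((t_ms, peak))
        return peak

    def conductance(self, t_ms: np.ndarray) -> np.ndarray:
        """Summed double-exponential conductance waveform (nS) of past events."""
        t = np.asarray(t_ms, dtype=float)
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        tp = tr * td / (td - tr) * np.log(td / tr)
        norm = 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))
        g = np.zeros_like(t)
        for t0, peak in self.events:
            dtv = t - t0
            mask = dtv > 0
            g[mask] += peak * norm * (np.exp(-dtv[mask] / td) - np.exp(-dtv[mask] / tr))
        return g


def deliver_synaptic_event(
    syn: TMSynapse, t_ms: float, amp_factor: float = 1.0, rel_factor: float = 1.0
) -> float:
    """Deliver one presynaptic spike to a synapse; returns the peak conductance (nS)."""
    return syn.deliver(t_ms, amp_factor=amp_factor, rel_factor=rel_factor)
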