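"""Batched compartmental integrator.

All neurons of one cell type share a morphology and channel complement, so a
:class:`CellGroup` integrates ``n`` instances side by side as ``(n, n_comp)``
arrays.  The same engine runs single-cell clamp protocols (n=1), whole
modulation-parameter populations (one instance per candidate set) and network
cell populations -- which is what makes bath application and replay of a
constant level trace produce bit-identical traces.

Numerics
--------
Voltage: backward (implicit) Euler on the compartment tree with ionic
conductances frozen at the current gate state; the linear tree system is
solved by Hines elimination (parents ordered before children), vectorized
over instances.  Gates: exponential Euler (exact relaxation toward the
steady state at frozen voltage).  Both are unconditionally stable.

Unit system: mV, ms, nF, uS, nA (1 uS * 1 mV = 1 nA; 1 nF * 1 mV / 1 ms =
1 nA).  Conductance densities in S/cm^2 are folded into per-compartment uS
using the compartment areas at construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modulation import ChannelSpec, gate_steady_state, gate_time_constant
from .morphology import Morphology

__all__ = ["ReceptorSpec", "CellTypeSpec", "CellGroup", "SimulationDiverged"]

SPIKE_THRESHOLD_MV = -10.0
SPIKE_DEAD_TIME_MS = 1.0


class SimulationDiverged(RuntimeError):
    """Raised when a membrane potential becomes non-finite."""

    def __init__(self, t_ms: float, neuron: int, comp: int):
        self.t_ms, self.neuron, self.comp = t_ms, neuron, comp
        super().__init__(
            f"non-finite membrane potential at t={t_ms:.3f} ms "
            f"(instance {neuron}, compartment {comp})"
        )


@dataclass(frozen=True)
class ReceptorSpec:
    """Double-exponential conductance-based synaptic receptor."""

    name: str
    e_rev_mv: float
    tau_rise_ms: float
    tau_decay_ms: float

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("need 0 < tau_rise < tau_decay")

    @property
    def peak_norm(self) -> float:
        """Scale so a unit weight gives a unit peak conductance."""
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        tp = tr * td / (td - tr) * np.log(td / tr)
        return 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))


@dataclass(frozen=True)
class CellTypeSpec:
    """Morphology + channel complement + receptor templates for one cell type.

    ``channels`` maps each channel to the region names it is inserted in
    (``soma``, ``dendrite``, ``basal_dendrite``, ``apical_dendrite``,
    ``axon``); its ``gbar`` (S/cm^2) applies uniformly over those regions.
    """

    name: str
    morphology: Morphology
    channels: tuple[tuple[ChannelSpec, tuple[str, ...]], ...]
    receptors: tuple[ReceptorSpec, ...] = ()
    v_init_mv: float = -80.0

    def __post_init__(self) -> None:
        names = [ch.name for ch, _ in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names in cell type {self.name!r}")

    def channel_names(self) -> list[str]:
        return [ch.name for ch, _ in self.channels]

    def receptor(self, name: str) -> ReceptorSpec:
        for r in self.receptors:
            if r.name == name:
                return r
        raise KeyError(f"cell type {self.name!r} has no receptor {name!r}")


class _ChannelState:
    """Per-group state of one channel: conductance map and gate arrays."""

    def __init__(self, spec: ChannelSpec, regions: tuple[str, ...], morph: Morphology, n: int):
        self.spec = spec
        mask = np.zeros(len(morph), dtype=bool)
        for region in regions:
            mask[morph.region_indices(region)] = True
        self.comp_mask = mask
        # gbar (S/cm^2) * area (cm^2) -> S; *1e6 -> uS
        self.gbar_us = np.where(mask, spec.gbar * morph.areas_cm2 * 1e6, 0.0)
        self.gates: list[np.ndarray] = [
            np.zeros((n, len(morph))) for _ in spec.gates
        ]
        # per-modulator maxMod maps, shape (n, n_comp); created on registration
        self.max_mod: dict[str, np.ndarray] = {}

    def init_gates(self, v: np.ndarray) -> None:
        for x, gspec in zip(self.gates, self.spec.gates):
            x[:] = gate_steady_state(v, gspec)

    def open_fraction(self):
        """Product of gate^exponent over gates; scalar 1.0 for gateless channels."""
        out = 1.0
        for x, gspec in zip(self.gates, self.spec.gates):
            g = x
            for _ in range(gspec.exponent - 1):
                g = g * x
            out = out * g
        return out


class _ReceptorState:
    """Aggregated double-exponential conductance per compartment (uS)."""

    def __init__(self, spec: ReceptorSpec, n: int, n_comp: int):
        self.spec = spec
        self.a = np.zeros((n, n_comp))  # rise state
        self.b = np.zeros((n, n_comp))  # decay state
        self.max_mod_amp: dict[str, np.ndarray] = {}
        self.max_mod_rel: dict[str, np.ndarray] = {}

    @property
    def conductance_us(self) -> np.ndarray:
        return self.b - self.a


class CellGroup:
    """``n`` identical neurons integrated in lockstep.

    Modulation targets are registered with :meth:`register_channel_modulation`
    / :meth:`register_receptor_modulation`; per-instance levels are set with
    :meth:`set_level` and re-read every time step, so a level change takes
    effect on the very next step.
    """

    def __init__(self, cell_type: CellTypeSpec, n: int):
        if n < 1:
            raise ValueError("cell group needs n >= 1")
        self.ct = cell_type
        self.n = n
        morph = cell_type.morphology
        self.morph = morph
        self.n_comp = len(morph)
        self.parents = morph.parents
        self.cap_nf = morph.capacitances_nf
        self.g_ax_us = morph.axial_conductances_us
        self.soma_idx = 0

        self.v = np.full((n, self.n_comp), cell_type.v_init_mv, dtype=float)
        self.channels = [
            _ChannelState(spec, regions, morph, n) for spec, regions in cell_type.channels
        ]
        self._channel_by_name = {c.spec.name: c for c in self.channels}
        for ch in self.channels:
            ch.init_gates(self.v)
        self.receptors = {
            r.name: _ReceptorState(r, n, self.n_comp) for r in cell_type.receptors
        }
        self.levels: dict[str, np.ndarray] = {}
        self.mod_active: dict[str, bool] = {}

        self.t_last_spike = np.full(n, -np.inf)
        #: "raise" aborts on a non-finite voltage; "mask" flags the instance in
        #: :attr:`diverged`, parks it at v_init and lets the batch continue.
        self.divergence_policy = "raise"
        self.diverged = np.zeros(n, dtype=bool)
        self._v_soma_prev = self.v[:, self.soma_idx].copy()
        self.last_clamp_current_na: np.ndarray | None = None

        self._dt: float | None = None

    # ---------------------------------------------------------------- setup

    def channel(self, name: str) -> _ChannelState:
        try:
            return self._channel_by_name[name]
        except KeyError:
            raise KeyError(
                f"cell type {self.ct.name!r} has no channel {name!r}; "
                f"available: {sorted(self._channel_by_name)}"
            ) from None

    def register_channel_modulation(
        self, modulator: str, channel: str, region: str, max_mod, mod: int = 1
    ) -> None:
        """Declare that ``modulator`` scales ``channel`` conductance in ``region``.

        ``max_mod`` may be a scalar (same for all instances) or an array of
        length ``n`` (one candidate parameter set per instance).  Repeated
        registration for overlapping regions multiplies the maps.
        """
        ch = self.channel(channel)
        if modulator not in ch.spec.modulated_by:
            raise ValueError(
                f"channel {channel!r} is not declared as modulated by {modulator!r} "
                f"(modulated_by={sorted(ch.spec.modulated_by)})"
            )
        mm = np.asarray(max_mod, dtype=float)
        if np.any(~np.isfinite(mm)) or np.any(mm < 0):
            raise ValueError("maxMod must be finite and >= 0")
        if mm.ndim == 0:
            mm = np.full(self.n, float(mm))
        if mm.shape != (self.n,):
            raise ValueError(f"maxMod array must have shape ({self.n},)")
        idx = self.morph.region_indices(region)
        if idx.size == 0:
            raise ValueError(f"cell type {self.ct.name!r} has no {region!r} compartments")
        cur = ch.max_mod.setdefault(modulator, np.ones((self.n, self.n_comp)))
        cur[:, idx] *= mm[:, None]
        self._ensure_modulator(modulator, mod)

    def register_receptor_modulation(
        self, modulator: str, receptor: str, max_mod: float = 1.0,
        release_mod: float = 1.0, mod: int = 1,
    ) -> None:
        """Declare amplitude (g_max) and release-probability (U) modulation."""
        try:
            rec = self.receptors[receptor]
        except KeyError:
            raise KeyError(
                f"cell type {self.ct.name!r} has no receptor {receptor!r}; "
                f"available: {sorted(self.receptors)}"
            ) from None
        for target, value in (("amp", max_mod), ("rel", release_mod)):
            if not np.isfinite(value) or value < 0:
                raise ValueError("receptor maxMod must be finite and >= 0")
            store = rec.max_mod_amp if target == "amp" else rec.max_mod_rel
            cur = store.setdefault(modulator, np.ones(self.n))
            cur *= value
        self._ensure_modulator(modulator, mod)

    def _ensure_modulator(self, modulator: str, mod: int) -> None:
        if mod not in (0, 1):
            raise ValueError("mod flag must be 0 or 1")
        self.levels.setdefault(modulator, np.zeros(self.n))
        self.mod_active[modulator] = bool(self.mod_active.get(modulator, False) or mod)

    def set_level(self, modulator: str, level) -> None:
        """Set the instantaneous level for one modulator (scalar or per-instance)."""
        if modulator not in self.levels:
            raise KeyError(
                f"no modulation registered for {modulator!r} on cell type "
                f"{self.ct.name!r}; registered: {sorted(self.levels)}"
            )
        lv = np.asarray(level, dtype=float)
        if lv.ndim == 0:
            lv = np.full(self.n, float(lv))
        self.levels[modulator][:] = np.clip(lv, 0.0, 1.0)

    # ------------------------------------------------------------- dynamics

    def prepare(self, dt_ms: float) -> None:
        """Precompute per-dt constants; call once before stepping."""
        if dt_ms <= 0:
            raise ValueError("dt must be positive")
        self._dt = dt_ms
        self._c_over_dt = self.cap_nf / dt_ms  # (n_comp,)
        # gate relaxation factors for constant-tau gates
        self._gate_const_decay: list[list[float | None]] = []
        for ch in self.channels:
            per = []
            for gspec in ch.spec.gates:
                per.append(np.exp(-dt_ms / gspec.tau_base) if gspec.tau_amp == 0.0 else None)
            self._gate_const_decay.append(per)
        self._rec_decay = {
            name: (np.exp(-dt_ms / r.spec.tau_rise_ms), np.exp(-dt_ms / r.spec.tau_decay_ms))
            for name, r in self.receptors.items()
        }
        # axial structure: diagonal load from each coupling on both sides
        ax_diag = np.zeros(self.n_comp)
        for i in range(1, self.n_comp):
            g = self.g_ax_us[i]
            ax_diag[i] += g
            ax_diag[self.parents[i]] += g
        self._ax_diag = ax_diag

    def channel_factor(self, ch: _ChannelState) -> np.ndarray:
        """Combined modulation factor map (n, n_comp) for one channel, from the
        current levels; re-evaluated every step."""
        f = 1.0
        for modulator, mm in ch.max_mod.items():
            if not self.mod_active.get(modulator, False):
                continue
            lv = self.levels[modulator][:, None]
            f = f * (1.0 + lv * (mm - 1.0))
        if isinstance(f, float):
            return np.ones((self.n, self.n_comp))
        return f

    def receptor_event_factors(self, receptor: str) -> tuple[np.ndarray, np.ndarray]:
        """(amplitude factor, release factor) per instance for synaptic events
        delivered at the current step."""
        rec = self.receptors[receptor]
        amp = np.ones(self.n)
        rel = np.ones(self.n)
        for modulator, mm in rec.max_mod_amp.items():
            if self.mod_active.get(modulator, False):
                amp *= 1.0 + self.levels[modulator] * (mm - 1.0)
        for modulator, mm in rec.max_mod_rel.items():
            if self.mod_active.get(modulator, False):
                rel *= 1.0 + self.levels[modulator] * (mm - 1.0)
        return amp, rel

    def add_synaptic_input(self, receptor: str, comp, neuron_idx, weight_us) -> None:
        """Inject synaptic conductance events (weights already include release
        scaling): each adds a double-exponential transient peaking at
        ``weight_us`` on compartment ``comp`` (scalar or per-event array) of
        the given instances."""
        rec = self.receptors[receptor]
        q = np.asarray(weight_us, dtype=float) * rec.spec.peak_norm
        np.add.at(rec.a, (neuron_idx, comp), q)
        np.add.at(rec.b, (neuron_idx, comp), q)

    def step(
        self,
        t_ms: float,
        i_inj_na: np.ndarray | None = None,
        vclamp_cmd_mv: np.ndarray | float | None = None,
    ) -> np.ndarray:
        """Advance one time step; returns a boolean array of somatic spikes.

        ``i_inj_na`` is an (n, n_comp) array of injected currents (nA);
        ``vclamp_cmd_mv`` engages an ideal somatic voltage clamp for this step
        and stores the clamp current in :attr:`last_clamp_current_na`.
        """
        if self._dt is None:
            raise RuntimeError("call prepare(dt) before step()")
        dt = self._dt
        v = self.v

        # 1. gates: exponential Euler at frozen voltage
        for ch, decays in zip(self.channels, self._gate_const_decay):
            for x, gspec, dk in zip(ch.gates, ch.spec.gates, decays):
                x_inf = 1.0 / (1.0 + np.exp(-(v - gspec.v_half) / gspec.slope))
                if dk is None:
                    tau = gate_time_constant(v, gspec)
                    k = np.exp(-dt / tau)
                else:
                    k = dk
                x *= k
                x += x_inf * (1.0 - k)

        # 2. membrane conductance totals (uS) and their reversal-weighted sum
        g_tot = np.zeros((self.n, self.n_comp))
        ge_tot = np.zeros((self.n, self.n_comp))
        for ch in self.channels:
            g = ch.gbar_us * ch.open_fraction()
            if ch.max_mod:
                g = g * self.channel_factor(ch)
            g_tot += g
            ge_tot += g * ch.spec.e_rev
        for rec in self.receptors.values():
            kr, kd = self._rec_decay[rec.spec.name]
            rec.a *= kr
            rec.b *= kd
            gs = rec.conductance_us
            g_tot += gs
            ge_tot += gs * rec.spec.e_rev_mv

        # 3. implicit tree solve
        diag = self._c_over_dt + self._ax_diag + g_tot
        b = self._c_over_dt * v + ge_tot
        if i_inj_na is not None:
            b = b + i_inj_na
        # off-diagonal of the tree matrix is -g_ax(i, parent)
        off = self.g_ax_us
        bb = b  # freshly allocated above; eliminated in place
        for i in range(self.n_comp - 1, 0, -1):
            p = self.parents[i]
            f = off[i] / diag[:, i]
            diag[:, p] -= f * off[i]
            bb[:, p] += f * bb[:, i]

        v_new = np.empty_like(v)
        if vclamp_cmd_mv is None:
            v_new[:, 0] = bb[:, 0] / diag[:, 0]
        else:
            v_new[:, 0] = vclamp_cmd_mv
        for i in range(1, self.n_comp):
            p = self.parents[i]
            v_new[:, i] = (bb[:, i] + off[i] * v_new[:, p]) / diag[:, i]

        if vclamp_cmd_mv is not None:
            cmd = np.broadcast_to(np.asarray(vclamp_cmd_mv, dtype=float), (self.n,))
            i_cl = (
                self._c_over_dt[0] * (cmd - v[:, 0])
                + g_tot[:, 0] * cmd
                - ge_tot[:, 0]
            )
            if i_inj_na is not None:
                i_cl = i_cl - i_inj_na[:, 0]
            for i in range(1, self.n_comp):
                if self.parents[i] == 0:
                    i_cl = i_cl - off[i] * (v_new[:, i] - cmd)
            self.last_clamp_current_na = i_cl

        if not np.all(np.isfinite(v_new)):
            if self.divergence_policy == "raise":
                bad = np.argwhere(~np.isfinite(v_new))[0]
                raise SimulationDiverged(t_ms, int(bad[0]), int(bad[1]))
            bad_rows = ~np.isfinite(v_new).all(axis=1)
            self.diverged |= bad_rows
            v_new[bad_rows] = self.ct.v_init_mv

        self.v = v_new

        # 4. somatic spike detection (upward threshold crossing with dead time)
        v_soma = v_new[:, self.soma_idx]
        spiked = (
            (v_soma >= SPIKE_THRESHOLD_MV)
            & (self._v_soma_prev < SPIKE_THRESHOLD_MV)
            & (t_ms - self.t_last_spike >= SPIKE_DEAD_TIME_MS)
        )
        self.t_last_spike[spiked] = t_ms
        self._v_soma_prev = v_soma.copy()
        return spiked

    # ------------------------------------------------------------ utilities

    def settle(self, t_ms: float = 1000.0, dt_ms: float = 0.5) -> None:
        """Relax to rest with no input (coarse dt; the scheme is A-stable)."""
        saved_dt = self._dt
        self.prepare(dt_ms)
        n_steps = int(round(t_ms / dt_ms))
        for k in range(n_steps):
            self.step((k + 1) * dt_ms)
        self.t_last_spike[:] = -np.inf
        self._v_soma_prev = self.v[:, self.soma_idx].copy()
        if saved_dt is not None:
            self.prepare(saved_dt)

    def state_snapshot(self) -> dict:
        return {
            "v": self.v.copy(),
            "gates": [[x.copy() for x in ch.gates] for ch in self.channels],
        }

    def load_snapshot(self, snap: dict) -> None:
        self.v = snap["v"].copy()
        for ch, gates in zip(self.channels, snap["gates"]):
            for x, xs in zip(ch.gates, gates):
                x[:] = xs
        self._v_soma_prev = self.v[:, self.soma_idx].copy()
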