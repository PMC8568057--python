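"""Microcircuit simulation with replay and adaptive neuromodulation.

A :class:`NetworkRecipe` declares the volume, cell-type composition,
distance-dependent connectivity and external (cortical/thalamic-like) input
drive.  Networks are built in three seeded, reproducible stages -- placement,
wiring, input generation -- and simulated under one of two neuromodulation
engines:

*replay*
    every neuron's modulation levels follow a predefined
    :class:`~neuromodnet.transient.LevelArray` per cell type (or an explicit
    per-neuron level matrix), re-read every time step;
*adaptive*
    spiking modulatory source neurons drive a per-target concentration-like
    integrator (``conc``); each presynaptic spike increments ``conc``, which
    decays exponentially and is mapped to the instantaneous modulation level.

Both engines drive the same per-target modulation registries, so a constant
replay trace is trace-identical to bath application, and an adaptive run's
recorded level traces replayed through the replay engine reproduce its
spikes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .celltypes import CELL_TYPES, make_cell_group
from .engine import CellGroup
from .transient import LevelArray

__all__ = [
    "InputBlock",
    "ConnectionRule",
    "NetworkRecipe",
    "PlacedNetwork",
    "ReplayConfig",
    "AdaptiveConfig",
    "ConcState",
    "SimulationResult",
    "place_neurons",
    "connect_network",
    "build_external_inputs",
    "build_network",
    "simulate_replay",
    "simulate_adaptive",
    "update_conc",
]

_U_FLOOR = 1e-6


# ------------------------------------------------------------------- recipe

@dataclass(frozen=True)
class InputBlock:
    """External Poisson drive onto one cell type.

    Each target neuron receives ``n_synapses`` independent Poisson trains,
    each through its own short-term-plasticity synapse, at
    ``background_rate_hz`` -- raised to ``activation_rate_hz`` inside the
    activation window (emulating a cortical activation).
    """

    target_type: str
    n_synapses: int = 100
    background_rate_hz: float = 2.0
    activation_start_ms: float | None = None
    activation_duration_ms: float = 0.0
    activation_rate_hz: float = 0.0
    g_max_ns: float = 1.0
    receptor: str = "AMPA"
    u: float = 0.3
    tau_rec_ms: float = 150.0
    tau_fac_ms: float = 0.0
    compartment: int = 1

    def __post_init__(self) -> None:
        if self.background_rate_hz < 0 or self.activation_rate_hz < 0:
            raise ValueError("input rates must be >= 0")
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")


@dataclass(frozen=True)
class ConnectionRule:
    """Bernoulli(p) connection within a distance cutoff for one type pair."""

    p: float
    cutoff_um: float = 100.0
    g_max_ns: float = 0.6
    receptor: str = "GABA"
    n_synapses: int = 1
    u: float = 0.4
    tau_rec_ms: float = 150.0
    tau_fac_ms: float = 0.0
    delay_ms: float = 1.0
    compartment: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"connection probability must be in [0, 1], got {self.p}")
        if self.delay_ms <= 0:
            raise ValueError("synaptic delay must be positive")


@dataclass
class NetworkRecipe:
    """Volume, composition, connectivity rules and input drive."""

    side_um: float
    n_neurons: int
    composition: dict[str, float]  # fractions (sum 1) or integer counts (sum N)
    connectivity: dict[tuple[str, str], ConnectionRule] = field(default_factory=dict)
    inputs: list[InputBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.side_um <= 0:
            raise ValueError("volume side must be positive")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")
        for t in self.composition:
            if t not in CELL_TYPES:
                raise ValueError(f"unknown cell type {t!r} in composition")
        vals = list(self.composition.values())
        if all(float(v).is_integer() for v in vals) and sum(vals) == self.n_neurons:
            return  # integer counts
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(
                "composition must be fractions summing to 1 or counts summing to n_neurons"
            )

    def counts(self) -> dict[str, int]:
        """Integer counts per type; fractions resolved by largest remainder."""
        vals = list(self.composition.values())
        if all(float(v).is_integer() for v in vals) and sum(vals) == self.n_neurons:
            return {t: int(v) for t, v in self.composition.items()}
        types = list(self.composition)
        exact = np.array([self.composition[t] * self.n_neurons for t in types])
        base = np.floor(exact).astype(int)
        remainder = exact - base
        short = self.n_neurons - int(base.sum())
        # deterministic: largest remainders first, ties by declaration order
        order = sorted(range(len(types)), key=lambda i: (-remainder[i], i))
        for i in order[:short]:
            base[i] += 1
        return dict(zip(types, base.tolist()))

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkRecipe":
        conn = {
            tuple(k.split("->")): ConnectionRule(**v)
            for k, v in d.get("connectivity", {}).items()
        }
        inputs = [InputBlock(**b) for b in d.get("inputs", [])]
        return cls(
            side_um=float(d["side_um"]),
            n_neurons=int(d["n_neurons"]),
            composition=d["composition"],
            connectivity=conn,
            inputs=inputs,
        )

    @classmethod
    def from_json(cls, path) -> "NetworkRecipe":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "side_um": self.side_um,
            "n_neurons": self.n_neurons,
            "composition": self.composition,
            "connectivity": {
                f"{pre}->{post}": {k: getattr(r, k) for k in (
                    "p", "cutoff_um", "g_max_ns", "receptor", "n_synapses", "u",
                    "tau_rec_ms", "tau_fac_ms", "delay_ms", "compartment")}
                for (pre, post), r in self.connectivity.items()
            },
            "inputs": [
                {k: getattr(b, k) for k in (
                    "target_type", "n_synapses", "background_rate_hz",
                    "activation_start_ms", "activation_duration_ms",
                    "activation_rate_hz", "g_max_ns", "receptor", "u",
                    "tau_rec_ms", "tau_fac_ms", "compartment")}
                for b in self.inputs
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ----------------------------------------------------------------- building

@dataclass
class _Connections:
    """Struct-of-arrays connection list with Tsodyks-Markram state."""

    pre_gid: np.ndarray
    post_gid: np.ndarray
    g_max_ns: np.ndarray
    receptor: np.ndarray  # receptor name per connection (object array)
    u: np.ndarray
    tau_rec_ms: np.ndarray
    tau_fac_ms: np.ndarray
    delay_ms: np.ndarray
    compartment: np.ndarray

    def __len__(self) -> int:
        return self.pre_gid.size

    @classmethod
    def empty(cls) -> "_Connections":
        z = np.empty(0)
        return cls(np.empty(0, np.int64), np.empty(0, np.int64), z.copy(),
                   np.empty(0, object), z.copy(), z.copy(), z.copy(), z.copy(),
                   np.empty(0, np.int64))


@dataclass
class PlacedNetwork:
    """Placed (and optionally wired) network of surrogate neurons."""

    recipe: NetworkRecipe
    types: list[str]            # cell type per gid
    positions_um: np.ndarray    # (N, 3)
    type_slices: dict[str, slice]
    connections: _Connections | None = None

    @property
    def n(self) -> int:
        return len(self.types)

    def gids_of(self, cell_type: str) -> np.ndarray:
        s = self.type_slices.get(cell_type)
        return np.arange(s.start, s.stop) if s else np.empty(0, np.int64)

    @property
    def roster(self) -> dict[int, str]:
        return {i: t for i, t in enumerate(self.types)}

    def counts(self) -> dict[str, int]:
        return {t: s.stop - s.start for t, s in self.type_slices.items()}

    def to_json(self, path) -> None:
        """Serialize the placed (and wired) network to JSON text."""
        d = {
            "recipe": self.recipe.to_dict(),
            "types": self.types,
            "positions_um": self.positions_um.tolist(),
        }
        if self.connections is not None:
            c = self.connections
            d["connections"] = {
                "pre_gid": c.pre_gid.tolist(),
                "post_gid": c.post_gid.tolist(),
                "g_max_ns": c.g_max_ns.tolist(),
                "receptor": c.receptor.tolist(),
                "u": c.u.tolist(),
                "tau_rec_ms": c.tau_rec_ms.tolist(),
                "tau_fac_ms": c.tau_fac_ms.tolist(),
                "delay_ms": c.delay_ms.tolist(),
                "compartment": c.compartment.tolist(),
            }
        Path(path).write_text(json.dumps(d) + "\n")

    @classmethod
    def from_json(cls, path) -> "PlacedNetwork":
        d = json.loads(Path(path).read_text())
        recipe = NetworkRecipe.from_dict(d["recipe"])
        types = list(d["types"])
        slices: dict[str, slice] = {}
        start = 0
        for t in recipe.composition:
            n_t = types.count(t)
            slices[t] = slice(start, start + n_t)
            start += n_t
        net = cls(recipe, types, np.asarray(d["positions_um"], dtype=float), slices)
        if "connections" in d:
            c = d["connections"]
            net.connections = _Connections(
                pre_gid=np.asarray(c["pre_gid"], np.int64),
                post_gid=np.asarray(c["post_gid"], np.int64),
                g_max_ns=np.asarray(c["g_max_ns"], float),
                receptor=np.asarray(c["receptor"], object),
                u=np.asarray(c["u"], float),
                tau_rec_ms=np.asarray(c["tau_rec_ms"], float),
                tau_fac_ms=np.asarray(c["tau_fac_ms"], float),
                delay_ms=np.asarray(c["delay_ms"], float),
                compartment=np.asarray(c["compartment"], np.int64),
            )
        return net


def place_neurons(recipe: NetworkRecipe, seed: int) -> PlacedNetwork:
    """Place neurons uniformly at random in the cubic volume.

    Counts per type are exact (fractions resolved by largest remainder);
    gids are grouped by type in composition order.
    """
    counts = recipe.counts()
    rng = np.random.default_rng(seed)
    types: list[str] = []
    slices: dict[str, slice] = {}
    start = 0
    for t in recipe.composition:
        c = counts[t]
        types.extend([t] * c)
        slices[t] = slice(start, start + c)
        start += c
    n = len(types)
    positions = rng.uniform(0.0, recipe.side_um, size=(n, 3))
    density = n / (recipe.side_um * 1e-3) ** 3  # per mm^3
    if density > 2e5:
        import warnings

        warnings.warn(
            f"placement density {density:.3g} neurons/mm^3 exceeds the sanity "
            "bound of 2e5; continuing",
            stacklevel=2,
        )
    return PlacedNetwork(recipe, types, positions, slices)


def connect_network(
    placed: PlacedNetwork,
    rules: dict[tuple[str, str], ConnectionRule] | None = None,
    seed: int = 0,
) -> PlacedNetwork:
    """Wire the placed network: Bernoulli(p) per ordered pair within cutoff.

    Type pairs without a rule get no connections; self-connections are
    excluded.  Returns the same network with its connection list attached.
    """
    rules = placed.recipe.connectivity if rules is None else rules
    rng = np.random.default_rng(seed)
    cols: dict[str, list] = {k: [] for k in (
        "pre", "post", "g", "rec", "u", "trec", "tfac", "delay", "comp")}
    for (pre_t, post_t) in sorted(rules):
        rule = rules[(pre_t, post_t)]
        pre = placed.gids_of(pre_t)
        post = placed.gids_of(post_t)
        if pre.size == 0 or post.size == 0 or rule.p == 0.0:
            continue
        d = np.linalg.norm(
            placed.positions_um[pre][:, None, :] - placed.positions_um[post][None, :, :],
            axis=2,
        )
        eligible = d <= rule.cutoff_um
        if pre_t == post_t:
            np.fill_diagonal(eligible, False)
        hit = eligible & (rng.random(eligible.shape) < rule.p)
        ii, jj = np.nonzero(hit)
        k = ii.size * rule.n_synapses
        cols["pre"].append(np.repeat(pre[ii], rule.n_synapses))
        cols["post"].append(np.repeat(post[jj], rule.n_synapses))
        cols["g"].append(np.full(k, rule.g_max_ns))
        cols["rec"].append(np.full(k, rule.receptor, dtype=object))
        cols["u"].append(np.full(k, rule.u))
        cols["trec"].append(np.full(k, rule.tau_rec_ms))
        cols["tfac"].append(np.full(k, rule.tau_fac_ms))
        cols["delay"].append(np.full(k, rule.delay_ms))
        cols["comp"].append(np.full(k, rule.compartment, dtype=np.int64))

    def cat(key, dtype=None):
        if not cols[key]:
            return np.empty(0, dtype if dtype else float)
        return np.concatenate(cols[key])

    placed.connections = _Connections(
        pre_gid=cat("pre", np.int64), post_gid=cat("post", np.int64),
        g_max_ns=cat("g"), receptor=cat("rec", object), u=cat("u"),
        tau_rec_ms=cat("trec"), tau_fac_ms=cat("tfac"), delay_ms=cat("delay"),
        compartment=cat("comp", np.int64),
    )
    return placed


def build_network(recipe: NetworkRecipe, seed: int) -> PlacedNetwork:
    """Place and wire in one call (placement seed = seed, wiring seed = seed+1)."""
    return connect_network(place_neurons(recipe, seed), seed=seed + 1)


@dataclass
class ExternalInputs:
    """Pre-generated external Poisson events per input block."""

    block: InputBlock
    syn_target_gid: np.ndarray      # target gid per synapse
    event_step: np.ndarray          # sorted step index per event
    event_syn: np.ndarray           # synapse index per event
    # TM state per synapse
    r: np.ndarray = None
    t_last: np.ndarray = None

    def __post_init__(self) -> None:
        self.r = np.ones(self.syn_target_gid.size)
        self.t_last = np.full(self.syn_target_gid.size, -np.inf)


def build_external_inputs(
    recipe: NetworkRecipe,
    placed: PlacedNetwork,
    duration_ms: float,
    dt_ms: float,
    seed: int,
) -> list[ExternalInputs]:
    """Sample all external input spike trains for one simulation.

    Homogeneous Poisson at the background rate, plus an independent elevated
    component inside the activation window; event times discretized to steps.
    """
    rng = np.random.default_rng(seed)
    out = []
    for block in recipe.inputs:
        targets = placed.gids_of(block.target_type)
        if targets.size == 0:
            raise ValueError(
                f"input block targets {block.target_type!r} but the network has none"
            )
        n_syn = targets.size * block.n_synapses
        syn_gid = np.repeat(targets, block.n_synapses)
        steps_list, syn_list = [], []

        def add_segment(t0, t1, rate_hz):
            if rate_hz <= 0 or t1 <= t0:
                return
            lam = (t1 - t0) / 1000.0 * rate_hz
            counts = rng.poisson(lam, size=n_syn)
            total = int(counts.sum())
            if total == 0:
                return
            times = rng.uniform(t0, t1, size=total)
            syns = np.repeat(np.arange(n_syn), counts)
            steps_list.append((times / dt_ms).astype(np.int64))
            syn_list.append(syns)

        add_segment(0.0, duration_ms, block.background_rate_hz)
        if block.activation_start_ms is not None and block.activation_duration_ms > 0:
            extra = block.activation_rate_hz - block.background_rate_hz
            add_segment(
                block.activation_start_ms,
                min(block.activation_start_ms + block.activation_duration_ms, duration_ms),
                extra,
            )
        if steps_list:
            steps = np.concatenate(steps_list)
            syns = np.concatenate(syn_list)
            order = np.lexsort((syns, steps))
            steps, syns = steps[order], syns[order]
        else:
            steps = np.empty(0, np.int64)
            syns = np.empty(0, np.int64)
        out.append(ExternalInputs(block, syn_gid, steps, syns))
    return out


# -------------------------------------------------------------- conc state

@dataclass
class ConcState:
    """Concentration-like integrator translating spikes into modulation levels.

    Each presynaptic spike adds ``increment``; the value decays exponentially
    with ``tau_ms``.  The level map is ``min(1, conc)`` (default) or the
    saturating ``conc / (conc + k)``.
    """

    n: int
    increment: float
    tau_ms: float
    map: str = "min"  # "min" | "saturating"
    k: float = 1.0
    conc: np.ndarray = None

    def __post_init__(self) -> None:
        if self.increment < 0 or self.tau_ms <= 0:
            raise ValueError("need increment >= 0 and tau > 0")
        if self.map not in ("min", "saturating"):
            raise ValueError("conc->level map must be 'min' or 'saturating'")
        if self.conc is None:
            self.conc = np.zeros(self.n)

    @property
    def level(self) -> np.ndarray:
        if self.map == "min":
            return np.minimum(1.0, self.conc)
        return self.conc / (self.conc + self.k)


def update_conc(state: ConcState, spike_counts: np.ndarray | int, dt_ms: float) -> ConcState:
    """One integration step: exponential decay plus per-spike increments.

    ``conc <- conc * exp(-dt/tau) + increment * spike_counts``; levels are
    read from :attr:`ConcState.level`.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    state.conc *= np.exp(-dt_ms / state.tau_ms)
    state.conc += state.increment * np.asarray(spike_counts)
    return state


# ------------------------------------------------------------- sim configs

@dataclass
class ReplayConfig:
    """Cell-type-specific modulation targets plus predefined level traces.

    ``modulation`` maps cell type -> modulation schema (as in a modulation
    file); ``levels`` maps cell type -> modulator -> LevelArray.  An optional
    ``per_neuron_levels`` (cell type -> modulator -> (n_steps, n) array on the
    simulation grid) overrides the shared trace, which is how recorded
    adaptive level traces are replayed.
    """

    modulation: dict[str, dict] = field(default_factory=dict)
    levels: dict[str, dict[str, LevelArray]] = field(default_factory=dict)
    per_neuron_levels: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


@dataclass
class AdaptiveConfig:
    """Spike-driven modulation: source spike trains integrated by conc states.

    ``n_sources`` modulatory neurons fire Poisson (or regular) trains at
    ``rate_hz``, optionally elevated during an activation window; each source
    connects to each target neuron with probability ``connect_p`` and every
    source spike increments the target's conc integrator.
    """

    modulator: str = "DA"
    target_type: str = "dSPN"
    modulation: dict | None = None  # schema for the target type
    n_sources: int = 2
    rate_hz: float = 4.0
    source_kind: str = "poisson"  # "poisson" | "regular"
    activation_start_ms: float | None = None
    activation_duration_ms: float = 0.0
    activation_rate_hz: float = 0.0
    connect_p: float = 1.0
    conc_increment: float = 0.05
    conc_tau_ms: float = 300.0
    conc_map: str = "min"
    conc_k: float = 1.0


@dataclass
class SimulationResult:
    """Network simulation output: raster, per-type mean voltage, level traces."""

    dt_ms: float
    duration_ms: float
    spike_times_ms: np.ndarray
    spike_gids: np.ndarray
    roster: dict[int, str]
    mean_soma_v_mv: dict[str, np.ndarray]      # per type, (n_steps,)
    level_traces: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    conc_traces: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def times_ms(self) -> np.ndarray:
        n = int(round(self.duration_ms / self.dt_ms))
        return (np.arange(n) + 1) * self.dt_ms

    def save_spikes(self, path) -> None:
        """Two-column whitespace text: time_ms neuron_id."""
        np.savetxt(path, np.column_stack([self.spike_times_ms, self.spike_gids]),
                   fmt=["%.3f", "%d"])

    def save_roster(self, path) -> None:
        Path(path).write_text(json.dumps({str(k): v for k, v in self.roster.items()}) + "\n")


# -------------------------------------------------------------- simulation

class _NetworkEngine:
    """Shared machinery for replay and adaptive runs."""

    def __init__(self, placed: PlacedNetwork, duration_ms: float, dt_ms: float, seed: int,
                 record_levels: bool = False):
        if placed.connections is None:
            raise ValueError("network is not wired; call connect_network/build_network first")
        self.placed = placed
        self.duration_ms = duration_ms
        self.dt_ms = dt_ms
        self.n_steps = int(round(duration_ms / dt_ms))
        self.record_levels = record_levels

        ss = np.random.SeedSequence([int(seed), 0x5EED])
        child = ss.spawn(3)
        self.input_seed = child[0]
        self.mod_source_rng = np.random.default_rng(child[1])
        self.mod_wiring_rng = np.random.default_rng(child[2])

        self.types_present = [t for t in placed.recipe.composition if placed.counts()[t] > 0]
        self.groups: dict[str, CellGroup] = {
            t: make_cell_group(t, placed.counts()[t]) for t in self.types_present
        }
        self.offsets = {t: placed.type_slices[t].start for t in self.types_present}

        self.inputs = build_external_inputs(
            placed.recipe, placed, duration_ms, dt_ms, self.input_seed
        )
        self._input_ptr = [0] * len(self.inputs)

        conns = placed.connections
        self.conns = conns
        self.conn_delay_steps = np.maximum(
            1, np.round(conns.delay_ms / dt_ms).astype(np.int64)
        )
        self.max_delay = int(self.conn_delay_steps.max()) if len(conns) else 1
        # outgoing connection indices per presynaptic gid (CSR-ish)
        order = np.argsort(conns.pre_gid, kind="stable")
        self._out_sorted = order
        self._out_ptr = np.searchsorted(conns.pre_gid[order], np.arange(placed.n + 1))
        # TM state per connection
        self._tm_r = np.ones(len(conns))
        self._tm_t_last = np.full(len(conns), -np.inf)
        # ring buffer of pending connection events
        self.ring: list[list[np.ndarray]] = [[] for _ in range(self.max_delay + 1)]

        self.spike_t: list[float] = []
        self.spike_gid: list[int] = []
        self.mean_v = {t: np.empty(self.n_steps) for t in self.types_present}
        self.level_rec: dict[tuple[str, str], np.ndarray] = {}

    def register_modulation(self, per_type_schema: dict[str, dict]) -> None:
        for t, schema in per_type_schema.items():
            if t not in self.groups:
                raise ValueError(
                    f"modulation references cell type {t!r} absent from the network; "
                    f"present: {self.types_present}"
                )
            g = self.groups[t]
            for modulator, entry in schema.items():
                for region, targets in entry.get("ion_channels", {}).items():
                    for tg in targets:
                        g.register_channel_modulation(
                            modulator, tg["channel"], region, float(tg["maxMod"])
                        )
                for receptor, tg in entry.get("receptors", {}).items():
                    g.register_receptor_modulation(
                        modulator, receptor, float(tg.get("maxMod", 1.0)),
                        float(tg.get("release_mod", 1.0)),
                    )
            if self.record_levels:
                for modulator in schema:
                    self.level_rec[(t, modulator)] = np.zeros((self.n_steps, g.n))

    def prepare(self) -> None:
        for g in self.groups.values():
            g.prepare(self.dt_ms)

    # -- event delivery -----------------------------------------------------

    def _deliver_external(self, k: int, t: float) -> None:
        for bi, ext in enumerate(self.inputs):
            ev_steps, ev_syns = ext.event_step, ext.event_syn
            p = self._input_ptr[bi]
            q = p
            while q < ev_steps.size and ev_steps[q] == k:
                q += 1
            if q == p:
                continue
            self._input_ptr[bi] = q
            syns = ev_syns[p:q]
            block = ext.block
            gids = ext.syn_target_gid[syns]
            group = self.groups[block.target_type]
            local = gids - self.offsets[block.target_type]
            rec = group.receptors.get(block.receptor)
            if rec is None:
                raise KeyError(
                    f"cell type {block.target_type!r} has no receptor {block.receptor!r}"
                )
            # TM recovery + release, vectorized over this step's events
            dt_ev = t - ext.t_last[syns]
            r = 1.0 - (1.0 - ext.r[syns]) * np.exp(-dt_ev / block.tau_rec_ms)
            if rec.max_mod_amp or rec.max_mod_rel:
                amp_f, rel_f = group.receptor_event_factors(block.receptor)
                u_eff = np.clip(block.u * rel_f[local], _U_FLOOR, 1.0)
                amp = amp_f[local]
            else:
                u_eff = block.u
                amp = 1.0
            release = u_eff * r
            ext.r[syns] = r * (1.0 - u_eff)
            ext.t_last[syns] = t
            weight = block.g_max_ns * 1e-3 * amp * release
            group.add_synaptic_input(block.receptor, block.compartment, local, weight)

    def _deliver_recurrent(self, t: float) -> None:
        slot = self.ring[0]
        if not slot:
            return
        idx = np.concatenate(slot)
        slot.clear()
        conns = self.conns
        dt_ev = t - self._tm_t_last[idx]
        r = 1.0 - (1.0 - self._tm_r[idx]) * np.exp(-dt_ev / conns.tau_rec_ms[idx])
        post = conns.post_gid[idx]
        # group events by (post type, receptor); receptors are per-rule constants
        for tname in self.types_present:
            group = self.groups[tname]
            off = self.offsets[tname]
            sel = (post >= off) & (post < off + group.n)
            if not np.any(sel):
                continue
            sidx = idx[sel]
            local = post[sel] - off
            for receptor in sorted(set(conns.receptor[sidx])):
                rsel = conns.receptor[sidx] == receptor
                cidx = sidx[rsel]
                loc = local[rsel]
                rr = r[sel][rsel]
                u = conns.u[cidx]
                rec = group.receptors.get(receptor)
                if rec is None:
                    raise KeyError(f"cell type {tname!r} has no receptor {receptor!r}")
                if rec.max_mod_amp or rec.max_mod_rel:
                    amp_f, rel_f = group.receptor_event_factors(receptor)
                    u = np.clip(u * rel_f[loc], _U_FLOOR, 1.0)
                    amp = amp_f[loc]
                else:
                    amp = 1.0
                release = u * rr
                self._tm_r[cidx] = rr * (1.0 - u)
                self._tm_t_last[cidx] = t
                weight = conns.g_max_ns[cidx] * 1e-3 * amp * release
                group.add_synaptic_input(receptor, conns.compartment[cidx], loc, weight)

    def _queue_outgoing(self, gids: np.ndarray) -> None:
        if gids.size == 0 or len(self.conns) == 0:
            return
        for gid in gids:
            lo, hi = self._out_ptr[gid], self._out_ptr[gid + 1]
            if lo == hi:
                continue
            cidx = self._out_sorted[lo:hi]
            # split by delay (usually a single value)
            delays = self.conn_delay_steps[cidx]
            for d in np.unique(delays):
                self.ring[int(d)].append(cidx[delays == d])

    def rotate_ring(self) -> None:
        self.ring.append(self.ring.pop(0))

    def step_groups(self, k: int, t: float) -> None:
        for tname in self.types_present:
            group = self.groups[tname]
            spiked = group.step(t)
            self.mean_v[tname][k] = group.v[:, 0].mean()
            if np.any(spiked):
                gids = np.flatnonzero(spiked) + self.offsets[tname]
                self.spike_t.extend([t] * gids.size)
                self.spike_gid.extend(gids.tolist())
                self._queue_outgoing(gids)

    def result(self, **extra) -> SimulationResult:
        return SimulationResult(
            dt_ms=self.dt_ms,
            duration_ms=self.duration_ms,
            spike_times_ms=np.asarray(self.spike_t),
            spike_gids=np.asarray(self.spike_gid, dtype=np.int64),
            roster=self.placed.roster,
            mean_soma_v_mv=self.mean_v,
            **extra,
        )


def simulate_replay(
    placed: PlacedNetwork,
    replay: ReplayConfig | None,
    duration_ms: float,
    dt_ms: float = 0.025,
    seed: int = 0,
    record_levels: bool = False,
) -> SimulationResult:
    """Simulate the network with predefined modulation level traces.

    Levels are zero-order-hold resampled onto the simulation grid and applied
    to every registered target of each (cell type, modulator) every time step.
    A ``None`` or empty replay config is the unmodulated control.
    """
    replay = replay or ReplayConfig()
    eng = _NetworkEngine(placed, duration_ms, dt_ms, seed, record_levels=record_levels)
    eng.register_modulation(replay.modulation)

    # precompute per-type level matrices on the simulation grid
    level_arrays: dict[tuple[str, str], np.ndarray] = {}
    for t, per_mod in replay.levels.items():
        if t not in eng.groups:
            raise ValueError(
                f"replay levels reference cell type {t!r} absent from the network"
            )
        for modulator, arr in per_mod.items():
            level_arrays[(t, modulator)] = arr.resample(dt_ms, eng.n_steps).values
    for t, per_mod in replay.per_neuron_levels.items():
        for modulator, mat in per_mod.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (eng.n_steps, eng.groups[t].n):
                raise ValueError(
                    f"per-neuron level matrix for ({t}, {modulator}) must have shape "
                    f"({eng.n_steps}, {eng.groups[t].n})"
                )
            level_arrays[(t, modulator)] = mat

    eng.prepare()
    for k in range(eng.n_steps):
        t = (k + 1) * dt_ms
        for (tname, modulator), lv in level_arrays.items():
            eng.groups[tname].set_level(modulator, lv[k])
            if record_levels and (tname, modulator) in eng.level_rec:
                eng.level_rec[(tname, modulator)][k] = eng.groups[tname].levels[modulator]
        eng._deliver_external(k, t)
        eng._deliver_recurrent(t)
        eng.rotate_ring()
        eng.step_groups(k, t)

    return eng.result(level_traces=eng.level_rec)


def simulate_adaptive(
    placed: PlacedNetwork,
    config: AdaptiveConfig,
    duration_ms: float,
    dt_ms: float = 0.025,
    seed: int = 0,
    record_levels: bool = True,
) -> SimulationResult:
    """Simulate with spike-driven modulation from modulatory source neurons.

    Sources are spike generators (not biophysical models); each source spike
    increments the conc integrator of its connected target neurons, and the
    resulting level drives the same modulation registries replay uses.  The
    recorded level traces can be fed back through :func:`simulate_replay` via
    ``ReplayConfig.per_neuron_levels`` to reproduce the run.
    """
    if config.modulation is None:
        raise ValueError("adaptive config needs a modulation schema for the target type")
    if config.conc_increment is None or config.conc_tau_ms is None:
        raise ValueError("conc parameters (increment, tau) are required")
    eng = _NetworkEngine(placed, duration_ms, dt_ms, seed, record_levels=record_levels)
    eng.register_modulation({config.target_type: {config.modulator: config.modulation}})

    group = eng.groups[config.target_type]
    conc = ConcState(
        n=group.n, increment=config.conc_increment, tau_ms=config.conc_tau_ms,
        map=config.conc_map, k=config.conc_k,
    )

    # source spike trains, discretized to per-step counts
    src_counts = np.zeros((eng.n_steps, max(config.n_sources, 0)), dtype=np.int64)
    for s in range(config.n_sources):
        times = _source_train(config, duration_ms, eng.mod_source_rng)
        steps = np.minimum((times / dt_ms).astype(np.int64), eng.n_steps - 1)
        np.add.at(src_counts[:, s], steps, 1)
    # wiring: Bernoulli(connect_p) source -> target
    adj = (
        eng.mod_wiring_rng.random((max(config.n_sources, 0), group.n)) < config.connect_p
    ).astype(np.int64)

    conc_rec = np.zeros((eng.n_steps, group.n)) if record_levels else None

    eng.prepare()
    for k in range(eng.n_steps):
        t = (k + 1) * dt_ms
        counts = src_counts[k] @ adj if config.n_sources else 0
        update_conc(conc, counts, dt_ms)
        group.set_level(config.modulator, conc.level)
        if record_levels:
            key = (config.target_type, config.modulator)
            eng.level_rec[key][k] = group.levels[config.modulator]
            conc_rec[k] = conc.conc
        eng._deliver_external(k, t)
        eng._deliver_recurrent(t)
        eng.rotate_ring()
        eng.step_groups(k, t)

    extra = {"level_traces": eng.level_rec}
    if record_levels:
        extra["conc_traces"] = {(config.target_type, config.modulator): conc_rec}
    return eng.result(**extra)


def _source_train(config: AdaptiveConfig, duration_ms: float, rng) -> np.ndarray:
    """One modulatory source spike train (ms), Poisson or regular."""
    def segment(t0, t1, rate):
        if rate <= 0 or t1 <= t0:
            return np.empty(0)
        if config.source_kind == "regular":
            period = 1000.0 / rate
            return np.arange(t0 + period, t1, period)
        n = rng.poisson((t1 - t0) / 1000.0 * rate)
        return np.sort(rng.uniform(t0, t1, size=n))

    if config.activation_start_ms is None or config.activation_duration_ms <= 0:
        return segment(0.0, duration_ms, config.rate_hz)
    a0 = config.activation_start_ms
    a1 = min(a0 + config.activation_duration_ms, duration_ms)
    return np.concatenate([
        segment(0.0, a0, config.rate_hz),
        segment(a0, a1, config.activation_rate_hz),
        segment(a1, duration_ms, config.rate_hz),
    ])
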