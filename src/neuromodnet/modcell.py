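"""Population search for modulation parameter sets reproducing measured effects.

The workflow mirrors a bath-application experiment: a population of candidate
modulation parameter sets (each a map ``(channel, region, modulator) ->
maxMod``) is sampled uniformly from user-declared intervals, every candidate is
simulated under a clamp protocol twice -- once as unmodulated control, once
with the modulator bath-applied -- and electrophysiological features of the
change (spike-count change, mean-rate change, subthreshold depolarization) are
compared against acceptance bands derived from experimental data (typically
mean +/- SD).  Candidates satisfying every criterion are kept and serialized
to a modulation file for network simulation.

Two surfaces are provided: the functional operations
(:func:`sample_population`, :func:`evaluate_population`,
:func:`select_population`, :func:`save_modulation` / :func:`load_modulation`)
and a model/results pair (:class:`ModulationSearch` whose :meth:`fit` returns
a :class:`ModulationSearchResults` with a ``summary()`` table), for use as::

    search = ModulationSearch("dSPN", space, protocol, criteria, population=1000)
    res = search.fit(seed=42)
    print(res.summary())
    res.save("modulation.json")
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .celltypes import CELL_TYPES, make_cell_group
from .cellmodel import (
    ClampProtocol,
    GroupProtocolResult,
    NeuronModel,
    ProtocolResult,
    build_surrogate,
    run_group_protocol,
    run_protocol,
)

__all__ = [
    "SearchEntry",
    "SearchSpace",
    "ModulationSet",
    "SelectionCriterion",
    "PopulationResult",
    "sample_population",
    "evaluate_set",
    "evaluate_population",
    "select_population",
    "save_modulation",
    "load_modulation",
    "ModulationSearch",
    "ModulationSearchResults",
    "FEATURES",
]

REGIONS = ("soma", "dendrite", "basal_dendrite", "apical_dendrite", "axon")


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class SearchEntry:
    """One sampled dimension: maxMod for (channel, region, modulator) in [lo, hi]."""

    channel: str
    region: str
    modulator: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not 0.0 <= self.lo <= self.hi:
            raise ValueError(
                f"need 0 <= lo <= hi for {self.channel!r}, got [{self.lo}, {self.hi}]"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.channel, self.region, self.modulator)


class SearchSpace:
    """Ordered collection of :class:`SearchEntry` defining the sampling box."""

    def __init__(self, entries: Sequence[SearchEntry]):
        entries = list(entries)
        if not entries:
            raise ValueError("search space must contain at least one entry")
        keys = [e.key for e in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (channel, region, modulator) entries")
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def modulators(self) -> list[str]:
        return sorted({e.modulator for e in self.entries})

    @classmethod
    def from_config(cls, items: Sequence[dict]) -> "SearchSpace":
        return cls(
            [
                SearchEntry(
                    channel=i["channel"],
                    region=i.get("region", "soma"),
                    modulator=i["modulator"],
                    lo=float(i["interval"][0]),
                    hi=float(i["interval"][1]),
                )
                for i in items
            ]
        )


@dataclass
class ModulationSet:
    """One candidate: sampled maxMod per (channel, region, modulator) target,
    plus optional receptor modulation entries ``(receptor, modulator) ->
    (maxMod, release_mod)``."""

    set_id: int
    values: dict[tuple[str, str, str], float]
    receptors: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"maxMod for {key} must be finite and >= 0, got {v}")
        for key, (a, r) in self.receptors.items():
            if a < 0 or r < 0:
                raise ValueError(f"receptor modulation for {key} must be >= 0")

    @property
    def modulators(self) -> list[str]:
        return sorted(
            {m for _, _, m in self.values} | {m for _, m in self.receptors}
        )

    def is_neutral(self, tol: float = 0.0) -> bool:
        return all(abs(v - 1.0) <= tol for v in self.values.values()) and all(
            abs(a - 1.0) <= tol and abs(r - 1.0) <= tol
            for a, r in self.receptors.values()
        )

    def apply_to(self, model: NeuronModel, mod: int = 1) -> None:
        for (channel, region, modulator), v in self.values.items():
            model.group.register_channel_modulation(modulator, channel, region, v, mod=mod)
        for (receptor, modulator), (a, r) in self.receptors.items():
            model.group.register_receptor_modulation(modulator, receptor, a, r, mod=mod)

    def to_schema(self) -> dict:
        out: dict = {}
        for (channel, region, modulator), v in self.values.items():
            entry = out.setdefault(modulator, {"ion_channels": {}, "receptors": {}})
            entry["ion_channels"].setdefault(region, []).append(
                {"channel": channel, "maxMod": float(v)}
            )
        for (receptor, modulator), (a, r) in self.receptors.items():
            entry = out.setdefault(modulator, {"ion_channels": {}, "receptors": {}})
            entry["receptors"][receptor] = {"maxMod": float(a), "release_mod": float(r)}
        return out

    @classmethod
    def from_schema(cls, schema: dict, set_id: int = 0) -> "ModulationSet":
        values: dict[tuple[str, str, str], float] = {}
        receptors: dict[tuple[str, str], tuple[float, float]] = {}
        for modulator, entry in schema.items():
            for region, targets in entry.get("ion_channels", {}).items():
                for t in targets:
                    values[(t["channel"], region, modulator)] = float(t["maxMod"])
            for receptor, t in entry.get("receptors", {}).items():
                receptors[(receptor, modulator)] = (
                    float(t.get("maxMod", 1.0)),
                    float(t.get("release_mod", 1.0)),
                )
        return cls(set_id=set_id, values=values, receptors=receptors)


# ------------------------------------------------------------------ features

def _window_spikes(res: ProtocolResult, window: tuple[float, float]) -> int:
    st = res.spike_times_ms
    return int(np.count_nonzero((st >= window[0]) & (st < window[1])))


def _spike_count_change(ctrl, mod, window):
    return _window_spikes(mod, window) - _window_spikes(ctrl, window)


def _mean_rate_change(ctrl, mod, window):
    dur_s = (window[1] - window[0]) / 1000.0
    return (_window_spikes(mod, window) - _window_spikes(ctrl, window)) / dur_s


def _depolarization_mv(ctrl, mod, window):
    t = ctrl.times_ms
    mask = (t >= window[0]) & (t < window[1])
    return float(np.mean(mod.soma_v_mv[mask]) - np.mean(ctrl.soma_v_mv[mask]))


#: Feature registry: name -> f(control, modulated, window) -> float.  Custom
#: features are added by inserting a callable with the same signature.
FEATURES: dict[str, Callable[[ProtocolResult, ProtocolResult, tuple[float, float]], float]] = {
    "spike_count_change": _spike_count_change,
    "mean_rate_change": _mean_rate_change,
    "depolarization_mV": _depolarization_mv,
}


@dataclass(frozen=True)
class SelectionCriterion:
    """Acceptance band for one feature: pass iff ``lo <= value <= hi``.

    ``from_mean_sd`` builds the band ``[mean - n_sd*SD, mean + n_sd*SD]``
    from experimental summary statistics.
    """

    feature: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise ValueError("criterion bounds must be finite")
        if self.lo > self.hi:
            raise ValueError(
                f"empty acceptance interval for {self.feature!r}: "
                f"[{self.lo}, {self.hi}]"
            )

    @classmethod
    def from_mean_sd(cls, feature: str, mean: float, sd: float, n_sd: float = 1.0):
        if sd < 0:
            raise ValueError("SD must be >= 0")
        return cls(feature, mean - n_sd * sd, mean + n_sd * sd)

    def passes(self, value: float) -> bool:
        return bool(self.lo <= value <= self.hi)


@dataclass
class PopulationResult:
    """Features of every candidate set, control features, and divergence flags."""

    sets: list[ModulationSet]
    control: dict[str, float]
    modulated: pd.DataFrame  # one row per set, one column per feature
    diverged: np.ndarray

    def __post_init__(self) -> None:
        if len(self.modulated) != len(self.sets):
            raise ValueError("feature table and set list lengths differ")


# ---------------------------------------------------------------- operations

def sample_population(space: SearchSpace, n: int, seed: int) -> list[ModulationSet]:
    """Sample ``n`` candidate sets, each entry independent uniform on its interval."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(
        low=[e.lo for e in space], high=[e.hi for e in space], size=(n, len(space))
    )
    return [
        ModulationSet(set_id=i, values={e.key: float(draws[i, j]) for j, e in enumerate(space)})
        for i in range(n)
    ]


def _features_from_runs(
    ctrl: ProtocolResult,
    mod: ProtocolResult,
    window: tuple[float, float],
    feature_names: Sequence[str],
) -> dict[str, float]:
    out = {}
    for name in feature_names:
        try:
            fn = FEATURES[name]
        except KeyError:
            raise KeyError(
                f"unknown feature {name!r}; registered features: {sorted(FEATURES)}"
            ) from None
        out[name] = float(fn(ctrl, mod, window))
    return out


def _stimulus_window(protocol: ClampProtocol) -> tuple[float, float]:
    """Feature-extraction window: the span of the clamp stimulus segments."""
    return (
        min(s.start_ms for s in protocol.segments),
        max(s.end_ms for s in protocol.segments),
    )


def evaluate_set(
    model_or_cell_type,
    mset: ModulationSet,
    protocol: ClampProtocol,
    duration_ms: float,
    bath_level: float = 1.0,
    dt_ms: float = 0.025,
    feature_names: Sequence[str] = ("spike_count_change",),
    bath: dict[str, float] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Evaluate one candidate set: returns (control features, modulated features).

    The control run has modulation inactive (mod flag 0); the modulated run
    bath-applies ``bath_level`` to every modulator in the set (or the explicit
    ``bath`` map).
    """
    cell_type = (
        model_or_cell_type.cell_type
        if isinstance(model_or_cell_type, NeuronModel)
        else model_or_cell_type
    )
    ctrl_model = build_surrogate(cell_type)
    ctrl = run_protocol(ctrl_model, protocol, duration_ms, dt_ms=dt_ms)

    mod_model = build_surrogate(cell_type)
    mset.apply_to(mod_model)
    bath = bath if bath is not None else {m: bath_level for m in mset.modulators}
    modr = run_protocol(mod_model, protocol, duration_ms, dt_ms=dt_ms, bath=bath)

    window = _stimulus_window(protocol)
    ctrl_abs = {
        "spike_count": float(_window_spikes(ctrl, window)),
        "mean_soma_v_mV": float(
            np.mean(ctrl.soma_v_mv[(ctrl.times_ms >= window[0]) & (ctrl.times_ms < window[1])])
        ),
    }
    feats = _features_from_runs(ctrl, modr, window, feature_names)
    return ctrl_abs, feats


def evaluate_population(
    cell_type: str,
    sets: Sequence[ModulationSet],
    protocol: ClampProtocol,
    duration_ms: float,
    bath_level: float = 1.0,
    dt_ms: float = 0.025,
    feature_names: Sequence[str] = ("spike_count_change",),
) -> PopulationResult:
    """Evaluate a whole population in one batched run.

    The control run is computed once and shared across the population (control
    features do not depend on the candidate set); candidates are simulated
    side by side, one instance per set, so the result is identical to
    evaluating them one at a time in any order.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}; valid: {CELL_TYPES}")
    sets = list(sets)
    if not sets:
        raise ValueError("population must contain at least one set")

    ctrl_model = build_surrogate(cell_type)
    ctrl = run_protocol(ctrl_model, protocol, duration_ms, dt_ms=dt_ms)

    group = make_cell_group(cell_type, len(sets))
    group.divergence_policy = "mask"
    # assemble per-instance maxMod arrays per target
    all_keys = sorted({k for s in sets for k in s.values})
    for channel, region, modulator in all_keys:
        arr = np.array([s.values.get((channel, region, modulator), 1.0) for s in sets])
        group.register_channel_modulation(modulator, channel, region, arr)
    # receptor entries are inert here: clamp protocols drive no synapses, so
    # they cannot influence the extracted features; they matter at network stage
    modulators = sorted({m for s in sets for m in s.modulators})
    bath = {m: bath_level for m in modulators}
    res: GroupProtocolResult = run_group_protocol(
        group, protocol, duration_ms, dt_ms=dt_ms, bath=bath
    )

    window = _stimulus_window(protocol)
    rows = [
        _features_from_runs(ctrl, res.instance(i), window, feature_names)
        for i in range(len(sets))
    ]
    control = {
        "spike_count": float(_window_spikes(ctrl, window)),
        "mean_soma_v_mV": float(
            np.mean(ctrl.soma_v_mv[(ctrl.times_ms >= window[0]) & (ctrl.times_ms < window[1])])
        ),
    }
    return PopulationResult(
        sets=sets,
        control=control,
        modulated=pd.DataFrame(rows, index=[s.set_id for s in sets]),
        diverged=group.diverged.copy(),
    )


def select_population(
    result: PopulationResult, criteria: Sequence[SelectionCriterion]
) -> list[ModulationSet]:
    """Candidate sets whose every feature lies inside its acceptance band.

    Diverged candidates never pass.  Idempotent: re-applying the criteria to
    the features of the returned sets passes by construction.
    """
    for c in criteria:
        if c.feature not in result.modulated.columns:
            raise KeyError(
                f"criterion references feature {c.feature!r} absent from results; "
                f"available: {list(result.modulated.columns)}"
            )
    mask = ~result.diverged
    for c in criteria:
        vals = result.modulated[c.feature].to_numpy()
        mask &= (vals >= c.lo) & (vals <= c.hi)
    return [s for s, ok in zip(result.sets, mask) if ok]


# ------------------------------------------------------- modulation file I/O

class _ReceptorEntry(BaseModel):
    maxMod: float = Field(default=1.0, ge=0.0)
    release_mod: float = Field(default=1.0, ge=0.0)


class _ChannelEntry(BaseModel):
    channel: str
    maxMod: float = Field(ge=0.0)


class _ModulatorEntry(BaseModel):
    ion_channels: dict[str, list[_ChannelEntry]] = Field(default_factory=dict)
    receptors: dict[str, _ReceptorEntry] = Field(default_factory=dict)


def _validate_schema(obj: dict, pointer: str) -> None:
    for modulator, entry in obj.items():
        try:
            parsed = _ModulatorEntry.model_validate(entry)
        except ValidationError as exc:
            err = exc.errors()[0]
            loc = "/".join(str(p) for p in err["loc"])
            raise ValueError(
                f"invalid modulation file at {pointer}/{modulator}/{loc}: {err['msg']}"
            ) from exc
        for region in parsed.ion_channels:
            if region not in REGIONS:
                raise ValueError(
                    f"invalid modulation file at {pointer}/{modulator}/ion_channels/"
                    f"{region}: unknown region (expected one of {REGIONS})"
                )


def save_modulation(sets: Sequence[ModulationSet], path) -> None:
    """Write modulation parameter sets to a modulation file (JSON).

    A single set is written as one schema object; several sets as a JSON array
    of schema objects.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("cannot save an empty set list")
    payload = sets[0].to_schema() if len(sets) == 1 else [s.to_schema() for s in sets]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_modulation(path) -> list[ModulationSet]:
    """Read a modulation file; accepts one schema object or an array of them."""
    data = json.loads(Path(path).read_text())
    items = data if isinstance(data, list) else [data]
    out = []
    for i, obj in enumerate(items):
        pointer = f"/{i}" if isinstance(data, list) else ""
        if not isinstance(obj, dict):
            raise ValueError(f"invalid modulation file at {pointer}: expected an object")
        _validate_schema(obj, pointer)
        out.append(ModulationSet.from_schema(obj, set_id=i))
    return out


# ------------------------------------------------------------ model surface

class ModulationSearch:
    """Population search model: cell type + search space + protocol + criteria.

    Parameters
    ----------
    cell_type : str
        Surrogate model to modulate (``dSPN``, ``iSPN`` or ``FS``).
    search_space : SearchSpace
        Sampling intervals for each modulation target.
    protocol : ClampProtocol
        Clamp protocol replicating the experiment (features are extracted
        over the stimulus window).
    criteria : sequence of SelectionCriterion
        Experimental acceptance bands the candidates must satisfy.
    population : int
        Number of candidate sets per fit.
    bath_level : float
        Constant level bath-applied in the modulated run (default 1.0).
    duration_ms, dt_ms : float
        Simulation length and step.
    """

    def __init__(
        self,
        cell_type: str,
        search_space: SearchSpace,
        protocol: ClampProtocol,
        criteria: Sequence[SelectionCriterion],
        population: int = 1000,
        bath_level: float = 1.0,
        duration_ms: float = 1000.0,
        dt_ms: float = 0.025,
    ):
        if cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {cell_type!r}; valid: {CELL_TYPES}")
        if not criteria:
            raise ValueError("at least one selection criterion is required")
        if not any(s.mode == "current" for s in [protocol]):
            raise ValueError("the protocol must be a current clamp")
        self.cell_type = cell_type
        self.search_space = search_space
        self.protocol = protocol
        self.criteria = list(criteria)
        self.population = int(population)
        self.bath_level = float(bath_level)
        self.duration_ms = float(duration_ms)
        self.dt_ms = float(dt_ms)

    @classmethod
    def from_config(cls, config: dict) -> "ModulationSearch":
        """Build from an optimization-config mapping (see the JSON examples)."""
        space = SearchSpace.from_config(config["search_space"])
        protocol = ClampProtocol.from_dict(config["protocols"][0])
        criteria = []
        for c in config["criteria"]:
            if "interval" in c:
                criteria.append(
                    SelectionCriterion(c["feature"], float(c["interval"][0]),
                                       float(c["interval"][1]))
                )
            else:
                criteria.append(
                    SelectionCriterion.from_mean_sd(
                        c["feature"], float(c["mean"]), float(c["sd"]),
                        float(c.get("n_sd", 1.0)),
                    )
                )
        return cls(
            cell_type=config["cell_type"],
            search_space=space,
            protocol=protocol,
            criteria=criteria,
            population=int(config.get("population", 1000)),
            bath_level=float(config.get("bath_level", 1.0)),
            duration_ms=float(config.get("sim_time_ms", 1000.0)),
            dt_ms=float(config.get("dt_ms", 0.025)),
        )

    @classmethod
    def from_config_file(cls, path) -> "ModulationSearch":
        return cls.from_config(json.loads(Path(path).read_text()))

    @property
    def feature_names(self) -> list[str]:
        return sorted({c.feature for c in self.criteria})

    def sample(self, seed: int, n: int | None = None) -> list[ModulationSet]:
        return sample_population(self.search_space, n or self.population, seed)

    def fit(self, seed: int, population: int | None = None) -> "ModulationSearchResults":
        """Sample, simulate and select; deterministic given ``seed``."""
        sets = self.sample(seed, population)
        result = evaluate_population(
            self.cell_type,
            sets,
            self.protocol,
            self.duration_ms,
            bath_level=self.bath_level,
            dt_ms=self.dt_ms,
            feature_names=self.feature_names,
        )
        passing = select_population(result, self.criteria)
        return ModulationSearchResults(self, result, passing, seed)


class ModulationSearchResults:
    """Fit outcome: per-candidate features, pass flags, and the passing sets."""

    def __init__(
        self,
        model: ModulationSearch,
        population_result: PopulationResult,
        passing: list[ModulationSet],
        seed: int,
    ):
        self.model = model
        self.population_result = population_result
        self.passing_sets = passing
        self.seed = seed

    @property
    def n_sampled(self) -> int:
        return len(self.population_result.sets)

    @property
    def n_passing(self) -> int:
        return len(self.passing_sets)

    @property
    def features(self) -> pd.DataFrame:
        """Per-candidate feature table with per-criterion and overall pass flags."""
        df = self.population_result.modulated.copy()
        overall = ~self.population_result.diverged
        for c in self.model.criteria:
            flag = (df[c.feature] >= c.lo) & (df[c.feature] <= c.hi)
            df[f"pass[{c.feature} in [{c.lo:g}, {c.hi:g}]]"] = flag
            overall &= flag.to_numpy()
        df["diverged"] = self.population_result.diverged
        df["passed"] = overall
        return df

    def summary(self) -> str:
        ctrl = self.population_result.control
        lines = [
            "Modulation population search",
            "=" * 60,
            f"cell type:            {self.model.cell_type}",
            f"modulators:           {', '.join(self.model.search_space.modulators)}",
            f"population sampled:   {self.n_sampled} (seed {self.seed})",
            f"bath level:           {self.model.bath_level:g}",
            f"control spike count:  {ctrl['spike_count']:g} (stimulus window)",
            f"passing sets:         {self.n_passing} "
            f"({100.0 * self.n_passing / self.n_sampled:.1f} %)",
            "-" * 60,
        ]
        df = self.population_result.modulated
        for c in self.model.criteria:
            vals = df[c.feature]
            rate = np.mean((vals >= c.lo) & (vals <= c.hi))
            lines.append(
                f"{c.feature:>22s} in [{c.lo:8.3f}, {c.hi:8.3f}]  "
                f"pass {100.0 * rate:5.1f} %  "
                f"(population mean {vals.mean():8.3f}, sd {vals.std():8.3f})"
            )
        if self.n_passing:
            sel = df.loc[[s.set_id for s in self.passing_sets]]
            lines.append("-" * 60)
            for name in df.columns:
                lines.append(
                    f"{name:>22s} of passing sets: "
                    f"{sel[name].mean():8.3f} +/- {sel[name].std():8.3f}"
                )
        return "\n".join(lines)

    def save(self, path) -> None:
        """Persist the passing sets as a modulation file."""
        save_modulation(self.passing_sets, path)
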