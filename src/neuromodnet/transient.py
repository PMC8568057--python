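"""Time-varying neuromodulator level traces for replay-mode simulation.

A replay simulation drives the ``level`` parameter of every modulation target
from a precomputed :class:`LevelArray` -- one level value per time step, clipped
to [0, 1].  Transients are described phenomenologically as a tonic baseline
plus burst (positive) or pause (negative) events with a smooth
double-exponential time course, the motif reported for striatal acetylcholine
(tonic release from spontaneously active cholinergic interneurons, interrupted
by burst/pause responses) and for phasic dopamine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TransientEvent",
    "TransientSpec",
    "LevelArray",
    "build_transient",
    "shift_transient",
    "timing_sweep",
    "TIMING_SWEEP_DELAYS_MS",
]

#: Delay preset (ms) for the dopamine-timing sweep relative to a cortical
#: stimulation onset: peaks spanning well before to well after the stimulus.
TIMING_SWEEP_DELAYS_MS: tuple[float, ...] = (-500.0, -300.0, -100.0, 100.0, 300.0, 500.0)


@dataclass(frozen=True)
class TransientEvent:
    """One burst or pause: a peak deviation of ``amplitude`` from the tonic level.

    The kernel is ``(1 - exp(-t/tau_rise)) * exp(-t/tau_decay)`` for t >= onset,
    renormalized to unit peak, so ``amplitude`` is exactly the peak deviation.
    """

    kind: Literal["burst", "pause"]
    onset_ms: float
    amplitude: float
    tau_rise_ms: float = 50.0
    tau_decay_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.kind not in ("burst", "pause"):
            raise ValueError(f"event kind must be 'burst' or 'pause', got {self.kind!r}")
        if self.amplitude < 0.0:
            raise ValueError(f"event amplitude must be >= 0, got {self.amplitude}")
        if self.tau_rise_ms <= 0.0 or self.tau_decay_ms <= 0.0:
            raise ValueError("event time constants must be positive")

    @property
    def sign(self) -> float:
        return 1.0 if self.kind == "burst" else -1.0

    def kernel(self, t_ms: np.ndarray) -> np.ndarray:
        """Unit-peak double-exponential kernel evaluated at times ``t_ms`` (absolute)."""
        t = np.asarray(t_ms, dtype=float) - self.onset_ms
        out = np.zeros_like(t)
        pos = t > 0.0
        tp = t[pos]
        raw = (1.0 - np.exp(-tp / self.tau_rise_ms)) * np.exp(-tp / self.tau_decay_ms)
        # peak of (1-e^(-t/a))e^(-t/b) is at t* = a*ln(1 + b/a)
        t_peak = self.tau_rise_ms * np.log1p(self.tau_decay_ms / self.tau_rise_ms)
        peak = (1.0 - np.exp(-t_peak / self.tau_rise_ms)) * np.exp(-t_peak / self.tau_decay_ms)
        out[pos] = raw / peak
        return out


@dataclass(frozen=True)
class TransientSpec:
    """Tonic level plus a list of burst/pause events for one modulator."""

    modulator: str
    tonic: float = 0.0
    events: tuple[TransientEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.modulator:
            raise ValueError("modulator key must be non-empty")
        if not 0.0 <= self.tonic <= 1.0:
            raise ValueError(f"tonic level must be in [0, 1], got {self.tonic}")
        object.__setattr__(self, "events", tuple(self.events))

    @classmethod
    def from_dict(cls, d: dict) -> "TransientSpec":
        events = tuple(
            TransientEvent(
                kind=e["kind"],
                onset_ms=float(e["onset_ms"]),
                amplitude=float(e["amplitude"]),
                tau_rise_ms=float(e.get("tau_rise_ms", 50.0)),
                tau_decay_ms=float(e.get("tau_decay_ms", 300.0)),
            )
            for e in d.get("events", [])
        )
        return cls(modulator=d["modulator"], tonic=float(d.get("tonic", 0.0)), events=events)

    def to_dict(self) -> dict:
        return {
            "modulator": self.modulator,
            "tonic": self.tonic,
            "events": [
                {
                    "kind": e.kind,
                    "onset_ms": e.onset_ms,
                    "amplitude": e.amplitude,
                    "tau_rise_ms": e.tau_rise_ms,
                    "tau_decay_ms": e.tau_decay_ms,
                }
                for e in self.events
            ],
        }


@dataclass
class LevelArray:
    """Discretized modulation level trace: one value in [0, 1] per step of ``dt_ms``."""

    dt_ms: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.dt_ms <= 0.0:
            raise ValueError("dt must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("level array must be one-dimensional")
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ValueError("level values must lie in [0, 1]")

    @property
    def duration_ms(self) -> float:
        return self.dt_ms * self.values.size

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt_ms

    def resample(self, dt_ms: float, n_steps: int, fill: float | None = None) -> "LevelArray":
        """Zero-order-hold resample onto a grid of ``n_steps`` steps of ``dt_ms``.

        Samples beyond the end of the array hold ``fill`` (defaults to the last
        value, or 0 for an empty array).
        """
        if fill is None:
            fill = float(self.values[-1]) if self.values.size else 0.0
        idx = np.floor(np.arange(n_steps) * dt_ms / self.dt_ms).astype(np.int64)
        out = np.full(n_steps, fill, dtype=float)
        valid = idx < self.values.size
        out[valid] = self.values[idx[valid]]
        return LevelArray(dt_ms=dt_ms, values=out)

    def to_csv(self, path) -> None:
        """Write as two-column CSV (time_ms, level)."""
        arr = np.column_stack([self.times_ms, self.values])
        np.savetxt(path, arr, fmt="%.6f", delimiter=",", header="time_ms,level", comments="")

    @classmethod
    def from_csv(cls, path) -> "LevelArray":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if arr.shape[1] != 2:
            raise ValueError("level CSV must have two columns: time_ms, level")
        t, v = arr[:, 0], arr[:, 1]
        if len(t) < 2:
            raise ValueError("level CSV needs at least two samples to infer dt")
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("level CSV must be uniformly sampled")
        return cls(dt_ms=float(dts[0]), values=v)


def build_transient(spec: TransientSpec, duration_ms: float, dt_ms: float) -> LevelArray:
    """Evaluate a transient spec on a uniform grid.

    ``level(t) = clip(tonic + sum_events sign * A * kernel(t - onset), 0, 1)``
    with sign +1 for bursts and -1 for pauses.
    """
    if dt_ms <= 0.0 or duration_ms <= 0.0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration_ms / dt_ms))
    t = np.arange(n) * dt_ms
    level = np.full(n, spec.tonic, dtype=float)
    for ev in spec.events:
        level += ev.sign * ev.amplitude * ev.kernel(t)
    return LevelArray(dt_ms=dt_ms, values=np.clip(level, 0.0, 1.0))


def shift_transient(arr: LevelArray, delta_ms: float) -> LevelArray:
    """Time-shifted copy (positive delta = later), padded with the boundary value.

    Length is unchanged; samples shifted in from outside the original support
    take the first (for positive delta) or last (negative delta) value, which
    for a tonic-baseline transient is the tonic level.
    """
    if abs(delta_ms) >= arr.duration_ms:
        raise ValueError("|delta| must be smaller than the array duration")
    k = int(round(delta_ms / arr.dt_ms))
    v = arr.values
    out = np.empty_like(v)
    if k >= 0:
        out[k:] = v[: v.size - k]
        out[:k] = v[0]
    else:
        out[:k] = v[-k:]
        out[k:] = v[-1]
    return LevelArray(dt_ms=arr.dt_ms, values=out)


def timing_sweep(
    spec: TransientSpec,
    duration_ms: float,
    dt_ms: float,
    delays_ms: Sequence[float] = TIMING_SWEEP_DELAYS_MS,
) -> dict[float, LevelArray]:
    """Build the delay sweep used to probe modulation timing against a stimulus.

    Returns one shifted copy of the base transient per delay; the default
    preset covers {-500, -300, -100, +100, +300, +500} ms.
    """
    base = build_transient(spec, duration_ms, dt_ms)
    return {float(d): shift_transient(base, float(d)) for d in delays_ms}
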