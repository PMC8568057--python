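"""Population activity metrics from spike rasters.

Activity during a stimulation window is summarized by the percentage of
neurons of a type that spike at least once and by the population mean firing
rate.  Windows are half-open ``[t0, t1)`` so adjacent windows never double
count a spike.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeRaster", "percent_spiking", "mean_rate", "summarize"]


@dataclass
class SpikeRaster:
    """Spike (time, neuron id) pairs plus the population roster (id -> type)."""

    times_ms: np.ndarray
    gids: np.ndarray
    roster: dict[int, str]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.gids = np.asarray(self.gids, dtype=np.int64)
        if self.times_ms.shape != self.gids.shape:
            raise ValueError("times and gids must have equal length")
        if self.gids.size and not set(np.unique(self.gids)).issubset(self.roster):
            unknown = sorted(set(np.unique(self.gids)) - set(self.roster))[:5]
            raise ValueError(f"spikes reference ids absent from roster, e.g. {unknown}")

    @classmethod
    def from_simulation(cls, result) -> "SpikeRaster":
        return cls(result.spike_times_ms, result.spike_gids, result.roster)

    @classmethod
    def from_files(cls, spikes_path, roster_path) -> "SpikeRaster":
        """Load from two-column whitespace spike text and a roster JSON."""
        text = Path(spikes_path).read_text().strip()
        if not text:
            t, g = np.empty(0), np.empty(0, np.int64)
        else:
            arr = np.loadtxt(spikes_path, ndmin=2)
            t, g = arr[:, 0], arr[:, 1].astype(np.int64)
        roster = {int(k): v for k, v in json.loads(Path(roster_path).read_text()).items()}
        return cls(t, g, roster)

    def ids_of(self, cell_type: str) -> np.ndarray:
        return np.array([i for i, t in self.roster.items() if t == cell_type],
                        dtype=np.int64)

    def cell_types(self) -> list[str]:
        seen = {}
        for t in self.roster.values():
            seen.setdefault(t, None)
        return list(seen)


def _window_mask(raster: SpikeRaster, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if not t0 < t1:
        raise ValueError(f"window must satisfy t0 < t1, got [{t0}, {t1})")
    return (raster.times_ms >= t0) & (raster.times_ms < t1)


def percent_spiking(raster: SpikeRaster, cell_type: str,
                    window: tuple[float, float]) -> float:
    """Percentage of neurons of ``cell_type`` with >= 1 spike in ``[t0, t1)``."""
    ids = raster.ids_of(cell_type)
    if ids.size == 0:
        raise ValueError(f"roster contains no neurons of type {cell_type!r}")
    mask = _window_mask(raster, window)
    active = np.intersect1d(np.unique(raster.gids[mask]), ids)
    return 100.0 * active.size / ids.size


def mean_rate(raster: SpikeRaster, cell_type: str,
              window: tuple[float, float]) -> float:
    """Population mean firing rate (Hz) of ``cell_type`` in ``[t0, t1)``.

    Total spikes of the type divided by (type count x window length); silent
    neurons count in the denominator.
    """
    ids = raster.ids_of(cell_type)
    if ids.size == 0:
        raise ValueError(f"roster contains no neurons of type {cell_type!r}")
    mask = _window_mask(raster, window)
    n_spikes = np.count_nonzero(np.isin(raster.gids[mask], ids))
    return n_spikes / (ids.size * (window[1] - window[0]) / 1000.0)


def summarize(
    scenarios: dict[str, SpikeRaster], window: tuple[float, float]
) -> pd.DataFrame:
    """Tidy per-scenario, per-type metric table.

    All rasters must share the same roster; rows are ordered by scenario name
    then roster type order.
    """
    names = list(scenarios)
    if not names:
        raise ValueError("no scenarios given")
    ref = scenarios[names[0]]
    for name in names[1:]:
        if scenarios[name].roster != ref.roster:
            raise ValueError(f"scenario {name!r} has a mismatched roster")
    rows = []
    for name in names:
        raster = scenarios[name]
        for ct in ref.cell_types():
            rows.append(
                {
                    "scenario": name,
                    "cell_type": ct,
                    "percent_spiking": percent_spiking(raster, ct, window),
                    "mean_rate_hz": mean_rate(raster, ct, window),
                }
            )
    return pd.DataFrame(rows)
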