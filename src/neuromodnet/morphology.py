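"""Compartment trees: SWC parsing and built-in ball-and-stick morphologies.

Compartments are cylinders with a region tag (``soma``, ``dendrite`` with an
optional basal/apical sub-tag, or ``axon``).  The tree is stored root-first
(every compartment's parent index is smaller than its own), which is the
ordering the implicit cable solver relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Compartment", "Morphology", "load_swc", "ball_and_stick"]

_SWC_REGION = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}
_SWC_SUBREGION = {3: "basal", 4: "apical"}


@dataclass(frozen=True)
class Compartment:
    """One cylindrical compartment.

    ``length_um`` and ``diam_um`` give the geometry; ``ra_ohm_cm`` is the axial
    resistivity and ``cm_uf_cm2`` the specific membrane capacitance.  ``parent``
    is the index of the parent compartment (-1 for the root soma).
    """

    region: str
    length_um: float
    diam_um: float
    parent: int
    ra_ohm_cm: float = 150.0
    cm_uf_cm2: float = 1.0
    subregion: str | None = None  # "basal" / "apical" for dendrites

    def __post_init__(self) -> None:
        if self.region not in ("soma", "dendrite", "axon"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.length_um <= 0 or self.diam_um <= 0:
            raise ValueError("compartment geometry must be strictly positive")
        if self.ra_ohm_cm <= 0 or self.cm_uf_cm2 <= 0:
            raise ValueError("passive properties must be strictly positive")

    @property
    def area_cm2(self) -> float:
        """Lateral membrane area in cm^2 (1 um^2 = 1e-8 cm^2)."""
        return math.pi * self.diam_um * self.length_um * 1e-8

    @property
    def axial_half_resistance_mohm(self) -> float:
        """Axial resistance of half the cylinder, in MOhm."""
        r_cm = self.diam_um * 1e-4 / 2.0
        half_l_cm = self.length_um * 1e-4 / 2.0
        return self.ra_ohm_cm * half_l_cm / (math.pi * r_cm**2) * 1e-6


@dataclass
class Morphology:
    """Root-first compartment tree with precomputed cable quantities."""

    compartments: list[Compartment]

    def __post_init__(self) -> None:
        comps = self.compartments
        if not comps:
            raise ValueError("morphology needs at least one compartment")
        roots = [i for i, c in enumerate(comps) if c.parent < 0]
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("morphology must have exactly one root at index 0 (the soma)")
        if comps[0].region != "soma":
            raise ValueError("root compartment must be the soma")
        for i, c in enumerate(comps[1:], start=1):
            if not 0 <= c.parent < i:
                raise ValueError(
                    f"compartment {i} has parent {c.parent}; tree must be ordered root-first"
                )

    def __len__(self) -> int:
        return len(self.compartments)

    @property
    def parents(self) -> np.ndarray:
        return np.array([c.parent for c in self.compartments], dtype=np.int64)

    @property
    def areas_cm2(self) -> np.ndarray:
        return np.array([c.area_cm2 for c in self.compartments])

    @property
    def capacitances_nf(self) -> np.ndarray:
        """Per-compartment membrane capacitance in nF."""
        return np.array([c.cm_uf_cm2 * c.area_cm2 * 1e3 for c in self.compartments])

    @property
    def axial_conductances_us(self) -> np.ndarray:
        """Conductance (uS) coupling each compartment to its parent (0 for root)."""
        g = np.zeros(len(self.compartments))
        for i, c in enumerate(self.compartments):
            if c.parent < 0:
                continue
            p = self.compartments[c.parent]
            r_mohm = c.axial_half_resistance_mohm + p.axial_half_resistance_mohm
            g[i] = 1.0 / r_mohm  # 1/MOhm = uS
        return g

    def region_indices(self, region: str) -> np.ndarray:
        """Compartment indices for ``soma``/``dendrite``/``axon``, or a tagged
        sub-region ``basal_dendrite``/``apical_dendrite``."""
        if region in ("basal_dendrite", "apical_dendrite"):
            sub = region.split("_")[0]
            return np.array(
                [
                    i
                    for i, c in enumerate(self.compartments)
                    if c.region == "dendrite" and c.subregion == sub
                ],
                dtype=np.int64,
            )
        if region not in ("soma", "dendrite", "axon"):
            raise ValueError(f"unknown region {region!r}")
        return np.array(
            [i for i, c in enumerate(self.compartments) if c.region == region], dtype=np.int64
        )

    def region_counts(self) -> dict[str, int]:
        out = {"soma": 0, "dendrite": 0, "axon": 0}
        for c in self.compartments:
            out[c.region] += 1
        return out


class SWCError(ValueError):
    """Malformed SWC content; the message carries the offending line number."""


def load_swc(text: str, ra_ohm_cm: float = 150.0, cm_uf_cm2: float = 1.0) -> Morphology:
    """Parse standard 7-column SWC text into a compartment tree.

    Each non-root SWC point becomes a cylinder from its parent's coordinates to
    its own, with the point's radius; the root (parent -1, type 1) becomes the
    soma compartment with length equal to its diameter.  Type codes: 1 soma,
    2 axon, 3 basal dendrite, 4 apical dendrite (3 and 4 both map to region
    ``dendrite`` and keep a basal/apical sub-tag for region-specific
    modulation).
    """
    points: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(fields)}")
        try:
            idx = int(fields[0])
            tcode = int(fields[1])
            x, y, z, r = (float(f) for f in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from exc
        if tcode not in _SWC_REGION:
            raise SWCError(f"line {lineno}: unknown SWC type code {tcode}")
        if idx in points:
            raise SWCError(f"line {lineno}: duplicate sample id {idx}")
        if r <= 0:
            raise SWCError(f"line {lineno}: radius must be positive")
        points[idx] = (tcode, x, y, z, r, parent)
        order.append(idx)

    roots = [i for i in order if points[i][5] == -1]
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root point (parent -1), found {len(roots)}")
    root = roots[0]
    if points[root][0] != 1:
        raise SWCError("root point must have type code 1 (soma)")

    # topological order with cycle detection
    new_index: dict[int, int] = {}
    comps: list[Compartment] = []
    tcode, x0, y0, z0, r0, _ = points[root]
    comps.append(
        Compartment(
            region="soma",
            length_um=2 * r0,
            diam_um=2 * r0,
            parent=-1,
            ra_ohm_cm=ra_ohm_cm,
            cm_uf_cm2=cm_uf_cm2,
        )
    )
    new_index[root] = 0

    pending = [i for i in order if i != root]
    while pending:
        progressed = False
        remaining = []
        for idx in pending:
            tcode, x, y, z, r, parent = points[idx]
            if parent not in points:
                raise SWCError(f"sample {idx}: parent {parent} does not exist")
            if parent not in new_index:
                remaining.append(idx)
                continue
            px, py, pz = points[parent][1:4]
            length = math.dist((x, y, z), (px, py, pz))
            if length <= 0:
                length = 2 * r  # zero-length segment: fall back to a stub
            comps.append(
                Compartment(
                    region=_SWC_REGION[tcode],
                    length_um=length,
                    diam_um=2 * r,
                    parent=new_index[parent],
                    ra_ohm_cm=ra_ohm_cm,
                    cm_uf_cm2=cm_uf_cm2,
                    subregion=_SWC_SUBREGION.get(tcode),
                )
            )
            new_index[idx] = len(comps) - 1
            progressed = True
        if not progressed:
            raise SWCError(f"cyclic or unreachable parent links among samples {sorted(remaining)}")
        pending = remaining

    return Morphology(comps)


def ball_and_stick(
    soma_diam_um: float = 18.0,
    n_dend: int = 2,
    dend_length_um: float = 120.0,
    dend_diam_um: float = 2.0,
    axon_length_um: float = 60.0,
    axon_diam_um: float = 1.0,
    ra_ohm_cm: float = 150.0,
    cm_uf_cm2: float = 1.0,
) -> Morphology:
    """Soma + dendritic chain + one axonal compartment (the surrogate layout)."""
    comps = [
        Compartment("soma", soma_diam_um, soma_diam_um, -1, ra_ohm_cm, cm_uf_cm2)
    ]
    parent = 0
    for _ in range(n_dend):
        comps.append(
            Compartment(
                "dendrite", dend_length_um, dend_diam_um, parent, ra_ohm_cm, cm_uf_cm2,
                subregion="basal",
            )
        )
        parent = len(comps) - 1
    comps.append(Compartment("axon", axon_length_um, axon_diam_um, 0, ra_ohm_cm, cm_uf_cm2))
    return Morphology(comps)
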