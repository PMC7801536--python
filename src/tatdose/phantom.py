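"""Hounsfield-unit to tissue conversion (stoichiometric calibration).

A CT volume is converted to a voxel phantom carrying mass density and a
coarse material class per voxel, using a piecewise-linear HU-to-density
correlation of the Schneider type.  The default material table is reduced
to four classes (air, lung, soft tissue, bone) -- the simplified photon
dose engine only needs density plus coarse attenuation properties -- and a
finer bin table can be loaded from JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .volumes import CTVolume, VoxelPhantom

__all__ = ["MaterialTable", "hu_to_density", "hu_to_material", "build_phantom"]

HU_MIN, HU_MAX = -1024.0, 3000.0

#: Piecewise-linear HU -> density anchors (HU, g/cm^3); monotone.
#: Air at -1000 HU, inflated lung around -740, adipose -98, water 0,
#: soft-tissue/bone transition above ~100, skeletal densities beyond.
DENSITY_ANCHORS = (
    (-1024.0, 0.00121),
    (-1000.0, 0.00121),
    (-740.0, 0.26),
    (-98.0, 0.93),
    (0.0, 1.0),
    (100.0, 1.075),
    (2000.0, 1.92),
    (3000.0, 2.3),
)


@dataclass(frozen=True)
class MaterialTable:
    """HU bin edges and class names; HU below the first edge is class 0."""

    edges: tuple[float, ...] = (-950.0, -200.0, 120.0)
    names: tuple[str, ...] = ("air", "lung", "soft_tissue", "bone")

    def __post_init__(self) -> None:
        if len(self.names) != len(self.edges) + 1:
            raise ValueError("need one more class name than bin edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be increasing")

    @classmethod
    def from_json(cls, path: str | Path) -> "MaterialTable":
        raw = json.loads(Path(path).read_text())
        return cls(edges=tuple(raw["edges"]), names=tuple(raw["names"]))


DEFAULT_MATERIALS = MaterialTable()


def hu_to_density(hu, counters: Optional[dict] = None):
    """Mass density (g/cm^3) from Hounsfield units, piecewise linear and
    monotone; out-of-range HU values are clamped (counted if a counters
    dict is passed)."""
    h = np.asarray(hu, dtype=float)
    n_clamped = int(np.count_nonzero((h < HU_MIN) | (h > HU_MAX)))
    if counters is not None:
        counters["hu_clamped"] = counters.get("hu_clamped", 0) + n_clamped
    hc = np.clip(h, HU_MIN, HU_MAX)
    xs = np.array([a[0] for a in DENSITY_ANCHORS])
    ys = np.array([a[1] for a in DENSITY_ANCHORS])
    out = np.interp(hc, xs, ys)
    return float(out) if out.ndim == 0 else out


def hu_to_material(hu, table: MaterialTable = DEFAULT_MATERIALS):
    """Material class index from HU via the (configurable) bin table."""
    h = np.clip(np.asarray(hu, dtype=float), HU_MIN, HU_MAX)
    idx = np.digitize(h, table.edges)
    return int(idx) if idx.ndim == 0 else idx.astype(np.uint8)


def build_phantom(ct: CTVolume, table: MaterialTable = DEFAULT_MATERIALS) -> VoxelPhantom:
    """Voxelwise density/material phantom at the CT resolution."""
    counters: dict = {}
    density = hu_to_density(ct.hu, counters)
    material = hu_to_material(ct.hu, table)
    return VoxelPhantom(
        density=density,
        material=material,
        spacing_mm=ct.spacing_mm,
        affine=ct.affine,
        meta={"materials": list(table.names), **counters},
    )
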