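"""Shared volumetric containers and NIfTI I/O helpers.

Convention used by every module: voxel indices are 0-based with half-open
voxel extents; world coordinates come from the NIfTI affine; spacing is in
mm.  Maps written to disk are float32 NIfTI with a JSON sidecar for
provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units."""

    hu: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError("CT volume must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing_mm) + [1.0])

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0


@dataclass
class VoxelPhantom:
    """Voxelized patient/phantom model derived from CT."""

    density: np.ndarray  # g/cm^3
    material: np.ndarray  # material class index
    spacing_mm: tuple[float, float, float]
    affine: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.affine is None:
            self.affine = np.diag(list(self.spacing_mm) + [1.0])

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    @property
    def mass_kg(self) -> np.ndarray:
        """Per-voxel mass: density x voxel volume (g -> kg)."""
        return self.density * self.voxel_volume_cm3 * 1e-3

    @property
    def total_mass_kg(self) -> float:
        return float(self.mass_kg.sum())


@dataclass
class DoseMaps:
    """Absorbed-dose maps, Gy per voxel; photons are tallied into the beta
    component through their secondary electrons."""

    dose_alpha: np.ndarray
    dose_beta: np.ndarray
    e_dep_mev: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.dose_alpha + self.dose_beta


@dataclass
class VoxelField:
    """Co-registered per-voxel maps feeding the EQDX stage."""

    dose_alpha: np.ndarray
    dose_beta: np.ndarray
    cumulated_bqh: np.ndarray
    lambda_bio: np.ndarray
    phantom: VoxelPhantom

    def __post_init__(self) -> None:
        shape = self.dose_alpha.shape
        for name in ("dose_beta", "cumulated_bqh", "lambda_bio"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} map is not co-registered")
        if self.phantom.density.shape != shape:
            raise ValueError("phantom is not co-registered with the dose maps")


def save_nifti(
    data: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    sidecar: Optional[dict] = None,
) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Load a NIfTI volume; returns (data, affine, spacing_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, spacing
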