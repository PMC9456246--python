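"""Core in-memory containers for 3D confocal data.

A confocal z-stack is held as a :class:`VoxelStack`: one channel's 3D
brightness grid indexed ``(z, y, x)`` together with the physical voxel
spacing in nanometres.  Detected structures (nuclei, FISH loci,
chromosome territories) are represented by :class:`NucleusModel` and
:class:`DetectedObject`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelStack", "NucleusModel", "DetectedObject"]


@dataclass
class VoxelStack:
    """One channel of a 3D confocal series.

    Parameters
    ----------
    values
        Non-negative brightness grid indexed ``(z, y, x)``, 0-based.
    spacing
        Physical voxel spacing ``(dz, dy, dx)`` in nanometres; all
        strictly positive.  Axial (z) spacing is typically several-fold
        coarser than lateral spacing and all physical distances honour
        this anisotropy.
    channel
        Free-form channel label (e.g. ``"dna"``, ``"probe1"``).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelStack requires a 3D (z, y, x) array")
        if any(d < 1 for d in self.values.shape):
            raise ValueError("every axis must have at least one plane")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values (nm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "VoxelStack":
        return VoxelStack(self.values.copy(), self.spacing, self.channel)


@dataclass
class NucleusModel:
    """Cylindrical nucleus model, axis parallel to the optical (z) axis.

    ``center_xy`` is the continuous (y, x) centre in voxel units,
    ``radius`` the cylinder radius in voxels and ``z_range`` the
    inclusive range of voxel planes spanned by the nucleus.
    """

    center_xy: tuple[float, float]
    radius: float
    z_range: tuple[int, int]
    total_brightness: float = 0.0
    stable: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.z_range[0] > self.z_range[1]:
            raise ValueError("z_range must satisfy z_lo <= z_hi")

    @property
    def n_planes(self) -> int:
        return self.z_range[1] - self.z_range[0] + 1

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean voxel mask of the cylinder on a grid of ``shape``."""
        nz, ny, nx = shape
        cy, cx = self.center_xy
        yy, xx = np.ogrid[:ny, :nx]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2
        out = np.zeros(shape, dtype=bool)
        z_lo = max(0, self.z_range[0])
        z_hi = min(nz - 1, self.z_range[1])
        out[z_lo : z_hi + 1] = disc
        return out

    def contains(self, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        cy, cx = self.center_xy
        inside_disc = (y - cy) ** 2 + (x - cx) ** 2 <= self.radius**2
        return inside_disc & (z >= self.z_range[0]) & (z <= self.z_range[1])


@dataclass
class DetectedObject:
    """A connected set of voxels with per-voxel brightness weights.

    Used for both FISH loci and chromosome territories; ``voxels`` is an
    ``(n, 3)`` integer array of ``(z, y, x)`` indices and ``weights`` the
    matching strictly positive brightness values.
    """

    voxels: np.ndarray
    weights: np.ndarray
    channel: str = ""
    nucleus_id: int = -1
    object_id: int = -1

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.int64))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.voxels.shape[0] == 0:
            raise ValueError("DetectedObject requires at least one voxel")
        if self.voxels.shape[0] != self.weights.shape[0]:
            raise ValueError("voxels and weights must have matching length")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def total_brightness(self) -> float:
        return float(self.weights.sum())

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.voxels.tolist()}
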