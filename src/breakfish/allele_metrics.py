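"""Allele pairing and distance measurements for break-apart FISH.

A break-apart assay labels two regions flanking a gene with different
fluorophores ("green"/probe-1 and "red"/probe-2).  In an intact allele
the two signals nearly colocalize; a double-strand break between the
probes lets the signals drift apart.  This module turns detected
objects into point loci (brightness-weighted centroids in physical nm),
pairs cross-channel signals into alleles by mutual nearest neighbours,
measures inter-signal distances and signed distances to the chromosome
territory boundary, and applies the cell-level quality filters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stack import DetectedObject, NucleusModel

__all__ = [
    "LocusPoint",
    "AllelePair",
    "CellRecord",
    "weighted_centroid",
    "pair_loci",
    "pair_distance",
    "signed_territory_distance",
    "apply_distance_cutoff",
    "qc_cell",
]


@dataclass
class LocusPoint:
    """A FISH signal reduced to its brightness-weighted centre of mass.

    ``position`` is (x, y, z) in nm; ``channel`` identifies the probe.
    """

    position: np.ndarray
    channel: str
    object_ref: int = -1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).ravel()
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite (x, y, z) triple in nm")


@dataclass
class AllelePair:
    """A matched probe-1/probe-2 signal pair (one allele)."""

    locus1: LocusPoint
    locus2: LocusPoint
    pair_distance: float = float("nan")
    territory_dist1: float = float("nan")
    territory_dist2: float = float("nan")
    broken: bool | None = None
    cell_id: int = -1


@dataclass
class CellRecord:
    """Per-cell detection results plus QC verdict."""

    cell_id: int
    nucleus: NucleusModel | None = None
    loci1: list[LocusPoint] = field(default_factory=list)
    loci2: list[LocusPoint] = field(default_factory=list)
    territories: list[DetectedObject] = field(default_factory=list)
    pairs: list[AllelePair] = field(default_factory=list)
    qc_pass: bool = False
    qc_reason: str = ""


def weighted_centroid(
    obj: DetectedObject, spacing: tuple[float, float, float], channel: str | None = None
) -> LocusPoint:
    """Brightness-weighted centre of mass of an object, in physical nm.

    position = sum(w_i * coord_i) / sum(w_i), with coord = voxel index
    scaled by the per-axis spacing (dz, dy, dx).
    """
    w = obj.weights
    total = w.sum()
    if total <= 0:
        raise ValueError("all voxel weights are zero; centroid undefined")
    dz, dy, dx = spacing
    zyx = (obj.voxels * np.array([dz, dy, dx])) * w[:, None] / total
    z, y, x = zyx.sum(axis=0)
    return LocusPoint(
        position=np.array([x, y, z]),
        channel=channel if channel is not None else obj.channel,
        object_ref=obj.object_id,
    )


def pair_distance(pair: AllelePair) -> float:
    """Euclidean distance between the pair's two centroids, in nm."""
    return float(np.linalg.norm(pair.locus1.position - pair.locus2.position))


def pair_loci(
    greens: list[LocusPoint], reds: list[LocusPoint]
) -> tuple[list[tuple[LocusPoint, LocusPoint]], list[LocusPoint]]:
    """Match cross-channel signals into pairs by mutual nearest neighbours.

    Greedy extraction: repeatedly take the globally closest
    (green, red) pair, remove both points, and repeat until one side is
    exhausted.  Every returned pair is mutually nearest among the points
    remaining when it was extracted, so the output is symmetric in the
    channel labels.  Returns (pairs, leftovers).
    """
    if not greens or not reds:
        return [], list(greens) + list(reds)
    g_pos = np.array([g.position for g in greens])
    r_pos = np.array([r.position for r in reds])
    dists = np.linalg.norm(g_pos[:, None, :] - r_pos[None, :, :], axis=2)
    g_alive = list(range(len(greens)))
    r_alive = list(range(len(reds)))
    pairs: list[tuple[LocusPoint, LocusPoint]] = []
    while g_alive and r_alive:
        sub = dists[np.ix_(g_alive, r_alive)]
        gi, ri = np.unravel_index(int(np.argmin(sub)), sub.shape)
        pairs.append((greens[g_alive[gi]], reds[r_alive[ri]]))
        del g_alive[gi]
        del r_alive[ri]
    leftovers = [greens[i] for i in g_alive] + [reds[j] for j in r_alive]
    return pairs, leftovers


def _boundary_voxels(territory: DetectedObject) -> np.ndarray:
    """Boundary voxels: members with >= 1 non-member face (6-)neighbour.

    Face connectivity keeps the crust one axis-step thick.  With
    anisotropic spacing a diagonal (26-neighbour) definition would mark
    voxels up to a full voxel diagonal inside the surface as boundary,
    biasing inside distances low by several hundred nm.
    """
    vox = territory.voxels
    lo = vox.min(axis=0) - 1
    shape = tuple(vox.max(axis=0) - lo + 3)
    mask = np.zeros(shape, dtype=bool)
    idx = vox - lo
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1)
    )
    boundary = mask & ~eroded
    zz, yy, xx = np.nonzero(boundary)
    return np.stack([zz, yy, xx], axis=1) + lo


def signed_territory_distance(
    point: LocusPoint,
    territory: DetectedObject,
    spacing: tuple[float, float, float],
) -> float:
    """Signed distance (nm) from a locus point to the territory boundary.

    The three boundary-voxel centres nearest to the point define a local
    tangent plane; the unsigned distance is the point-to-plane distance.
    The sign is positive when the locus lies outside the territory and
    negative when inside, decided by voxel membership of the point's
    nearest voxel index (robust to concave territories).

    The plane refines the nearest-boundary-point distance (it removes
    the lateral quantization offset of the nearest voxel centre), so it
    is trusted only when it agrees with that distance to within a
    quarter voxel diagonal.  Triples that disagree more — collinear
    points, lattice planes through the query point, secant planes
    through a curved surface far from the query — are quantization
    artifacts, and the nearest-point distance (itself accurate to about
    half a diagonal) is used instead.
    """
    dz, dy, dx = spacing
    diag = math.sqrt(dz * dz + dy * dy + dx * dx)
    p_nm = point.position  # (x, y, z)
    bnd = _boundary_voxels(territory)
    bnd_nm = np.stack([bnd[:, 2] * dx, bnd[:, 1] * dy, bnd[:, 0] * dz], axis=1)
    d2 = np.sum((bnd_nm - p_nm) ** 2, axis=1)
    # deterministic tie-break: stable sort on (distance, z, y, x)
    order = np.lexsort((bnd[:, 2], bnd[:, 1], bnd[:, 0], d2))
    d_near = math.sqrt(float(d2[order[0]]))
    if len(bnd) < 3:
        warnings.warn("territory has fewer than 3 boundary voxels; nearest-point fallback")
        dist = d_near
    else:
        tri = bnd_nm[order[:3]]
        normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        norm = np.linalg.norm(normal)
        if norm < 1e-9:  # collinear triple
            dist = d_near
        else:
            dist = abs(float(np.dot(p_nm - tri[0], normal / norm)))
            if dist < d_near - 0.25 * diag:  # degenerate (secant) triple
                dist = d_near
    # inside/outside by membership of the nearest voxel index
    nearest_idx = (
        int(round(p_nm[2] / dz)),
        int(round(p_nm[1] / dy)),
        int(round(p_nm[0] / dx)),
    )
    inside = nearest_idx in territory.voxel_set()
    return -dist if inside else dist


def nearest_territory_distance(
    point: LocusPoint,
    territories: list[DetectedObject],
    spacing: tuple[float, float, float],
) -> float:
    """Signed distance to the nearest territory (smallest |distance|)."""
    if not territories:
        raise ValueError("no territories supplied")
    dists = [signed_territory_distance(point, t, spacing) for t in territories]
    return min(dists, key=abs)


def apply_distance_cutoff(
    pairs: list[AllelePair], cutoff: float = 2000.0
) -> tuple[list[AllelePair], list[AllelePair]]:
    """Drop pairs whose signals sit implausibly far apart.

    A pair is removed when its inter-signal distance exceeds ``cutoff``
    (default 2000 nm) or when either locus lies farther than ``cutoff``
    from the territory boundary (|signed distance|) — such cases are
    recognition errors, not biology.  Returns (kept, removed).
    """
    kept: list[AllelePair] = []
    removed: list[AllelePair] = []
    for p in pairs:
        too_far = p.pair_distance > cutoff
        for td in (p.territory_dist1, p.territory_dist2):
            if np.isfinite(td) and abs(td) > cutoff:
                too_far = True
        (removed if too_far else kept).append(p)
    return kept, removed


def qc_cell(cell: CellRecord, cutoff: float = 2000.0) -> CellRecord:
    """Apply the cell-retention rules and set ``qc_pass``/``qc_reason``.

    A cell is retained iff it has exactly two probe-1 and two probe-2
    objects (two alleles), one or two chromosome territories (two
    territories may merge into one), and both mutually-nearest pairs
    survive the distance cutoff.  ``qc_reason`` records the first
    failing rule.
    """
    if len(cell.loci1) != 2 or len(cell.loci2) != 2:
        cell.qc_pass = False
        cell.qc_reason = "locus count"
        return cell
    if not 1 <= len(cell.territories) <= 2:
        cell.qc_pass = False
        cell.qc_reason = "territory count"
        return cell
    if len(cell.pairs) != 2:
        cell.qc_pass = False
        cell.qc_reason = "pairing"
        return cell
    kept, _ = apply_distance_cutoff(cell.pairs, cutoff)
    if len(kept) != 2:
        cell.qc_pass = False
        cell.qc_reason = "distance cutoff"
        return cell
    cell.qc_pass = True
    cell.qc_reason = ""
    return cell
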