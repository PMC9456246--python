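"""Synthetic multi-channel 3D FISH z-stacks with known ground truth.

The generator emulates the imaging geometry of a break-apart FISH
experiment on coverslip-flattened nuclei: a DNA counterstain channel in
which nuclei appear as bright cylinders (axis along the optical z axis),
two probe channels carrying diffraction-limited Gaussian spots (one
spot per allele and probe), and a whole-chromosome-paint channel with
blurred territory blobs.  Additive Gaussian background plus isolated
single-voxel speckles provide the noise floor the despeckling filter is
designed to remove.

Every random choice flows from a single integer seed, so regenerating
with the same parameters is numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..stack import VoxelStack
from .cohort import DEFAULT_INTACT, DistSpec

__all__ = [
    "FishGeometry",
    "FishLayout",
    "FishNoise",
    "NucleusTruth",
    "LocusTruth",
    "TerritoryTruth",
    "FishTruth",
    "make_fish_stack",
]

CHANNELS = ("dna", "probe1", "probe2", "paint")


@dataclass(frozen=True)
class FishGeometry:
    """Voxel grid and physical spacing of the simulated stack.

    Default 256 x 256 x 20 voxels at (dz, dy, dx) = (400, 200, 200) nm —
    a scaled-down field; full 1024 x 1024 acquisition geometry is
    supported by changing ``shape``.
    """

    shape: tuple[int, int, int] = (20, 256, 256)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (400.0, 200.0, 200.0)  # (dz, dy, dx) nm


@dataclass(frozen=True)
class FishLayout:
    """Cell/locus/territory layout parameters (all lengths in nm)."""

    n_nuclei: int = 10
    nucleus_radius_nm: float = 3000.0
    nucleus_height_nm: float = 4800.0
    nucleus_brightness: float = 1000.0
    alleles_per_nucleus: int = 2
    spot_sigma_nm: float = 250.0
    spot_amplitude: float = 8000.0
    territories_per_nucleus: int = 2
    territory_radius_nm: float = 1400.0
    territory_amplitude: float = 600.0
    territory_blur_vox: float = 1.5
    intact_dist: DistSpec = DEFAULT_INTACT
    broken_fraction: float = 0.0
    broken_shift_nm: float = 1500.0
    break_distance_nm: float = 1000.0
    outside_fraction: float = 0.0
    nucleus_centers_nm: tuple[tuple[float, float, float], ...] | None = None


@dataclass(frozen=True)
class FishNoise:
    """Background offset, Gaussian noise and single-voxel speckles."""

    background: float = 100.0
    gaussian_sd: float = 50.0
    speckle_rate: float = 1e-4
    speckle_amplitude: float = 4000.0


@dataclass
class NucleusTruth:
    nucleus_id: int
    center_nm: tuple[float, float, float]  # (x, y, z)
    radius_nm: float
    z_extent_nm: float


@dataclass
class LocusTruth:
    locus_id: int
    channel: str  # "probe1" | "probe2"
    position_nm: tuple[float, float, float]  # (x, y, z)
    allele_id: int
    nucleus_id: int
    planted_outside: bool


@dataclass
class TerritoryTruth:
    nucleus_id: int
    center_nm: tuple[float, float, float]
    radius_nm: float


@dataclass
class FishTruth:
    """Ground truth of a generated stack."""

    nuclei: list[NucleusTruth] = field(default_factory=list)
    loci: list[LocusTruth] = field(default_factory=list)
    territories: list[TerritoryTruth] = field(default_factory=list)
    planted_broken: dict[int, bool] = field(default_factory=dict)
    planted_outside: dict[int, bool] = field(default_factory=dict)
    pair_separation_nm: dict[int, float] = field(default_factory=dict)

    def validate(self, break_distance_nm: float) -> None:
        """Check the structural invariants of the truth table.

        Every locus must reference an existing nucleus and lie inside
        its cylinder; each allele must carry exactly one probe-1 and one
        probe-2 locus; ``planted_broken`` must hold exactly when the
        intra-allele separation exceeds the break-distance parameter.
        """
        by_id = {n.nucleus_id: n for n in self.nuclei}
        alleles: dict[int, dict[str, LocusTruth]] = {}
        for locus in self.loci:
            nuc = by_id.get(locus.nucleus_id)
            if nuc is None:
                raise ValueError(f"locus {locus.locus_id} references missing nucleus")
            x, y, z = locus.position_nm
            cx, cy, cz = nuc.center_nm
            lateral = (x - cx) ** 2 + (y - cy) ** 2
            if lateral > nuc.radius_nm**2 or abs(z - cz) > nuc.z_extent_nm / 2:
                raise ValueError(f"locus {locus.locus_id} lies outside its nucleus")
            alleles.setdefault(locus.allele_id, {})[locus.channel] = locus
        for allele_id, probes in alleles.items():
            if set(probes) != {"probe1", "probe2"}:
                raise ValueError(f"allele {allele_id} lacks a probe-1/probe-2 pair")
            sep = float(
                np.linalg.norm(
                    np.array(probes["probe1"].position_nm)
                    - np.array(probes["probe2"].position_nm)
                )
            )
            if self.planted_broken[allele_id] != (sep > break_distance_nm):
                raise ValueError(
                    f"allele {allele_id}: planted_broken inconsistent with separation"
                )


def _sample_nucleus_centers(
    rng: np.random.Generator, geometry: FishGeometry, layout: FishLayout
) -> list[tuple[float, float, float]]:
    nz, ny, nx = geometry.shape
    dz, dy, dx = geometry.spacing
    X, Y, Z = (nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz
    r = layout.nucleus_radius_nm
    h = layout.nucleus_height_nm
    margin = r + 2 * max(dx, dy)
    if 2 * margin >= min(X, Y):
        raise ValueError("field too small for the requested nucleus radius")
    if h + 2 * dz > Z:
        raise ValueError("stack too shallow for the requested nucleus height")
    if layout.nucleus_centers_nm is not None:
        centers = [tuple(map(float, c)) for c in layout.nucleus_centers_nm]
    else:
        centers = []
        min_sep = 2.0 * r * 1.1
        for _ in range(20000):
            if len(centers) == layout.n_nuclei:
                break
            cx = rng.uniform(margin, X - margin)
            cy = rng.uniform(margin, Y - margin)
            cz = rng.uniform(h / 2 + dz, Z - h / 2 - dz)
            if all((cx - ox) ** 2 + (cy - oy) ** 2 >= min_sep**2 for ox, oy, _ in centers):
                centers.append((cx, cy, cz))
        else:
            raise RuntimeError("could not place all nuclei without overlap")
    for i, (ax, ay, _) in enumerate(centers):
        for bx, by, _ in centers[:i]:
            if (ax - bx) ** 2 + (ay - by) ** 2 < (2 * r) ** 2:
                raise ValueError("overlapping nuclei: centers closer than sum of radii")
    return centers


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _add_spot(
    arr: np.ndarray,
    pos_nm: tuple[float, float, float],
    sigma_nm: float,
    amplitude: float,
    spacing: tuple[float, float, float],
) -> None:
    dz, dy, dx = spacing
    x, y, z = pos_nm
    nz, ny, nx = arr.shape
    rz = int(np.ceil(4 * sigma_nm / dz))
    ry = int(np.ceil(4 * sigma_nm / dy))
    rx = int(np.ceil(4 * sigma_nm / dx))
    kz, ky, kx = int(round(z / dz)), int(round(y / dy)), int(round(x / dx))
    z0, z1 = max(0, kz - rz), min(nz, kz + rz + 1)
    y0, y1 = max(0, ky - ry), min(ny, ky + ry + 1)
    x0, x1 = max(0, kx - rx), min(nx, kx + rx + 1)
    zz = (np.arange(z0, z1) * dz - z)[:, None, None]
    yy = (np.arange(y0, y1) * dy - y)[None, :, None]
    xx = (np.arange(x0, x1) * dx - x)[None, None, :]
    arr[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(
        -(zz**2 + yy**2 + xx**2) / (2 * sigma_nm**2)
    )


def make_fish_stack(
    geometry: FishGeometry | None = None,
    layout: FishLayout | None = None,
    noise: FishNoise | None = None,
    seed: int = 0,
) -> tuple[dict[str, VoxelStack], FishTruth]:
    """Render a 4-channel synthetic FISH stack and its ground truth.

    Returns ``(channels, truth)`` where ``channels`` maps
    ``dna/probe1/probe2/paint`` to :class:`VoxelStack`.  Each nucleus
    carries ``alleles_per_nucleus`` alleles; an allele is planted broken
    with probability ``broken_fraction`` (its probe separation is an
    intact draw plus ``broken_shift_nm``, always beyond
    ``break_distance_nm``).  A locus is planted outside the chromosome
    territory (but always inside the nucleus) with probability
    ``outside_fraction``.
    """
    from scipy import ndimage  # local import keeps module import light

    geometry = geometry or FishGeometry()
    layout = layout or FishLayout()
    noise = noise or FishNoise()
    rng = np.random.default_rng(seed)
    nz, ny, nx = geometry.shape
    dz, dy, dx = geometry.spacing
    if layout.nucleus_radius_nm < 2 * max(dx, dy) or layout.nucleus_height_nm < 2 * dz:
        raise ValueError("nucleus radius/height must span at least 2 voxels")
    if layout.spot_sigma_nm < 0.5 * min(dx, dy):
        raise ValueError("spot sigma below half a lateral voxel is unresolvable")

    arrays = {ch: np.zeros(geometry.shape, dtype=np.float64) for ch in CHANNELS}
    truth = FishTruth()

    centers = _sample_nucleus_centers(rng, geometry, layout)
    # voxel-center coordinate grids (nm)
    zz = (np.arange(nz) * dz)[:, None, None]
    yy = (np.arange(ny) * dy)[None, :, None]
    xx = (np.arange(nx) * dx)[None, None, :]

    r_nuc = layout.nucleus_radius_nm
    h = layout.nucleus_height_nm
    r_ter = layout.territory_radius_nm
    allele_id = 0
    locus_id = 0
    for nid, (cx, cy, cz) in enumerate(centers):
        truth.nuclei.append(NucleusTruth(nid, (cx, cy, cz), r_nuc, h))
        cyl = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r_nuc**2) & (np.abs(zz - cz) <= h / 2)
        arrays["dna"][cyl] += layout.nucleus_brightness

        # territories: spheres inside the nucleus cylinder
        lat_max = r_nuc - r_ter - 2 * dx
        z_half = max(h / 2 - r_ter - dz, 0.0)
        t_min_sep = 1200.0  # territories may overlap (and merge) but not coincide
        for _attempt in range(5000):
            t_centers = []
            for _ in range(layout.territories_per_nucleus):
                rho = lat_max * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                t_centers.append(
                    np.array(
                        [
                            cx + rho * np.cos(theta),
                            cy + rho * np.sin(theta),
                            cz + rng.uniform(-z_half, z_half),
                        ]
                    )
                )
            ok = all(
                np.linalg.norm(a - b) >= t_min_sep
                for i, a in enumerate(t_centers)
                for b in t_centers[:i]
            )
            if ok:
                break
        else:
            raise RuntimeError("could not place territories inside the nucleus")
        for tc in t_centers:
            truth.territories.append(TerritoryTruth(nid, tuple(tc), r_ter))
            ball = (xx - tc[0]) ** 2 + (yy - tc[1]) ** 2 + (zz - tc[2]) ** 2 <= r_ter**2
            arrays["paint"][ball] += layout.territory_amplitude

        # alleles: one probe-1 and one probe-2 spot each.  Broken flags and
        # separations are drawn once; the geometric placement of the whole
        # allele set is retried on constraint deadlock.
        allele_params = []
        for a in range(layout.alleles_per_nucleus):
            broken = bool(rng.random() < layout.broken_fraction)
            sep = float(layout.intact_dist.sample(rng, 1)[0])
            while sep > layout.break_distance_nm:
                sep = float(layout.intact_dist.sample(rng, 1)[0])
            if broken:
                sep += layout.broken_shift_nm
            out1 = bool(rng.random() < layout.outside_fraction)
            allele_params.append((broken, sep, out1))
        for _attempt in range(200):
            try:
                placements = _place_allele_set(
                    rng, allele_params, (cx, cy, cz), r_nuc, h,
                    geometry.spacing, t_centers, r_ter,
                )
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError("could not place alleles inside the nucleus")
        for a, ((broken, sep, _), (anchor, partner)) in enumerate(
            zip(allele_params, placements)
        ):
            for ch, pos in (("probe1", anchor), ("probe2", partner)):
                outside = _is_outside(pos, t_centers, r_ter)
                truth.loci.append(
                    LocusTruth(locus_id, ch, tuple(pos), allele_id, nid, outside)
                )
                truth.planted_outside[locus_id] = outside
                _add_spot(
                    arrays[ch], tuple(pos), layout.spot_sigma_nm,
                    layout.spot_amplitude, geometry.spacing,
                )
                locus_id += 1
            truth.planted_broken[allele_id] = broken
            truth.pair_separation_nm[allele_id] = sep
            allele_id += 1

    arrays["paint"] = ndimage.gaussian_filter(arrays["paint"], layout.territory_blur_vox)

    for ch in CHANNELS:
        arr = arrays[ch]
        arr += noise.background + rng.normal(0.0, noise.gaussian_sd, arr.shape)
        if noise.speckle_rate > 0:
            speckle = rng.random(arr.shape) < noise.speckle_rate
            arr[speckle] += noise.speckle_amplitude
        np.clip(arr, 0.0, None, out=arr)

    truth.validate(layout.break_distance_nm)
    channels = {
        ch: VoxelStack(arrays[ch], geometry.spacing, channel=ch) for ch in CHANNELS
    }
    return channels, truth


def _is_outside(pos: np.ndarray, t_centers: list[np.ndarray], r_ter: float) -> bool:
    return all(np.linalg.norm(pos - tc) > r_ter for tc in t_centers)


def _place_allele_set(
    rng: np.random.Generator,
    allele_params: list[tuple[bool, float, bool]],
    nucleus_center: tuple[float, float, float],
    r_nuc: float,
    height: float,
    spacing: tuple[float, float, float],
    t_centers: list[np.ndarray],
    r_ter: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Place every allele of one nucleus; raises on constraint deadlock."""
    anchors: list[np.ndarray] = []
    partners: list[np.ndarray] = []
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for a, (_broken, sep, want_outside) in enumerate(allele_params):
        terr = t_centers[a % len(t_centers)]
        anchor = _place_locus(
            rng, nucleus_center, r_nuc, height, spacing, terr, t_centers, r_ter,
            want_outside=want_outside, avoid=anchors, max_tries=500,
        )
        partner = _place_partner(
            rng, anchor, sep, nucleus_center, r_nuc, height, spacing,
            avoid=partners, max_tries=500,
        )
        anchors.append(anchor)
        partners.append(partner)
        out.append((anchor, partner))
    return out


def _place_locus(
    rng: np.random.Generator,
    nucleus_center: tuple[float, float, float],
    r_nuc: float,
    height: float,
    spacing: tuple[float, float, float],
    territory: np.ndarray,
    t_centers: list[np.ndarray],
    r_ter: float,
    want_outside: bool,
    avoid: list[np.ndarray],
    min_sep: float = 2000.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample a locus position inside the nucleus cylinder."""
    dz, dy, dx = spacing
    cx, cy, cz = nucleus_center
    lat_margin = 3 * max(dx, dy)
    z_margin = dz
    diag = float(np.linalg.norm([dz, dy, dx]))
    for _ in range(max_tries):
        if want_outside:
            rho = (r_nuc - lat_margin) * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            pos = np.array(
                [
                    cx + rho * np.cos(theta),
                    cy + rho * np.sin(theta),
                    cz + rng.uniform(-(height / 2 - z_margin), height / 2 - z_margin),
                ]
            )
            if not all(np.linalg.norm(pos - tc) > r_ter + diag for tc in t_centers):
                continue
        else:
            # uniform in a shrunken sphere inside the assigned territory
            u = _unit_vector(rng)
            rad = (r_ter - diag) * rng.uniform() ** (1 / 3)
            pos = territory + u * rad
            lateral = (pos[0] - cx) ** 2 + (pos[1] - cy) ** 2
            if lateral > (r_nuc - lat_margin) ** 2:
                continue
            if abs(pos[2] - cz) > height / 2 - z_margin:
                continue
        if all(np.linalg.norm(pos - q) >= min_sep for q in avoid):
            return pos
    raise RuntimeError("could not place a locus satisfying the layout constraints")


def _place_partner(
    rng: np.random.Generator,
    anchor: np.ndarray,
    separation: float,
    nucleus_center: tuple[float, float, float],
    r_nuc: float,
    height: float,
    spacing: tuple[float, float, float],
    avoid: list[np.ndarray],
    min_sep: float = 1500.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Place the second probe at a fixed separation from the anchor."""
    dz, dy, dx = spacing
    cx, cy, cz = nucleus_center
    lat_margin = 3 * max(dx, dy)
    z_margin = dz
    for _ in range(max_tries):
        pos = anchor + _unit_vector(rng) * separation
        lateral = (pos[0] - cx) ** 2 + (pos[1] - cy) ** 2
        if lateral > (r_nuc - lat_margin) ** 2:
            continue
        if abs(pos[2] - cz) > height / 2 - z_margin:
            continue
        if all(np.linalg.norm(pos - q) >= min_sep for q in avoid):
            return pos
    raise RuntimeError("locus would fall outside its nucleus at this separation")
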