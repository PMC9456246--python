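"""Detection of nuclei, FISH loci and chromosome territories in z-stacks.

The detection chain mirrors a classical confocal quantification recipe:

1. *despeckling* — a 1 x 1 x 3 median filter along z removes isolated
   hot voxels (single-plane shot noise) without blurring in-plane detail;
2. *nucleus detection* — iterative fitting of a cylindrical nucleus
   model (axis along z) to the Gaussian-blurred DNA counterstain,
   seeding each round at the current brightest voxel and removing the
   fitted cylinder before the next round;
3. *object detection* — inside each nucleus, the top-k brightest voxels
   of a probe (or blurred paint) channel are selected and split into
   connected components, which are then size-filtered.

All operators work on :class:`~breakfish.stack.VoxelStack` grids and are
fully deterministic (ties among equal-brightness voxels are broken in
lexicographic ``(z, y, x)`` order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack import DetectedObject, NucleusModel, VoxelStack

__all__ = [
    "NucleusDetectConfig",
    "despeckle",
    "gaussian_blur",
    "fit_cylinder",
    "detect_nuclei",
    "detect_objects",
    "size_filter",
]


def despeckle(stack: VoxelStack) -> VoxelStack:
    """Apply the 1 x 1 x 3 (z-axis) median despeckling filter.

    Each voxel is replaced by the median of itself and its two z
    neighbours; edge planes replicate their nearest neighbour.  Stacks
    with fewer than 3 planes are returned unchanged with a warning.
    The output range is contained in the input range, and any isolated
    single-voxel speckle flanked by dimmer z-neighbours is suppressed.
    """
    if stack.shape[0] < 3:
        warnings.warn("stack has fewer than 3 z-planes; despeckling skipped")
        return stack.copy()
    filtered = ndimage.median_filter(stack.values, size=(3, 1, 1), mode="nearest")
    return VoxelStack(filtered, stack.spacing, stack.channel)


def gaussian_blur(stack: VoxelStack, sigma: float = 1.0) -> VoxelStack:
    """3D Gaussian blur with sigma given in voxels (isotropic in index space)."""
    blurred = ndimage.gaussian_filter(stack.values.astype(np.float64), sigma=sigma)
    return VoxelStack(blurred, stack.spacing, stack.channel)


@dataclass
class NucleusDetectConfig:
    """Tunables of the iterative nucleus detector.

    stop_fraction
        Loop stops once the next seed voxel is dimmer than this fraction
        of the initial global maximum (default 0.3).
    init_radius
        Initial cylinder radius in voxels for every fit.
    beta
        Volume exponent of the fit objective ``mean brightness *
        volume**beta``; beta < 1 biases towards dense cylinders, beta=1
        would reduce to raw total brightness (unbounded in volume).
    min_voxels, max_voxels
        Size filter on accepted nuclei (cylinder voxel count).
    clear_margin, clear_z_margin
        Extra radius (voxels) / extra z planes zeroed around each fitted
        cylinder so residual rims cannot re-seed the next iteration.
    """

    stop_fraction: float = 0.3
    init_radius: float = 10.0
    beta: float = 0.5
    min_voxels: int = 1000
    max_voxels: int = 1_000_000
    max_nuclei: int = 200
    step_init: float = 2.0
    step_tol: float = 1e-3
    max_iter: int = 200
    min_radius: float = 1.5
    max_radius: float = 50.0
    clear_margin: float = 2.0
    clear_z_margin: int = 1
    blur_sigma: float = 1.0
    min_contrast: float = 2.0


def _cylinder_objective(
    values: np.ndarray, cy: float, cx: float, r: float, z_lo: int, z_hi: int, beta: float
) -> tuple[float, float, int]:
    """Objective = mean in-cylinder brightness * volume**beta.

    Returns (objective, total brightness, voxel count).
    """
    nz, ny, nx = values.shape
    if z_lo > z_hi or r <= 0:
        return -np.inf, 0.0, 0
    # volume counts the full (unclipped) cylinder so that sliding the
    # model off the field edge cannot inflate the brightness density
    y0 = int(np.floor(cy - r))
    y1 = int(np.ceil(cy + r)) + 1
    x0 = int(np.floor(cx - r))
    x1 = int(np.ceil(cx + r)) + 1
    yy = np.arange(y0, y1, dtype=np.float64)[:, None]
    xx = np.arange(x0, x1, dtype=np.float64)[None, :]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    area = int(disc.sum())
    if area == 0:
        return -np.inf, 0.0, 0
    yb0, yb1 = max(y0, 0), min(y1, ny)
    xb0, xb1 = max(x0, 0), min(x1, nx)
    if yb0 >= yb1 or xb0 >= xb1:
        total = 0.0
    else:
        sub = values[z_lo : z_hi + 1, yb0:yb1, xb0:xb1]
        disc_in = disc[yb0 - y0 : yb1 - y0, xb0 - x0 : xb1 - x0]
        total = float(sub.sum(axis=0)[disc_in].sum())
    volume = area * (z_hi - z_lo + 1)
    return total / volume * volume**beta, total, volume


def fit_cylinder(
    image: VoxelStack,
    seed: tuple[int, int, int],
    config: NucleusDetectConfig | None = None,
) -> NucleusModel:
    """Fit a z-axis cylinder around ``seed`` by coordinate-wise ascent.

    The objective is mean in-cylinder brightness times ``volume**beta``
    (raw total brightness grows without bound with volume, so a density
    bias is required).  Parameters ``(cy, cx, r)`` take finite-difference
    steps with halving, the z-range grows/shrinks in whole planes;
    the procedure is deterministic and RNG-free.  A fit whose interior
    is no brighter than the remaining image is flagged ``stable=False``
    (the objective is then translation-degenerate, e.g. on a uniform
    image).
    """
    cfg = config or NucleusDetectConfig()
    values = image.values
    if not np.all(np.isfinite(values)):
        raise ValueError("image contains non-finite values")
    nz, ny, nx = values.shape
    sz, sy, sx = (int(v) for v in seed)
    if values[sz, sy, sx] <= 0:
        raise ValueError("seed voxel must have positive brightness")

    cy, cx, r = float(sy), float(sx), float(cfg.init_radius)
    z_lo = z_hi = sz
    best, _, _ = _cylinder_objective(values, cy, cx, r, z_lo, z_hi, cfg.beta)
    step = cfg.step_init
    for _ in range(cfg.max_iter):
        improved = False
        # continuous parameters: center and radius
        for name in ("cy", "cx", "r"):
            for sign in (1.0, -1.0):
                ncy, ncx, nr = cy, cx, r
                if name == "cy":
                    ncy = min(max(cy + sign * step, 0.0), ny - 1.0)
                elif name == "cx":
                    ncx = min(max(cx + sign * step, 0.0), nx - 1.0)
                else:
                    nr = min(max(r + sign * step, cfg.min_radius), cfg.max_radius)
                obj, _, _ = _cylinder_objective(values, ncy, ncx, nr, z_lo, z_hi, cfg.beta)
                if obj > best + 1e-12:
                    cy, cx, r, best = ncy, ncx, nr, obj
                    improved = True
        # integer z bounds
        for lo, hi in ((z_lo - 1, z_hi), (z_lo + 1, z_hi), (z_lo, z_hi + 1), (z_lo, z_hi - 1)):
            if lo < 0 or hi > nz - 1 or lo > hi:
                continue
            obj, _, _ = _cylinder_objective(values, cy, cx, r, lo, hi, cfg.beta)
            if obj > best + 1e-12:
                z_lo, z_hi, best = lo, hi, obj
                improved = True
        if not improved:
            step /= 2.0
            if step < cfg.step_tol:
                break

    _, total, volume = _cylinder_objective(values, cy, cx, r, z_lo, z_hi, cfg.beta)
    inside_mean = total / volume if volume else 0.0
    # contrast vs the nonzero voxels outside the fit (zeros are regions
    # already cleared by the iterative caller and carry no information);
    # a fit no denser than its surroundings is degenerate (uniform
    # image) or a background artifact and is flagged unstable
    mask = NucleusModel((cy, cx), max(r, 1e-6), (z_lo, z_hi)).mask(values.shape)
    outside_pos = values[~mask & (values > 0)]
    if outside_pos.size == 0:
        stable = True
    else:
        stable = inside_mean > cfg.min_contrast * float(outside_pos.mean())
    return NucleusModel(
        center_xy=(cy, cx),
        radius=r,
        z_range=(z_lo, z_hi),
        total_brightness=total,
        stable=stable,
    )


def detect_nuclei(
    counterstain: VoxelStack, config: NucleusDetectConfig | None = None
) -> list[NucleusModel]:
    """Iteratively detect nuclei in a (despeckled) DNA counterstain channel.

    The channel is Gaussian-blurred (sigma = 1 voxel); the global
    brightest voxel seeds a cylinder fit; the fitted cylinder (plus a
    small margin) is zeroed and the loop repeats until the next seed is
    dimmer than ``stop_fraction`` of the initial maximum.  Fits failing
    the voxel-count thresholds are discarded but still zeroed, so the
    loop always terminates.
    """
    cfg = config or NucleusDetectConfig()
    work = gaussian_blur(counterstain, cfg.blur_sigma).values
    initial_max = float(work.max(initial=0.0))
    if initial_max <= 0:
        return []
    nz, ny, nx = work.shape
    nuclei: list[NucleusModel] = []
    for _ in range(cfg.max_nuclei):
        flat = int(np.argmax(work))  # argmax is first-occurrence: lexicographic tie-break
        seed = np.unravel_index(flat, work.shape)
        seed_val = float(work[seed])
        if seed_val < cfg.stop_fraction * initial_max or seed_val <= 0:
            break
        model = fit_cylinder(VoxelStack(work, counterstain.spacing), seed, cfg)
        # zero a dilated cylinder so rims cannot re-seed; a degenerate
        # (unstable) fit only clears a small seed neighbourhood so that
        # the rest of the image survives for later iterations
        if model.stable:
            cy, cx = model.center_xy
            rr = model.radius + cfg.clear_margin
        else:
            cy, cx = float(seed[1]), float(seed[2])
            rr = 2.0 + cfg.clear_margin
        z0 = max(0, model.z_range[0] - cfg.clear_z_margin)
        z1 = min(nz - 1, model.z_range[1] + cfg.clear_z_margin)
        y0, y1 = max(0, int(cy - rr) - 1), min(ny, int(cy + rr) + 2)
        x0, x1 = max(0, int(cx - rr) - 1), min(nx, int(cx + rr) + 2)
        yy = np.arange(y0, y1, dtype=float)[:, None]
        xx = np.arange(x0, x1, dtype=float)[None, :]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= rr * rr
        region = work[z0 : z1 + 1, y0:y1, x0:x1]
        region[np.broadcast_to(disc, region.shape)] = 0.0
        work[seed] = 0.0  # guarantee strict progress even for degenerate fits
        n_vox = _cylinder_voxels(model, (nz, ny, nx))
        if cfg.min_voxels <= n_vox <= cfg.max_voxels and model.stable:
            nuclei.append(model)
    return nuclei


def _cylinder_voxels(model: NucleusModel, shape: tuple[int, int, int]) -> int:
    nz, ny, nx = shape
    cy, cx = model.center_xy
    y0, y1 = max(0, int(cy - model.radius) - 1), min(ny, int(cy + model.radius) + 2)
    x0, x1 = max(0, int(cx - model.radius) - 1), min(nx, int(cx + model.radius) + 2)
    yy = np.arange(y0, y1, dtype=float)[:, None]
    xx = np.arange(x0, x1, dtype=float)[None, :]
    area = int(((yy - cy) ** 2 + (xx - cx) ** 2 <= model.radius**2).sum())
    z0 = max(0, model.z_range[0])
    z1 = min(nz - 1, model.z_range[1])
    return area * (z1 - z0 + 1)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def detect_objects(
    channel: VoxelStack,
    nucleus: NucleusModel,
    mode: str = "locus",
    top_k: int = 300,
    connectivity: int = 26,
    nucleus_id: int = -1,
) -> list[DetectedObject]:
    """Detect loci or territories inside one nucleus cylinder.

    The channel is restricted to the nucleus cylinder; in ``territory``
    mode it is first passed through a 3D Gaussian blur (sigma = 1).  The
    ``top_k`` brightest in-cylinder voxels are selected (ties broken in
    lexicographic (z, y, x) order) and partitioned into connected
    components under the chosen connectivity (6, 18 or 26).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    if top_k <= 0:
        return []
    values = channel.values
    if mode == "territory":
        values = ndimage.gaussian_filter(values.astype(np.float64), sigma=1.0)
    elif mode != "locus":
        raise ValueError("mode must be 'locus' or 'territory'")

    nz, ny, nx = values.shape
    cy, cx = nucleus.center_xy
    r = nucleus.radius
    z0 = max(0, nucleus.z_range[0])
    z1 = min(nz - 1, nucleus.z_range[1])
    y0, y1 = max(0, int(cy - r) - 1), min(ny, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(nx, int(cx + r) + 2)
    yy = np.arange(y0, y1)[:, None]
    xx = np.arange(x0, x1)[None, :]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    if not disc.any() or z0 > z1:
        return []
    sub = values[z0 : z1 + 1, y0:y1, x0:x1]
    in_nuc = np.broadcast_to(disc, sub.shape)
    vals = sub[in_nuc]
    k = top_k
    if k > vals.size:
        warnings.warn("top_k exceeds in-nucleus voxel count; using all voxels")
        k = vals.size
    # threshold at the k-th brightest value, then trim ties lexicographically
    kth = np.partition(vals, vals.size - k)[vals.size - k]
    selected = in_nuc & (sub >= kth)
    n_sel = int(selected.sum())
    if n_sel > k:  # drop excess tied-at-threshold voxels, keeping earliest indices
        tie = selected & (sub == kth)
        tie_idx = np.flatnonzero(tie.ravel())
        drop = tie_idx[len(tie_idx) - (n_sel - k) :]
        flat = selected.ravel().copy()
        flat[drop] = False
        selected = flat.reshape(selected.shape)

    labels, n_comp = ndimage.label(selected, structure=_STRUCTURES[connectivity])
    objects: list[DetectedObject] = []
    for comp in range(1, n_comp + 1):
        zz, yyc, xxc = np.nonzero(labels == comp)
        vox = np.stack([zz + z0, yyc + y0, xxc + x0], axis=1)
        weights = sub[zz, yyc, xxc].astype(float)
        objects.append(
            DetectedObject(
                voxels=vox,
                weights=weights,
                channel=channel.channel,
                nucleus_id=nucleus_id,
                object_id=comp - 1,
            )
        )
    return objects


def size_filter(
    objects: list[DetectedObject], min_vox: int, max_vox: int | float = np.inf
) -> list[DetectedObject]:
    """Keep objects whose voxel count lies in ``[min_vox, max_vox]`` (order preserved)."""
    if min_vox > max_vox:
        raise ValueError("min_vox must not exceed max_vox")
    return [o for o in objects if min_vox <= o.n_voxels <= max_vox]
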