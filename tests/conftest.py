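"""Shared fixtures and small synthetic builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from breakfish.stack import DetectedObject, VoxelStack


def make_cylinder_stack(
    shape=(16, 64, 64),
    center_yx=(32.0, 32.0),
    radius=10.0,
    z_range=(4, 11),
    brightness=100.0,
    spacing=(400.0, 200.0, 200.0),
):
    """Noise-free indicator cylinder (axis along z)."""
    nz, ny, nx = shape
    arr = np.zeros(shape)
    yy, xx = np.ogrid[:ny, :nx]
    disc = (yy - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2 <= radius**2
    arr[z_range[0] : z_range[1] + 1] = disc * brightness
    return VoxelStack(arr, spacing, "dna")


def make_ball_object(
    center_idx=(10, 20, 20),
    radius_nm=1400.0,
    spacing=(400.0, 200.0, 200.0),
    shape=(21, 41, 41),
):
    """Voxelized sphere as a DetectedObject: all voxel centers within radius."""
    dz, dy, dx = spacing
    cz, cy, cx = center_idx
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    d2 = ((zz - cz) * dz) ** 2 + ((yy - cy) * dy) ** 2 + ((xx - cx) * dx) ** 2
    sel = d2 <= radius_nm**2
    vox = np.stack([zz[sel], yy[sel], xx[sel]], axis=1)
    return DetectedObject(voxels=vox, weights=np.ones(len(vox)), channel="paint")


@pytest.fixture(scope="session")
def small_fourc():
    """A small 4C dataset shared across unit tests (3 x 300 kb, 2000 reads)."""
    from breakfish.synth import FourCContactModel, FourCGenomeSpec, make_fourc_dataset

    genome, reps, truth = make_fourc_dataset(
        FourCGenomeSpec(n_chromosomes=3, chrom_length=300_000),
        FourCContactModel(alpha=1.0, trans_floor=0.1),
        n_reads=2000,
        junk_fraction=0.1,
        n_replicates=2,
        seed=11,
    )
    return genome, reps, truth
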