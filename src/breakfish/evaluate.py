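"""Ground-truth benchmarks of the full pipelines on synthetic data.

Each function generates data with the :mod:`breakfish.synth` module,
runs the corresponding analysis chain, and scores it against the
planted truth.  These benchmarks back both the test suite and the
reproduction script; all randomness flows from explicit seeds.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import fourc as fc
from . import pipeline as pl
from .allele_metrics import LocusPoint, signed_territory_distance
from .config import RunConfig
from .synth import (
    FishGeometry,
    FishLayout,
    FishNoise,
    FourCContactModel,
    FourCGenomeSpec,
    make_fourc_dataset,
)
from .synth.fish import make_fish_stack

__all__ = [
    "locus_recovery",
    "sphere_distance_agreement",
    "break_call_recovery",
    "fourc_exactness",
    "enrichment_type_one_error",
]


@dataclass
class RecoveryResult:
    n_planted: int
    n_recovered: int
    errors_vox: list[float]

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 0.0


def locus_recovery(
    n_stacks: int = 20,
    seed: int = 0,
    noise: FishNoise | None = None,
    geometry: FishGeometry | None = None,
    layout: FishLayout | None = None,
    max_error_vox: float = 1.0,
) -> RecoveryResult:
    """Fraction of planted FISH loci recovered within a voxel of truth.

    A planted locus counts as recovered when some detected locus of the
    same probe channel lies within ``max_error_vox`` of its true
    position (Euclidean distance in voxel units, per-axis spacing
    honoured).
    """
    geometry = geometry or FishGeometry()
    layout = layout or FishLayout()
    noise = noise if noise is not None else FishNoise()
    cfg = RunConfig()
    dz, dy, dx = geometry.spacing
    sp_xyz = np.array([dx, dy, dz])
    n_planted = n_recovered = 0
    errors: list[float] = []
    for k in range(n_stacks):
        channels, truth = make_fish_stack(geometry, layout, noise, seed=seed + k)
        cells = pl.analyze_stack(channels, cfg.fish)
        detected: dict[str, list[np.ndarray]] = {"probe1": [], "probe2": []}
        for cell in cells:
            for p in cell.loci1:
                detected["probe1"].append(p.position)
            for p in cell.loci2:
                detected["probe2"].append(p.position)
        for locus in truth.loci:
            n_planted += 1
            cands = detected[locus.channel]
            if not cands:
                continue
            err = np.linalg.norm(
                (np.array(cands) - np.array(locus.position_nm)) / sp_xyz, axis=1
            ).min()
            if err <= max_error_vox:
                n_recovered += 1
                errors.append(float(err))
    return RecoveryResult(n_planted, n_recovered, errors)


def sphere_distance_agreement(
    n_points: int = 500,
    seed: int = 0,
    radius_nm: float = 1400.0,
    spacing: tuple[float, float, float] = (400.0, 200.0, 200.0),
) -> tuple[float, float]:
    """Signed-distance check against an analytic sphere.

    Plants a voxelized spherical territory, samples ``n_points`` at
    analytic distances of 1-4 voxel diagonals from the surface (both
    sides), and returns ``(sign agreement rate, max |distance error| in
    diagonals)`` relative to the analytic sphere distance.
    """
    from .stack import DetectedObject

    dz, dy, dx = spacing
    diag = math.sqrt(dz * dz + dy * dy + dx * dx)
    shape = (25, 51, 51)
    center_idx = np.array([12, 25, 25])
    center_nm = np.array([center_idx[2] * dx, center_idx[1] * dy, center_idx[0] * dz])
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = ((zz - center_idx[0]) * dz) ** 2 + ((yy - center_idx[1]) * dy) ** 2 + (
        (xx - center_idx[2]) * dx
    ) ** 2
    sel = d2 <= radius_nm**2
    ball = DetectedObject(
        np.stack([zz[sel], yy[sel], xx[sel]], axis=1), np.ones(int(sel.sum()))
    )
    rng = np.random.default_rng(seed)
    n_sign_ok = 0
    max_err = 0.0
    for _ in range(n_points):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        outside = rng.random() < 0.5
        depth = rng.uniform(1.0, 4.0) * diag
        if not outside:
            depth = min(depth, radius_nm - diag)
        rho = radius_nm + depth if outside else radius_nm - depth
        pt = LocusPoint(center_nm + u * rho, "probe1")
        got = signed_territory_distance(pt, ball, spacing)
        if (got > 0) == outside:
            n_sign_ok += 1
        max_err = max(max_err, abs(abs(got) - depth) / diag)
    return n_sign_ok / n_points, max_err


def break_call_recovery(
    n_control: int = 2000,
    n_treated: int = 2000,
    planted_fraction: float = 0.03,
    seed: int = 0,
    q: float = 0.99,
):
    """Quantile break calling on synthetic distance cohorts.

    Returns a dict with the control self-classification fraction, the
    treated fraction, and the excess fraction after subtracting the
    expected false-positive floor (1 - q).
    """
    from .break_stats import broken_threshold, classify_broken, tail_test
    from .synth import make_cohort_distances

    control = make_cohort_distances(n_control, broken_fraction=0.0, seed=seed)
    treated = make_cohort_distances(
        n_treated, broken_fraction=planted_fraction, broken_shift=1500.0, seed=seed + 1
    )
    thr = broken_threshold(control.distance_nm.to_numpy(), q)
    control_frac = classify_broken(control.distance_nm.to_numpy(), thr).broken_fraction
    treated_frac = classify_broken(treated.distance_nm.to_numpy(), thr).broken_fraction
    tail = tail_test(treated_frac, n_treated)
    return {
        "threshold_nm": thr,
        "control_fraction": control_frac,
        "treated_fraction": treated_frac,
        "excess_fraction": treated_frac - (1.0 - q),
        "planted_fraction": planted_fraction,
        "tail_margin": tail.margin,
        "tail_significant": tail.significant,
    }


def fourc_exactness(seed: int = 0, n_reads: int = 10_000):
    """End-to-end 4C run on a noise-free synthetic dataset.

    Returns a dict with the fraction of fragments whose recovered raw
    signal equals the planted count (per replicate), the Pearson r of a
    duplicated replicate, the replicate correlation of the two
    independent replicates, and the trans-contact fraction together
    with its model expectation.
    """
    genome, reps, truth = make_fourc_dataset(
        FourCGenomeSpec(n_chromosomes=3, chrom_length=1_000_000),
        FourCContactModel(alpha=1.0, trans_floor=0.05),
        n_reads=n_reads,
        junk_fraction=0.1,
        n_replicates=2,
        seed=seed,
    )
    anchor = truth.anchors[0]
    rep_signals = []
    exact = []
    for r, reads in enumerate(reps):
        parsed = fc.parse_reads(reads, [anchor])
        mapped, _ = fc.map_exact(parsed.captured[anchor.anchor_id], genome)
        signals, _ = fc.fragment_signal(mapped, truth.fragment_map)
        rep_signals.append(signals)
        got = Counter({i: s.raw for i, s in enumerate(signals) if s.raw})
        want = Counter(
            {k: v for k, v in truth.planted_counts[(anchor.anchor_id, r)].items() if v}
        )
        exact.append(got == want)
    _, r_dup = fc.normalize_and_merge([rep_signals[0], rep_signals[0]])
    merged, r_reps = fc.normalize_and_merge(rep_signals)
    trans = fc.trans_fraction(merged, anchor.bait_chrom)
    # model expectation of the fragment-level trans share: probability each
    # fragment carries >= 1 of the planted reads, summed cis vs trans
    planted_all = Counter()
    for counter in truth.planted_counts.values():
        planted_all.update(counter)
    n_cis = sum(
        1 for i, c in planted_all.items() if c and truth.fragment_map[i].chrom == anchor.bait_chrom
    )
    n_trans = sum(
        1 for i, c in planted_all.items() if c and truth.fragment_map[i].chrom != anchor.bait_chrom
    )
    return {
        "exact_per_replicate": exact,
        "duplicate_r": r_dup,
        "replicate_r": r_reps,
        "trans_fraction": trans,
        "trans_fraction_truth": n_trans / (n_cis + n_trans),
        "signals": rep_signals,
        "fragments": truth.fragment_map,
    }


def enrichment_type_one_error(
    n_sims: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    n_genes_per_chrom: int = 60,
    n_partners: int = 20,
) -> float:
    """Type-I error of the partner-enrichment test under the null.

    Fragments carry i.i.d. contact indicators, partner genes are a
    uniformly random subset each simulation, so the null of exchangeable
    group labels holds exactly; returns the rejection rate at ``alpha``.
    """
    import pandas as pd

    from .fourc import FragmentSignal, RestrictionFragment, partner_enrichment

    frag_len = 5000
    chrom_len = 5_000_000
    chroms = ["chr2", "chr3"]
    fragments = [
        RestrictionFragment(c, i * frag_len, (i + 1) * frag_len, i)
        for c in chroms
        for i in range(chrom_len // frag_len)
    ]
    rng = np.random.default_rng(seed)
    genes = []
    gi = 0
    for c in chroms:
        for _ in range(n_genes_per_chrom):
            start = int(rng.integers(0, chrom_len - 400_000))
            genes.append((c, start, start + 400_000, f"g{gi}"))
            gi += 1
    gene_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "name"])
    names = gene_df["name"].tolist()
    rejections = 0
    for _ in range(n_sims):
        raws = rng.random(len(fragments)) < 0.25
        signals = [
            FragmentSignal(f, int(r)) for f, r in zip(fragments, raws)
        ]
        partners = list(rng.choice(names, size=n_partners, replace=False))
        _, p, _ = partner_enrichment(signals, gene_df, partners, "chr1")
        rejections += p < alpha
    return rejections / n_sims
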