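"""Synthetic 4C-seq read sets over a toy multi-chromosome genome.

The generator draws a random genome (HindIII sites occur at natural
random-sequence density, about one per 4 kb), designs one or more
anchor primers sitting immediately upstream of a HindIII site on the
bait chromosome, and emits reads of the literal form
``primer + AAGCTT + prefix-of-a-target-fragment-end``.  Target
fragments are sampled from a distance-decay contact model: with
probability ``trans_floor`` a uniform fragment on a non-bait
chromosome, otherwise a cis fragment with probability proportional to
``(1 + d)**(-alpha)`` in genomic distance ``d`` from the bait.  The
planted per-fragment counts are recorded so the downstream counting
path can be checked for exact recovery; a configurable fraction of junk
reads (no ligation site, or an unclassifiable prefix) is appended.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ..fourc.digest import RestrictionFragment, digest_genome, find_sites
from ..fourc.reads import AnchorSpec, KmerIndex, revcomp

__all__ = ["FourCGenomeSpec", "FourCContactModel", "FourCTruth", "make_fourc_dataset"]

HINDIII = "AAGCTT"


@dataclass(frozen=True)
class FourCGenomeSpec:
    """Toy genome layout: equal-length random chromosomes."""

    n_chromosomes: int = 3
    chrom_length: int = 1_000_000
    names: tuple[str, ...] | None = None

    def chrom_names(self) -> list[str]:
        if self.names is not None:
            return list(self.names)
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass(frozen=True)
class FourCContactModel:
    """Cis distance decay plus a uniform trans floor."""

    alpha: float = 1.0
    trans_floor: float = 0.05


@dataclass
class FourCTruth:
    """Ground truth of a generated 4C read set."""

    genome: dict[str, str]
    fragment_map: list[RestrictionFragment]
    planted_counts: dict[tuple[str, int], Counter] = field(default_factory=dict)
    bait: tuple[str, str, int] = ("", "", 0)  # (anchor_id, chrom, position)
    anchors: list[AnchorSpec] = field(default_factory=list)
    n_junk: dict[int, int] = field(default_factory=dict)

    def total_planted(self) -> int:
        return sum(sum(c.values()) for c in self.planted_counts.values())


def _random_genome(rng: np.random.Generator, spec: FourCGenomeSpec) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        name: "".join(bases[rng.integers(0, 4, spec.chrom_length)])
        for name in spec.chrom_names()
    }


def _design_anchor(
    genome: dict[str, str],
    bait_chrom: str,
    fragments: list[RestrictionFragment],
    primer_len: int,
    anchor_id: str,
    index: KmerIndex,
    skip: int = 0,
) -> tuple[AnchorSpec, int]:
    """Pick a primer immediately upstream of a HindIII site on the bait.

    The primer must occur exactly once genome-wide (both strands), must
    not contain the site, and concatenating it with the site must not
    create an earlier site occurrence.  Returns the anchor and the
    genomic position of its adjacent site.
    """
    seq = genome[bait_chrom]
    sites = find_sites(seq, HINDIII)
    if not sites:
        raise ValueError("bait chromosome has no HindIII sites")
    mid = len(seq) // 2
    skipped = 0
    for site_pos in sorted(sites, key=lambda s: abs(s - mid)):
        if site_pos < primer_len:
            continue
        primer = seq[site_pos - primer_len : site_pos]
        if HINDIII in primer or (primer + HINDIII).find(HINDIII) != primer_len:
            continue
        if index.count_both_strands(primer) != 1:
            continue
        if skipped < skip:
            skipped += 1
            continue
        frag_idx = next(
            f.index
            for f in fragments
            if f.chrom == bait_chrom and f.start <= site_pos < f.end
        )
        return (
            AnchorSpec(anchor_id, primer, bait_chrom, frag_idx),
            site_pos,
        )
    raise RuntimeError("no usable anchor primer found on the bait chromosome")


def make_fourc_dataset(
    genome_spec: FourCGenomeSpec | None = None,
    contact_model: FourCContactModel | None = None,
    anchors: list[AnchorSpec] | None = None,
    n_reads: int = 10_000,
    junk_fraction: float = 0.1,
    n_replicates: int = 2,
    capture_len: int = 40,
    primer_len: int = 20,
    map_min_len: int = 20,
    seed: int = 0,
) -> tuple[dict[str, str], list[list[tuple[str, str]]], FourCTruth]:
    """Generate (genome, per-replicate reads, truth).

    Each replicate holds ``n_reads`` reads as ``(read_id, sequence)``
    pairs, of which ``round(junk_fraction * n_reads)`` are junk and the
    rest carry a valid anchor + site + capture structure whose target
    fragment is recorded in ``truth.planted_counts[(anchor, replicate)]``.
    Captures are fragment-end prefixes whose ``map_min_len`` prefix is
    unique genome-wide, so exact mapping recovers the planted counts
    without loss.  Identical seeds reproduce the read sets byte for
    byte.
    """
    genome_spec = genome_spec or FourCGenomeSpec()
    contact_model = contact_model or FourCContactModel()
    rng = np.random.default_rng(seed)
    genome = _random_genome(rng, genome_spec)
    fragments = digest_genome(genome, HINDIII, cut_offset=1)

    bait_chrom = genome_spec.chrom_names()[0]
    cap_index = KmerIndex(genome, map_min_len)
    primer_index = cap_index if primer_len == map_min_len else KmerIndex(genome, primer_len)
    if anchors is None:
        anchor, site_pos = _design_anchor(
            genome, bait_chrom, fragments, primer_len, "anchor1", primer_index
        )
        anchors = [anchor]
        bait_positions = {anchor.anchor_id: site_pos}
    else:
        bait_positions = {}
        for a in anchors:
            seq = genome.get(a.bait_chrom, "")
            if not find_sites(seq, HINDIII):
                raise ValueError("bait chromosome has no HindIII sites")
            occ = sum(s.count(a.primer) + s.count(revcomp(a.primer)) for s in genome.values())
            if occ != 1:
                raise ValueError(f"primer of {a.anchor_id} must occur exactly once")
            bait_positions[a.anchor_id] = seq.find(a.primer) + len(a.primer)

    truth = FourCTruth(genome=genome, fragment_map=fragments, anchors=list(anchors))
    a0 = anchors[0]
    truth.bait = (a0.anchor_id, a0.bait_chrom, bait_positions[a0.anchor_id])

    # eligible target fragment ends: long enough, off the bait fragment
    # and its genomic neighbours, with a genome-wide-unique capture prefix
    bait_indices = {
        (a.bait_chrom, a.bait_fragment_index + k) for a in anchors for k in (-1, 0, 1)
    }
    eligible: list[int] = []
    end_captures: dict[int, list[tuple[str, str]]] = {}  # frag id -> [(end, capture)]
    for i, f in enumerate(fragments):
        if f.length < capture_len + 6 or (f.chrom, f.index) in bait_indices:
            continue
        seq = genome[f.chrom]
        ok_ends = []
        for end_name, cap in (
            ("left", seq[f.start : f.start + capture_len]),
            ("right", revcomp(seq[f.end - capture_len : f.end])),
        ):
            if cap_index.count_both_strands(cap[:map_min_len]) == 1:
                ok_ends.append((end_name, cap))
        if ok_ends:
            eligible.append(i)
            end_captures[i] = ok_ends
    if not eligible:
        raise RuntimeError("no eligible target fragments")

    elig = np.array(eligible)
    elig_chrom = np.array([fragments[i].chrom for i in elig])
    cis_mask = elig_chrom == bait_chrom
    trans_ids = elig[~cis_mask]
    cis_ids = elig[cis_mask]
    bait_mid = fragments[
        next(i for i, f in enumerate(fragments) if f.chrom == a0.bait_chrom and f.index == a0.bait_fragment_index)
    ].midpoint
    cis_d = np.array([abs(fragments[i].midpoint - bait_mid) for i in cis_ids], dtype=float)
    cis_w = (1.0 + cis_d) ** (-contact_model.alpha)
    cis_p = cis_w / cis_w.sum()

    n_junk = int(round(junk_fraction * n_reads))
    n_valid = n_reads - n_junk
    read_len = primer_len + len(HINDIII) + capture_len
    replicates: list[list[tuple[str, str]]] = []
    for rep in range(n_replicates):
        for a in anchors:
            truth.planted_counts[(a.anchor_id, rep)] = Counter()
        reads: list[str] = []
        for _ in range(n_valid):
            a = anchors[int(rng.integers(len(anchors)))] if len(anchors) > 1 else anchors[0]
            use_trans = len(trans_ids) > 0 and rng.random() < contact_model.trans_floor
            if use_trans:
                frag_id = int(trans_ids[int(rng.integers(len(trans_ids)))])
            else:
                frag_id = int(rng.choice(cis_ids, p=cis_p))
            ends = end_captures[frag_id]
            _, cap = ends[int(rng.integers(len(ends)))] if len(ends) > 1 else ends[0]
            reads.append(a.primer + HINDIII + cap)
            truth.planted_counts[(a.anchor_id, rep)][frag_id] += 1
        primers = [a.primer for a in anchors]
        for _ in range(n_junk):
            reads.append(_junk_read(rng, read_len, primers))
        order = rng.permutation(len(reads))
        replicates.append(
            [(f"rep{rep}_read{k}", reads[j]) for k, j in enumerate(order)]
        )
        truth.n_junk[rep] = n_junk
    return genome, replicates, truth


def _junk_read(rng: np.random.Generator, length: int, primers: list[str]) -> str:
    """A read guaranteed not to parse as a valid anchor + site read."""
    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(bases[rng.integers(0, 4, length)])
        pos = seq.find(HINDIII)
        if pos < 1:
            return seq
        prefix = seq[:pos]
        if not any(prefix.startswith(p) for p in primers):
            return seq
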