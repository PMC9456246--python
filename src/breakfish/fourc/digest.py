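"""In-silico restriction digestion of a genome into a fragment map."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RestrictionFragment", "digest_genome", "find_sites"]


@dataclass(frozen=True)
class RestrictionFragment:
    """Genomic interval between consecutive primary-enzyme cut positions.

    Coordinates are 0-based half-open; ``index`` is the ordinal of the
    fragment on its chromosome.  Fragments tile each chromosome without
    gaps or overlaps.
    """

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment requires start < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def find_sites(sequence: str, motif: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrences of ``motif``."""
    sites: list[int] = []
    pos = sequence.find(motif)
    while pos != -1:
        sites.append(pos)
        pos = sequence.find(motif, pos + 1)
    return sites


def digest_genome(
    sequences: dict[str, str], site: str = "AAGCTT", cut_offset: int = 1
) -> list[RestrictionFragment]:
    """Digest a genome at every occurrence of a restriction motif.

    Cuts fall at ``occurrence + cut_offset`` (HindIII A^AGCTT: offset 1;
    DpnII ^GATC: offset 0).  Fragments span consecutive cuts plus the
    chromosome ends; a chromosome without a site yields one fragment
    covering the whole sequence.  Ambiguity codes never match the exact
    motif and are therefore treated as non-cutting.
    """
    if not site:
        raise ValueError("restriction motif must be nonempty")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must lie within the motif")
    fragments: list[RestrictionFragment] = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        length = len(seq)
        cuts = sorted({s + cut_offset for s in find_sites(seq, site.upper())})
        cuts = [c for c in cuts if 0 < c < length]
        bounds = [0] + cuts + [length]
        for i, (start, end) in enumerate(zip(bounds[:-1], bounds[1:])):
            fragments.append(RestrictionFragment(chrom, start, end, i))
    return fragments
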