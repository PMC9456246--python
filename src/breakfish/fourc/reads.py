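"""Bait-anchored read parsing and exact-match mapping.

A valid 4C read is structured ``<anchor primer><ligation site><capture>``:
the bait-side subsequence before the first HindIII site classifies the
read by anchor, and the capture after the site is the contacting
sequence.  Captures are mapped by exact, genome-wide-unique occurrence
of their ``min_len`` prefix (forward or reverse-complement), emulating
unique mapping; multi-hit and zero-hit captures are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnchorSpec",
    "MappedPosition",
    "ParseResult",
    "KmerIndex",
    "parse_reads",
    "map_exact",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnchorSpec:
    """A 4C viewpoint: its inverse-PCR primer and bait fragment."""

    anchor_id: str
    primer: str
    bait_chrom: str = ""
    bait_fragment_index: int = -1

    def __post_init__(self) -> None:
        if not self.primer or set(self.primer) - set("ACGT"):
            raise ValueError("primer must be a nonempty uppercase ACGT string")


@dataclass(frozen=True)
class MappedPosition:
    """A uniquely mapped capture: chromosome, position, strand.

    ``position`` is the genomic coordinate of the capture's 5' base on
    the plus strand: for a plus-strand hit the leftmost matched base,
    for a minus-strand hit the rightmost.
    """

    chrom: str
    position: int
    strand: str  # "+" | "-"


@dataclass
class ParseResult:
    """Per-anchor captured sequences plus a categorized discard log."""

    captured: dict[str, list[str]] = field(default_factory=dict)
    n_classified: int = 0
    n_no_site: int = 0
    n_unknown_anchor: int = 0
    n_ambiguous: int = 0

    @property
    def n_total(self) -> int:
        return self.n_classified + self.n_no_site + self.n_unknown_anchor + self.n_ambiguous


def parse_reads(
    reads,
    anchors: list[AnchorSpec],
    site: str = "AAGCTT",
    include_site: bool = False,
) -> ParseResult:
    """Classify reads by anchor primer and extract captured sequences.

    ``reads`` yields sequences (str) or ``(read_id, sequence)`` pairs.
    A read is kept iff the ligation-site motif occurs at position >= 1
    and the prefix before its first occurrence begins with exactly one
    anchor primer.  The capture is the subsequence after (by default
    excluding) the site.  Rejections are categorized as ``no_site``,
    ``unknown_anchor`` or ``ambiguous``.
    """
    for i, a in enumerate(anchors):
        for b in anchors[i + 1 :]:
            if a.primer.startswith(b.primer) or b.primer.startswith(a.primer):
                raise ValueError("anchor primers must be mutually non-prefix")
    result = ParseResult(captured={a.anchor_id: [] for a in anchors})
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else str(item)
        seq = seq.upper()
        pos = seq.find(site)
        if pos < 1:
            result.n_no_site += 1
            continue
        prefix = seq[:pos]
        matches = [a for a in anchors if prefix.startswith(a.primer)]
        if not matches:
            result.n_unknown_anchor += 1
            continue
        if len(matches) > 1:
            result.n_ambiguous += 1
            continue
        capture = seq[pos:] if include_site else seq[pos + len(site) :]
        result.captured[matches[0].anchor_id].append(capture)
        result.n_classified += 1
    return result


_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


class KmerIndex:
    """Sorted packed-k-mer index for exact occurrence queries.

    Every length-``k`` window of the plus strand is packed into a 2-bit
    per-base integer (k <= 31); windows containing non-ACGT characters
    are dropped.  Occurrence counts and positions of a query k-mer (and,
    via the reverse complement of the query, minus-strand matches) come
    from binary search on the sorted hash array.
    """

    def __init__(self, genome: dict[str, str], k: int):
        if not 1 <= k <= 31:
            raise ValueError("k must be between 1 and 31")
        self.k = k
        hashes: list[np.ndarray] = []
        positions: list[np.ndarray] = []
        chrom_ids: list[np.ndarray] = []
        self.chroms = sorted(genome)
        for ci, chrom in enumerate(self.chroms):
            seq = genome[chrom].upper()
            if len(seq) < k:
                continue
            codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            n = len(seq) - k + 1
            h = np.zeros(n, dtype=np.int64)
            bad = np.zeros(n, dtype=bool)
            for j in range(k):
                c = codes[j : j + n]
                h = (h << 2) | np.where(c < 4, c, 0)
                bad |= c >= 4
            keep = ~bad
            hashes.append(h[keep])
            positions.append(np.flatnonzero(keep))
            chrom_ids.append(np.full(int(keep.sum()), ci, dtype=np.int32))
        allh = np.concatenate(hashes) if hashes else np.empty(0, dtype=np.int64)
        order = np.argsort(allh, kind="stable")
        self._hashes = allh[order]
        self._positions = np.concatenate(positions)[order] if hashes else np.empty(0, int)
        self._chrom_ids = np.concatenate(chrom_ids)[order] if hashes else np.empty(0, int)

    def _pack(self, kmer: str) -> int | None:
        if len(kmer) != self.k:
            return None
        codes = _BASE_CODE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
        if np.any(codes >= 4):
            return None
        h = 0
        for c in codes:
            h = (h << 2) | int(c)
        return h

    def count(self, kmer: str) -> int:
        h = self._pack(kmer)
        if h is None:
            return 0
        lo = int(np.searchsorted(self._hashes, h, side="left"))
        hi = int(np.searchsorted(self._hashes, h, side="right"))
        return hi - lo

    def occurrences(self, kmer: str) -> list[tuple[str, int]]:
        """Plus-strand occurrences of ``kmer`` as (chrom, start)."""
        h = self._pack(kmer)
        if h is None:
            return []
        lo = int(np.searchsorted(self._hashes, h, side="left"))
        hi = int(np.searchsorted(self._hashes, h, side="right"))
        return [
            (self.chroms[int(self._chrom_ids[i])], int(self._positions[i]))
            for i in range(lo, hi)
        ]

    def count_both_strands(self, kmer: str) -> int:
        rc = revcomp(kmer)
        n = self.count(kmer)
        if rc != kmer:
            n += self.count(rc)
        return n


class _ExactMapper:
    """Cached unique-occurrence mapping of fixed-length capture prefixes."""

    def __init__(self, genome: dict[str, str], min_len: int):
        self.min_len = min_len
        self.index = KmerIndex(genome, min_len)
        self._cache: dict[str, MappedPosition | None] = {}

    def map(self, capture: str) -> MappedPosition | None:
        if len(capture) < self.min_len:
            return None
        key = capture[: self.min_len]
        if key not in self._cache:
            fwd = self.index.occurrences(key)
            rc = revcomp(key)
            rev = self.index.occurrences(rc) if rc != key else []
            if len(fwd) + len(rev) != 1:
                self._cache[key] = None
            elif fwd:
                chrom, pos = fwd[0]
                self._cache[key] = MappedPosition(chrom, pos, "+")
            else:
                # capture's 5' base sits at the right edge of the match
                chrom, pos = rev[0]
                self._cache[key] = MappedPosition(chrom, pos + self.min_len - 1, "-")
        return self._cache[key]


def map_exact(
    captures: list[str], genome: dict[str, str], min_len: int = 20
) -> tuple[list[MappedPosition], dict[str, int]]:
    """Map captured sequences by unique exact prefix occurrence.

    A capture maps iff its ``min_len`` prefix occurs exactly once in the
    genome over both strands.  Returns the mapped positions (in input
    order, unmapped captures skipped) and a log with counts of
    ``mapped``, ``unmapped_multi_or_absent`` and ``too_short``.
    """
    mapper = _ExactMapper(genome, min_len)
    mapped: list[MappedPosition] = []
    log = {"mapped": 0, "unmapped": 0, "too_short": 0}
    for cap in captures:
        if len(cap) < min_len:
            log["too_short"] += 1
            continue
        hit = mapper.map(cap.upper())
        if hit is None:
            log["unmapped"] += 1
        else:
            mapped.append(hit)
            log["mapped"] += 1
    return mapped, log
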