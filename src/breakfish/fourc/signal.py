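"""Fragment-end signal, window profiles, merging and enrichment tests.

Raw 4C signal is counted per restriction fragment: a uniquely mapped
plus-strand read within a few bp of a fragment's left end, or a
minus-strand read at its right end, increments that fragment.  Contact
profiles aggregate fragments into non-overlapping genomic windows
(500 kb by default), counting fragments with at least one captured
contact; this fragment-level (rather than read-level) statistic is
robust to PCR amplification of individual ligation products.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..break_stats import mann_whitney
from .digest import RestrictionFragment
from .reads import MappedPosition

__all__ = [
    "FragmentSignal",
    "WindowProfile",
    "fragment_signal",
    "mask_bait",
    "window_profile",
    "normalize_and_merge",
    "trans_fraction",
    "partner_enrichment",
]


@dataclass(frozen=True)
class FragmentSignal:
    """Read count assigned to one restriction fragment's two ends."""

    fragment: RestrictionFragment
    raw: int
    normalized: float = 0.0

    def __post_init__(self) -> None:
        if self.raw < 0 or self.normalized < 0:
            raise ValueError("signal counts must be non-negative")


@dataclass
class WindowProfile:
    """Per-window count of fragments carrying at least one contact."""

    window: int
    values: dict[str, np.ndarray]

    def total(self) -> int:
        return int(sum(v.sum() for v in self.values.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.values):
            for i, v in enumerate(self.values[chrom]):
                rows.append((chrom, i * self.window, (i + 1) * self.window, v))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _validate_tiling(fragments: list[RestrictionFragment]) -> None:
    by_chrom: dict[str, list[RestrictionFragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, frags in by_chrom.items():
        frags = sorted(frags, key=lambda f: f.start)
        if frags[0].start != 0:
            raise ValueError(f"{chrom}: fragments do not start at 0")
        for a, b in zip(frags[:-1], frags[1:]):
            if a.end != b.start:
                raise ValueError(f"{chrom}: gap or overlap at {a.end}")


def fragment_signal(
    mapped: list[MappedPosition],
    fragments: list[RestrictionFragment],
    end_tolerance: int = 4,
) -> tuple[list[FragmentSignal], dict[str, int]]:
    """Assign mapped positions to fragment ends and sum into raw signal.

    A plus-strand position within ``end_tolerance`` bp of a fragment
    start increments that fragment's left-end count; a minus-strand
    position within tolerance of ``end - 1`` increments the right-end
    count; ``raw`` is their sum.  Positions matching no fragment end are
    discarded and counted in the log.
    """
    _validate_tiling(fragments)
    order = sorted(range(len(fragments)), key=lambda i: (fragments[i].chrom, fragments[i].start))
    starts: dict[str, np.ndarray] = {}
    idx_of: dict[str, np.ndarray] = {}
    for chrom in {f.chrom for f in fragments}:
        chrom_order = [i for i in order if fragments[i].chrom == chrom]
        starts[chrom] = np.array([fragments[i].start for i in chrom_order])
        idx_of[chrom] = np.array(chrom_order)
    raw = np.zeros(len(fragments), dtype=np.int64)
    log = {"assigned": 0, "end_miss": 0, "no_chrom": 0}
    for hit in mapped:
        if hit.chrom not in starts:
            log["no_chrom"] += 1
            continue
        st = starts[hit.chrom]
        ids = idx_of[hit.chrom]
        target = hit.position if hit.strand == "+" else hit.position + 1
        # "+" matches a fragment start; "-" matches an end (== next start or L)
        j = int(np.searchsorted(st, target))
        best = -1
        best_d = end_tolerance + 1
        for k in (j - 1, j):
            if 0 <= k < len(st):
                if hit.strand == "+":
                    d = abs(hit.position - st[k])
                else:
                    frag = fragments[ids[k]]
                    d = abs(hit.position - (frag.end - 1))
                if d < best_d:
                    best_d, best = d, k
        # minus-strand reads may also match the *previous* fragment's end
        if hit.strand == "-":
            for k in (j - 2, j + 1):
                if 0 <= k < len(st):
                    frag = fragments[ids[k]]
                    d = abs(hit.position - (frag.end - 1))
                    if d < best_d:
                        best_d, best = d, k
        if best >= 0 and best_d <= end_tolerance:
            raw[ids[best]] += 1
            log["assigned"] += 1
        else:
            log["end_miss"] += 1
    signals = [FragmentSignal(f, int(raw[i])) for i, f in enumerate(fragments)]
    return signals, log


def mask_bait(
    signals: list[FragmentSignal],
    bait_chrom: str,
    bait_fragment_index: int,
    flank: int = 1,
) -> list[FragmentSignal]:
    """Zero the bait fragment and its ``flank`` genomic neighbours.

    Standard viewpoint masking: self-ligation and undigested products
    dominate the bait and its immediate neighbours, so they are excluded
    from profiles and statistics (disable with ``flank=-1`` upstream).
    """
    out = []
    for s in signals:
        f = s.fragment
        if f.chrom == bait_chrom and abs(f.index - bait_fragment_index) <= flank:
            out.append(replace(s, raw=0, normalized=0.0))
        else:
            out.append(s)
    return out


def window_profile(signals: list[FragmentSignal], window: int = 500_000) -> WindowProfile:
    """Count contact-bearing fragments per non-overlapping genomic window.

    Windows start at 0 on each chromosome; a fragment belongs to the
    window containing its midpoint and contributes 1 when ``raw >= 1``.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    sizes: dict[str, int] = {}
    for s in signals:
        sizes[s.fragment.chrom] = max(sizes.get(s.fragment.chrom, 0), s.fragment.end)
    values = {
        chrom: np.zeros(int(np.ceil(L / window)) or 1, dtype=np.int64)
        for chrom, L in sizes.items()
    }
    for s in signals:
        if s.raw >= 1:
            values[s.fragment.chrom][s.fragment.midpoint // window] += 1
    return WindowProfile(window=window, values=values)


def normalize_and_merge(
    replicates: list[list[FragmentSignal]],
    scale: float = 1e6,
    window: int = 500_000,
) -> tuple[list[FragmentSignal], float]:
    """Scale replicates to a common library size and average them.

    Each replicate is normalized to ``scale`` total assigned reads
    (``normalized = raw * scale / sum(raw)``); the merged signal is the
    mean of normalized values per fragment.  Returns the merged list and
    the Pearson correlation of per-window contact profiles between
    replicates (mean over pairs when more than two).
    """
    if not replicates:
        raise ValueError("no replicates supplied")
    n_frag = len(replicates[0])
    frags = [s.fragment for s in replicates[0]]
    norm = np.zeros((len(replicates), n_frag))
    for r, rep in enumerate(replicates):
        if len(rep) != n_frag or any(s.fragment != f for s, f in zip(rep, frags)):
            raise ValueError("replicates must share one fragment map")
        raw = np.array([s.raw for s in rep], dtype=float)
        total = raw.sum()
        if total == 0:
            raise ValueError("replicate with zero assigned reads")
        norm[r] = raw * scale / total
    merged_vals = norm.mean(axis=0)
    raw_sums = [sum(rep[i].raw for rep in replicates) for i in range(n_frag)]
    merged = [
        FragmentSignal(f, int(rs), float(v))
        for f, rs, v in zip(frags, raw_sums, merged_vals)
    ]
    profiles = [window_profile(rep, window) for rep in replicates]
    flat = [
        np.concatenate([p.values[c] for c in sorted(p.values)]).astype(float)
        for p in profiles
    ]
    rs = []
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if np.std(flat[i]) == 0 or np.std(flat[j]) == 0:
                # degenerate profile (single window or constant): correlation
                # is defined as 1 for identical profiles, 0 otherwise
                rs.append(1.0 if np.array_equal(flat[i], flat[j]) else 0.0)
            else:
                rs.append(float(np.corrcoef(flat[i], flat[j])[0, 1]))
    r = float(np.mean(rs)) if rs else 1.0
    return merged, r


def trans_fraction(signals: list[FragmentSignal], bait_chrom: str) -> float:
    """Fraction of contact-bearing fragments on non-bait chromosomes."""
    bearing = [s for s in signals if s.raw >= 1]
    if not bearing:
        raise ValueError("no contact-bearing fragments")
    n_trans = sum(1 for s in bearing if s.fragment.chrom != bait_chrom)
    return n_trans / len(bearing)


def partner_enrichment(
    signals: list[FragmentSignal],
    genes: pd.DataFrame,
    partners: list[str],
    bait_chrom: str,
    level: str = "window",
    window: int = 500_000,
    alternative: str = "two-sided",
) -> tuple[float, float, pd.DataFrame]:
    """Compare 4C signal on translocation-partner genes vs other genes.

    ``genes`` has BED-like columns (chrom, start, end, name); only genes
    on non-bait chromosomes enter the comparison.  Per-gene signal is,
    at ``level="window"``, the sum of contact-bearing-fragment counts
    over the 500-kb windows overlapping the gene, or, at
    ``level="fragment"``, the count of contact-bearing fragments whose
    midpoint lies inside the gene.  Partner genes are compared with all
    other non-bait genes by the Mann-Whitney test.  Returns
    (U, p, per-gene table).
    """
    if not partners:
        raise ValueError("empty partner set")
    genes = genes[genes["chrom"] != bait_chrom]
    names = set(genes["name"])
    missing = set(partners) - names
    if missing:
        raise ValueError(f"partners absent from gene list (or on bait chrom): {missing}")
    if level == "window":
        prof = window_profile(signals, window)
        per_gene = []
        for _, g in genes.iterrows():
            vals = prof.values.get(g["chrom"])
            if vals is None:
                per_gene.append(0.0)
                continue
            w0 = int(g["start"]) // window
            w1 = (int(g["end"]) - 1) // window
            per_gene.append(float(vals[max(w0, 0) : min(w1, len(vals) - 1) + 1].sum()))
    elif level == "fragment":
        per_gene = []
        for _, g in genes.iterrows():
            per_gene.append(
                float(
                    sum(
                        1
                        for s in signals
                        if s.raw >= 1
                        and s.fragment.chrom == g["chrom"]
                        and int(g["start"]) <= s.fragment.midpoint < int(g["end"])
                    )
                )
            )
    else:
        raise ValueError("level must be 'window' or 'fragment'")
    table = genes.copy()
    table["signal"] = per_gene
    table["is_partner"] = table["name"].isin(partners)
    a = table.loc[table["is_partner"], "signal"].to_numpy()
    b = table.loc[~table["is_partner"], "signal"].to_numpy()
    if b.size == 0:
        raise ValueError("no background genes to compare against")
    u, p = mann_whitney(a, b, alternative=alternative)
    return u, p, table
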