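"""4C chain: digestion, parsing, mapping, counting, profiles, enrichment."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breakfish.fourc import (
    AnchorSpec,
    FragmentSignal,
    MappedPosition,
    RestrictionFragment,
    digest_genome,
    fragment_signal,
    map_exact,
    mask_bait,
    normalize_and_merge,
    parse_reads,
    partner_enrichment,
    trans_fraction,
    window_profile,
)
from breakfish.fourc.reads import revcomp

# the published HindIII anchor primer for the bait gene
AML1_H_PRIMER = "CAGGTGAGTGTGGAGGTAGAGAG"


class TestDigest:
    def test_worked_example(self):
        frags = digest_genome({"c": "NNAAGCTTNNNNAAGCTTNN"})
        spans = [(f.start, f.end) for f in frags]
        assert spans == [(0, 3), (3, 13), (13, 20)]

    def test_no_site_single_fragment(self):
        frags = digest_genome({"c": "ACGT" * 10})
        assert [(f.start, f.end) for f in frags] == [(0, 40)]

    def test_overlapping_motif_cuts_deduplicated(self):
        frags = digest_genome({"c": "AAAA"}, site="AA", cut_offset=0)
        # brute-force occurrence scan: sites at 0, 1, 2 -> interior cuts 1, 2
        spans = [(f.start, f.end) for f in frags]
        assert spans == [(0, 1), (1, 2), (2, 4)]

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(50, 400))
    def test_fragments_tile_chromosome(self, seed, length):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), length))
        frags = digest_genome({"c": seq})
        assert frags[0].start == 0 and frags[-1].end == length
        for a, b in zip(frags[:-1], frags[1:]):
            assert a.end == b.start
        assert sum(f.length for f in frags) == length

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            digest_genome({"c": "ACGT"}, site="")


class TestParseReads:
    ANCHOR = AnchorSpec("AML1-H", AML1_H_PRIMER, "chr21", 0)

    def test_published_primer_read_classified(self):
        read = AML1_H_PRIMER + "AAGCTT" + "TGCATTTTCCAGGACGTACA"
        res = parse_reads([read], [self.ANCHOR])
        assert res.n_classified == 1
        assert res.captured["AML1-H"] == ["TGCATTTTCCAGGACGTACA"]

    def test_include_site_option(self):
        read = AML1_H_PRIMER + "AAGCTT" + "TGCA"
        res = parse_reads([read], [self.ANCHOR], include_site=True)
        assert res.captured["AML1-H"] == ["AAGCTTTGCA"]

    def test_no_site_discarded(self):
        res = parse_reads([AML1_H_PRIMER + "TGCATGCA"], [self.ANCHOR])
        assert res.n_classified == 0 and res.n_no_site == 1

    def test_unknown_prefix_discarded(self):
        res = parse_reads(["TTTTTTTTTT" + "AAGCTT" + "ACGT"], [self.ANCHOR])
        assert res.n_unknown_anchor == 1

    def test_site_at_position_zero_is_no_site(self):
        res = parse_reads(["AAGCTT" + "ACGTACGT"], [self.ANCHOR])
        assert res.n_no_site == 1

    def test_prefix_primers_rejected(self):
        with pytest.raises(ValueError, match="non-prefix"):
            parse_reads([], [self.ANCHOR, AnchorSpec("x", AML1_H_PRIMER[:10])])

    def test_read_conservation(self):
        reads = [
            AML1_H_PRIMER + "AAGCTT" + "ACGTACGTACGT",
            "GGGG",
            "TTTTTTTTTTAAGCTTACGT",
        ]
        res = parse_reads(reads, [self.ANCHOR])
        assert res.n_total == len(reads)


class TestMapExact:
    GENOME = {
        "chrA": "ATGCATTTCCAGGACGTACAGGCATCGATCGGATATTACGCTAGCTAGGCTAGCTAACGATCGATCGATTT",
        "chrB": "CCGGTTAACCGGTTAACCGGCCGGTTAACCGGTTAACCGGACGTACGTAGGCCTAGGCCTTAGGACCTAGG",
    }

    def test_verbatim_capture_maps_plus(self):
        cap = self.GENOME["chrA"][10:40]
        (hit,), log = map_exact([cap], self.GENOME, min_len=20)
        assert (hit.chrom, hit.position, hit.strand) == ("chrA", 10, "+")
        assert log["mapped"] == 1

    def test_duplicated_sequence_unmapped(self):
        cap = self.GENOME["chrB"][0:20]  # CCGGTTAACCGG... occurs twice
        hits, log = map_exact([cap], self.GENOME, min_len=20)
        assert hits == [] and log["unmapped"] == 1

    def test_revcomp_capture_maps_minus_with_5prime_position(self):
        s, L = 15, 25
        cap = revcomp(self.GENOME["chrA"][s : s + L])
        (hit,), _ = map_exact([cap], self.GENOME, min_len=20)
        # oracle: the capture reads genome[s : s+L] in reverse complement,
        # so its 5' base sits at plus-strand coordinate s + L - 1
        assert hit.strand == "-"
        assert hit.chrom == "chrA"
        assert hit.position == s + L - 1

    def test_short_capture_logged(self):
        _, log = map_exact(["ACGT"], self.GENOME, min_len=20)
        assert log["too_short"] == 1


def _frags(spec):
    """spec: {chrom: [lengths]} -> tiling fragment list."""
    out = []
    for chrom, lengths in spec.items():
        pos = 0
        for i, ln in enumerate(lengths):
            out.append(RestrictionFragment(chrom, pos, pos + ln, i))
            pos += ln
    return out


class TestFragmentSignal:
    def test_left_and_right_end_counts_sum(self):
        frags = _frags({"c": [100, 200, 150]})
        mapped = [MappedPosition("c", 100, "+")] * 3 + [MappedPosition("c", 299, "-")] * 2
        signals, log = fragment_signal(mapped, frags)
        assert signals[1].raw == 5
        assert log["assigned"] == 5 and log["end_miss"] == 0

    def test_mid_fragment_read_discarded(self):
        frags = _frags({"c": [100, 200]})
        signals, log = fragment_signal([MappedPosition("c", 150, "+")], frags)
        assert all(s.raw == 0 for s in signals)
        assert log["end_miss"] == 1

    def test_tolerance_window(self):
        frags = _frags({"c": [100, 200]})
        signals, _ = fragment_signal([MappedPosition("c", 104, "+")], frags, end_tolerance=4)
        assert signals[1].raw == 1
        signals, _ = fragment_signal([MappedPosition("c", 105, "+")], frags, end_tolerance=4)
        assert signals[1].raw == 0

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_assignment(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(30, 120, 6).tolist()
        frags = _frags({"c": lengths})
        L = sum(lengths)
        mapped = [
            MappedPosition("c", int(rng.integers(0, L)), "+" if rng.random() < 0.5 else "-")
            for _ in range(40)
        ]
        signals, log = fragment_signal(mapped, frags, end_tolerance=4)
        # brute force: nearest end over all fragments
        brute = Counter()
        miss = 0
        for m in mapped:
            best, best_d = None, 5
            for i, f in enumerate(frags):
                d = abs(m.position - f.start) if m.strand == "+" else abs(m.position - (f.end - 1))
                if d < best_d:
                    best, best_d = i, d
            if best is None:
                miss += 1
            else:
                brute[best] += 1
        assert miss == log["end_miss"]
        assert {i: s.raw for i, s in enumerate(signals) if s.raw} == dict(brute)

    def test_non_tiling_fragments_rejected(self):
        bad = [RestrictionFragment("c", 0, 50, 0), RestrictionFragment("c", 60, 100, 1)]
        with pytest.raises(ValueError, match="gap"):
            fragment_signal([], bad)


class TestWindowProfile:
    def test_two_fragments_one_window(self):
        frags = _frags({"c": [200_000, 150_000, 400_000]})
        signals = [FragmentSignal(f, raw) for f, raw in zip(frags, [1, 3, 0])]
        prof = window_profile(signals, 500_000)
        assert prof.values["c"][0] == 2  # midpoints 100 kb and 275 kb; third has no signal

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(10_000, 300_000, 8).tolist()
        frags = _frags({"c": lengths})
        signals = [FragmentSignal(f, int(rng.integers(0, 3))) for f in frags]
        window = 250_000
        prof = window_profile(signals, window)
        L = sum(lengths)
        n_win = int(np.ceil(L / window))
        brute = np.zeros(n_win, dtype=int)
        for w in range(n_win):
            for s in signals:
                mid = (s.fragment.start + s.fragment.end) // 2
                if s.raw >= 1 and w * window <= mid < (w + 1) * window:
                    brute[w] += 1
        assert np.array_equal(prof.values["c"], brute)


class TestNormalizeAndMerge:
    def _signals(self, raws):
        frags = _frags({"c": [100] * len(raws)})
        return [FragmentSignal(f, r) for f, r in zip(frags, raws)]

    def test_identical_replicates_r_one(self):
        rep = self._signals([5, 0, 3, 2])
        merged, r = normalize_and_merge([rep, rep], scale=100.0)
        assert r == pytest.approx(1.0)
        norm = [s.normalized for s in merged]
        assert norm == pytest.approx([50.0, 0.0, 30.0, 20.0])

    def test_scale_invariance(self):
        a = self._signals([5, 0, 3, 2])
        b = self._signals([10, 0, 6, 4])
        merged, r = normalize_and_merge([a, b], scale=100.0)
        assert r == pytest.approx(1.0)
        assert [s.normalized for s in merged] == pytest.approx([50.0, 0.0, 30.0, 20.0])

    def test_correlation_matches_recomputation(self):
        rng = np.random.default_rng(3)
        a = self._signals(list(rng.integers(0, 20, 12)))
        b = self._signals(list(rng.integers(0, 20, 12)))
        _, r = normalize_and_merge([a, b], window=300)
        pa = window_profile(a, 300)
        pb = window_profile(b, 300)
        expected = float(np.corrcoef(pa.values["c"].astype(float), pb.values["c"].astype(float))[0, 1])
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_read_replicate_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_and_merge([self._signals([0, 0])])


class TestTransFraction:
    def test_all_cis_zero(self):
        frags = _frags({"bait": [100, 100], "other": [100]})
        signals = [FragmentSignal(f, 1 if f.chrom == "bait" else 0) for f in frags]
        assert trans_fraction(signals, "bait") == 0.0

    def test_balanced_half(self):
        frags = _frags({"bait": [100, 100], "other": [100, 100]})
        signals = [FragmentSignal(f, 1) for f in frags]
        assert trans_fraction(signals, "bait") == 0.5

    def test_no_signal_rejected(self):
        frags = _frags({"bait": [100]})
        with pytest.raises(ValueError):
            trans_fraction([FragmentSignal(frags[0], 0)], "bait")


class TestMaskBait:
    def test_bait_and_neighbours_zeroed(self):
        frags = _frags({"bait": [100] * 5, "other": [100]})
        signals = [FragmentSignal(f, 7) for f in frags]
        masked = mask_bait(signals, "bait", 2, flank=1)
        raws = [s.raw for s in masked]
        assert raws == [7, 0, 0, 0, 7, 7]


class TestPartnerEnrichment:
    def _setup(self, partner_raw, background_raw, n_genes=6):
        frags = _frags({"chr2": [100_000] * 30})
        raws = [background_raw] * 30
        genes = []
        for g in range(n_genes):
            start = g * 500_000
            genes.append(("chr2", start, start + 400_000, f"g{g}"))
        for i in (0, 5):  # fragments under partner gene g0
            raws[i] = partner_raw
        signals = [FragmentSignal(f, r) for f, r in zip(frags, raws)]
        return signals, pd.DataFrame(genes, columns=["chrom", "start", "end", "name"])

    def test_equal_singleton_groups_p_one(self):
        signals, genes = self._setup(1, 1, n_genes=2)
        u, p, _ = partner_enrichment(signals, genes, ["g0"], "chr1", window=500_000)
        assert p == pytest.approx(1.0)

    def test_all_partners_exceed_background(self):
        # distinct per-gene signals (no ties): partners 5 and 6 signal-
        # bearing fragments, background genes 1..4
        frags = _frags({"chr2": [100_000] * 60})
        per_gene = [5, 6, 1, 2, 3, 4]
        raws = [0] * 60
        for g, k in enumerate(per_gene):
            for i in range(k):
                raws[g * 10 + i] = 1
        signals = [FragmentSignal(f, r) for f, r in zip(frags, raws)]
        genes = pd.DataFrame(
            [("chr2", g * 1_000_000, g * 1_000_000 + 400_000, f"g{g}") for g in range(6)],
            columns=["chrom", "start", "end", "name"],
        )
        u, p, table = partner_enrichment(signals, genes, ["g0", "g1"], "chr1", window=1_000_000)
        assert u == 8.0  # maximal U for 2 vs 4
        assert p == pytest.approx(2 / 15)  # exact enumeration: 2 / C(6,2) two-sided
        assert table.signal[table.is_partner].min() > table.signal[~table.is_partner].max()

    def test_empty_partner_set_rejected(self):
        signals, genes = self._setup(1, 1)
        with pytest.raises(ValueError):
            partner_enrichment(signals, genes, [], "chr1")

    def test_partner_on_bait_chromosome_rejected(self):
        signals, genes = self._setup(1, 1)
        with pytest.raises(ValueError):
            partner_enrichment(signals, genes, ["g0"], "chr2")
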