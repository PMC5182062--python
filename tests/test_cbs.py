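"""Cbs scanning, classification, profiles, breakage maps, centromeres, Fitch."""

import itertools

import numpy as np
import pytest

from micmac.cbs import (breakage_map, cbs_parsimony, classify_variant,
                        conservation_profile, detect_nmcs, map_centromere,
                        scan_cbs, strand_asymmetry, CbsHit)
from micmac.sequence import revcomp
from micmac.tables import (CBS_CANONICAL, CBS_VARIANT_COUNTS, CENTROMERE_TABLE,
                           variant_census_sequences, variant_to_sequence)

FLANK = "GATTGCAGTCGGATCGATTACGGATCAGGTAC"


def _hit(seq, chrom="c"):
    label, n = classify_variant(seq)
    return CbsHit(chrom, 0, 15, "+", seq, label, n)


class TestScan:
    def test_canonical_embedded_single_hit(self):
        seq = FLANK + CBS_CANONICAL + FLANK
        hits = scan_cbs(seq, "chr")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (len(FLANK), len(FLANK) + 15, "+")
        assert h.variant_label == "canonical" and h.n_substitutions == 0

    def test_poly_a_has_no_hits(self):
        assert scan_cbs("A" * 200, "chr") == []

    def test_single_substitution_variant_1a(self):
        seq = FLANK + "AAAACCAACCTCTTT" + FLANK
        (h,) = scan_cbs(seq, "chr")
        assert h.variant_label == "1A" and h.n_substitutions == 1

    def test_minus_strand_reported_as_c_rich(self):
        seq = FLANK + revcomp(CBS_CANONICAL) + FLANK
        (h,) = scan_cbs(seq, "chr")
        assert h.strand == "-" and h.sequence == CBS_CANONICAL
        assert h.start == len(FLANK)

    def test_n_never_matches(self):
        seq = FLANK + "TAAACCAACCTCNTT".replace("N", "N") + FLANK
        assert scan_cbs(seq, "chr") == []
        assert scan_cbs("", "chr") == []

    def test_scan_recovers_planted_truth_exactly(self, genomes):
        mic, _, truth = genomes
        for chrom, seq in mic.items():
            got = {(h.start, h.strand, h.sequence, h.variant_label)
                   for h in scan_cbs(seq, chrom)}
            want = {(c.start, c.strand, c.sequence, c.variant)
                    for c in truth.cbs_by_chromosome(chrom)}
            assert got == want


class TestClassify:
    @pytest.mark.parametrize("seq,label,n", [
        (CBS_CANONICAL, "canonical", 0),
        ("TAAACCAACCCCTTT", "11C", 1),
        ("AAAACCAACCTCTTA", "1A,15A", 2),
    ])
    def test_examples(self, seq, label, n):
        assert classify_variant(seq) == (label, n)

    def test_census_labels_round_trip(self):
        for label in CBS_VARIANT_COUNTS:
            assert classify_variant(variant_to_sequence(label))[0] == label

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="15-mer"):
            classify_variant("TAAACC")

    def test_more_than_two_substitutions_flagged_nonfunctional(self):
        label, n = classify_variant("AAAACCAACCCCAAA")
        assert n > 2
        hit = _hit("AAAACCAACCCCAAA")
        assert not hit.functional


class TestConservation:
    def test_identical_sequences_two_bits(self):
        prof = conservation_profile([CBS_CANONICAL] * 5)
        assert np.allclose(prof, 2.0)

    def test_uniform_column_zero_bits(self):
        prof = conservation_profile(["A", "C", "G", "T"])
        assert prof[0] == pytest.approx(0.0)

    def test_census_multiset_ten_fully_conserved_positions(self):
        prof = conservation_profile(variant_census_sequences())
        assert int(np.sum(np.isclose(prof, 2.0))) == 10
        assert prof.min() >= 0.0 and prof.max() <= 2.0

    def test_order_invariance_and_empty_error(self):
        seqs = variant_census_sequences()
        shuffled = list(reversed(seqs))
        assert np.allclose(conservation_profile(seqs),
                           conservation_profile(shuffled))
        with pytest.raises(ValueError):
            conservation_profile([])

    def test_n_columns_excluded_from_counts(self):
        prof = conservation_profile(["NA", "AA", "AA"])
        assert prof[0] == pytest.approx(2.0)


class TestStrandAsymmetry:
    def test_census_counts_27_to_1(self):
        hits = [_hit(s) for s in variant_census_sequences()]
        n_c, n_g, chi2, p = strand_asymmetry(hits)
        assert (n_c, n_g) == (27, 1)
        assert chi2 == pytest.approx(338 / 14)
        assert p < 0.01

    def test_balanced_counts_give_zero_statistic(self):
        hits = [_hit("TAAACCAACCCCTTT")] * 5 + [_hit("TAAACCAACCTCGTT")] * 5
        n_c, n_g, chi2, p = strand_asymmetry(hits)
        assert (n_c, n_g) == (5, 5)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_no_cg_substitutions_undefined(self):
        n_c, n_g, chi2, p = strand_asymmetry([_hit(CBS_CANONICAL)])
        assert (n_c, n_g) == (0, 0) and chi2 is None and p is None

    def test_substitution_bookkeeping_consistency(self):
        """Sum over variants of count*n_subs = C+G subs + A/T subs."""
        hits = [_hit(s) for s in variant_census_sequences()]
        total = sum(h.n_substitutions for h in hits)
        n_c, n_g, _, _ = strand_asymmetry(hits)
        n_at = sum(1 for h in hits
                   for obs, canon in zip(h.sequence, CBS_CANONICAL)
                   if obs != canon and obs in "AT")
        assert total == n_c + n_g + n_at == 139


class TestBreakageMap:
    def test_three_hits_four_segments(self):
        seq = ("G" * 100 + CBS_CANONICAL) * 3 + "G" * 100
        hits = scan_cbs(seq, "chr")
        bmap = breakage_map(seq, hits)
        assert len(hits) == 3 and len(bmap.segments) == 4
        assert bmap.segments[0].terminal and bmap.segments[-1].terminal
        assert not bmap.segments[1].terminal
        # segments tile the chromosome minus the motifs
        spans = sum(s.length for s in bmap.segments)
        assert spans == len(seq) - 3 * 15

    def test_no_hits_single_segment(self):
        bmap = breakage_map(1000, [], chromosome_id="chr")
        assert len(bmap.segments) == 1
        assert bmap.segments[0].length == 1000

    def test_printed_chromosome1_bounds_give_9_26_mb(self):
        row = CENTROMERE_TABLE[1]
        l = int(row["l_cbs_mb"] * 1e6)
        r = int(row["r_cbs_mb"] * 1e6)
        hits = [CbsHit("chr1", l, l + 15, "+", CBS_CANONICAL, "canonical", 0),
                CbsHit("chr1", r, r + 15, "+", CBS_CANONICAL, "canonical", 0)]
        bmap = breakage_map(int(row["length_mb"] * 1e6), hits, "chr1")
        mid = bmap.segments[1]
        assert mid.end - mid.start == pytest.approx(9.26e6, abs=20)


class TestNmc:
    def _map(self):
        seq = "G" * 500 + CBS_CANONICAL + "G" * 300 + CBS_CANONICAL + "G" * 500
        return breakage_map(seq, scan_cbs(seq, "chr"))

    def test_uncovered_internal_segment_reported(self):
        bmap = self._map()
        cov = np.ones(bmap.length)
        cov[515:815] = 0
        nmcs = detect_nmcs(bmap, cov)
        assert [(s.start, s.end) for s in nmcs] == [(515, 815)]

    def test_covered_segment_not_reported(self):
        bmap = self._map()
        assert detect_nmcs(bmap, np.ones(bmap.length)) == []

    def test_uncovered_terminal_segment_excluded(self):
        bmap = self._map()
        cov = np.ones(bmap.length)
        cov[:500] = 0
        assert detect_nmcs(bmap, cov) == []

    def test_missing_coverage_is_error(self):
        with pytest.raises(ValueError):
            detect_nmcs(self._map(), None)


class TestCentromere:
    def _table_map(self, chrom_no, extra_cbs=()):
        row = CENTROMERE_TABLE[chrom_no]
        length = int(row["length_mb"] * 1e6)
        pos = sorted([int(row["l_cbs_mb"] * 1e6), int(row["r_cbs_mb"] * 1e6),
                      *extra_cbs])
        hits = [CbsHit(f"chr{chrom_no}", p, p + 15, "+", CBS_CANONICAL,
                       "canonical", 0) for p in pos]
        return breakage_map(length, hits, f"chr{chrom_no}"), row, length

    def test_chr1_interval_and_midpoint(self):
        bmap, row, length = self._table_map(1, extra_cbs=(5_000_000, 30_000_000))
        dels = [(0, 13_000_000), (24_000_000, length)]
        call = map_centromere(bmap, dels)
        assert call.cen_length == pytest.approx(9.26e6, abs=20)
        assert call.cen_midpoint == pytest.approx(18.61e6, rel=1e-3)
        assert call.chromosome_midpoint == pytest.approx(18.16e6, rel=1e-3)

    def test_chr5_interval(self):
        bmap, row, length = self._table_map(5, extra_cbs=(3_000_000,))
        dels = [(0, 10_000_000), (18_000_000, length)]
        call = map_centromere(bmap, dels)
        assert call.cen_length == pytest.approx(7.02e6, abs=20)

    def test_deletions_covering_chromosome_error(self):
        bmap, _, length = self._table_map(1)
        with pytest.raises(ValueError, match="whole chromosome"):
            map_centromere(bmap, [(0, length)])

    def test_no_deletion_touching_cbs_keeps_outermost_survivors(self):
        # With every Cbs surviving, the deletion evidence cannot narrow the
        # interval below the full surviving Cbs range.
        bmap, row, length = self._table_map(1, extra_cbs=(5_000_000,))
        call = map_centromere(bmap, [(0, 1_000_000)])
        assert call.cen_interval == (5_000_000, int(row["r_cbs_mb"] * 1e6))


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def all_rooted_trees(tips):
    """All rooted binary tree shapes over labelled tips, as nested tuples."""
    if len(tips) == 1:
        yield tips[0]
        return
    first, rest = tips[0], tips[1:]
    for k in range(len(rest) + 1):
        for left_rest in itertools.combinations(rest, k):
            left = (first,) + left_rest
            right = tuple(t for t in rest if t not in left_rest)
            if not right:
                continue
            for lt in all_rooted_trees(left):
                for rt in all_rooted_trees(right):
                    yield (lt, rt)


def to_newick(tree):
    if isinstance(tree, str):
        return tree
    return f"({to_newick(tree[0])},{to_newick(tree[1])})"


def brute_force_parsimony(tree, tip_states, states):
    """Minimum mutation count by exhaustive internal-node labelling."""
    internals = []

    def collect(node):
        if isinstance(node, str):
            return
        internals.append(node)
        collect(node[0])
        collect(node[1])

    collect(tree)
    best = float("inf")
    for labels in itertools.product(states, repeat=len(internals)):
        assign = dict(zip(map(id, internals), labels))

        def cost(node, parent_state):
            if isinstance(node, str):
                s = tip_states.get(node)
                return 0 if s is None or s == parent_state else 1
            mine = assign[id(node)]
            c = 0 if parent_state is None or mine == parent_state else 1
            return c + cost(node[0], mine) + cost(node[1], mine)

        best = min(best, cost(tree, None))
    return best


class TestParsimony:
    def test_uniform_tips_zero_mutations(self):
        nwk = "((a,b),(c,d));"
        assert cbs_parsimony(nwk, {t: "canonical" for t in "abcd"}) == 0

    def test_single_variant_one_mutation(self):
        nwk = "((a,b),(c,d));"
        states = {"a": "canonical", "b": "canonical", "c": "canonical", "d": "14C"}
        assert cbs_parsimony(nwk, states) == 1

    def test_missing_tip_unconstrained(self):
        nwk = "((a,b),(c,d));"
        states = {"a": "canonical", "b": "canonical", "c": "canonical", "d": None}
        assert cbs_parsimony(nwk, states) == 0

    def test_empty_tip_set_error(self):
        with pytest.raises(ValueError):
            cbs_parsimony("((a,b),(c,d));", {})

    def test_matches_brute_force_on_random_four_tip_assignments(self):
        rng = np.random.default_rng(0)
        states = ["canonical", "1A", "11C"]
        tips = ["a", "b", "c", "d"]
        for tree in all_rooted_trees(tuple(tips)):
            assign = {t: states[rng.integers(3)] for t in tips}
            got = cbs_parsimony(to_newick(tree) + ";", assign)
            want = brute_force_parsimony(tree, assign, states)
            assert got == want, (tree, assign)
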