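"""IES callers: per-method rules, merging, context labels, oracle agreement."""

import numpy as np
import pytest

from micmac import pipeline
from micmac.align import AlignmentBlock, ExactAligner, KmerIndex, ReadAlignment, coverage_from_blocks
from micmac.ies import (GeneModel, IesCandidate, assembly_gap_ies,
                        broken_read_sites, classify_context, length_stats,
                        load_gene_models, merge_high_confidence,
                        residual_sites_to_candidates, split_read_ies)
from micmac.sequence import revcomp
from micmac.simulate import simulate_reads


def _split_aln(name, chrom, l, r, piece=60, q0=0):
    """A read aligning in two colinear pieces around junction (l, r)."""
    return ReadAlignment(name, blocks=[
        AlignmentBlock(name, q0, q0 + piece, chrom, l - piece, l),
        AlignmentBlock(name, q0 + piece, q0 + 2 * piece, chrom, r, r + piece),
    ])


class TestSplitReads:
    def _cov(self, n=10_000, fill=5.0):
        return {"chr": np.full(n, fill)}

    def test_five_spanning_reads_exact_candidate(self):
        alns = [_split_aln(f"r{i}", "chr", 2000, 3000) for i in range(5)]
        cov = self._cov()
        cov["chr"][2000:3000] = 0
        (cand,) = split_read_ies(alns, cov)
        assert (cand.left_junction, cand.right_junction) == (2000, 3000)
        assert cand.support == 5 and cand.method == 1

    def test_two_spanning_reads_insufficient(self):
        alns = [_split_aln(f"r{i}", "chr", 2000, 3000) for i in range(2)]
        cov = self._cov()
        cov["chr"][2000:3000] = 0
        assert split_read_ies(alns, cov) == []

    def test_internal_coverage_rejects_candidate(self):
        alns = [_split_aln(f"r{i}", "chr", 2000, 3000) for i in range(4)]
        cov = self._cov()
        cov["chr"][2000:3000] = 2.1
        assert split_read_ies(alns, cov) == []

    def test_junction_in_n_run_rejected(self):
        alns = [_split_aln(f"r{i}", "chr", 2000, 3000) for i in range(4)]
        cov = self._cov()
        cov["chr"][2000:3000] = 0
        seq = "A" * 1999 + "NNN" + "A" * 10_000
        assert split_read_ies(alns, cov, mic_sequences={"chr": seq}) == []

    def test_missing_coverage_error(self):
        with pytest.raises(ValueError):
            split_read_ies([], None)

    def test_threshold_monotonicity(self, ies_run):
        base = {(c.chromosome, c.left_junction, c.right_junction)
                for c in ies_run.candidates_m1}
        assert base  # computed once on the session genome

    def test_raising_min_spanning_never_adds_candidates(self):
        alns = ([_split_aln(f"a{i}", "chr", 2000, 3000) for i in range(5)]
                + [_split_aln(f"b{i}", "chr", 5000, 5500) for i in range(3)])
        cov = self._cov()
        cov["chr"][2000:3000] = 0
        cov["chr"][5000:5500] = 0
        sets = []
        for ms in (3, 4, 5, 6):
            cands = split_read_ies(alns, cov, min_spanning=ms)
            sets.append({(c.left_junction, c.right_junction) for c in cands})
        for a, b in zip(sets, sets[1:]):
            assert b <= a

    def test_lowering_coverage_ceiling_never_adds_candidates(self):
        alns = [_split_aln(f"r{i}", "chr", 2000, 3000) for i in range(5)]
        cov = self._cov()
        cov["chr"][2000:3000] = 0.8
        sets = []
        for mc in (1.0, 0.9, 0.5, 0.1):
            cands = split_read_ies(alns, cov, max_internal_coverage=mc)
            sets.append({(c.left_junction, c.right_junction) for c in cands})
        for a, b in zip(sets, sets[1:]):
            assert b <= a


def _broken(name, mac, bp, direction, qlen=100, alen=60):
    if direction == "fwd":     # aligned prefix, breakpoint at its right end
        block = AlignmentBlock(name, 0, alen, mac, bp - alen, bp)
    else:                      # aligned suffix, breakpoint at its left end
        block = AlignmentBlock(name, qlen - alen, qlen, mac, bp, bp + alen)
    return ReadAlignment(name, blocks=[block])


class TestBrokenReads:
    def test_six_reads_both_directions_validated(self):
        alns = ([_broken(f"f{i}", "m", 500, "fwd") for i in range(3)]
                + [_broken(f"r{i}", "m", 498, "rev") for i in range(3)])
        lengths = {a.query_id: 100 for a in alns}
        (site,) = broken_read_sites(alns, lengths)
        assert site.validated
        assert site.n_forward == 3 and site.n_reverse == 3
        assert site.overlap == 2   # breakpoint overlap = TDR evidence

    def test_one_direction_only_rejected(self):
        alns = [_broken(f"f{i}", "m", 500, "fwd") for i in range(8)]
        lengths = {a.query_id: 100 for a in alns}
        (site,) = broken_read_sites(alns, lengths)
        assert not site.validated

    def test_distant_clusters_split_and_unvalidated(self):
        alns = ([_broken(f"f{i}", "m", 500, "fwd") for i in range(2)]
                + [_broken(f"g{i}", "m", 502, "rev") for i in range(1)]
                + [_broken(f"h{i}", "m", 527, "fwd") for i in range(2)]
                + [_broken(f"k{i}", "m", 528, "rev") for i in range(1)])
        lengths = {a.query_id: 100 for a in alns}
        sites = broken_read_sites(alns, lengths)
        assert len(sites) == 2
        assert not any(s.validated for s in sites)

    def test_liftover_to_mic_junctions(self):
        sites = [type("S", (), dict(mac_id="m", left_breakpoint=1000,
                                    right_breakpoint=998, n_forward=4,
                                    n_reverse=3, n_total=7, validated=True))()]
        chains = {"m": [
            AlignmentBlock("m", 0, 1000, "mic", 5000, 6000),
            AlignmentBlock("m", 1000, 2000, "mic", 8000, 9000),
        ]}
        (cand,) = residual_sites_to_candidates(sites, chains)
        assert (cand.left_junction, cand.right_junction) == (6000, 8000)
        assert cand.method == 2


class TestAssemblyGaps:
    def _blocks(self, mic_gap, mac_gap):
        return [
            AlignmentBlock("mac1", 0, 1000, "mic1", 0, 1000),
            AlignmentBlock("mac1", 1000 + mac_gap, 2000, "mic1",
                           1000 + mic_gap, 2000 + mic_gap),
        ]

    def test_large_asymmetric_gap_called(self):
        (cand,) = assembly_gap_ies(self._blocks(1500, 8))
        assert cand.length == 1500 and cand.method == 3

    def test_small_gap_not_called(self):
        assert assembly_gap_ies(self._blocks(60, 4)) == []

    def test_boundary_delta_101_called(self):
        (cand,) = assembly_gap_ies(self._blocks(104, 3))
        assert cand.length == 104

    def test_non_colinear_pair_skipped(self):
        blocks = [AlignmentBlock("mac1", 0, 1000, "mic1", 5000, 6000),
                  AlignmentBlock("mac1", 1000, 2000, "mic1", 1000, 2000)]
        assert assembly_gap_ies(blocks) == []


class TestMerge:
    def test_cross_method_agreement_merges(self):
        cands = [IesCandidate("chr", 100, 600, method=1, support=5),
                 IesCandidate("chr", 100, 600, method=3, support=490)]
        (rec,) = merge_high_confidence(cands, {"chr": "A" * 1000})
        assert rec.methods == frozenset({1, 3})
        assert rec.support == 5 and rec.length == 500

    def test_junction_gap_demotes_to_provisional(self):
        seq = "A" * 95 + "NNNNN" + "A" * 900
        cands = [IesCandidate("chr", 100, 600, method=3, support=500)]
        (rec,) = merge_high_confidence(cands, {"chr": seq})
        assert rec.confidence == "provisional" and "junction_gap" in rec.flags

    def test_disagreeing_junctions_kept_separate(self):
        cands = [IesCandidate("chr", 100, 600, method=1, support=3),
                 IesCandidate("chr", 104, 600, method=3, support=500)]
        recs = merge_high_confidence(cands, {"chr": "A" * 1000})
        assert len(recs) == 2

    def test_full_synthetic_run_equals_truth(self, ies_run):
        assert ies_run.detected_junctions() == ies_run.truth_junctions

    def test_method_concordance_on_well_covered_ies(self, ies_run, genomes):
        """Truth IESs >= 500 bp are all found by the assembly route, and the
        read-based routes corroborate nearly all of them; sites whose random
        read draw leaves fewer than the required spanning/broken reads are
        the only single-method calls."""
        _, _, truth = genomes
        by_junction = {(r.chromosome, r.left_junction, r.right_junction): r
                       for r in ies_run.records}
        n = multi = 0
        for ies in truth.ies_intervals:
            if ies.length < 500:
                continue
            rec = by_junction[(ies.chromosome, *ies.realized)]
            assert 3 in rec.methods
            n += 1
            multi += len(rec.methods) >= 2
        assert multi / n >= 0.9


class TestLengthStats:
    def test_small_examples(self):
        recs = [IesCandidate("c", 0, n, 1) for n in (100, 200, 300)]
        merged = [type("R", (), {"length": n})() for n in (100, 200, 300)]
        stats = length_stats(merged)
        assert stats["mean"] == 200 and stats["median"] == 200

    def test_single_shortest_class(self):
        stats = length_stats([type("R", (), {"length": 136})()])
        assert stats["min"] == 136

    def test_empty_error(self):
        with pytest.raises(ValueError):
            length_stats([])

    def test_synthetic_sample_mean_near_configured(self, ies_run, sim_config):
        stats = length_stats(ies_run.records)
        mean, _ = sim_config.ies_length_lognormal
        mu, sigma = sim_config.ies_lognormal_params
        sd = np.sqrt((np.exp(sigma ** 2) - 1) * np.exp(2 * mu + sigma ** 2))
        se = sd / np.sqrt(stats["n"])
        assert abs(stats["mean"] - mean) <= 3.5 * se


class TestContext:
    def _gene(self):
        return GeneModel("chr", "chr", 1000, 3000, "+",
                         exons=[(1000, 1500), (2500, 3000)])

    def _rec(self, l, r):
        from micmac.ies import IesRecord
        return IesRecord("chr", l, r, frozenset({1}), 3)

    def test_between_genes_intergenic(self):
        (rec,) = classify_context([self._rec(5000, 6000)], [self._gene()])
        assert rec.context == "intergenic"

    def test_inside_intron_intronic(self):
        (rec,) = classify_context([self._rec(1600, 2400)], [self._gene()])
        assert rec.context == "intronic"

    def test_single_base_exon_overlap_is_exonic(self):
        (rec,) = classify_context([self._rec(1499, 2400)], [self._gene()])
        assert rec.context == "exonic"

    def test_gff3_round_trip_labels_match_truth(self, genomes, tmp_path):
        from micmac.io import write_gff3
        from micmac.ies import IesRecord
        _, _, truth = genomes
        path = tmp_path / "genes.gff3"
        write_gff3(truth.gene_intervals, path)
        genes = load_gene_models(str(path))
        recs = [IesRecord(i.chromosome, i.left_junction, i.right_junction,
                          frozenset({1}), 3) for i in truth.ies_intervals]
        classify_context(recs, genes)
        for rec, ies in zip(recs, truth.ies_intervals):
            assert rec.context == ies.context


# ---------------------------------------------------------------------------
# Brute-force oracle on the toy world
# ---------------------------------------------------------------------------

def brute_force_align(read, genome, k=31, max_pieces=4):
    """Exhaustive substring alignment mirroring the greedy split policy."""
    def occurrences(s):
        out = []
        for chrom, g in genome.items():
            start = g.find(s)
            while start != -1:
                out.append((chrom, start))
                start = g.find(s, start + 1)
        return out

    def longest_prefix(s):
        best = None
        lo = k
        if len(s) < k or not occurrences(s[:k]):
            return None
        length = k
        while length < len(s) and occurrences(s[:length + 1]):
            length += 1
        occ = occurrences(s[:length])
        return (length, occ)

    for strand, seq in (("+", read), ("-", revcomp(read))):
        res = longest_prefix(seq)
        if res is None:
            # suffix anchor
            if len(seq) >= k and occurrences(seq[-k:]):
                length = k
                while length < len(seq) and occurrences(seq[-length - 1:]):
                    length += 1
                occ = occurrences(seq[-length:])
                chrom, pos = occ[0]
                blocks = [AlignmentBlock("r", len(seq) - length, len(seq),
                                         chrom, pos, pos + length, strand)]
                return ReadAlignment("r", blocks, strand, ambiguous=len(occ) > 1)
            continue
        blocks, pos_q, ambiguous = [], 0, False
        rest = seq
        while rest and len(blocks) < max_pieces:
            got = longest_prefix(rest)
            if got is None:
                break
            length, occ = got
            ambiguous = ambiguous or len(occ) > 1
            chrom, pos = occ[0]
            blocks.append(AlignmentBlock("r", pos_q, pos_q + length,
                                         chrom, pos, pos + length, strand))
            pos_q += length
            rest = seq[pos_q:]
        if blocks:
            return ReadAlignment("r", blocks, strand, ambiguous=ambiguous)
    return ReadAlignment("r", [], "+")


def test_split_read_calls_match_exhaustive_oracle(toy_genomes, toy_config):
    """On a <10 kb toy genome the k-mer aligner route and an exhaustive
    substring-matching oracle produce identical split-read IES calls."""
    mic, mac, truth = toy_genomes
    rng = np.random.default_rng(17)
    reads = simulate_reads(mac, toy_config, rng)
    index = KmerIndex(mic)
    aligner = ExactAligner(index)
    lengths = {c: len(s) for c, s in mic.items()}

    fast, slow = [], []
    for r in reads:
        fa = aligner.align_read(r.name, r.sequence)
        oa = brute_force_align(r.sequence, mic)
        fast.append(fa)
        slow.append(ReadAlignment(r.name, oa.blocks, oa.strand, oa.ambiguous))
    cov_f = coverage_from_blocks([b for a in fast for b in a.blocks], lengths)
    cov_s = coverage_from_blocks([b for a in slow for b in a.blocks], lengths)
    cands_f = split_read_ies(fast, cov_f, mic_sequences=mic)
    cands_s = split_read_ies(slow, cov_s, mic_sequences=mic)
    as_set = lambda cs: {(c.chromosome, c.left_junction, c.right_junction,
                          c.support) for c in cs}
    assert as_set(cands_f) == as_set(cands_s)
    assert cands_f  # the toy world has detectable IESs
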