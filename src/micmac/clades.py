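"""Detection and clustering of duplicated Cbs-containing segments.

Duplications of a Cbs together with its flanking sequence are detected by
all-vs-all local alignment of 415 bp "Cbs segments" (the motif plus 200 bp
of flank on each side), and clustered into clades — groups presumed to
descend from successive duplications of an ancestral Cbs-containing
segment.  Two clustering routes are provided: connected components over an
expectation threshold, and Markov clustering of self-normalized bit scores.

Expectations are Karlin-Altschul-style values computed for this package's
own scoring scheme (match +1 / mismatch -2, affine gaps 5/2, BLASTN-like);
they are comparable within one run but not numerically identical to NCBI
E-values, so clustering thresholds should be calibrated against the
randomized-flank null (:func:`randomize_flanks`) rather than read as
absolute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .cbs import CbsHit
from .sequence import encode

DEFAULT_FLANK = 200
MERGE_DISTANCE = 400   # Cbs's closer than this share one merged segment


@dataclass
class CbsSegment:
    """A Cbs-centred genomic segment used for duplication detection."""

    segment_id: str
    chromosome: str
    start: int
    end: int
    sequence: str
    cbs_offsets: list[tuple[int, int]]   # motif intervals, segment-local
    source_hits: list[int] = field(default_factory=list)
    truncated: bool = False

    @property
    def contained_cbs_count(self) -> int:
        return len(self.cbs_offsets)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimilarityEdge:
    query_id: str
    target_id: str
    score: float               # raw local alignment score
    bit_score: float
    normalized_score: float    # score / self-score of the query
    expectation: float
    cbs_aligned: bool


@dataclass
class CladeSet:
    clades: list[list[str]]
    method: str

    @property
    def n_clades(self) -> int:
        return len(self.clades)

    def clade_of(self) -> dict[str, int]:
        return {sid: i for i, clade in enumerate(self.clades) for sid in clade}


def extract_segments(genome: dict[str, str], hits: list[CbsHit],
                     flank: int = DEFAULT_FLANK) -> list[CbsSegment]:
    """Cut one segment per Cbs (motif + ``flank`` bp each side).

    Cbs's whose starts are closer than ``2 * flank`` are merged into one
    segment spanning all of them with outer flanks; segments running off a
    chromosome end are truncated and flagged.
    """
    segments: list[CbsSegment] = []
    by_chrom: dict[str, list[tuple[int, CbsHit]]] = {}
    for i, h in enumerate(hits):
        by_chrom.setdefault(h.chromosome, []).append((i, h))
    n = 0
    for chrom, items in by_chrom.items():
        items.sort(key=lambda ih: ih[1].start)
        group: list[tuple[int, CbsHit]] = []
        for ih in items:
            if group and ih[1].start - group[-1][1].start < 2 * flank:
                group.append(ih)
                continue
            if group:
                segments.append(_realize(genome[chrom], chrom, group, flank, n))
                n += 1
            group = [ih]
        if group:
            segments.append(_realize(genome[chrom], chrom, group, flank, n))
            n += 1
    return segments


def _realize(seq: str, chrom: str, group: list[tuple[int, CbsHit]],
             flank: int, n: int) -> CbsSegment:
    first, last = group[0][1], group[-1][1]
    start = max(0, first.start - flank)
    end = min(len(seq), last.end + flank)
    return CbsSegment(
        segment_id=f"seg{n}",
        chromosome=chrom,
        start=start,
        end=end,
        sequence=seq[start:end],
        cbs_offsets=[(h.start - start, h.end - start) for _, h in group],
        source_hits=[i for i, _ in group],
        truncated=(start > first.start - flank) or (end < last.end + flank),
    )


def split_merged_segments(segments: list[CbsSegment]) -> list[CbsSegment]:
    """Decompose multi-Cbs segments at midpoints between contained Cbs's.

    Merged segments would self-match through their shared sequence and
    spuriously inflate significance; splitting them into one-Cbs pieces
    avoids that while keeping each Cbs aligned with its own flank.
    """
    out: list[CbsSegment] = []
    for seg in segments:
        if seg.contained_cbs_count <= 1:
            out.append(seg)
            continue
        offs = seg.cbs_offsets
        cuts = [0] + [
            (offs[i][1] + offs[i + 1][0]) // 2 for i in range(len(offs) - 1)
        ] + [seg.length]
        for j, (o_start, o_end) in enumerate(offs):
            lo, hi = cuts[j], cuts[j + 1]
            out.append(CbsSegment(
                segment_id=f"{seg.segment_id}.{j}",
                chromosome=seg.chromosome,
                start=seg.start + lo,
                end=seg.start + hi,
                sequence=seg.sequence[lo:hi],
                cbs_offsets=[(o_start - lo, o_end - lo)],
                source_hits=[seg.source_hits[j]] if j < len(seg.source_hits) else [],
                truncated=True,
            ))
    return out


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _make_aligner(match: float, mismatch: float,
                  gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def karlin_altschul_lambda(base_freqs: np.ndarray, match: float = 1.0,
                           mismatch: float = -2.0) -> float:
    """Ungapped Karlin-Altschul lambda for a match/mismatch scheme.

    Solves ``sum_ij p_i p_j exp(lambda s_ij) = 1`` for the background base
    frequencies; composition-aware so AT-rich genomes get the smaller
    lambda (and hence larger expectations) they deserve.
    """
    p = np.asarray(base_freqs, dtype=float)
    p = p / p.sum()
    p_match = float(np.sum(p ** 2))

    def f(lam: float) -> float:
        return (p_match * math.exp(lam * match)
                + (1.0 - p_match) * math.exp(lam * mismatch) - 1.0)

    return float(brentq(f, 1e-6, 10.0))


def _composition(segments: list[CbsSegment]) -> np.ndarray:
    counts = np.zeros(4)
    for seg in segments:
        arr = encode(seg.sequence)
        counts += np.bincount(arr[arr < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def align_all_pairs(segments: list[CbsSegment],
                    match: float = 1.0, mismatch: float = -2.0,
                    gap_open: float = 5.0, gap_extend: float = 2.0,
                    k_const: float = 0.1,
                    require_cbs_aligned: bool = True) -> list[SimilarityEdge]:
    """All-vs-all local alignment of Cbs segments.

    Every unordered pair is aligned once and reported in both directions
    (normalized scores differ when segment lengths do).  An edge is kept
    only if the two Cbs motifs fall inside the aligned region and align to
    one another, unless ``require_cbs_aligned`` is off.  Low-complexity
    masking is never applied — the flanks of these genomes are legitimately
    AT-rich.
    """
    if len(segments) < 2:
        return []
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    lam = karlin_altschul_lambda(_composition(segments), match, mismatch)
    ln_k = math.log(k_const)
    edges: list[SimilarityEdge] = []
    self_scores = {seg.segment_id: match * seg.length for seg in segments}
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            a, b = segments[i], segments[j]
            score = float(aligner.score(a.sequence, b.sequence))
            if score <= 0:
                continue
            best = aligner.align(a.sequence, b.sequence)[0]
            cbs_ok = _cbs_aligned(best, a, b)
            if require_cbs_aligned and not cbs_ok:
                continue
            bits = (lam * score - ln_k) / math.log(2.0)
            expect = a.length * b.length * 2.0 ** (-bits)
            for q, t in ((a, b), (b, a)):
                edges.append(SimilarityEdge(
                    query_id=q.segment_id, target_id=t.segment_id,
                    score=score, bit_score=bits,
                    normalized_score=score / self_scores[q.segment_id],
                    expectation=expect, cbs_aligned=cbs_ok))
    return edges


def _cbs_aligned(alignment, a: CbsSegment, b: CbsSegment) -> bool:
    """True iff some Cbs of a maps onto some Cbs of b within the alignment."""
    try:
        blocks_a, blocks_b = alignment.aligned
    except AttributeError:
        return False
    for (qa, qe), (ta, te) in zip(blocks_a, blocks_b):
        for ca_s, ca_e in a.cbs_offsets:
            if ca_s >= qa and ca_e <= qe:
                mapped_s = ta + (ca_s - qa)
                mapped_e = mapped_s + (ca_e - ca_s)
                for cb_s, cb_e in b.cbs_offsets:
                    overlap = min(mapped_e, cb_e) - max(mapped_s, cb_s)
                    if overlap >= (ca_e - ca_s) - 3:
                        return True
    return False


def randomize_flanks(segment: CbsSegment, seed: int) -> CbsSegment:
    """Composition-preserving shuffle of the flanks, Cbs bases untouched.

    Each maximal non-Cbs run is permuted independently, so the control has
    exactly the original base multiset per flank.  Used to build the
    empirical null for clustering-threshold calibration (the intact Cbs
    alone produces a floor of spurious similarity).
    """
    rng = np.random.default_rng(seed)
    chars = list(segment.sequence)
    runs: list[tuple[int, int]] = []
    prev = 0
    for s, e in sorted(segment.cbs_offsets):
        if s > prev:
            runs.append((prev, s))
        prev = e
    if prev < len(chars):
        runs.append((prev, len(chars)))
    for s, e in runs:
        sub = chars[s:e]
        rng.shuffle(sub)
        chars[s:e] = sub
    return CbsSegment(
        segment_id=f"{segment.segment_id}|shuffled{seed}",
        chromosome=segment.chromosome,
        start=segment.start, end=segment.end,
        sequence="".join(chars),
        cbs_offsets=list(segment.cbs_offsets),
        source_hits=list(segment.source_hits),
        truncated=segment.truncated,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_threshold(edges: list[SimilarityEdge],
                      threshold_expectation: float = 1e-18) -> CladeSet:
    """Connected components over edges at or below the expectation cutoff."""
    g = nx.Graph()
    for e in edges:
        if e.cbs_aligned and e.expectation <= threshold_expectation:
            g.add_edge(e.query_id, e.target_id)
    clades = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    clades.sort()
    return CladeSet(clades=clades, method="threshold-components")


def cluster_score_ratio(edges: list[SimilarityEdge],
                        inflation: float = 2.0,
                        max_iter: int = 200,
                        tol: float = 1e-8,
                        expect_threshold: float | None = None) -> CladeSet:
    """Markov clustering on the self-normalized score matrix.

    Deterministic given the inflation parameter and iteration cap; if the
    iteration does not converge within the cap the partition at the cap is
    returned (callers can inspect ``method`` which gains a ``!cap`` suffix).
    """
    ids = sorted({e.query_id for e in edges} | {e.target_id for e in edges})
    if not ids:
        return CladeSet(clades=[], method="score-ratio-mcl")
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    m = np.eye(n)
    for e in edges:
        if not e.cbs_aligned:
            continue
        if expect_threshold is not None and e.expectation > expect_threshold:
            continue
        m[idx[e.target_id], idx[e.query_id]] = max(
            m[idx[e.target_id], idx[e.query_id]], e.normalized_score)
    m = m / m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m                       # expansion
        m = np.power(m, inflation)      # inflation
        m[m < 1e-12] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    clusters: list[set[str]] = []
    attractors = np.nonzero(np.diag(m) > 1e-6)[0]
    for a in attractors:
        members = {ids[j] for j in np.nonzero(m[a] > 1e-6)[0]} | {ids[a]}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    clades = sorted(sorted(c) for c in clusters if len(c) >= 2)
    tag = "score-ratio-mcl" + ("" if converged else "!cap")
    return CladeSet(clades=clades, method=tag)
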