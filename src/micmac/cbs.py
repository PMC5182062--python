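"""Chromosome breakage sequence (Cbs) mapping and analysis.

The Cbs is a 15 bp cis-acting element that directs developmental
fragmentation of germline (MIC) chromosomes into somatic (MAC) chromosomes.
This module finds Cbs motifs on both strands, classifies variants relative
to the canonical C-rich strand 15-mer, computes per-position information
content and C/G substitution strand asymmetry, tiles chromosomes into
breakage maps, classifies non-maintained chromosomes (NMCs) from MAC
presence evidence, demarcates centromeres from viable arm-deletion strains,
and counts minimum-mutation (Fitch) histories for cross-species Cbs
variants on small trees.

Coordinates are 0-based half-open internally; report/TSV output is 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from .sequence import revcomp, encode
from .tables import CBS_CANONICAL

# Explicit character classes so that N never matches.
_CBS_FWD = re.compile(r"(?=([AT]AAACCAACC[CT]C[ACGT][ACT][AT]))")
_REV = re.compile(r"(?=([AT][AGT][ACGT]G[AG]GGTTGGTTT[AT]))")


@dataclass(frozen=True)
class CbsHit:
    """One Cbs motif match, reported on the C-rich strand."""

    chromosome: str
    start: int          # 0-based, on the forward axis
    end: int            # start + 15
    strand: str         # '+' if the C-rich strand is the forward strand
    sequence: str       # C-rich strand 15-mer
    variant_label: str
    n_substitutions: int
    overlaps_previous: bool = False

    @property
    def functional(self) -> bool:
        return self.n_substitutions <= 2


def classify_variant(sequence: str) -> tuple[str, int]:
    """Label a 15-mer by its substitutions relative to the canonical Cbs.

    Returns ``("canonical", 0)`` for an exact match, else a comma-joined
    list of position+base tokens in ascending position order, e.g.
    ``("11C,13A", 2)``.  More than two substitutions marks a sequence that
    would not be a functional breakage signal; the label is still returned
    and the caller can test :attr:`CbsHit.functional`.
    """
    if len(sequence) != 15:
        raise ValueError(f"Cbs variant classification needs a 15-mer, got length {len(sequence)}")
    sequence = sequence.upper()
    subs = [
        f"{i + 1}{b}"
        for i, (b, c) in enumerate(zip(sequence, CBS_CANONICAL))
        if b != c
    ]
    if not subs:
        return "canonical", 0
    return ",".join(subs), len(subs)


def scan_cbs(sequence: str, chromosome_id: str) -> list[CbsHit]:
    """Scan both strands of a chromosome for Cbs family motifs.

    Minus-strand hits are reported with the C-rich strand sequence and
    forward-axis coordinates.  Hits are sorted by start; overlapping hits
    (possible through the degenerate terminal positions) are all kept and
    marked.
    """
    seq = sequence.upper()
    raw: list[tuple[int, str, str]] = []
    for m in _CBS_FWD.finditer(seq):
        raw.append((m.start(), "+", m.group(1)))
    for m in _REV.finditer(seq):
        raw.append((m.start(), "-", revcomp(m.group(1))))
    raw.sort()
    hits: list[CbsHit] = []
    prev_end = -1
    for start, strand, crich in raw:
        label, nsub = classify_variant(crich)
        hits.append(
            CbsHit(
                chromosome=chromosome_id,
                start=start,
                end=start + 15,
                strand=strand,
                sequence=crich,
                variant_label=label,
                n_substitutions=nsub,
                overlaps_previous=start < prev_end,
            )
        )
        prev_end = max(prev_end, start + 15)
    return hits


def conservation_profile(sequences: list[str]) -> np.ndarray:
    """Per-position information content (bits) of aligned sequences.

    ``value = 2 + sum_b f_b log2 f_b`` with zero-frequency terms dropped;
    2 bits means a single base occupies the column, 0 bits means all four
    bases are equally frequent.  Columns may include N (e.g. in flanks);
    N's are excluded from the frequency counts.  All sequences must have
    equal length (hits plus flanks aligned on the C-rich strand).
    """
    if not sequences:
        raise ValueError("conservation profile of an empty sequence set")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    mat = np.stack([encode(s) for s in sequences])
    ncol = mat.shape[1]
    out = np.empty(ncol)
    for j in range(ncol):
        col = mat[:, j]
        col = col[col < 4]
        if len(col) == 0:
            out[j] = 0.0
            continue
        freqs = np.bincount(col, minlength=4) / len(col)
        nz = freqs[freqs > 0]
        out[j] = 2.0 + float(np.sum(nz * np.log2(nz)))
    return out


def strand_asymmetry(hits: list[CbsHit]) -> tuple[int, int, float | None, float | None]:
    """Count substitutions to C vs to G on the C-rich strand.

    Doubly substituted variants contribute each of their mismatches.  The
    chi-square (df=1, no continuity correction) tests the C/G counts
    against an even split; with zero C+G substitutions the statistic is
    undefined and reported as None.
    """
    n_c = n_g = 0
    for hit in hits:
        for obs, canon in zip(hit.sequence, CBS_CANONICAL):
            if obs != canon:
                if obs == "C":
                    n_c += 1
                elif obs == "G":
                    n_g += 1
    total = n_c + n_g
    if total == 0:
        return 0, 0, None, None
    expected = total / 2.0
    chi2 = (n_c - expected) ** 2 / expected + (n_g - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return n_c, n_g, float(chi2), p


@dataclass(frozen=True)
class Segment:
    """One inter-Cbs interval of a breakage map."""

    chromosome: str
    start: int
    end: int
    left_cbs: int | None   # index into BreakageMap.hits, None at chromosome start
    right_cbs: int | None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def terminal(self) -> bool:
        return self.left_cbs is None or self.right_cbs is None


@dataclass
class BreakageMap:
    """Ordered Cbs hits and the inter-Cbs segments they delimit."""

    chromosome: str
    length: int
    hits: list[CbsHit]
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            hits = sorted(self.hits, key=lambda h: h.start)
            self.hits = hits
            bounds = [(None, 0)] + [(i, h.end) for i, h in enumerate(hits)]
            segs = []
            for k, (left_idx, seg_start) in enumerate(bounds):
                if k + 1 < len(bounds):
                    right_idx = bounds[k + 1][0]
                    seg_end = hits[right_idx].start
                else:
                    right_idx, seg_end = None, self.length
                segs.append(Segment(self.chromosome, seg_start, seg_end, left_idx, right_idx))
            self.segments = segs


def breakage_map(sequence_or_length: str | int, hits: list[CbsHit],
                 chromosome_id: str | None = None) -> BreakageMap:
    """Tile a chromosome into inter-Cbs segments (hits + 1 segments)."""
    if isinstance(sequence_or_length, str):
        length = len(sequence_or_length)
    else:
        length = int(sequence_or_length)
    chrom = chromosome_id or (hits[0].chromosome if hits else "chromosome")
    return BreakageMap(chromosome=chrom, length=length, hits=list(hits))


def detect_nmcs(bmap: BreakageMap,
                coverage: np.ndarray | dict[int, float],
                threshold: float = 0.05) -> list[Segment]:
    """Classify non-maintained chromosome (NMC) segments.

    An NMC is a segment delimited by two consecutive Cbs's whose bases are
    (almost) absent from the MAC: fraction of segment bases with MAC
    alignment evidence below ``threshold``.  ``coverage`` is either a
    per-base 0/1-or-depth vector over the chromosome, or a mapping of
    segment index to covered fraction.  Terminal segments (bounded by a
    chromosome end) are never NMC-classified.
    """
    if coverage is None:
        raise ValueError("MAC presence evidence (coverage) is required for NMC detection")
    out = []
    for i, seg in enumerate(bmap.segments):
        if seg.terminal or seg.length == 0:
            continue
        if isinstance(coverage, dict):
            frac = coverage[i]
        else:
            if len(coverage) != bmap.length:
                raise ValueError("coverage vector length does not match the chromosome")
            frac = float(np.mean(np.asarray(coverage[seg.start:seg.end]) > 0))
        if frac < threshold:
            out.append(seg)
    return out


@dataclass(frozen=True)
class CentromereCall:
    chromosome: str
    left_cbs: CbsHit
    right_cbs: CbsHit
    cen_interval: tuple[int, int]
    cen_midpoint: float
    chromosome_midpoint: float

    @property
    def cen_length(self) -> int:
        return self.cen_interval[1] - self.cen_interval[0]


def map_centromere(bmap: BreakageMap,
                   surviving_deletions: list[tuple[int, int]]) -> CentromereCall:
    """Demarcate the centromere from viable germline arm deletions.

    Viable deletions never extend into the region essential for centromere
    function, so the centromere is the interval between the two Cbs's that
    bound the never-deleted central region: the first Cbs inward of the
    union of left-arm deletions and the last Cbs inward of the right-arm
    deletions.  (The region may contain further Cbs's; deletion mapping
    cannot exclude them from the centromere.)
    """
    if not bmap.hits:
        raise ValueError("centromere mapping requires a breakage map with Cbs hits")
    removed = np.zeros(bmap.length, dtype=bool)
    for s, e in surviving_deletions:
        removed[max(0, s):min(bmap.length, e)] = True
    if removed.all():
        raise ValueError("deletions cover the whole chromosome; no viable centromere interval")
    survivors = [h for h in bmap.hits if not removed[h.start:h.end].any()]
    if not survivors:
        raise ValueError("every Cbs is removed by some deletion; no centromere-flanking Cbs pair")
    left = survivors[0]
    right = survivors[-1]
    if left is right:
        raise ValueError("only one surviving Cbs; an interval needs a flanking pair")
    cen = (left.start, right.start)
    return CentromereCall(
        chromosome=bmap.chromosome,
        left_cbs=left,
        right_cbs=right,
        cen_interval=cen,
        cen_midpoint=(cen[0] + cen[1]) / 2.0,
        chromosome_midpoint=bmap.length / 2.0,
    )


def cbs_parsimony(tree: dendropy.Tree | str,
                  tip_variants: dict[str, str | None]) -> int:
    """Fitch small-parsimony count of Cbs variant changes on a species tree.

    ``tip_variants`` maps tip labels to discrete variant labels; a missing
    tip (absent key or None, an unsequenced Cbs) is unconstrained.  The
    tree may be a dendropy Tree or a newick string; it is treated as rooted.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    states = sorted({v for v in tip_variants.values() if v is not None})
    if not states:
        raise ValueError("no observed variant states at any tip")
    full = frozenset(states)
    count = 0

    def state_set(node) -> frozenset:
        nonlocal count
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            # newick readers map unquoted underscores to spaces
            v = tip_variants.get(label)
            if v is None and label is not None:
                v = tip_variants.get(label.replace(" ", "_"))
            return frozenset([v]) if v is not None else full
        child_sets = [state_set(c) for c in node.child_nodes()]
        acc = child_sets[0]
        for cs in child_sets[1:]:
            inter = acc & cs
            if inter:
                acc = inter
            else:
                acc = acc | cs
                count += 1
        return acc

    state_set(tree.seed_node)
    return count
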