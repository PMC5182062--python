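"""IES identification from read- and assembly-alignment evidence.

Internal eliminated sequences (IESs) are germline-limited intervals excised
during somatic genome development.  Three complementary alignment methods
locate them:

1. **Split reads** — somatic (MAC) reads aligned to the germline (MIC)
   break into two colinear pieces around each IES; candidates need at
   least three spanning reads with a consistent junction pair and near-zero
   MAC read coverage inside the interval.
2. **Broken reads** — germline reads aligned to the somatic assembly stop
   mid-read at the residual excision site; at least six broken reads, with
   at least one facing the site from each direction and breakpoints within
   10 bp, validate a site.
3. **Assembly gaps** — colinear MIC/MAC alignment chains show a much larger
   coordinate gap on the MIC side (>100 bp difference) at each IES.

Candidates are merged into a high-confidence record set with precise
junctions; records whose junctions touch assembly gaps (N runs) are demoted
to provisional.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .align import AlignmentBlock, ReadAlignment

logger = logging.getLogger(__name__)


@dataclass
class IesCandidate:
    chromosome: str
    left_junction: int
    right_junction: int
    method: int                      # 1 | 2 | 3
    support: int = 0
    support_left: int = 0            # method 2: broken reads per direction
    support_right: int = 0
    internal_coverage: float = 0.0
    flags: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.right_junction - self.left_junction


@dataclass
class IesRecord:
    chromosome: str
    left_junction: int
    right_junction: int
    methods: frozenset[int]
    support: int
    tdr: str = ""
    context: str = "unknown"
    confidence: str = "high"         # high | provisional
    flags: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.right_junction - self.left_junction


# ---------------------------------------------------------------------------
# Method 1: split MAC reads on the MIC
# ---------------------------------------------------------------------------

def split_read_ies(alignments: list[ReadAlignment],
                   coverage: dict[str, np.ndarray],
                   mic_sequences: dict[str, str] | None = None,
                   min_spanning: int = 3,
                   max_internal_coverage: float = 1.0,
                   query_slack: int = 5) -> list[IesCandidate]:
    """Call IES candidates from split somatic-read alignments to the MIC.

    ``coverage`` is the per-base MAC-read coverage of each MIC chromosome
    (from the same alignments); a candidate interval must stay below
    ``max_internal_coverage`` mean depth — residual coverage indicates
    somatic retention or contamination rather than elimination.
    """
    if coverage is None:
        raise ValueError("MAC read coverage over the MIC is required")
    junctions: dict[tuple[str, int, int], int] = defaultdict(int)
    for aln in alignments:
        if aln.ambiguous or len(aln.blocks) < 2:
            continue
        # a read spanning several IESs yields several colinear pieces; each
        # query-adjacent same-orientation pair evidences one junction
        for b1, b2 in zip(aln.blocks, aln.blocks[1:]):
            if b1.ref_id != b2.ref_id or b1.strand != b2.strand:
                continue
            if abs(b2.q_start - b1.q_end) > query_slack:
                continue
            left, right = (b1, b2) if b1.r_start <= b2.r_start else (b2, b1)
            if right.r_start <= left.r_end:
                continue
            junctions[(b1.ref_id, left.r_end, right.r_start)] += 1
    out: list[IesCandidate] = []
    for (chrom, l, r), n in sorted(junctions.items()):
        if n < min_spanning:
            continue
        cov = coverage.get(chrom)
        if cov is None:
            raise ValueError(f"missing coverage vector for {chrom}")
        internal = float(np.mean(cov[l:r])) if r > l else 0.0
        cand = IesCandidate(chrom, l, r, method=1, support=n,
                            internal_coverage=internal)
        if internal >= max_internal_coverage:
            cand.flags.add("low_mac_coverage_failed")
            logger.info("rejecting %s:%d-%d: internal MAC coverage %.2fx",
                        chrom, l, r, internal)
            continue
        if mic_sequences is not None and _junction_in_gap(mic_sequences[chrom], l, r):
            cand.flags.add("junction_gap")
            continue
        out.append(cand)
    return out


def _junction_in_gap(seq: str, l: int, r: int, window: int = 3) -> bool:
    for p in (l, r):
        if "N" in seq[max(0, p - window):p + window]:
            return True
    return False


# ---------------------------------------------------------------------------
# Method 2: broken MIC reads on the MAC
# ---------------------------------------------------------------------------

@dataclass
class ResidualSite:
    """A residual IES site on the MAC evidenced by broken germline reads."""

    mac_id: str
    left_breakpoint: int       # mode of forward-facing (rightward) breakpoints
    right_breakpoint: int      # mode of reverse-facing (leftward) breakpoints
    n_forward: int
    n_reverse: int
    validated: bool

    @property
    def n_total(self) -> int:
        return self.n_forward + self.n_reverse

    @property
    def overlap(self) -> int:
        """Positive overlap of the two breakpoint modes = TDR evidence."""
        return self.left_breakpoint - self.right_breakpoint


def broken_read_sites(alignments: list[ReadAlignment],
                      read_lengths: dict[str, int],
                      min_broken: int = 6,
                      cluster_bp: int = 10,
                      min_tail: int = 5) -> list[ResidualSite]:
    """Cluster broken-read breakpoints on the MAC into residual IES sites.

    A read is *broken* if its single alignment block leaves an unaligned
    tail of at least ``min_tail`` bases on one side.  Breakpoints are
    single-linkage clustered within ``cluster_bp``; a site validates iff it
    has ``min_broken`` broken reads in total with at least one facing it
    from each direction.  Duplicate reads must be removed upstream.
    """
    points: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for aln in alignments:
        if aln.ambiguous or len(aln.blocks) != 1:
            continue
        b = aln.blocks[0]
        qlen = read_lengths[aln.query_id]
        tail_right = qlen - b.q_end
        tail_left = b.q_start
        if tail_right >= min_tail and tail_left < min_tail:
            points[b.ref_id].append((b.r_end, "fwd"))
        elif tail_left >= min_tail and tail_right < min_tail:
            points[b.ref_id].append((b.r_start, "rev"))
    sites: list[ResidualSite] = []
    for mac_id, pts in sorted(points.items()):
        pts.sort()
        cluster: list[tuple[int, str]] = []
        for pt in pts:
            if cluster and pt[0] - cluster[-1][0] > cluster_bp:
                sites.append(_site_from_cluster(mac_id, cluster, min_broken))
                cluster = []
            cluster.append(pt)
        if cluster:
            sites.append(_site_from_cluster(mac_id, cluster, min_broken))
    return sites


def _mode(values: list[int]) -> int:
    counts: dict[int, int] = defaultdict(int)
    for v in values:
        counts[v] += 1
    return max(sorted(counts), key=lambda v: counts[v])


def _site_from_cluster(mac_id: str, cluster: list[tuple[int, str]],
                       min_broken: int) -> ResidualSite:
    fwd = [p for p, d in cluster if d == "fwd"]
    rev = [p for p, d in cluster if d == "rev"]
    validated = (len(cluster) >= min_broken and fwd and rev)
    return ResidualSite(
        mac_id=mac_id,
        left_breakpoint=_mode(fwd) if fwd else (_mode(rev) if rev else 0),
        right_breakpoint=_mode(rev) if rev else (_mode(fwd) if fwd else 0),
        n_forward=len(fwd),
        n_reverse=len(rev),
        validated=bool(validated),
    )


def residual_sites_to_candidates(sites: list[ResidualSite],
                                 chains: dict[str, list[AlignmentBlock]],
                                 tol: int = 10) -> list[IesCandidate]:
    """Lift validated residual sites to MIC junction candidates.

    ``chains`` maps each MAC contig to its colinear MIC alignment blocks;
    the residual site corresponds to the boundary between two adjacent
    blocks, whose MIC-side gap is the IES interval.
    """
    out: list[IesCandidate] = []
    for site in sites:
        if not site.validated:
            continue
        blocks = sorted(chains.get(site.mac_id, []), key=lambda b: b.q_start)
        for b1, b2 in zip(blocks, blocks[1:]):
            if (abs(b1.q_end - site.left_breakpoint) <= tol
                    and b1.ref_id == b2.ref_id
                    and b2.r_start > b1.r_end):
                out.append(IesCandidate(
                    b1.ref_id, b1.r_end, b2.r_start, method=2,
                    support=site.n_total,
                    support_left=site.n_forward,
                    support_right=site.n_reverse))
                break
    return out


# ---------------------------------------------------------------------------
# Method 3: MIC/MAC cross-assembly alignment gaps
# ---------------------------------------------------------------------------

def assembly_gap_ies(blocks: list[AlignmentBlock],
                     min_delta: int = 100) -> list[IesCandidate]:
    """Call IESs from coordinate-gap asymmetry in colinear block chains.

    For each adjacent block pair of one (MIC scaffold, MAC scaffold) chain,
    a candidate is emitted iff the MIC-side gap exceeds the MAC-side gap by
    more than ``min_delta``; the candidate interval is the MIC-side gap.
    Inverted or out-of-order pairs are skipped and logged.
    """
    by_pair: dict[tuple[str, str, str], list[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        by_pair[(b.ref_id, b.query_id, b.strand)].append(b)
    out: list[IesCandidate] = []
    for (mic_id, _mac_id, _strand), chain in sorted(by_pair.items()):
        chain.sort(key=lambda b: b.q_start)
        for b1, b2 in zip(chain, chain[1:]):
            if b2.r_start < b1.r_end:
                logger.warning("non-colinear block pair on %s; skipped", mic_id)
                continue
            mic_gap = b2.r_start - b1.r_end
            mac_gap = b2.q_start - b1.q_end
            if mic_gap - mac_gap > min_delta:
                out.append(IesCandidate(mic_id, b1.r_end, b2.r_start,
                                        method=3, support=mic_gap - mac_gap))
    return out


# ---------------------------------------------------------------------------
# Merging and record statistics
# ---------------------------------------------------------------------------

def merge_high_confidence(candidates: list[IesCandidate],
                          mic_sequences: dict[str, str],
                          merge_tol: int = 0,
                          max_tdr: int = 10) -> list[IesRecord]:
    """Merge candidates across methods into IES records.

    Candidates agree when both junctions match within ``merge_tol`` (the
    default 0 enforces the precise-junction requirement of the
    high-confidence set).  Junctions falling in N runs demote a record to
    provisional.  The terminal direct repeat is read off the MIC: the
    maximal sequence (up to ``max_tdr``) immediately left of both
    junctions.
    """
    groups: dict[tuple[str, int, int], list[IesCandidate]] = defaultdict(list)
    for cand in candidates:
        placed = False
        if merge_tol > 0:
            for key in list(groups):
                if (key[0] == cand.chromosome
                        and abs(key[1] - cand.left_junction) <= merge_tol
                        and abs(key[2] - cand.right_junction) <= merge_tol):
                    groups[key].append(cand)
                    placed = True
                    break
        if not placed:
            groups[(cand.chromosome, cand.left_junction, cand.right_junction)].append(cand)
    records: list[IesRecord] = []
    for (chrom, l, r), cands in sorted(groups.items()):
        seq = mic_sequences.get(chrom, "")
        tdr = _tdr_from_mic(seq, l, r, max_tdr) if seq else ""
        confidence = "high"
        flags: set[str] = set()
        if seq and _junction_in_gap(seq, l, r):
            confidence = "provisional"
            flags.add("junction_gap")
        if seq and "N" in seq[l:r]:
            flags.add("internal_gap")
        read_support = max((c.support for c in cands if c.method in (1, 2)),
                           default=0)
        records.append(IesRecord(
            chromosome=chrom, left_junction=l, right_junction=r,
            methods=frozenset(c.method for c in cands),
            support=read_support,
            tdr=tdr, confidence=confidence, flags=flags))
    return records


def _tdr_from_mic(seq: str, l: int, r: int, max_tdr: int) -> str:
    """Maximal junction overlap on the MIC: back- plus forward-extension."""
    a = 0
    while (a < max_tdr and l - a - 1 >= 0
           and seq[l - a - 1] == seq[r - a - 1]):
        a += 1
    b = 0
    while (a + b < max_tdr and r + b < len(seq)
           and seq[l + b] == seq[r + b]):
        b += 1
    return seq[l - a:l + b]


def length_stats(records: list[IesRecord]) -> dict:
    """Length summary of an IES record set (mean/median/log2 histogram)."""
    if not records:
        raise ValueError("length statistics of an empty record set")
    lengths = np.array([rec.length for rec in records], dtype=float)
    lo = int(np.floor(np.log2(lengths.min())))
    hi = int(np.ceil(np.log2(lengths.max()))) + 1
    edges = 2.0 ** np.arange(lo, hi + 1)
    hist, _ = np.histogram(lengths, bins=edges)
    return {
        "n": len(lengths),
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "min": float(lengths.min()),
        "max": float(lengths.max()),
        "fraction_1_to_10_kb": float(np.mean((lengths >= 1000) & (lengths <= 10_000))),
        "log2_bin_edges": edges,
        "log2_histogram": hist,
    }


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:])]


def load_gene_models(gff3_path: str) -> list[GeneModel]:
    """Parse gene models (gene + exon features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(gff3_path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = [(e.start - 1, e.end)
                 for e in db.children(gene, featuretype="exon", order_by="start")]
        if not exons:
            logger.warning("gene %s has no exons; skipped", gene.id)
            continue
        models.append(GeneModel(gene.id, gene.seqid, gene.start - 1, gene.end,
                                gene.strand, exons))
    return models


def classify_context(records: list[IesRecord],
                     genes: list[GeneModel]) -> list[IesRecord]:
    """Label each record intergenic / intronic / exonic (in place).

    The full IES interval decides: any overlap with a coding exon base is
    exonic; otherwise containment in an intron is intronic; otherwise a
    boundary-straddling interval is labelled by the majority of its bases,
    and gene-free intervals are intergenic.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        if g.end <= g.start:
            logger.warning("malformed gene model %s; skipped", g.gene_id)
            continue
        trees[g.chromosome][g.start:g.end] = g
    for rec in records:
        l, r = rec.left_junction, rec.right_junction
        hits = trees[rec.chromosome][l:r] if rec.chromosome in trees else set()
        if not hits:
            rec.context = "intergenic"
            continue
        exon_bp = intron_bp = 0
        for iv in hits:
            g: GeneModel = iv.data
            for es, ee in g.exons:
                exon_bp += max(0, min(r, ee) - max(l, es))
            for is_, ie in g.introns:
                intron_bp += max(0, min(r, ie) - max(l, is_))
        if exon_bp > 0:
            rec.context = "exonic"
        elif intron_bp >= (r - l):
            rec.context = "intronic"
        else:
            genic = exon_bp + intron_bp
            rec.context = "intronic" if genic >= (r - l) / 2 else "intergenic"
    return records
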