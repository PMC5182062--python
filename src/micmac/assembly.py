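"""Cross-assembly tiling of scaffolds and windowed feature densities.

When the terminal regions of two germline (MIC) scaffolds align to
adjacent, disjoint intervals of one somatic (MAC) scaffold, those two ends
are inferred to be adjacent in the germline genome (the two genomes are
nearly always colinear); the symmetric rule joins MAC scaffolds bridged by
one MIC scaffold.  Accepted adjacencies form simple paths that are emitted
as ordered, oriented super-assemblies.  Ends with conflicting proposals —
typically repetitive sequence — are flagged and left unjoined rather than
guessed.

The module also computes sliding-window feature-density tracks (covered
base pairs per window) used for chromosome landscape plots.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .align import AlignmentBlock
from .sequence import revcomp

logger = logging.getLogger(__name__)

GAP_SPACER = 100   # Ns written between joined scaffolds in layouts


@dataclass(frozen=True)
class Adjacency:
    """Proposed join between two scaffold ends, bridged on the other assembly."""

    scaffold_a: str
    end_a: str        # '5p' | '3p' (end of A facing the join)
    scaffold_b: str
    end_b: str
    bridge_id: str    # scaffold of the other assembly spanning the join
    bridge_gap: int   # separation of the two alignments on the bridge
    support: tuple[int, int] = (0, 0)


@dataclass
class ScaffoldGraph:
    nodes: set[tuple[str, str]] = field(default_factory=set)
    accepted: list[Adjacency] = field(default_factory=list)
    conflicted: list[Adjacency] = field(default_factory=list)

    def conflicted_ends(self) -> set[tuple[str, str]]:
        out = set()
        for adj in self.conflicted:
            out.add((adj.scaffold_a, adj.end_a))
            out.add((adj.scaffold_b, adj.end_b))
        return out


def _envelopes(blocks: list[AlignmentBlock]) -> list[dict]:
    """Collapse a bridge scaffold's blocks into per-(query, strand) envelopes."""
    by_src: dict[tuple[str, str], list[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        by_src[(b.ref_id, b.strand)].append(b)
    envs = []
    for (ref_id, strand), bs in by_src.items():
        envs.append({
            "ref_id": ref_id,
            "strand": strand,
            "q_start": min(b.q_start for b in bs),
            "q_end": max(b.q_end for b in bs),
            "r_start": min(b.r_start for b in bs),
            "r_end": max(b.r_end for b in bs),
        })
    envs.sort(key=lambda e: e["q_start"])
    return envs


def build_adjacency(blocks: list[AlignmentBlock],
                    scaffold_lengths: dict[str, int],
                    min_identity: float = 95.0,
                    min_length: int = 1000,
                    gap_tol: int = 2000,
                    overlap_tol: int = 50,
                    terminal_tol: int = 1000) -> ScaffoldGraph:
    """Propose scaffold-end adjacencies from bridge alignments.

    ``blocks`` align scaffolds of one assembly (``ref_id``, the scaffolds
    being joined) onto scaffolds of the other (``query_id``, the bridges).
    Two different ref scaffolds whose terminal regions occupy consecutive
    bridge intervals — separated by at most ``gap_tol`` and overlapping by
    at most ``overlap_tol`` — propose one adjacency.  An end collecting
    more than one distinct proposal is flagged unresolved and excluded.
    """
    usable = [b for b in blocks if b.identity >= min_identity]
    by_bridge: dict[str, list[AlignmentBlock]] = defaultdict(list)
    for b in usable:
        by_bridge[b.query_id].append(b)
    proposals: list[Adjacency] = []
    for bridge_id, bs in sorted(by_bridge.items()):
        envs = [e for e in _envelopes(bs)
                if e["q_end"] - e["q_start"] >= min_length]
        for e1, e2 in zip(envs, envs[1:]):
            if e1["ref_id"] == e2["ref_id"]:
                continue
            gap = e2["q_start"] - e1["q_end"]
            if gap > gap_tol or gap < -overlap_tol:
                continue
            end1 = _facing_end(e1, scaffold_lengths, "right", terminal_tol)
            end2 = _facing_end(e2, scaffold_lengths, "left", terminal_tol)
            if end1 is None or end2 is None:
                continue
            proposals.append(Adjacency(
                scaffold_a=e1["ref_id"], end_a=end1,
                scaffold_b=e2["ref_id"], end_b=end2,
                bridge_id=bridge_id, bridge_gap=gap))
    graph = ScaffoldGraph()
    for name in scaffold_lengths:
        graph.nodes.add((name, "5p"))
        graph.nodes.add((name, "3p"))
    # deduplicate identical proposals, then reject ends with conflicts
    uniq: dict[tuple, Adjacency] = {}
    for p in proposals:
        key = tuple(sorted([(p.scaffold_a, p.end_a), (p.scaffold_b, p.end_b)]))
        if key not in uniq:
            uniq[key] = p
    per_end: dict[tuple[str, str], list[Adjacency]] = defaultdict(list)
    for p in uniq.values():
        per_end[(p.scaffold_a, p.end_a)].append(p)
        per_end[(p.scaffold_b, p.end_b)].append(p)
    bad_ends = {end for end, ps in per_end.items() if len(ps) > 1}
    for p in uniq.values():
        ends = {(p.scaffold_a, p.end_a), (p.scaffold_b, p.end_b)}
        if ends & bad_ends:
            graph.conflicted.append(p)
            logger.info("conflicting adjacency at %s flagged unresolved", ends)
        else:
            graph.accepted.append(p)
    return graph


def _facing_end(env: dict, lengths: dict[str, int], side: str,
                terminal_tol: int = 1000) -> str | None:
    """Which end of the aligned scaffold faces the join; None if internal."""
    length = lengths[env["ref_id"]]
    # side='right': the join lies at higher bridge coordinates, i.e. past the
    # high-coordinate edge of this envelope on the bridge
    if side == "right":
        if env["strand"] == "+":
            return "3p" if env["r_end"] >= length - terminal_tol else None
        return "5p" if env["r_start"] <= terminal_tol else None
    if env["strand"] == "+":
        return "5p" if env["r_start"] <= terminal_tol else None
    return "3p" if env["r_end"] >= length - terminal_tol else None


@dataclass
class SuperAssembly:
    paths: list[list[tuple[str, str]]]     # (scaffold, '+'|'-') in order
    unplaced: list[str]
    layout: list[dict]                      # AGP-like rows (1-based)
    sequences: dict[str, str] | None = None

    @property
    def placed_length(self) -> int:
        return sum(row["length"] for row in self.layout if row["kind"] == "scaffold")


def emit_superassembly(graph: ScaffoldGraph,
                       scaffolds: dict[str, str]) -> SuperAssembly:
    """Order and orient scaffolds along accepted adjacency paths.

    Each connected component of the end-graph becomes one path; a cycle is
    an error (it names its edges).  Orientation propagates from each path's
    first scaffold; a contradiction rejects the component's edges.
    """
    g = nx.Graph()
    for name in scaffolds:
        # internal edge ties the two ends of one scaffold together
        g.add_edge((name, "5p"), (name, "3p"), kind="internal")
    for adj in graph.accepted:
        g.add_edge((adj.scaffold_a, adj.end_a), (adj.scaffold_b, adj.end_b),
                   kind="join", adj=adj)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise ValueError(f"adjacency graph contains a cycle: {cycle}")
    paths: list[list[tuple[str, str]]] = []
    seen: set[str] = set()
    for comp in nx.connected_components(g):
        names = sorted({n for n, _ in comp})
        if any(n in seen for n in names):
            continue
        seen.update(names)
        # walk from a terminal end (degree-1 node)
        endpoints = [n for n in comp if g.degree(n) == 1]
        start = sorted(endpoints)[0] if endpoints else sorted(comp)[0]
        path: list[tuple[str, str]] = []
        prev = None
        node = start
        while True:
            name, end = node
            other = (name, "3p" if end == "5p" else "5p")
            orientation = "+" if end == "5p" else "-"
            path.append((name, orientation))
            nxt = [n for n in g.neighbors(other) if n != node and n[0] != name]
            prev, node = other, (nxt[0] if nxt else None)
            if node is None:
                break
        paths.append(path)
    paths.sort()
    layout: list[dict] = []
    sequences: dict[str, str] = {}
    for i, path in enumerate(paths):
        sa_name = f"superasm_{i + 1}"
        pos = 1
        parts: list[str] = []
        for j, (name, orient) in enumerate(path):
            if j > 0:
                layout.append({"object": sa_name, "start": pos,
                               "end": pos + GAP_SPACER - 1, "kind": "gap",
                               "length": GAP_SPACER})
                parts.append("N" * GAP_SPACER)
                pos += GAP_SPACER
            seq = scaffolds[name]
            layout.append({"object": sa_name, "start": pos,
                           "end": pos + len(seq) - 1, "kind": "scaffold",
                           "scaffold": name, "orientation": orient,
                           "length": len(seq)})
            parts.append(seq if orient == "+" else revcomp(seq))
            pos += len(seq)
        sequences[sa_name] = "".join(parts)
    unplaced = [p[0][0] for p in paths if len(p) == 1]
    return SuperAssembly(paths=paths, unplaced=sorted(unplaced),
                         layout=layout, sequences=sequences)


# ---------------------------------------------------------------------------
# Feature-density tracks
# ---------------------------------------------------------------------------

@dataclass
class DensityTrack:
    chromosome: str
    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray          # covered bp per window (interval union)
    partial_last: bool


def windowed_density(features: list[tuple[int, int]],
                     chromosome_length: int,
                     chromosome: str = "chromosome",
                     window: int = 500_000,
                     step: int = 100_000) -> DensityTrack:
    """Covered base pairs (union of features) per sliding window.

    Windows advance by ``step``; the final partial window is included and
    flagged.  Overlapping features count once per base; a feature beyond
    the chromosome end is an error.
    """
    if window < step:
        raise ValueError("window span must be at least the step")
    covered = np.zeros(chromosome_length + 1, dtype=np.int32)
    for s, e in features:
        if s < 0 or e > chromosome_length:
            raise ValueError(f"feature {s}-{e} outside chromosome of "
                             f"length {chromosome_length}")
        if e > s:
            covered[s] += 1
            covered[e] -= 1
    mask = (np.cumsum(covered[:-1]) > 0).astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(mask)])
    starts = list(range(0, max(1, chromosome_length - window + 1), step))
    partial = False
    if starts[-1] + window < chromosome_length:
        starts.append(starts[-1] + step)
        partial = True
    starts_arr = np.array(starts, dtype=np.int64)
    ends = np.minimum(starts_arr + window, chromosome_length)
    values = prefix[ends] - prefix[starts_arr]
    partial = partial or (ends[-1] - starts_arr[-1] < window)
    return DensityTrack(chromosome=chromosome, window=window, step=step,
                        starts=starts_arr, values=values, partial_last=partial)
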