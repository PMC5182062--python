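"""Exact seed-and-extend alignment for simulated reads and assemblies.

Real read alignments enter the pipeline as SAM/PAF produced by external
aligners; for the bundled synthetic genomes, where reads are error-free (or
carry only substitutions at configurable rates), a sorted k-mer index with
greedy exact extension is sufficient and fully deterministic.  The detection
logic downstream consumes only :class:`AlignmentBlock`, so the two routes
are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import encode, revcomp


@dataclass(frozen=True)
class AlignmentBlock:
    """One colinear match between a query and a reference interval."""

    query_id: str
    q_start: int
    q_end: int
    ref_id: str
    r_start: int
    r_end: int
    strand: str = "+"          # orientation of the query against the reference
    identity: float = 100.0
    source: str = "read-alignment"   # or "assembly-alignment"

    @property
    def q_length(self) -> int:
        return self.q_end - self.q_start

    @property
    def r_length(self) -> int:
        return self.r_end - self.r_start


@dataclass
class ReadAlignment:
    """Result of aligning one read: its blocks plus an ambiguity flag."""

    query_id: str
    blocks: list[AlignmentBlock] = field(default_factory=list)
    strand: str = "+"
    ambiguous: bool = False

    @property
    def mapped(self) -> bool:
        return bool(self.blocks)


class KmerIndex:
    """Sorted-array index of every k-mer position in a reference genome."""

    def __init__(self, sequences: dict[str, str], k: int = 31):
        if k < 4 or k > 31:
            raise ValueError("k must be in [4, 31] to fit a 2-bit uint64 code")
        self.k = k
        self.names = list(sequences)
        self.seqs = {name: seq.upper() for name, seq in sequences.items()}
        self.arrs = {name: encode(seq) for name, seq in self.seqs.items()}
        codes_all, pos_all, chrom_all = [], [], []
        for ci, name in enumerate(self.names):
            arr = self.arrs[name]
            if len(arr) < k:
                continue
            codes, valid = self._rolling_codes(arr, k)
            idx = np.nonzero(valid)[0]
            codes_all.append(codes[idx])
            pos_all.append(idx.astype(np.int64))
            chrom_all.append(np.full(len(idx), ci, dtype=np.int32))
        if codes_all:
            codes = np.concatenate(codes_all)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = np.concatenate(pos_all)[order]
            self._chrom = np.concatenate(chrom_all)[order]
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)
            self._chrom = np.empty(0, dtype=np.int32)

    @staticmethod
    def _rolling_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        # 2 bits per base; k <= 31 keeps the code within a signed int64,
        # which avoids dtype-promotion copies in searchsorted lookups
        n = len(arr) - k + 1
        codes = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        a = arr.astype(np.int64)
        for j in range(k):
            codes = (codes << 2) | (a[j:j + n] & 3)
            bad |= arr[j:j + n] > 3
        return codes, ~bad

    def lookup(self, code: int) -> list[tuple[str, int]]:
        code = np.int64(code)
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return [
            (self.names[self._chrom[i]], int(self._pos[i]))
            for i in range(lo, hi)
        ]

    # -- extension helpers -------------------------------------------------

    def extend_forward(self, name: str, r_pos: int, query: np.ndarray, q_pos: int) -> int:
        """Length of the exact match starting at (r_pos, q_pos)."""
        ref = self.arrs[name]
        n = min(len(ref) - r_pos, len(query) - q_pos)
        if n <= 0:
            return 0
        eq = ref[r_pos:r_pos + n] == query[q_pos:q_pos + n]
        bad = np.nonzero(~eq)[0]
        return int(bad[0]) if len(bad) else n

    def extend_backward(self, name: str, r_end: int, query: np.ndarray, q_end: int) -> int:
        """Length of the exact match ending at (r_end, q_end), exclusive."""
        ref = self.arrs[name]
        n = min(r_end, q_end)
        if n <= 0:
            return 0
        eq = ref[r_end - n:r_end] == query[q_end - n:q_end]
        bad = np.nonzero(~eq)[0]
        return n - int(bad[-1]) - 1 if len(bad) else n


class ExactAligner:
    """Greedy split alignment of reads/contigs against a :class:`KmerIndex`.

    A read is consumed left to right: the best (longest, unique) exact
    extension from the current seed becomes a block, then the remainder is
    re-seeded.  Reads whose best extension is tied between reference
    positions are flagged ambiguous and left to the caller to drop.
    """

    def __init__(self, index: KmerIndex, max_pieces: int = 4, seed_step: int = 8):
        self.index = index
        self.max_pieces = max_pieces
        self.seed_step = seed_step

    # -- single reads ------------------------------------------------------

    def align_read(self, name: str, read: str, source: str = "read-alignment") -> ReadAlignment:
        fwd = self._align_oriented(name, read, "+", source)
        if fwd.mapped:
            return fwd
        rev = self._align_oriented(name, revcomp(read), "-", source)
        return rev if rev.mapped else fwd

    def _seed_hits(self, q: np.ndarray, q_pos: int) -> list[tuple[str, int]]:
        k = self.index.k
        if q_pos + k > len(q):
            return []
        if (q[q_pos:q_pos + k] > 3).any():
            return []
        code = 0
        for v in q[q_pos:q_pos + k]:
            code = (code << 2) | int(v)
        return self.index.lookup(code)

    def _best_extension(self, q: np.ndarray, q_pos: int) -> tuple[tuple[str, int] | None, int, bool]:
        hits = self._seed_hits(q, q_pos)
        if not hits:
            return None, 0, False
        best, best_len, tie = None, -1, False
        for name, pos in hits:
            ext = self.index.extend_forward(name, pos, q, q_pos)
            if ext > best_len:
                best, best_len, tie = (name, pos), ext, False
            elif ext == best_len:
                tie = True
        return best, best_len, tie

    def _align_oriented(self, name: str, read: str, strand: str, source: str) -> ReadAlignment:
        q = encode(read.upper())
        k = self.index.k
        aln = ReadAlignment(query_id=name, strand=strand)
        # seed at the start; if that fails, try a backward-anchored suffix
        best, ext, tie = self._best_extension(q, 0)
        if best is None:
            # suffix-anchored: seed at the last full k-mer, extend both ways
            q_pos = len(q) - k
            if q_pos <= 0:
                return aln
            hits = self._seed_hits(q, q_pos)
            best_blk, best_len, tie2 = None, -1, False
            for rname, pos in hits:
                back = self.index.extend_backward(rname, pos + k, q, q_pos + k)
                fwd = self.index.extend_forward(rname, pos + k, q, q_pos + k)
                total = back + fwd
                if total > best_len:
                    best_blk = (rname, pos + k - back, q_pos + k - back, total)
                    best_len, tie2 = total, False
                elif total == best_len:
                    tie2 = True
            if best_blk is None:
                return aln
            rname, r_start, q_start, total = best_blk
            aln.blocks.append(AlignmentBlock(name, q_start, q_start + total,
                                             rname, r_start, r_start + total,
                                             strand=strand, source=source))
            aln.ambiguous = tie2
            return aln
        q_pos = 0
        pieces = 0
        ambiguous = tie
        while best is not None and pieces < self.max_pieces:
            rname, pos = best
            aln.blocks.append(AlignmentBlock(name, q_pos, q_pos + ext,
                                             rname, pos, pos + ext,
                                             strand=strand, source=source))
            q_pos += ext
            pieces += 1
            if q_pos + k > len(q):
                break
            best, ext, tie = self._best_extension(q, q_pos)
            ambiguous = ambiguous or tie
        aln.ambiguous = ambiguous
        return aln

    # -- long queries (assembly-to-assembly chains) ------------------------

    def chain_query(self, name: str, seq: str, min_block: int = 31) -> list[AlignmentBlock]:
        """Colinear block chain of a long query (e.g. a MAC contig vs MIC).

        Greedy left-to-right: unmatched stretches (telomeres, residual
        unique sequence) are skipped by re-seeding every ``seed_step``
        bases.  Blocks shorter than ``min_block`` are dropped.
        """
        q = encode(seq.upper())
        k = self.index.k
        blocks: list[AlignmentBlock] = []
        q_pos = 0
        while q_pos + k <= len(q):
            best, ext, _tie = self._best_extension(q, q_pos)
            if best is None or ext < min_block:
                q_pos += self.seed_step
                continue
            rname, pos = best
            blocks.append(AlignmentBlock(name, q_pos, q_pos + ext,
                                         rname, pos, pos + ext,
                                         strand="+", source="assembly-alignment"))
            q_pos += ext
        return blocks


def coverage_from_blocks(blocks: list[AlignmentBlock],
                         chromosome_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base reference coverage accumulated over alignment blocks."""
    cov = {name: np.zeros(length, dtype=np.int32)
           for name, length in chromosome_lengths.items()}
    for b in blocks:
        if b.ref_id in cov:
            cov[b.ref_id][b.r_start:b.r_end] += 1
    return cov
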