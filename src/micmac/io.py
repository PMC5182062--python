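"""File input/output: FASTA/FASTQ, BED/bedGraph, SAM/PAF, GFF3, truth ledgers.

FASTA is read and written through Biopython; SAM through pysam.  PAF is a
plain 12+ column TSV and is parsed directly.  All BED output is 0-based
half-open; TSV reports use 1-based inclusive coordinates.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentBlock
from .simulate import Read, RearrangementTruth


# -- FASTA / FASTQ ----------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path,
                header_note: str | None = None) -> None:
    records = []
    for name, seq in sequences.items():
        rec = SeqRecord(Seq(seq), id=name, description=header_note or "")
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")   # Biopython wraps at 60 columns


def write_fastq(reads: list[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


# -- BED / bedGraph ---------------------------------------------------------

def write_bed(rows: list[tuple], path: str | Path,
              columns: tuple[str, ...] = ("chrom", "start", "end", "name",
                                          "score", "strand")) -> None:
    df = pd.DataFrame(rows, columns=list(columns)[: len(rows[0])] if rows else list(columns))
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]]
    return df


def write_bedgraph(track, path: str | Path) -> None:
    with open(path, "w") as fh:
        for start, value in zip(track.starts, track.values):
            fh.write(f"{track.chromosome}\t{start}\t{start + track.window}\t{value}\n")


# -- truth ledger -----------------------------------------------------------

def write_truth(truth: RearrangementTruth, outdir: str | Path) -> None:
    """Write the ground-truth ledger as BED files plus one TSV summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed([(c.chromosome, c.start, c.end, c.variant, 0, c.strand)
               for c in truth.cbs_sites], outdir / "cbs.bed")
    write_bed([(i.chromosome, i.start, i.end, i.tdr or ".", i.tdr_length, "+")
               for i in truth.ies_intervals], outdir / "ies.bed")
    write_bed([(n.chromosome, n.start, n.end, "NMC", 0, "+")
               for n in truth.nmc_intervals], outdir / "nmc.bed")
    rows = []
    for seg in truth.mac_segments:
        rows.append({
            "chromosome": seg.chromosome, "start_1based": seg.start + 1,
            "end": seg.end, "contig": seg.contig_id or ".",
            "offset_left": seg.offsets[0], "offset_right": seg.offsets[1],
            "maintained": int(seg.maintained),
        })
    pd.DataFrame(rows).to_csv(outdir / "mac_segments.tsv", sep="\t", index=False)


def write_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in vars(config).items():
            fh.write(f"{key}\t{value!r}\n")


# -- gene models ------------------------------------------------------------

def write_gff3(genes, path: str | Path) -> None:
    """Write GeneTruth-style records (gene + mRNA + exon/CDS) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            gid = f"gene{i + 1}"
            fh.write(f"{g.chromosome}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={gid}\n")
            mid = f"{gid}.m1"
            fh.write(f"{g.chromosome}\t.\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mid};Parent={gid}\n")
            for j, (es, ee) in enumerate(g.exons):
                fh.write(f"{g.chromosome}\t.\texon\t{es + 1}\t{ee}\t.\t"
                         f"{g.strand}\t.\tID={mid}.e{j + 1};Parent={mid}\n")
                if getattr(g, "coding", True):
                    fh.write(f"{g.chromosome}\t.\tCDS\t{es + 1}\t{ee}\t.\t"
                             f"{g.strand}\t0\tID={mid}.c{j + 1};Parent={mid}\n")


# -- alignment input --------------------------------------------------------

def read_sam_blocks(path: str | Path, source: str = "read-alignment"
                    ) -> list[AlignmentBlock]:
    """Read primary alignments from a (text) SAM file as AlignmentBlocks.

    Each aligned reference segment of a read becomes one block; soft and
    hard clips delimit the query interval.  Supplementary alignments are
    kept (they carry the second piece of split reads); secondary
    alignments and unmapped reads are dropped.
    """
    blocks: list[AlignmentBlock] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary:
                continue
            q_start = rec.query_alignment_start
            q_end = rec.query_alignment_end
            if rec.cigartuples and rec.cigartuples[0][0] == 5:   # leading hard clip
                q_start += rec.cigartuples[0][1]
                q_end += rec.cigartuples[0][1]
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            span = max(1, q_end - q_start)
            blocks.append(AlignmentBlock(
                query_id=rec.query_name,
                q_start=q_start, q_end=q_end,
                ref_id=rec.reference_name,
                r_start=rec.reference_start, r_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                identity=100.0 * (1.0 - nm / span),
                source=source,
            ))
    return blocks


def read_paf_blocks(path: str | Path, source: str = "assembly-alignment"
                    ) -> list[AlignmentBlock]:
    """Read a PAF file (minimap2-style 12+ column TSV) as AlignmentBlocks."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            matches, aln_len = int(f[9]), int(f[10])
            blocks.append(AlignmentBlock(
                query_id=f[0], q_start=int(f[2]), q_end=int(f[3]),
                ref_id=f[5], r_start=int(f[7]), r_end=int(f[8]),
                strand=f[4],
                identity=100.0 * matches / max(1, aln_len),
                source=source,
            ))
    return blocks


# -- report tables ----------------------------------------------------------

def cbs_table(hits) -> pd.DataFrame:
    """1-based report table of Cbs hits."""
    return pd.DataFrame([
        {"chromosome": h.chromosome, "start_1based": h.start + 1,
         "strand": h.strand, "sequence": h.sequence,
         "variant": h.variant_label, "n_substitutions": h.n_substitutions}
        for h in hits
    ])


def ies_table(records) -> pd.DataFrame:
    return pd.DataFrame([
        {"chromosome": r.chromosome, "start_1based": r.left_junction + 1,
         "end": r.right_junction, "length": r.length,
         "methods": ",".join(map(str, sorted(r.methods))),
         "support": r.support, "tdr": r.tdr or ".",
         "context": r.context, "confidence": r.confidence}
        for r in records
    ])
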