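"""Published reference tables for the T. thermophila breakage-site analyses.

These are the printed worked-example inputs: the genome-wide census of
chromosome breakage sequence (Cbs) variants and the deletion-mapped
centromere intervals of the five germline (MIC) chromosomes.  They are used
as inputs to the motif/centromere routines and in the worked examples; the
package never treats them as expected outputs to tune against.
"""

from __future__ import annotations

# Consensus Cbs, written on the conventionally reported C-rich strand.
CBS_CANONICAL = "TAAACCAACCTCTTT"

# Degenerate family pattern: W=A/T, Y=C/T, H=A/C/T, N=any base (N in the
# *genome* never matches: character classes below are explicit).
CBS_PATTERN = "WAAACCAACCYCNHW"

# Census of the 225 functional Cbs's by variant, labelled by
# position+substituted-base relative to the canonical 15-mer.
# Singles total 93, doubles total 23, plus 109 canonical = 225.
CBS_VARIANT_COUNTS: dict[str, int] = {
    "canonical": 109,
    "1A": 53,
    "11C": 8,
    "13A": 7,
    "13C": 2,
    "14A": 9,
    "14C": 4,
    "15A": 10,
    "1A,11C": 5,
    "1A,13A": 2,
    "1A,13C": 1,
    "1A,14C": 2,
    "1A,15A": 8,
    "11C,13A": 1,
    "11C,13G": 1,
    "11C,14C": 1,
    "11C,15A": 1,
    "14A,15A": 1,
}

# Deletion-mapped centromere intervals per MIC chromosome (megabases,
# measured from the far telomere of the left arm): centromere-flanking
# left/right Cbs locations and the chromosome super-assembly length.
CENTROMERE_TABLE: dict[int, dict[str, float]] = {
    1: {"l_cbs_mb": 13.98, "r_cbs_mb": 23.24, "length_mb": 36.32},
    2: {"l_cbs_mb": 9.81, "r_cbs_mb": 14.85, "length_mb": 25.51},
    3: {"l_cbs_mb": 9.98, "r_cbs_mb": 20.32, "length_mb": 31.52},
    4: {"l_cbs_mb": 12.23, "r_cbs_mb": 18.34, "length_mb": 31.72},
    5: {"l_cbs_mb": 10.37, "r_cbs_mb": 17.39, "length_mb": 27.47},
}

# Combined length of the five chromosome-length super-assemblies (Mb).
SUPERASSEMBLY_TOTAL_MB = 152.54


def variant_to_sequence(label: str) -> str:
    """Realize a variant label (e.g. ``"1A,13C"``) as its 15-mer sequence."""
    seq = list(CBS_CANONICAL)
    if label != "canonical":
        for token in label.split(","):
            pos, base = int(token[:-1]), token[-1]
            if not (1 <= pos <= 15) or base not in "ACGT":
                raise ValueError(f"malformed variant token: {token!r}")
            seq[pos - 1] = base
    return "".join(seq)


def variant_census_sequences() -> list[str]:
    """The 225-member Cbs multiset realized from the census counts."""
    out: list[str] = []
    for label, count in CBS_VARIANT_COUNTS.items():
        out.extend([variant_to_sequence(label)] * count)
    return out
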