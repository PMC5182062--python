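"""IES junction characterization: TDRs, excision variability, coding IESs.

Excision of an IES often leaves a short terminal direct repeat (TDR): a
sequence present at both IES termini in the germline, exactly one copy of
which remains at the excision site in the soma.  This module detects TDRs,
summarizes their composition (they are markedly more AT-rich than flanking
sequence), groups AT-only TDR patterns into reverse-complement equivalence
classes, quantifies excision-endpoint variability across a progeny pool
against the parental reference, and screens exonic IESs for the four
features shared by precisely excised coding-region IESs (TTAA TDR, CACTTT
terminal inverted repeat, exceptional shortness, precision).
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .ies import IesRecord
from .sequence import revcomp, encode

logger = logging.getLogger(__name__)

FLANK_WINDOW = 6   # bases shown on each side of the TDR in logo input


@dataclass
class TdrRecord:
    ies_id: str
    tdr_length: int
    tdr_sequence: str
    left_flank: str      # MAC-destined side (left of the junction overlap)
    right_flank: str     # MIC-limited side


@dataclass
class JunctionProfile:
    site_id: str
    parental: tuple[int, int]
    observed: list[tuple[tuple[int, int], int]]   # validated (pair, read count)
    n_distinct_junctions: int
    distance_histogram: dict[int, int]            # summed L+R distance -> reads
    fraction_identical: float
    fraction_within_20bp: float

    @property
    def modal_distance(self) -> int | None:
        if not self.distance_histogram:
            return None
        return max(sorted(self.distance_histogram),
                   key=lambda d: self.distance_histogram[d])


def detect_tdr(mic_sequence: str, left_junction: int, right_junction: int,
               mac_sequence: str | None = None, mac_junction: int | None = None,
               max_len: int = 10, ies_id: str = "ies") -> TdrRecord:
    """Find the maximal terminal direct repeat at an excision junction.

    The TDR is the maximal sequence present at both IES termini in the MIC
    and once at the excision site in the MAC.  When both a backward and a
    shifted forward overlap exist, the leftmost placement on the MIC
    forward strand is reported.  If the MAC sequence and junction point are
    supplied they are checked for consistency.
    """
    seq, l, r = mic_sequence, left_junction, right_junction
    if not (0 <= l < r <= len(seq)):
        raise ValueError("junction coordinates inconsistent with the MIC sequence")
    a = 0
    while a < max_len and l - a - 1 >= 0 and seq[l - a - 1] == seq[r - a - 1]:
        a += 1
    b = 0
    while a + b < max_len and r + b < len(seq) and seq[l + b] == seq[r + b]:
        b += 1
    tdr = seq[l - a:l + b]
    if mac_sequence is not None and mac_junction is not None:
        p = mac_junction - a
        if mac_sequence[p:p + len(tdr)] != tdr:
            raise ValueError(
                f"MAC sequence at the excision site does not carry the TDR {tdr!r}")
    return TdrRecord(
        ies_id=ies_id,
        tdr_length=len(tdr),
        tdr_sequence=tdr,
        left_flank=seq[max(0, l - a - FLANK_WINDOW):l - a],
        right_flank=seq[l + b:l + b + FLANK_WINDOW],
    )


def tdr_records_from_ies(mic: dict[str, str],
                         records: list[IesRecord]) -> list[TdrRecord]:
    return [
        detect_tdr(mic[rec.chromosome], rec.left_junction, rec.right_junction,
                   ies_id=f"{rec.chromosome}:{rec.left_junction}-{rec.right_junction}")
        for rec in records
    ]


def tdr_composition(records: list[TdrRecord],
                    max_class: int = 4) -> dict[int, dict]:
    """AT fraction and logo-count matrix per TDR length class (0..max_class).

    The logo input covers the TDR plus ``FLANK_WINDOW`` bases on each side
    (MAC-destined sequence left, MIC-limited right, matching the published
    junction-logo convention); counts are per column over A,C,G,T.
    """
    if not records:
        raise ValueError("TDR composition of an empty record set")
    out: dict[int, dict] = {}
    by_class: dict[int, list[TdrRecord]] = defaultdict(list)
    for rec in records:
        if rec.tdr_length <= max_class:
            by_class[rec.tdr_length].append(rec)
    for t, recs in sorted(by_class.items()):
        at = gc = 0
        width = t + 2 * FLANK_WINDOW
        counts = np.zeros((width, 4), dtype=int)
        for rec in recs:
            for base in rec.tdr_sequence:
                if base in "AT":
                    at += 1
                elif base in "GC":
                    gc += 1
            window = (rec.left_flank.rjust(FLANK_WINDOW, "N")
                      + rec.tdr_sequence
                      + rec.right_flank.ljust(FLANK_WINDOW, "N"))
            arr = encode(window)
            for j, code in enumerate(arr[:width]):
                if code < 4:
                    counts[j, code] += 1
        out[t] = {
            "n": len(recs),
            "at_fraction": at / (at + gc) if (at + gc) else float("nan"),
            "logo_counts": counts,
        }
    return out


def tdr_pattern_groups(records: list[TdrRecord], k: int) -> dict[str, int]:
    """Tally observed AT-only k-mer TDRs by reverse-complement class.

    Classes enumerate *all* AT-only k-mers modulo reverse complement (each
    named by its lexicographically smaller member, palindromes by
    themselves); classes with zero observations are included.  k=4 yields
    10 classes, k=3 yields 4, and k=2 yields 3.
    """
    if k not in (2, 3, 4):
        raise ValueError("pattern grouping is defined for k in {2, 3, 4}")
    classes: dict[str, int] = {}
    for mer in ("".join(p) for p in itertools.product("AT", repeat=k)):
        rep = min(mer, revcomp(mer))
        classes.setdefault(rep, 0)
    for rec in records:
        s = rec.tdr_sequence
        if len(s) == k and set(s) <= {"A", "T"}:
            classes[min(s, revcomp(s))] += 1
    return dict(sorted(classes.items()))


def excision_variability(observations: list[tuple[tuple[int, int], int]],
                         parental: tuple[int, int],
                         site_id: str = "site",
                         min_reads: int = 3) -> JunctionProfile:
    """Profile endpoint variability at one IES site in a progeny pool.

    ``observations`` are (endpoint pair, independent read count); a pair is
    validated by at least ``min_reads`` identical independent reads.  The
    distance of each validated pair to the parental reference sums the
    left- and right-junction offsets onto one axis; fractions are weighted
    by validated reads.
    """
    if parental is None:
        raise ValueError("a parental reference junction is required")
    validated = [(pair, n) for pair, n in observations if n >= min_reads]
    hist: dict[int, int] = defaultdict(int)
    total = ident = within = 0
    for (l, r), n in validated:
        d = abs(l - parental[0]) + abs(r - parental[1])
        hist[d] += n
        total += n
        if d == 0:
            ident += n
        if d <= 20:
            within += n
    return JunctionProfile(
        site_id=site_id,
        parental=parental,
        observed=sorted(validated),
        n_distinct_junctions=len(validated),
        distance_histogram=dict(sorted(hist.items())),
        fraction_identical=ident / total if total else float("nan"),
        fraction_within_20bp=within / total if total else float("nan"),
    )


def pool_variability(profiles: list[JunctionProfile]) -> dict:
    """Aggregate endpoint-distance statistics over many sites."""
    hist: dict[int, int] = defaultdict(int)
    for p in profiles:
        for d, n in p.distance_histogram.items():
            hist[d] += n
    total = sum(hist.values())
    ident = hist.get(0, 0)
    within = sum(n for d, n in hist.items() if d <= 20)
    modal = max(sorted(hist), key=lambda d: hist[d]) if hist else None
    return {
        "n_sites": len(profiles),
        "n_validated_reads": total,
        "modal_distance": modal,
        "fraction_identical": ident / total if total else float("nan"),
        "fraction_within_20bp": within / total if total else float("nan"),
        "distance_histogram": dict(sorted(hist.items())),
    }


# ---------------------------------------------------------------------------
# Coding-region IES screen
# ---------------------------------------------------------------------------

TIR_CONSENSUS = "CACTTT"


@dataclass
class CodingIesFeatures:
    ies_id: str
    length: int
    ttaa_tdr: bool
    tir_match: bool
    exceptionally_short: bool
    all_features: bool = field(init=False)

    def __post_init__(self) -> None:
        self.all_features = self.ttaa_tdr and self.tir_match and self.exceptionally_short


def coding_ies_screen(records: list[IesRecord],
                      mic: dict[str, str],
                      all_lengths: list[int] | None = None,
                      max_tir_mismatches: int = 2,
                      short_quantile: float = 0.01) -> list[CodingIesFeatures]:
    """Feature checks for exonic (coding-region) IESs.

    Each exonic record is tested for: a TTAA terminal direct repeat; a
    terminal inverted repeat internal to the TTAA matching the CACTTT
    consensus with at most ``max_tir_mismatches``; and exceptional
    shortness (below the ``short_quantile`` of the length distribution
    given by ``all_lengths``, defaulting to the records themselves).
    Non-exonic records are outside the screen and omitted.
    """
    lengths = all_lengths if all_lengths else [r.length for r in records]
    cutoff = float(np.quantile(lengths, short_quantile)) if lengths else 0.0
    out: list[CodingIesFeatures] = []
    for rec in records:
        if rec.context != "exonic":
            continue
        seq = mic[rec.chromosome]
        l, r = rec.left_junction, rec.right_junction
        ttaa = rec.tdr == "TTAA"
        left_tir = seq[l:l + len(TIR_CONSENSUS)]
        right_tir = revcomp(seq[r - len(rec.tdr) - len(TIR_CONSENSUS):r - len(rec.tdr)])
        tir_ok = (
            _mismatches(left_tir, TIR_CONSENSUS) <= max_tir_mismatches
            and _mismatches(right_tir, TIR_CONSENSUS) <= max_tir_mismatches
        )
        out.append(CodingIesFeatures(
            ies_id=f"{rec.chromosome}:{l}-{r}",
            length=rec.length,
            ttaa_tdr=ttaa,
            tir_match=tir_ok,
            exceptionally_short=rec.length <= cutoff,
        ))
    return out


def _mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))
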