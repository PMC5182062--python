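"""Miniature germline/soma genome simulator with a ground-truth ledger.

The generator emulates the rearrangement architecture of a *Tetrahymena*-like
germline (MIC) genome at desk scale: multi-chromosome MIC sequences with
planted chromosome breakage sequences (Cbs) drawn from the published variant
census, internal eliminated sequences (IESs) with a lognormal length
distribution and short AT-rich terminal direct repeats (TDRs), tandem Cbs
duplications that delimit non-maintained chromosomes (NMCs), long-range Cbs
segment duplications (clade ancestors), and simple gene models for
intergenic/intronic/exonic IES placement.  The somatic (MAC) genome is then
derived by excising IESs (one TDR copy retained per junction, optional
endpoint jitter), dropping each Cbs with 5-25 bp of flank, appending
telomere-repeat markers, and omitting non-maintained segments.  Reads are
simulated uniformly from either genome.

Every feature is recorded in a :class:`RearrangementTruth` ledger so that
downstream detectors can be scored exactly.  All randomness flows through a
single seeded generator: the same seed reproduces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import cbs as cbs_mod
from .sequence import BASES, mutate, random_sequence, revcomp
from .tables import CBS_VARIANT_COUNTS, variant_to_sequence

TELOMERE_UNIT = "CCCCAA"

# Genomic-context mix of IES placements (intergenic, intronic, exonic),
# matching the observed 82/16/2 percent split of the high-confidence set.
CONTEXT_FRACTIONS = {"intergenic": 0.82, "intronic": 0.16, "exonic": 0.02}

_CBS_WEIGHTS_DEFAULT = {
    label: count / sum(CBS_VARIANT_COUNTS.values())
    for label, count in CBS_VARIANT_COUNTS.items()
}

# Observed TDR length spectrum restricted to the 0-4 bp classes, with the
# no-TDR class largest, renormalized to 1.
_TDR_WEIGHTS_DEFAULT = {0: 0.37, 1: 0.23, 2: 0.18, 3: 0.12, 4: 0.10}


@dataclass
class SimConfig:
    """Study conditions for the synthetic rearranged genome."""

    seed: int = 1
    n_chromosomes: int = 5
    chromosome_length: int = 500_000          # nominal; features may stretch it slightly
    gc_fraction: float = 0.221                # germline assembly is 77.9% A+T
    n_cbs_per_chromosome: int = 9
    cbs_variant_weights: dict[str, float] = field(
        default_factory=lambda: dict(_CBS_WEIGHTS_DEFAULT))
    n_ies: int = 120
    ies_length_lognormal: tuple[float, float] = (3780.0, 2780.0)   # (mean bp, median bp)
    tdr_class_weights: dict[int, float] = field(
        default_factory=lambda: dict(_TDR_WEIGHTS_DEFAULT))
    excision_endpoint_sd: float = 0.0
    telomere_offset_range: tuple[int, int] = (5, 25)
    n_tandem_dup_cbs: int = 2
    read_length: int = 100
    coverage: float = 10.0
    frag_insert: int = 500
    # extensions beyond the core parameter set
    n_longrange_dup_cbs: int = 1
    duplication_divergence: float = 0.08
    tdr_at_fraction: float = 0.97             # A+T share inside 2-4 bp TDRs
    tdr_consensus_excess: float = 0.25        # excess of the TT(A)(A) pattern
    parental_identity_fraction: float = 0.25  # progeny endpoints identical to parent
    telomere_repeats: int = 20
    ies_min_length: int = 136
    ies_max_length: int = 43_400

    def __post_init__(self) -> None:
        for name, weights in (("cbs_variant_weights", self.cbs_variant_weights),
                              ("tdr_class_weights", self.tdr_class_weights)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total!r})")
        lo, hi = self.telomere_offset_range
        if not (1 <= lo <= hi):
            raise ValueError("telomere_offset_range must be an increasing positive pair")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be a proportion")

    @property
    def ies_lognormal_params(self) -> tuple[float, float]:
        mean, median = self.ies_length_lognormal
        mu = math.log(median)
        sigma = math.sqrt(max(0.0, 2.0 * math.log(mean / median)))
        return mu, sigma


@dataclass
class CbsTruth:
    chromosome: str
    start: int
    end: int
    strand: str
    variant: str
    sequence: str          # C-rich strand
    clade_id: int | None = None
    tandem: bool = False


@dataclass
class IesTruth:
    chromosome: str
    start: int             # element start (left TDR copy included)
    end: int               # element end (right TDR copy included)
    tdr: str
    context: str           # intergenic | intronic | exonic
    realized: tuple[int, int] | None = None   # endpoints realized in the MAC

    @property
    def tdr_length(self) -> int:
        return len(self.tdr)

    @property
    def left_junction(self) -> int:
        """Leftmost-convention excision junction (after the retained TDR copy)."""
        return self.start + len(self.tdr)

    @property
    def right_junction(self) -> int:
        return self.end

    @property
    def length(self) -> int:
        """Excised length (element minus the one retained TDR copy)."""
        return self.end - self.start - len(self.tdr)


@dataclass
class NmcTruth:
    chromosome: str
    start: int
    end: int


@dataclass
class MacSegmentTruth:
    chromosome: str
    start: int             # MIC interval realized in this MAC contig
    end: int
    contig_id: str | None  # None for non-maintained segments
    offsets: tuple[int, int]
    maintained: bool


@dataclass
class GeneTruth:
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    coding: bool = True


@dataclass
class RearrangementTruth:
    """Ground-truth ledger emitted alongside the synthetic genomes."""

    seed: int
    cbs_sites: list[CbsTruth] = field(default_factory=list)
    ies_intervals: list[IesTruth] = field(default_factory=list)
    nmc_intervals: list[NmcTruth] = field(default_factory=list)
    mac_segments: list[MacSegmentTruth] = field(default_factory=list)
    gene_intervals: list[GeneTruth] = field(default_factory=list)

    def cbs_by_chromosome(self, chrom: str) -> list[CbsTruth]:
        return sorted((c for c in self.cbs_sites if c.chromosome == chrom),
                      key=lambda c: c.start)

    def ies_by_chromosome(self, chrom: str) -> list[IesTruth]:
        return sorted((i for i in self.ies_intervals if i.chromosome == chrom),
                      key=lambda i: i.start)

    def length_ledger(self, mic: dict[str, str], mac: dict[str, str],
                      telomere_unit: str = TELOMERE_UNIT) -> dict[str, int]:
        """Exact MIC/MAC length bookkeeping.

        ``mic_total - mac_total_excluding_telomeres`` must equal
        ``sum(IES element lengths) - sum(retained TDR lengths)
        + sum(Cbs + trimmed flank lengths) + sum(NMC lengths)``.
        """
        mic_total = sum(len(s) for s in mic.values())
        telo = 0
        for seq in mac.values():
            s = seq
            while s.startswith(telomere_unit):
                telo += len(telomere_unit)
                s = s[len(telomere_unit):]
            while s.endswith(telomere_unit):
                telo += len(telomere_unit)
                s = s[:-len(telomere_unit)]
        mac_total = sum(len(s) for s in mac.values()) - telo
        ies_total = sum(i.end - i.start for i in self.ies_intervals)
        tdr_total = sum(len(i.tdr) for i in self.ies_intervals)
        nmc_total = sum(n.end - n.start for n in self.nmc_intervals)
        trimmed = 0
        chrom_cbs_bp = sum(c.end - c.start for c in self.cbs_sites)
        for seg in self.mac_segments:
            if seg.maintained:
                trimmed += seg.offsets[0] + seg.offsets[1]
        return {
            "mic_total": mic_total,
            "mac_total_excluding_telomeres": mac_total,
            "ies_element_total": ies_total,
            "retained_tdr_total": tdr_total,
            "cbs_total": chrom_cbs_bp,
            "trimmed_flank_total": trimmed,
            "nmc_total": nmc_total,
        }


# ---------------------------------------------------------------------------
# MIC genome generation
# ---------------------------------------------------------------------------

class PlacementError(RuntimeError):
    """Raised when the requested features cannot fit on a chromosome."""


def _draw_tdr(rng: np.random.Generator, length: int, config: SimConfig) -> str:
    """AT-biased TDR with a configurable excess of the TT(A)(A) consensus.

    The AT/GC decision is made per base first (so the overall A+T fraction
    matches ``tdr_at_fraction`` regardless of the pattern excess), then with
    probability ``tdr_consensus_excess`` the A/T letters follow the TT(A)(A)
    consensus instead of being uniform.
    """
    if length == 0:
        return ""
    at_frac = config.tdr_at_fraction if length >= 2 else 0.92
    is_at = rng.random(length) < at_frac
    consensus = "TTAA"[:length]
    use_consensus = rng.random() < config.tdr_consensus_excess
    out = []
    for i in range(length):
        if is_at[i]:
            if use_consensus:
                out.append(consensus[i] if consensus[i] in "AT" else "A")
            else:
                out.append("A" if rng.random() < 0.5 else "T")
        else:
            out.append("C" if rng.random() < 0.5 else "G")
    return "".join(out)


def _draw_ies_length(rng: np.random.Generator, config: SimConfig) -> int:
    mu, sigma = config.ies_lognormal_params
    L = int(round(float(rng.lognormal(mu, sigma))))
    return int(np.clip(L, config.ies_min_length, config.ies_max_length))


def _pick_different(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in BASES if b != avoid]
    return choices[int(rng.integers(len(choices)))]


class _ChromBuilder:
    """Accumulates sequence parts and truth records for one chromosome."""

    def __init__(self, name: str, rng: np.random.Generator, config: SimConfig):
        self.name = name
        self.rng = rng
        self.config = config
        self.parts: list[str] = []
        self.pos = 0

    def emit(self, s: str) -> int:
        start = self.pos
        self.parts.append(s)
        self.pos += len(s)
        return start

    def gap(self, lo: int = 300, hi: int = 800) -> None:
        n = int(self.rng.integers(lo, hi + 1))
        self.emit(random_sequence(self.rng, n, self.config.gc_fraction))

    def set_last_base_not(self, base: str) -> None:
        """Adjust the final emitted base (junction guard)."""
        last = self.parts[-1]
        if last and last[-1] == base:
            self.parts[-1] = last[:-1] + _pick_different(self.rng, base)

    def sequence(self) -> str:
        return "".join(self.parts)


def _build_ies_element(rng: np.random.Generator, config: SimConfig,
                       context: str) -> tuple[str, str]:
    """Return (element sequence, tdr).  Element = TDR + interior + TDR."""
    if context == "exonic":
        tdr = "TTAA"
        excised = int(rng.integers(config.ies_min_length, 251))
        tir = "CACTTT"
        mid_core = random_sequence(rng, excised - len(tdr) - 2 * len(tir),
                                   config.gc_fraction)
        mid = tir + mid_core + revcomp(tir)
    else:
        classes = sorted(config.tdr_class_weights)
        probs = [config.tdr_class_weights[c] for c in classes]
        t = int(rng.choice(classes, p=probs))
        tdr = _draw_tdr(rng, t, config)
        excised = _draw_ies_length(rng, config)
        mid = random_sequence(rng, excised - len(tdr), config.gc_fraction)
    element = tdr + mid + tdr
    return element, tdr


def _emit_ies(builder: _ChromBuilder, truth: RearrangementTruth,
              context: str) -> tuple[IesTruth, str]:
    """Emit an IES element; returns the record and the base that must NOT
    follow it (junction guard, so the planted TDR is the maximal overlap)."""
    rng, config = builder.rng, builder.config
    element, tdr = _build_ies_element(rng, config, context)
    t = len(tdr)
    # the base before the element must differ from the last interior base
    builder.set_last_base_not(element[-(t + 1)])
    start = builder.emit(element)
    rec = IesTruth(builder.name, start, start + len(element), tdr, context)
    truth.ies_intervals.append(rec)
    return rec, element[t]


def _guarded(rng: np.random.Generator, seq: str, forbidden_first: str) -> str:
    if seq and seq[0] == forbidden_first:
        return _pick_different(rng, forbidden_first) + seq[1:]
    return seq


def _emit_gene_with_ies(builder: _ChromBuilder, truth: RearrangementTruth,
                        context: str) -> None:
    rng, config = builder.rng, builder.config
    g_start = builder.emit(random_sequence(rng, 200, config.gc_fraction))
    if context == "intronic":
        exon1 = (g_start, builder.pos)
        builder.emit(random_sequence(rng, 30, config.gc_fraction))
        _rec, guard = _emit_ies(builder, truth, context)
        builder.emit(_guarded(rng, random_sequence(rng, 30, config.gc_fraction), guard))
        exon2_start = builder.pos
        builder.emit(random_sequence(rng, 200, config.gc_fraction))
        exons = [exon1, (exon2_start, builder.pos)]
    else:  # exonic: the IES interrupts a single coding exon
        _rec, guard = _emit_ies(builder, truth, context)
        builder.emit(_guarded(rng, random_sequence(rng, 200, config.gc_fraction), guard))
        exons = [(g_start, builder.pos)]
    truth.gene_intervals.append(
        GeneTruth(builder.name, g_start, builder.pos, "+", exons))


def _emit_plain_gene(builder: _ChromBuilder, truth: RearrangementTruth) -> None:
    rng, config = builder.rng, builder.config
    g_start = builder.emit(random_sequence(rng, 180, config.gc_fraction))
    exon1 = (g_start, builder.pos)
    builder.emit(random_sequence(rng, 40, config.gc_fraction))
    exon2_start = builder.pos
    builder.emit(random_sequence(rng, 180, config.gc_fraction))
    truth.gene_intervals.append(
        GeneTruth(builder.name, g_start, builder.pos, "+",
                  [exon1, (exon2_start, builder.pos)]))


def _emit_intergenic_ies(builder: _ChromBuilder, truth: RearrangementTruth) -> None:
    _rec, guard = _emit_ies(builder, truth, "intergenic")
    builder.emit(_guarded(builder.rng,
                          random_sequence(builder.rng, 30, builder.config.gc_fraction),
                          guard))


def _emit_cbs(builder: _ChromBuilder, truth: RearrangementTruth,
              variant: str, strand: str, clade_id: int | None = None,
              tandem: bool = False, motif: str | None = None) -> CbsTruth:
    crich = motif or variant_to_sequence(variant)
    planted = crich if strand == "+" else revcomp(crich)
    start = builder.emit(planted)
    rec = CbsTruth(builder.name, start, start + 15, strand, variant, crich,
                   clade_id=clade_id, tandem=tandem)
    truth.cbs_sites.append(rec)
    return rec


def generate_mic_genome(config: SimConfig) -> tuple[dict[str, str], RearrangementTruth]:
    """Generate the germline genome and its ground-truth ledger."""
    rng = np.random.default_rng(config.seed)
    truth = RearrangementTruth(seed=config.seed)
    variant_labels = sorted(config.cbs_variant_weights)
    variant_probs = [config.cbs_variant_weights[v] for v in variant_labels]

    # assign contexts to the requested IESs, then deal them out
    n_exonic = max(1, round(CONTEXT_FRACTIONS["exonic"] * config.n_ies)) \
        if config.n_ies >= 20 else 0
    n_intronic = round(CONTEXT_FRACTIONS["intronic"] * config.n_ies)
    contexts = (["exonic"] * n_exonic + ["intronic"] * n_intronic
                + ["intergenic"] * (config.n_ies - n_exonic - n_intronic))
    rng.shuffle(contexts)

    # deal IESs across chromosomes, then across inter-Cbs interiors
    per_chrom: list[list[str]] = [[] for _ in range(config.n_chromosomes)]
    for i, ctx in enumerate(contexts):
        per_chrom[i % config.n_chromosomes].append(ctx)

    # pick Cbs instances to tandem-duplicate (producing NMCs) and the donor
    # of long-range duplications (clade ancestors)
    total_cbs = config.n_chromosomes * config.n_cbs_per_chromosome
    if total_cbs == 0 and (config.n_tandem_dup_cbs or config.n_longrange_dup_cbs):
        raise ValueError("cannot duplicate Cbs's in a genome with none")
    tandem_flags = set()
    if config.n_tandem_dup_cbs:
        tandem_flags = set(map(int, rng.choice(total_cbs,
                                               size=min(config.n_tandem_dup_cbs, total_cbs),
                                               replace=False)))
    longrange_targets: dict[int, int] = {}   # chromosome index -> clade id
    donor_window: str | None = None
    donor_clade = 1

    chromosomes: dict[str, str] = {}
    next_clade = 2
    cbs_counter = 0
    for ci in range(config.n_chromosomes):
        name = f"mic_chr{ci + 1}"
        builder = _ChromBuilder(name, rng, config)
        contexts_here = per_chrom[ci]
        n_seg = config.n_cbs_per_chromosome + 1
        # estimate feasibility: IES content must leave room for flanks/genes
        est_content = sum(4000 for _ in contexts_here) + n_seg * 2000
        if est_content > 3 * config.chromosome_length:
            raise PlacementError(
                f"chromosome {name} too crowded: {len(contexts_here)} IESs plus "
                f"{config.n_cbs_per_chromosome} Cbs's do not fit in "
                f"{config.chromosome_length} bp")
        seg_of: list[list[str]] = [[] for _ in range(n_seg)]
        for ctx in contexts_here:
            seg_of[int(rng.integers(n_seg))].append(ctx)
        target_interior = max(2000, (config.chromosome_length
                                     - config.n_cbs_per_chromosome * 415) // n_seg)

        # long-range duplication copy planted once per recipient chromosome
        plant_longrange_in_segment = None
        if ci in longrange_targets:
            plant_longrange_in_segment = int(rng.integers(n_seg))

        for si in range(n_seg):
            seg_start = builder.pos
            builder.gap()
            if plant_longrange_in_segment == si and donor_window is not None:
                copy = mutate(rng, donor_window, config.duplication_divergence,
                              protected=[(200, 215)])
                off = builder.emit(copy)
                label, _n = cbs_mod.classify_variant(copy[200:215]
                                                     if _is_crich(copy[200:215])
                                                     else revcomp(copy[200:215]))
                strand = "+" if _is_crich(copy[200:215]) else "-"
                crich = copy[200:215] if strand == "+" else revcomp(copy[200:215])
                truth.cbs_sites.append(CbsTruth(name, off + 200, off + 215, strand,
                                                label, crich,
                                                clade_id=longrange_targets[ci]))
                builder.gap()
            for ctx in seg_of[si]:
                if ctx == "intergenic":
                    _emit_intergenic_ies(builder, truth)
                else:
                    _emit_gene_with_ies(builder, truth, ctx)
                builder.gap()
            if config.n_ies and rng.random() < 0.6:
                _emit_plain_gene(builder, truth)
                builder.gap()
            pad = target_interior - (builder.pos - seg_start)
            if pad > 0:
                builder.emit(random_sequence(rng, pad, config.gc_fraction))
            if si == n_seg - 1:
                break
            # Cbs with explicit 200 bp flanks (duplication donor windows)
            variant = str(rng.choice(variant_labels, p=variant_probs))
            strand = "+" if rng.random() < 0.5 else "-"
            flank_l = random_sequence(rng, 200, config.gc_fraction)
            builder.emit(flank_l)
            site = _emit_cbs(builder, truth, variant, strand)
            flank_r = random_sequence(rng, 200, config.gc_fraction)
            builder.emit(flank_r)
            planted_motif = builder.parts[-2]
            if donor_window is None and config.n_longrange_dup_cbs and ci == 0:
                donor_window = flank_l + planted_motif + flank_r
                site.clade_id = donor_clade
                for r in range(1, config.n_chromosomes)[: config.n_longrange_dup_cbs]:
                    longrange_targets[r] = donor_clade
            if cbs_counter in tandem_flags:
                # tandem duplicate: mutated copy of (left flank + Cbs) right
                # after the original's right flank; the spanned ~400 bp
                # becomes a non-maintained chromosome.  A Cbs that is also a
                # long-range duplication donor keeps its clade: all copies
                # descend from the same ancestral segment.
                if site.clade_id is not None:
                    clade = site.clade_id
                else:
                    clade = next_clade
                    next_clade += 1
                site.clade_id = clade
                site.tandem = True
                spacer = mutate(rng, flank_l, config.duplication_divergence)
                builder.emit(spacer)
                copy = _emit_cbs(builder, truth, variant, strand,
                                 clade_id=clade, tandem=True,
                                 motif=site.sequence)
                truth.nmc_intervals.append(NmcTruth(name, site.end, copy.start))
                builder.emit(random_sequence(rng, 200, config.gc_fraction))
            cbs_counter += 1
        chromosomes[name] = builder.sequence()

    _scrub_accidental_motifs(chromosomes, truth, rng)
    _check_composition(chromosomes, config)
    return chromosomes, truth


def _is_crich(motif: str) -> bool:
    return motif.count("C") >= revcomp(motif).count("C")


def _scrub_accidental_motifs(chromosomes: dict[str, str],
                             truth: RearrangementTruth,
                             rng: np.random.Generator) -> None:
    """Break any chance Cbs-regex match so planted motifs are unambiguous."""
    for name in list(chromosomes):
        want = {(c.start, c.strand) for c in truth.cbs_by_chromosome(name)}
        protected = set()
        for ies in truth.ies_by_chromosome(name):
            t = ies.tdr_length
            for p in range(ies.start - 1, ies.start + t + 1):
                protected.add(p)
            for p in range(ies.end - t - 1, ies.end + 1):
                protected.add(p)
        for _round in range(6):
            seq = chromosomes[name]
            stray = [h for h in cbs_mod.scan_cbs(seq, name)
                     if (h.start, h.strand) not in want]
            if not stray:
                break
            chars = list(seq)
            for h in stray:
                fixed = False
                for off in (4, 5, 7, 8):          # absolutely conserved C/A core
                    p = h.start + off
                    if p in protected:
                        continue
                    old = chars[p]
                    for b in BASES:
                        if b == old:
                            continue
                        chars[p] = b
                        w_start = max(0, h.start - 15)
                        window = "".join(chars[w_start:h.end + 15])
                        still = any(w.start + w_start == h.start and w.strand == h.strand
                                    for w in cbs_mod.scan_cbs(window, "w"))
                        if not still:
                            fixed = True
                            break
                        chars[p] = old
                    if fixed:
                        break
                if not fixed:
                    raise PlacementError(
                        f"could not scrub accidental Cbs match on {name} at {h.start}")
            chromosomes[name] = "".join(chars)
        else:
            raise PlacementError(f"accidental Cbs matches persist on {name}")


def _check_composition(chromosomes: dict[str, str], config: SimConfig) -> None:
    from .sequence import gc_content
    total = "".join(chromosomes.values())
    at = 1.0 - gc_content(total)
    want_at = 1.0 - config.gc_fraction
    if abs(at - want_at) > 0.02:
        raise PlacementError(
            f"base composition drifted: A+T {at:.3f} vs configured {want_at:.3f}")


# ---------------------------------------------------------------------------
# MAC derivation
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, sd: float) -> int:
    if sd <= 0:
        return 0
    return int(round(float(rng.normal(0.0, sd))))


def derive_mac_genome(mic: dict[str, str], truth: RearrangementTruth,
                      config: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[dict[str, str], RearrangementTruth]:
    """Derive the somatic genome: fragment at Cbs's, excise IESs, add telomeres.

    Maintained inter-Cbs segments become MAC contigs that exclude the Cbs and
    5-25 bp of flank on each side (drawn from ``telomere_offset_range``), with
    IESs excised (one TDR copy retained, endpoints jittered by
    ``excision_endpoint_sd``) and ``CCCCAA`` telomere-repeat markers appended
    at Cbs-derived ends.  Non-maintained segments are omitted from the FASTA
    but stay in the truth ledger.  Returns the MAC sequences and the truth
    updated with realized excision endpoints and MAC segment records.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    lo, hi = config.telomere_offset_range
    telo = TELOMERE_UNIT * config.telomere_repeats
    nmc_keys = {(n.chromosome, n.start, n.end) for n in truth.nmc_intervals}
    mac: dict[str, str] = {}
    truth.mac_segments = []
    for chrom, seq in mic.items():
        sites = truth.cbs_by_chromosome(chrom)
        iess = truth.ies_by_chromosome(chrom)
        for ies in iess:
            for c in sites:
                if ies.start < c.end and c.start < ies.end:
                    raise ValueError(
                        f"truth inconsistency: IES {chrom}:{ies.start}-{ies.end} "
                        f"spans Cbs at {c.start}")
        bounds = [(None, 0)] + [(c, c.end) for c in sites]
        contig_n = 0
        excised_ids: set[int] = set()
        for k, (left_cbs, seg_start) in enumerate(bounds):
            if k + 1 < len(bounds):
                right_cbs = bounds[k + 1][0]
                seg_end = right_cbs.start
            else:
                right_cbs, seg_end = None, len(seq)
            if (chrom, seg_start, seg_end) in nmc_keys:
                truth.mac_segments.append(
                    MacSegmentTruth(chrom, seg_start, seg_end, None, (0, 0), False))
                continue
            off_l = int(rng.integers(lo, hi + 1)) if left_cbs is not None else 0
            off_r = int(rng.integers(lo, hi + 1)) if right_cbs is not None else 0
            c_start, c_end = seg_start + off_l, seg_end - off_r
            pieces: list[str] = []
            cursor = c_start
            for ies in iess:
                if ies.start < c_start or ies.end > c_end:
                    continue
                excised_ids.add(id(ies))
                l0, r0 = ies.left_junction, ies.right_junction
                dl = _jitter(rng, config.excision_endpoint_sd)
                dr = _jitter(rng, config.excision_endpoint_sd)
                l1 = int(np.clip(l0 + dl, ies.start, ies.end - 1))
                r1 = int(np.clip(r0 + dr, l1 + 1, ies.end))
                ies.realized = (l1, r1)
                pieces.append(seq[cursor:l1])
                cursor = r1
            pieces.append(seq[cursor:c_end])
            contig_n += 1
            cid = f"mac_{chrom}_{contig_n}"
            body = "".join(pieces)
            left_t = telo if left_cbs is not None else ""
            right_t = telo if right_cbs is not None else ""
            mac[cid] = left_t + body + right_t
            truth.mac_segments.append(
                MacSegmentTruth(chrom, seg_start, seg_end, cid, (off_l, off_r), True))
        missed = [i for i in iess if id(i) not in excised_ids]
        if missed:
            raise ValueError(
                f"{len(missed)} IESs on {chrom} fall outside every maintained "
                f"segment (first at {missed[0].start}); truth inconsistent")
    return mac, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Read:
    name: str
    sequence: str

    @property
    def quality(self) -> str:
        return "I" * len(self.sequence)


def simulate_reads(genome: dict[str, str], config: SimConfig,
                   rng: np.random.Generator | None = None,
                   read_length: int | None = None,
                   coverage: float | None = None,
                   error_rate: float = 0.0,
                   paired: bool = False) -> list[Read]:
    """Uniform shotgun reads with true origin encoded in the read name.

    Single-end mode emits ``round(coverage * length / read_length)`` reads
    per sequence; paired mode emits that many read *pairs* drawn from
    ``frag_insert``-length fragments.  Reads come from either strand;
    substitution errors are applied at ``error_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, 3])
    L = read_length if read_length is not None else config.read_length
    cov = coverage if coverage is not None else config.coverage
    if cov <= 0:
        raise ValueError("coverage must be positive")
    reads: list[Read] = []
    for chrom, seq in genome.items():
        span = config.frag_insert if paired else L
        if span > len(seq):
            raise ValueError(
                f"read span {span} exceeds length of {chrom} ({len(seq)} bp)")
        n = int(round(cov * len(seq) / (2 * L if paired else L)))
        starts = rng.integers(0, len(seq) - span + 1, size=n)
        strands = rng.random(n) < 0.5
        for i, (s, fwd) in enumerate(zip(starts, strands)):
            s = int(s)
            frag = seq[s:s + span]
            strand = "+" if fwd else "-"
            if paired:
                r1, r2 = frag[:L], revcomp(frag[-L:])
                if not fwd:
                    r1, r2 = revcomp(frag[-L:]), frag[:L]
                for mate, rs in ((1, r1), (2, r2)):
                    rs = _apply_errors(rng, rs, error_rate)
                    reads.append(Read(f"{chrom}|{s}|{strand}|{i}/{mate}", rs))
            else:
                r = frag if fwd else revcomp(frag)
                r = _apply_errors(rng, r, error_rate)
                reads.append(Read(f"{chrom}|{s}|{strand}|{i}", r))
    return reads


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    return mutate(rng, seq, rate)


# ---------------------------------------------------------------------------
# Progeny-pool excision endpoints
# ---------------------------------------------------------------------------

def simulate_progeny_endpoints(parental: tuple[int, int],
                               rng: np.random.Generator,
                               sd: float = 3.0,
                               p_parental: float = 0.25,
                               n_events: int = 30,
                               mean_reads_per_event: float = 5.0
                               ) -> list[tuple[tuple[int, int], int]]:
    """Observed excision endpoints at one IES site in a progeny pool.

    Each of ``n_events`` independent somatic differentiation events realizes
    an endpoint pair: identical to the parental pair with probability
    ``p_parental`` (cis-acting boundary elements make the parental endpoint
    the single most likely outcome), otherwise both endpoints jittered by a
    discretized Gaussian of the given sd.  Events are then sampled by reads
    (Poisson); the return value aggregates read counts per distinct pair.
    """
    l0, r0 = parental
    counts: dict[tuple[int, int], int] = {}
    for _ in range(n_events):
        if rng.random() < p_parental:
            pair = (l0, r0)
        else:
            pair = (l0 + _jitter(rng, sd), r0 + _jitter(rng, sd))
            if pair[1] <= pair[0]:
                pair = (l0, r0)
        n_reads = int(rng.poisson(mean_reads_per_event))
        if n_reads:
            counts[pair] = counts.get(pair, 0) + n_reads
    return sorted(counts.items())
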