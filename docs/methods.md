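# Methods

## The rearrangement model

The package models a germline (MIC) genome that matures into a somatic (MAC)
genome through two programmed events:

1. **Chromosome fragmentation** at a conserved 15 bp chromosome breakage
   sequence (Cbs).  The Cbs and roughly 5–25 bp of flank on each side are
   lost; telomere repeats (`CCCCAA` units) are added at the new ends.  The
   Cbs family is written on the C-rich strand as `WAAACCAACCYCNHW`; ten
   positions are invariant and functional members carry at most two
   substitutions relative to the canonical `TAAACCAACCTCTTT`.
2. **DNA elimination** of internal eliminated sequences (IESs): MIC-limited
   intervals excised during MAC development, with the flanking MAC-destined
   sequences joined.  Excision often leaves a short terminal direct repeat
   (TDR): a sequence present at both IES termini of which exactly one copy
   remains at the somatic junction.  A segment delimited by two consecutive
   Cbs's but absent from the mature MAC is a non-maintained chromosome (NMC).

Junction conventions: an IES element occupies the half-open MIC interval
`[s, e)` with its TDR (length `t`) at both termini; the excision removes
`e − s − t` bases and the canonical ("leftmost") junction pair is
`(s + t, e)`, i.e. the retained TDR copy sits immediately left of the left
junction.  All coordinates are 0-based half-open internally; report tables
are 1-based.

## Synthetic study conditions

`SimConfig` defaults define the simulated conditions; they mirror the
empirical genome this package targets:

| parameter | default | rationale |
| --- | --- | --- |
| chromosomes × length | 5 × 500 kb | five germline chromosomes, miniature scale |
| gc_fraction | 0.221 | germline assembly is 77.9 % A+T |
| Cbs per chromosome | 9 (≈ 48 with duplications) | one breakage site per ~50 kb at this scale |
| cbs_variant_weights | published census proportions | 109 canonical, 93 single-, 23 double-substituted of 225 |
| n_ies | 120 | ≈ 48 IESs per Mb, the genome-wide density of the high-confidence set |
| ies_length_lognormal | mean 3.78 kb, median 2.78 kb | observed set statistics; the lognormal family is an assumption (the reported size histogram is log₂-scaled and right-skewed; no family is stated) with `μ = ln(median)`, `σ² = 2 ln(mean/median)`, truncated to [136 bp, 43.4 kb] |
| tdr_class_weights | {0: .37, 1: .23, 2: .18, 3: .12, 4: .10} | no-TDR is the largest class; 1–4 bp classes decline |
| tdr_at_fraction | 0.97 (0.92 for 1-mers) | TDRs are far more AT-rich than flanks |
| tdr_consensus_excess | 0.25 | a slight TT(A)(A) pattern bias among AT-only TDRs; applied after the AT/GC draw so the AT fraction is unaffected |
| telomere_offset_range | (5, 25) bp | telomere-addition window on each side of a Cbs |
| excision_endpoint_sd | 0 | the reference MAC realizes one endpoint per site; variability belongs to the progeny pool (below) |
| n_tandem_dup_cbs / n_longrange_dup_cbs | 2 / 1 | tandem duplications create NMCs; long-range duplications seed multi-copy clades (8 % divergence between copies) |
| coverage / read_length | 10× / 100 bp | matches the ~9.3× somatic read coverage; somatic libraries are simulated as 700 bp "Sanger-like" reads |

The generator plants every feature with junction guard bases so the planted
TDR is provably the maximal overlap, scrubs any chance Cbs-regex match so
scan recall and precision are exactly 1 by construction, and emits a
`RearrangementTruth` ledger (BED/TSV-serializable) for scoring.  A single
seeded generator drives everything; identical seeds give byte-identical
output.

**Progeny-pool endpoint model.**  Excision endpoints across independent MAC
differentiation events are drawn from a *zero-inflated* discretized
Gaussian: with probability `p_parental` (default 0.25) an event reproduces
the parental junction exactly; otherwise both endpoints receive independent
rounded-Gaussian jitter.  The point mass is deliberate: empirically the
single most common progeny endpoint is the parental one by a wide margin
(consistent with cis-acting boundary elements), which a pure Gaussian of any
sd cannot reproduce — its summed-|distance| histogram peaks at 1, not 0.
Events are sampled by Poisson read counts and an endpoint is validated by
≥ 3 identical independent reads.

**What the simulator does not emulate:** assembly gaps (N runs) arise only
in handcrafted fixtures, repeats are limited to the planted duplications,
reads are error-free by default, and MIC→MAC order is strictly colinear (no
scrambling).  Passing benchmarks therefore demonstrates correctness of the
detection logic under clean evidence, not robustness to assembly artifacts
or sequencing error on real libraries.

## Detection methods

**Alignment substrate.**  Synthetic reads/contigs are aligned by an exact
k-mer (k = 31) seed-and-extend aligner: greedy left-to-right maximal exact
extension, re-seeding the remainder, ambiguity flagged when two reference
positions tie.  Real alignments enter as SAM (pysam) or PAF and become the
same `AlignmentBlock` records.

**Method 1 — split reads** (somatic reads on the germline): every
query-adjacent (≤ 5 bp slack), same-scaffold, same-orientation block pair of
a read evidences one junction pair; a candidate needs ≥ 3 spanning reads
with the identical pair, mean internal somatic coverage < 1× and junctions
clear of N runs.  Multi-IES-spanning reads contribute one count per junction.

**Method 2 — broken reads** (germline reads on the somatic assembly):
single-block alignments leaving an unaligned tail ≥ 5 bp mark breakpoints;
single-linkage clusters within 10 bp validate with ≥ 6 broken reads and
≥ 1 facing from each direction.  The overlap of the two directional
breakpoint modes is direct TDR evidence.  Duplicate alignment footprints are
removed first.  Validated sites are lifted to MIC junctions through the
cross-assembly block chains.

**Method 3 — assembly gaps**: in a colinear MIC/MAC block chain, an adjacent
pair whose MIC-side gap exceeds the MAC-side gap by > 100 bp yields a
candidate spanning the MIC gap.

**Merging**: candidates agreeing at both junctions within `merge_tol`
(default 0 — precise junctions are the definition of high confidence) merge
into one record carrying the corroborating method set; junction-gap records
are demoted to provisional; the TDR is read off the MIC as the maximal
two-sided junction overlap (leftmost placement on ties; capped at 10 bp).

**Clades**: Cbs segments are the motif ± 200 bp (members closer than 400 bp
merged, then split at inter-Cbs midpoints for alignment to avoid
self-matches).  Local alignment uses match +1 / mismatch −2, affine gaps
5/2 (open/extend).  Expectations are Karlin–Altschul style,
`E = m·n·2^(−bits)` with λ solved from the segment base composition and a
fixed K = 0.1; they are internally consistent but not NCBI-comparable, so
the clustering threshold (default 1e−18-equivalent) is validated against a
composition-preserving randomized-flank null (Cbs kept intact, three
independent control sets) rather than read as an absolute number.  Marker
clustering is either connected components over the threshold or Markov
clustering (inflation 2.0, deterministic, iteration-capped) on
score/self-score ratios; edges count only when the two Cbs motifs align to
one another.

**Centromeres**: viable germline arm deletions never remove sequence
essential for centromere function, so the centromere is reported as the
interval between the outermost Cbs's untouched by any deletion (the
interval may contain further Cbs's).  Worked-example inputs are the
published per-chromosome flanking-Cbs positions.

**Tiling**: scaffold ends join when their terminal regions (within 1 kb of
an end) align to consecutive intervals of one bridge scaffold of the other
assembly, separated by ≤ 2 kb and overlapping by ≤ 50 bp, at ≥ 95 % identity
over ≥ 1 kb.  An end with two distinct proposals is flagged unresolved and
left unjoined — the package never guesses between repeat-induced
alternatives.  Accepted edges must form simple paths; orientation propagates
along each path; layouts are AGP-like with fixed 100 N spacers (no spacer
length is prescribed by the biology).

**Fitch parsimony**: Cbs variants are discrete states on a rooted species
tree; unsequenced tips are unconstrained.  The implementation is checked
against exhaustive enumeration of internal labelings on all rooted binary
shapes up to six tips.

## Numerical and design choices

- Information content uses base-2 logs with zero-frequency terms dropped; N
  columns are excluded from counts.  Chi-square uses no continuity
  correction (n = 28 C+G substitutions is ample).
- k-mer codes are 2-bit packed into signed int64 (k ≤ 31) so index lookups
  binary-search without dtype promotion; N-containing k-mers are invalid.
- NMC classification threshold: < 5 % of segment bases with MAC alignment
  evidence.  The biological definition is "absent from the MAC assembly";
  the numeric cutoff is a tolerance for stray short matches, configurable.
- The coding-IES screen's shortness criterion is the 1st percentile of the
  length distribution (configurable); its TIR consensus `CACTTT` allows two
  mismatches.
- Degenerate inputs: empty sequences scan to empty hit lists; empty record
  sets raise for statistics that need data (conservation profile, length
  stats, TDR composition); deletions covering a whole chromosome raise.

## Limitations

- Absolute alignment expectations differ from NCBI BLAST; reproducing the
  published clade count on real data would require the original tool build
  and database sizing.  Clade benchmarks here are planted-truth recovery.
- Genome-scale published counts (225 Cbs's, 7551 high-confidence IESs,
  33 NMCs, 15 clades) require the deposited assemblies and read sets; the
  package reproduces the printed worked values exactly and the genome-scale
  claims as scaled-down properties on synthetic truth.
- The tiling stage flags, but does not resolve, repeat-induced ambiguity;
  published chromosome-scale super-assemblies additionally used mapping data
  and human judgment.
- Paired-end simulation is minimal (uniform fragments, fixed insert); no
  indel or quality model.
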