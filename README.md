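# micmac

Analysis toolkit for programmed genome rearrangement in ciliate-style
germline/soma nuclear dimorphism: the relationship between a germline
micronuclear (MIC) genome and the somatic macronuclear (MAC) genome derived
from it by chromosome fragmentation and DNA elimination.

Built for genome analysts studying *Tetrahymena*-like systems, the package
covers:

- **Cbs mapping** — scanning both strands for the 15 bp chromosome breakage
  sequence family `5'-WAAACCAACCYCNHW-3'` (C-rich strand convention),
  classifying variants by substitutions against the canonical
  `TAAACCAACCTCTTT`, per-position information content
  `R_i = 2 + Σ_b f_b log₂ f_b` (bits), and the C-vs-G substitution strand
  asymmetry (χ², df = 1).
- **Breakage maps, NMCs, centromeres** — tiling chromosomes into inter-Cbs
  segments, classifying non-maintained chromosomes (Cbs-delimited segments
  absent from the MAC), and demarcating centromeres from viable germline
  arm-deletion strains.
- **Cbs duplication clades** — all-vs-all local alignment of 415 bp
  Cbs-centred segments, Karlin–Altschul-style expectations calibrated on a
  composition-preserving randomized-flank null, and clustering by expectation
  threshold or Markov clustering of self-normalized bit scores.
- **IES detection** — internal eliminated sequences called by three
  complementary alignment methods (split somatic reads on the MIC, broken
  germline reads on the MAC, MIC/MAC cross-assembly gap asymmetry) and merged
  into a high-confidence set with precise junctions.
- **Junction statistics** — terminal direct repeats (TDRs), their AT-rich
  composition, reverse-complement pattern classes, progeny-pool excision
  endpoint variability, and the four-feature screen for precisely excised
  coding-region IESs (TTAA TDR, CACTTT terminal inverted repeat, exceptional
  shortness, precision).
- **Super-assembly tiling** — joining scaffolds into chromosome-length paths
  when terminal regions of two scaffolds align to adjacent intervals of one
  scaffold of the other assembly, plus sliding-window feature-density tracks.
- **Synthetic data** — a ground-truthed simulator of miniature rearranged
  genomes (planted Cbs variants from the published census, lognormal IES
  lengths, AT-biased TDRs, tandem-duplication NMCs, telomere-addition
  trimming, read simulation) against which every detector is scored.

Real data enters as FASTA plus SAM/PAF alignments; synthetic data uses a
built-in exact seed-and-extend aligner producing the same `AlignmentBlock`
records, so the detection logic is identical on both routes.

## Worked example

```python
import numpy as np
from micmac.cbs import CbsHit, classify_variant, conservation_profile, strand_asymmetry
from micmac.tables import variant_census_sequences

census = variant_census_sequences()          # the published 225-member census
prof = conservation_profile(census)
hits = [CbsHit("c", 0, 15, "+", s, *classify_variant(s)) for s in census]
n_c, n_g, chi2, p = strand_asymmetry(hits)

from micmac.simulate import SimConfig
from micmac import pipeline
from micmac.ies import length_stats

cfg = SimConfig(seed=1)                      # 5 chromosomes, ~2.5 Mb, 120 IESs
mic, mac, truth = pipeline.simulate_genomes(cfg)
res = pipeline.run_ies_detection(mic, mac, truth, cfg)
recall, precision = res.recall_precision()
stats = length_stats(res.records)
```

prints (via the formatting in `scripts/acceptance.py`-style reporting):

```
census size        : 225
conserved positions: 10 of 15 at 2.0 bits
substitutions to C : 27, to G: 1  (chi2 = 24.14, p = 8.94e-07)
synthetic MIC      : 2,500,805 bp, 48 Cbs, 120 IESs
high-confidence set: 120 records, recall 1.000, precision 1.000
IES length         : mean 3.82 kb, median 3.15 kb, 85% in 1-10 kb
```

Ten of the fifteen Cbs positions are fully conserved (2 bits); substitutions
on the C-rich strand go to C 27 times but to G only once — the same strand
asymmetry shown by telomeric repeats.  On the synthetic genome the merged
high-confidence IES set recovers the planted truth exactly at zero endpoint
jitter, and the sample length distribution reflects the configured lognormal
(mean 3.78 kb, median 2.78 kb).

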