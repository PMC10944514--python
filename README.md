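# neojx

Screening of tumor-specific alternative-splicing junctions
("neojunctions") predicted to yield MHC-independent cell-surface
antigens, for bulk RNA-seq cohorts of tumors and normal tissues.

## The problem

Tumor-specific alternative splicing can create protein changes on the
cell surface that antibodies or CAR-T cells could target without MHC
presentation. Finding such events from short-read RNA-seq means sifting
hundreds of thousands of exon-exon junctions per cohort for the few that
are (1) robustly expressed, (2) absent from normal tissues, (3) shared
across patients, (4) hosted by a cell-surface ("surfaceome") gene, and
(5) predicted — after in-silico translation — to alter an extracellular
segment while keeping the transmembrane anchor intact and introducing no
premature termination codon (PTC). `neojx` implements that screen as a
reusable, deterministic pipeline, together with a synthetic-cohort
generator that plants ground-truth events so every filter can be tested
end to end.

## The method

Junctions come from STAR `SJ.out.tab` files, keyed by
`(chromosome, first intronic base, last intronic base, strand)` with the
column-7 uniquely-mapped read count. A junction is **positive** in a
sample when three conditions hold (tumor cohort / normal cohort):

- supportive read count `c >= 10` / `>= 2`
- read depth `c + d >= 20` / `>= 10`, where `d` is the count of the
  *most dominant overlapping junction* — the most abundant annotated
  junction whose intron intersects the query (fallback: most abundant
  overlapping junction of any kind), ranked on summed tumor-cohort
  counts and reused unchanged for the normal cohort
- supportive read frequency `c / (c + d) >= 0.01`

The **positive sample rate** (PSR) of a junction in a group is the number
of positive samples divided by the full group size. The screen then runs
eight stages: detection (count >= 10 in at least one tumor sample,
chromosomes 1-22/X/Y) → removal of annotated junctions (GTF-derived
reference set) → restriction to surfaceome genes with mean tumor
TPM >= 10 → tumor specificity (pooled-normal PSR < 1%) → sharedness
(PSR >= 10% in at least one disease group) → extracellular impact →
protein compatibility (no PTC, transmembrane segment intact, single-pass
host) → a machine-readable manual-exclusion list. Each junction that
drops out carries exactly one first-failure stage, and the per-stage
survivor ledger is non-increasing by construction.

Protein consequences are predicted by rebuilding the template
transcript's exon chain around the novel intron, re-extracting the CDS
from the annotated start codon, translating with the standard code
(stops marked `*`), and comparing against the wild-type protein; splice
patterns are classified as alternative 3'/5' splice site, exon skipping,
cryptic intron, or complex. Multi-region and primary/recurrent cohorts
are summarized per event with tumor-wide (100% of pieces) and >= 50%
timepoint-positivity rules.

## Worked example

Generate a synthetic cohort (60 tumor samples in three disease groups,
300 normals, five planted pass-filter events, one decoy per failure
class) and screen it:

```sh
neojx simulate --seed 7 --out demo
neojx screen --sj-dir demo/sj --gtf demo/annotation.gtf \
    --fasta demo/genome.fa --expression demo/expression.tsv \
    --surfaceome demo/surfaceome.tsv --manifest demo/manifest.tsv \
    --out demo/screen
```

which prints the stage ledger

```json
{
  "detected": 98,
  "non_annotated": 12,
  "surfaceome_expressed": 11,
  "tumor_specific": 10,
  "shared": 8,
  "extracellular": 7,
  "protein_compatible": 5,
  "final": 5
}
```

98 junctions reached the detection floor; 12 were non-annotated (the
annotated decoy and all reference junctions fall out here); the
low-expression decoy leaves at the surfaceome/TPM gate, the
normal-shared decoy at tumor specificity, the rare and low-frequency
decoys at sharedness, the intracellular decoy at the extracellular gate,
and the frameshift/PTC and multi-pass decoys at protein compatibility —
leaving exactly the five planted events. The final candidates in
`demo/screen/candidates.tsv`:

```
   junction_key gene_symbol        pattern  psr_IDHwt  psr_IDH-A  psr_IDH-O  psr_normal
  1:1172-1341:+       SG000        alt_3ss        0.5        0.4        0.6         0.0
1:12045-12068:-       SG003 cryptic_intron        0.5        0.5        0.2         0.0
  1:5562-5868:-       SG001        alt_5ss        0.2        0.5        0.5         0.0
  1:7159-7952:+       SG002      exon_skip        0.6        0.3        0.3         0.0
  2:1136-1410:+       SG004        alt_3ss        0.3        0.6        0.4         0.0
```

PSR columns are per disease group: `1:1172-1341:+` is positive in 50% of
IDHwt, 40% of IDH-A and 60% of IDH-O samples and in none of the 300
normals, matching its designed positivity probabilities. A sidecar
`candidates.consequences.tsv` carries the per-template translation
verdicts (frame status, amino acids lost, PTC flag, transmembrane
integrity), and `ledger.json` the stage counts.

The same screen is available as a library call
(`neojx.screen_cohort(...)` on in-memory objects, `neojx.run_screen` on
files), and `neojx.spatial_summary` / `neojx.longitudinal_classify`
produce the multi-region and paired-timepoint summaries.

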