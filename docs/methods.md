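# Methods

## Screening model

The unit of analysis is an exon-exon splice junction, identified by the
intron it excises: `(chromosome, first intronic base, last intronic
base, strand)`, all coordinates 1-based inclusive as in STAR
`SJ.out.tab` and Ensembl GTF. Only uniquely-mapped junction reads
(column 7) are used; the multi-mapped column is ignored. Junctions
outside chromosomes 1-22/X/Y are dropped at parse time. Junctions whose
strand STAR left undetermined (code 0) are resolved from the strand of
the overlapping gene; when overlapping genes disagree the junction is
dropped with a log entry, and with no overlapping gene it is kept
strand-undetermined and matches either strand downstream.

### Positivity

A junction is called positive in a sample from three statistics:

| quantity | definition | tumor threshold | normal threshold |
| --- | --- | --- | --- |
| supportive count `c` | unique reads crossing the junction | >= 10 | >= 2 |
| depth `c + d` | `d` = count of the dominant overlapping junction | >= 20 | >= 10 |
| frequency `c/(c+d)` | supportive-read fraction at the locus | >= 0.01 | >= 0.01 |

The looser normal thresholds reflect the systematically smaller
sequencing depth of large normal-tissue compendia relative to tumor
cohorts. The *dominant overlapping junction* is the most abundant
annotated junction whose intron interval intersects the query on the
same chromosome with a compatible strand; if no annotated junction
overlaps, the most abundant overlapping junction of any kind is used.
Abundance is the summed count over the tumor cohort, and the selection
made on the tumor cohort is reused for normal samples, so the frequency
denominator is comparable across cohorts. Ties break on the larger
total, then the lexicographically smaller junction key, making the
choice deterministic.

Two points are underdetermined in the screening procedure as published
and are explicit choices here, both configurable:

- "overlapping" is implemented as intron-interval intersection —
  the natural reading for competing splice-site usage at a locus;
- the query junction is excluded from being its own dominant junction;
  a junction with no overlapping junction at all gets depth = count and
  frequency 1, so isolated novel junctions remain callable
  (`allow_self_dominant` restores the alternative reading).

The positive sample rate (PSR) of a junction in a group is
`n_positive / group_size` with the **full** group size as denominator,
not the per-junction callable samples.

### The cascade

Stages, in order, with their gates (all thresholds configurable):

1. `detected` — count >= 10 in at least one tumor sample. Normal-cohort
   tables never expand the universe; sub-threshold counts in other
   samples are retained because they feed depth and frequency.
2. `non_annotated` — exact-coordinate absence from the GTF-derived
   reference junction set (introns between consecutive exons of every
   transcript). Strand participates in matching only when defined on
   both sides.
3. `surfaceome_expressed` — assigned to a surfaceome gene (any-portion
   overlap of the intron with the gene footprint; the larger overlap
   wins among several, exact ties are reported as ambiguous) whose mean
   TPM across the tumor cohort is >= 10. The mean is used because the
   screen's own description uses an average; a median variant is
   available via `expression_statistic` since summaries of the same
   data are sometimes quoted as medians.
4. `tumor_specific` — pooled-normal PSR strictly below 1%. A stricter
   per-tissue variant (< 1% in every normal tissue type) is implemented
   and off by default.
5. `shared` — PSR >= 10% in at least one tumor disease group.
6. `extracellular` — at least one canonical template on which the
   predicted amino-acid change intersects an extracellular segment.
7. `protein_compatible` — single-pass host protein (multi-pass topology
   is excluded as unreliably predictable) and at least one canonical
   template with no PTC and the transmembrane segment retained
   verbatim.
8. `final` — removal of junctions on a machine-readable exclusion list,
   standing in for manual review so reruns stay deterministic.

Stages 6 and 7 are recorded separately in the ledger (matching the
published two-step accounting) but are also exposed as the combined
`filter_extracellular` gate.

### In-silico translation

For each candidate and canonical template, the altered transcript is the
template exon chain with the novel intron excised: exonic bases inside
the novel intron are removed, and template-intronic bases between an
annotated splice site and a shifted novel site are retained (this is why
a genome FASTA is required). The CDS restarts at the annotated start
codon; if the event removes it, the template is non-translatable and
fails. Translation uses the standard code via Biopython; every stop,
including premature ones, is marked `*`. A PTC is any in-frame stop
strictly upstream of the position aligned with the canonical stop; no
NMD 50-nt rule is applied. Amino-acid deltas come from the longest
common prefix/suffix against the wild-type protein, which also defines
the affected interval used for the extracellular test. "Transmembrane
intact" means the wild-type TM amino-acid sequence occurs verbatim in
the altered protein (before the first stop), which implies it is in
frame. As a self-check, every template's unaltered CDS is required to
translate to its reference protein exactly.

Topology segments are defined in protein coordinates of one named
reference isoform. On other templates they are transferred by locating
the TM sequence by exact subsequence match and shifting all segments by
the resulting offset; when the match fails the template is
non-assessable and fails with a logged reason. A gene passes when *any*
canonical template passes; all per-template reports are emitted.

Splice patterns are classified per template: both intron ends strictly
inside one exon → cryptic intron; both ends on annotated exon boundaries
skipping >= 1 whole exon → exon skip; annotated donor with shifted
acceptor → alternative 3' splice site (and symmetrically 5'); otherwise
complex. Donor/acceptor orientation follows the template strand, so the
same junction may classify differently on different templates; the
per-template label is reported.

### Sample gating

Bulk-cohort gating keeps tumor samples with purity >= 0.6 (inclusive).
Spatial (multi-region) gating keeps IDHwt/IDH-O pieces with
purity >= 0.5 and IDH-A pieces with IDH1-R132 VAF strictly > 0.25
(purity estimates are unreliable for these tumors, so the mutant allele
fraction stands in). Normal samples are always retained; tumor samples
with neither purity nor VAF are excluded with a warning.

### Heterogeneity summaries

Spatial: per (tumor, event), the fraction of purity-gated pieces that
are positive; `tumor_wide` iff the fraction is exactly 1. Longitudinal:
a timepoint is positive when >= 50% (inclusive) of its pieces are
positive — applied symmetrically to primary and recurrent, a single
published rule extended to both sides — and the (patient, event) status
is the truth table of the two calls: shared / primary_only /
recurrent_only / absent. Patients missing a timepoint and tumors with
no gated pieces are omitted with warnings.

## Synthetic cohorts

The generator emulates the statistics the screen consumes — junction
count tables, a TPM matrix, manifests — rather than reads; nothing in
the pipeline looks below the junction-count level, so read-level
simulation would add nothing testable.

**Reference.** 16 genes by default (5-7 exons of 120-240 nt on both
strands, introns 100-300 nt with GT..AG ends, valid start/stop codons,
one canonical transcript each). 14 genes carry surfaceome topology: 13
single-pass (extracellular up to ~55% of the protein, a 21-aa TM
segment, intracellular tail) and one four-pass. Exon and UTR lengths are
multiples of 3, so every exon boundary is codon-aligned; codon-aligned
deletions therefore never form novel codons at the junction, making
planted in-frame events PTC-free by construction. The frameshift decoy's
PTC is verified at design time by a plain codon walk over the spliced
string (independent of the pipeline's translation code), retrying
another locus if needed.

**Cohort design.** Defaults: three tumor groups of 20 (IDHwt, IDH-A,
IDH-O), 300 normals across ten tissue labels, five planted pass-filter
events cycling through the splice patterns, and one decoy per class,
each mapped to exactly one cascade stage so every filter has a dedicated
failure control:

| decoy class | designed failure stage |
| --- | --- |
| annotated | non_annotated |
| low_expression (host TPM ~2) | surfaceome_expressed |
| normal_shared (normal PSR 5%) | tumor_specific |
| low_frequency (frequency 0.5%), rare (PSR 3%) | shared |
| intracellular | extracellular |
| frameshift_ptc, multi_pass | protein_compatible |

Locus depth per sample is negative-binomial (mean 150, dispersion 10,
floored at 30 so annotated junctions stay detectable); an event that is
"on" receives `round(f*D/(1-f))` reads against its locus depth `D`,
floored at 24 for pass classes (comfortably above the 10-read and
20-depth bars at frequency 0.15) and capped at `0.008*D` for the
low-frequency decoy (above the 10-read detection floor, strictly below
the 1% frequency bar, on a 20x-depth locus so the cap stays above the
floor). Off tumor samples receive sub-threshold leak reads (1-3, with
probability 0.15) to exercise the retained-counts path. Event-positive
samples per group are `round(p*n)` samples drawn without replacement
rather than independent Bernoulli trials: the realized PSR then equals
the designed probability up to rounding, so recovery tests and the
designed failure stages are reproducible for any seed, while which
samples carry the event stays random. Host-gene TPM is lognormal around
50 (2 for the low-expression host).

What the generator does **not** emulate: alignment artifacts and
mapping ambiguity, splice-motif sequence context beyond GT..AG
decoration, fuzzy junction boundaries, correlated expression structure,
library-size variation between cohorts, intron-retention events, and
real annotation complexity (overlapping genes, many isoforms per gene).
Passing the planted-truth tests therefore demonstrates that the
filtering logic, arithmetic and bookkeeping are correct under the
designed margins — not that the thresholds are well-calibrated for real
cohorts, where the published screen's counts depend on controlled-access
data this package does not ship.

## Numerical and design notes

- All boundary comparisons follow the stated inequalities exactly:
  count/depth/frequency and the shared gate are inclusive (`>=`), the
  tumor-specific gate and the IDH-A VAF gate are strict (`<`, `>`).
- The Xena-style expression back-transform `2^x - 0.001` is clipped at 0
  to absorb negative round-off for genes encoded at the floor value.
- Reruns with identical inputs and configuration are bit-identical;
  every tie-break (dominance, gene assignment) is total-ordered.
- Problem sizes in the tests and the acceptance script (60 + 300
  samples, ~100-junction catalogs, 200x50 oracle grids over 20 seeds,
  1000 randomized translation events) keep the whole suite in the
  seconds range while every planted margin is at least 2x away from its
  threshold.
- The PSR-convergence check at group size 500 is exact by construction
  (deterministic positive counts); it guards the assignment logic, not
  sampling noise.

## Known limitations

- Exact-coordinate annotation matching only; no fuzzy (+/- k nt)
  junction clustering.
- The extracellular/TM verdicts rely on segment coordinates of one
  reference isoform per gene; transfer to other templates fails safe
  (non-assessable) when the TM subsequence is absent rather than
  attempting an alignment.
- No statistical testing of PSR differences between groups; the screen
  is thresholds-only by design.
- Intron retention, proteomics validation and long-read isoform
  analysis are out of scope; the pipeline consumes junction tables
  only.
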