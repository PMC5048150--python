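# Methods

## Scope and model

`ki-audit` audits F1 heterozygous knockin (KI) mice for unintended coding
mutations.  The underlying genetic model is simple: an F1 animal is the
cross of an edited founder (F0) with an inbred wild-type mate, so every
*bona fide* novel mutation in the F1 must be heterozygous, absent from the
same-colony control, and supported by a balanced read ratio at adequate
depth.  Variants violating any of these are artifacts or strain background.
Surviving InDels are then attributed to one of three origins — carried-over
colony variant, de novo mutation, or Cas9 off-target cleavage — using
colony-wide founder genotyping, pedigree, and guide-similarity scanning.

## The six-rule filter

The first selection keeps effect classes {missense, nonsense, insertion,
deletion, frameshift, splice_donor, splice_acceptor}.  The rules run in
canonical order R1…R6 for trace attribution; because R2–R6 are conjunctive,
the surviving set is identical under any evaluation order (property-tested).

Interpretation choices that were genuinely open:

* **R3 depth scope.** "Fewer than 10 reads in all samples" is read as
  *exclude only when no sample reaches 10 reads* — the reliability concern
  is about the variant, not individual samples.  The stricter reading
  (exclude if any sample is shallow) is available as
  `FilterConfig(min_depth_mode="any")`.
* **R1 counting unit.** Gene recurrence counts *distinct variant sites* per
  gene on the first-selection list, pooled over all samples including the
  control; the same site seen in several animals counts once.  R1 is always
  evaluated on the first-selection set, before R2–R6.
* **R4 sharedness.** The per-record rule ("a control carries the allele")
  is applied to KI-sample carriages.  A control carriage is excluded only
  when the variant is *shared* with a KI sample; a variant private to the
  control is the control's own novel mutation and is retained.  Without
  this reading the control column of the audit matrix would be empty.
* **R6 ratio.** The ratio is literally mutated/non-mutated reads
  (alt/ref), not VAF; alt/ref < 0.5 is equivalent to VAF < 1/3.  With zero
  reference reads the ratio is +∞ and the variant is kept; zero reads of
  either kind is a contract error, not a silent decision.
* **R5 scope.** Homozygosity excludes a carriage only for F1 samples; a
  variant shared by two F1 mice survives through the heterozygous carrier
  and the trace records the per-sample outcome.
* **Trace scope.** Traces cover exactly the first-selection output;
  synonymous/other records are dropped before rule tracing, so
  `failed_rule` never needs a "not selected" value.

## Off-target scanning

A hit is any 20-nt window immediately 5′ of a PAM-matching triplet (IUPAC
semantics, default NGG) within the mismatch budget.  The scanner is
numpy-vectorised and PAM-anchored; tests hold it equal to an exhaustive
pure-python scan on both strands (100 × 2 kb × mismatch 0–6).  Coordinates
are 1-based on the + strand regardless of hit strand.  The blunt cut falls
`cut_offset` (default 3) bp upstream of the PAM, between protospacer
positions 17 and 18; the reported cut coordinate is the base immediately 5′
of the cut on the protospacer strand.

Bulge-tolerant matching allows at most one single-base gap (19- or 21-nt
windows) and ranks alignments lexicographically by (bulges, mismatches): a
gap is rarer than a substitution among reported off-targets, so one bulge
is never preferred over any number of avoidable mismatches.  For
attribution, a hit qualifies when mismatches + bulges ≤ 4 (configurable);
the default scan window is ±50 bp around the variant.  Both defaults are
deliberately permissive relative to the audited case in which the nearest
guide-like site sat 14 mismatches away — far beyond plausible cleavage —
so that sequence similarity alone never over-claims an off-target verdict.

## Cause attribution

Decision order (configurable, recorded in the output):

1. **carried_over** — the identical allele is present in ≥ 1 founder
   outside the variant's own lineage.  Direct observation of a carrier
   outranks sequence similarity; two independent de novo events at one
   site are vastly less likely than colony segregation.
2. **off_target** — a qualifying hit in the scan window, or wet-lab
   cleavage evidence injected via `cleavage_positive=True`.  The package
   computes no gel results; the flag exists because the audited 3-bp
   insertion was attributable only through an extended in-vitro digestion.
3. **de_novo** — the default, but only when colony typing is complete
   enough to rule carriers out; with no typed non-parental founder the
   call is **undetermined** rather than a guess.

Mosaicism is flagged when the carrying F1's allele is absent from its
parent founder's somatic genotype; an untyped parent raises an error
distinct from "not mosaic".

## Synthetic cohort

The simulator generates the study conditions end to end: a miniature exome
(200 genes × 5 × 200 bp = 0.2 Mb; rates are per exome, not per bp), a
founder generation (81 mice; per-allele mutation probability 0.96, KI
probability 6/162, mosaic KI probability 2/6), and five sequenced exomes
(4 F1 KI + 1 control) containing strain-shared background (25 sites, 90%
catalogued), colony variants (40 sites at 5% allele frequency, transmitted
Mendelianly through the sequenced parent), de novo SNVs (Poisson, mean 3
per exome — the control included, matching the background seen in untreated
animals), de novo InDels (Poisson, mean 0.1), off-target InDels at planted
guide-like sites (defaults: 2- and 3-mismatch sites with PAM, plus a
14-mismatch site that correctly stays unattributable), and the intended KI
allele heterozygous in every F1.

Numerical choices:

* **Depth** is negative-binomial with mean 110 and s.d. 0.25 × mean
  (capture data are overdispersed); below the overdispersion threshold the
  generator falls back to Poisson.
* **Allele balance** at heterozygous sites is binomial with a
  Beta(50, 50) site-specific rate, giving the allele-ratio rule a
  realistic operating point rather than a degenerate always-pass.
* **Colony variants** are guaranteed ≥ 2 founder carriers including ≥ 1
  non-parental one (binomial draw, topped up when below): a transmitted
  variant with no unrelated carrier would be statistically
  indistinguishable from a de novo event, and colony segregation at 5%
  across 81 founders makes a singleton carrier unrealistic anyway.
* **Placement** of de novo and colony variants re-draws the position on
  the (rare) event that a qualifying guide-like site falls inside the scan
  window, keeping the planted cause classes disjoint by construction.
* All randomness flows from a single seed through named child streams;
  reruns are byte-identical.

Every planted variant carries a truth record: its class, its true cause,
and whether it *should* survive the filter — the latter computed directly
from the planted genotypes, depths and flags by restating each rule's
condition.  End-to-end tests then require the filter's retained set to
equal the truth set exactly and cause attribution to recover 100% of the
planted labels; this is an internal-consistency guarantee, not a claim
about real data.

What the simulator does **not** model: read-level errors, mapping and
capture bias, multi-nucleotide artifacts, germline/somatic mosaic
fractions, linkage between colony variants, or annotation errors.  Passing
tests therefore demonstrate that the pipeline implements its stated rules
faithfully and recovers planted structure; they do not validate variant
calling itself, which is upstream of this package.

## Packaged fixtures

The example cohort ships as a small VCF with synthetic coordinates and
invented gene symbols for the unnamed SNVs; the per-sample counts, the
three InDels' genes and lengths (+2 Zfp365, −17 Alox12, +3 Aspa), the
founder-allele tallies (156/162 mutated, 6 KI, 2 mosaic) and the colony
genotyping pattern (an unrelated carrier for the insertion; parental-only
carriage elsewhere) follow the audited cohort.  Files are labelled
`_synthetic` to mark reconstructed content.  Problem sizes throughout the
test suite (2 kb scan sequences, 0.2 Mb exomes, 50-cohort calibration
runs) are the package's own desk-scale choices.

## Known limitations

* The filter consumes upstream annotation (gene, effect, known flag) and
  genotype calls as given; it never re-derives zygosity from read counts.
* Off-target evidence is sequence-similarity only; no thermodynamic or
  learned cleavage scores.
* The merge of multi-sample and matched-pair callers that precedes the
  first selection is treated as upstream: the pipeline accepts one merged
  table.
* Percentages round half-up to whole percent for reporting; exact ratios
  are preserved in the returned objects.
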