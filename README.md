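# ki-audit

Auditing CRISPR/Cas-generated knockin (KI) mice for unintended mutations.

When a point-mutation KI mouse line is made with wild-type SpCas9, the
phenotype rests on the assumption that no *other* coding mutation rode along.
That assumption can fail three ways: Cas9 can cleave guide-like **off-target**
sites; **de novo** mutations arise spontaneously during founder production;
and rare **carried-over** variants segregating in the breeding colony can be
mistaken for induced damage.  `ki-audit` implements an exome-level audit of
F1 heterozygous KI mice against a same-colony wild-type control: a six-rule
variant filter isolates the unintended InDels/SNVs, a protospacer scanner
asks whether each InDel sits next to a guide-like site, and a cause-attribution
step combines colony-wide founder genotyping, pedigree and scan results into
a per-variant verdict — with mosaicism flagged when an allele present in an
F1 is absent from its parent founder's somatic (tail) DNA.

The package ships a synthetic-cohort simulator with a ground-truth channel so
the whole pipeline is testable without any sequencing data.

## The filter

Starting from multi-sample exome calls annotated with gene, effect class and
known-variant status, the *first selection* keeps non-synonymous and
splice-site calls.  Six rules then run in order; a variant is a candidate
only if it survives all of them:

| rule | excludes | rationale |
|------|----------|-----------|
| R1 | all variants in genes with ≥ 3 distinct sites | clustered calls are mapping artifacts |
| R2 | catalogued ("known") variants | focus on novel mutations |
| R3 | variants with < 10 reads in all samples | unreliable everywhere |
| R4 | variants shared between KI mouse and control | strain background |
| R5 | homozygous calls in an F1 | an F1 from an outcross must be heterozygous |
| R6 | alt/ref read ratio < 0.5 in the carrier | allele-balance artifact |

Each first-selection variant receives a trace naming the first failing rule.

## Worked example

The packaged example cohort (4 F1 KI mice for an Ntrk1 E495K design plus one
B6J control; synthetic coordinates) reproduces the audit's confirmed-variant
table:

```
$ python analysis/01_confirmed_variant_audit.py
Per-sample confirmed variants:
                268-1  283-1  306-1  316-2  B6J
Insertion           0      1      0      1    0
Deletion            0      1      0      0    0
Total InDels        0      2      0      1    0
Total SNVs          4      5      3      4    3
Total Variants      4      7      3      5    3

InDels per KI mouse:      0.75 (3 InDels / 4 mice)
LoF InDels per KI mouse:  0.50
SNVs per KI mouse:        4.00
SNVs in the control:      3
```

Read: each KI mouse carries ~4 novel SNVs — the same burden as the untreated
control, so SNVs look like background — but the 0.75 InDels per mouse (0.5 of
them frameshifting) far exceed the < 0.1 de novo InDels expected per exome,
so the InDels were acquired during KI production.  Attribution
(`analysis/05_end_to_end_audit.py`, `tests/test_cause_attribution.py`) then
resolves the three InDels: a 2-bp insertion also present in an unrelated
founder (carried over, with the parent founder mosaic), a 17-bp deletion
found nowhere else (de novo), and a 3-bp insertion whose site only wet-lab
cleavage evidence — representable as the `cleavage_positive` flag — ties to
Cas9 (off-target; its sequence sits 14 mismatches from the guide, beyond any
similarity threshold).

The numbered scripts under `analysis/` run the other stages: founder
efficiency (96% of 162 founder alleles mutated, 4% intended KI, 2/6 KI
alleles mosaic), donor TfiI-site and cleavage-fragment predictions, and the
synthetic end-to-end audit.  A `ki-audit` CLI
(`simulate` / `filter` / `offtarget` / `attribute` / `report`) exposes the
same pipeline on files.

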