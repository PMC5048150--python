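"""Reference data for the bundled Ntrk1 E495K knockin audit.

The audited cohort is four F1 mice heterozygous for an intended Ntrk1
point mutation (c.1483 G>A, p.E495K) plus one C57BL/6J control from the
same breeding colony.  The constants here are the study-level inputs the
rest of the package consumes: the 20-nt sgRNA guide, the 120-nt donor
oligodeoxynucleotide (which introduces a TfiI site for genotyping), the
PCR cleavage-template lengths used for in-vitro digestion predictions,
and the annotation-category bookkeeping of the first-selection variant
list.

Packaged fixtures (``data/``) reconstruct the cohort's confirmed-variant
table and the founder-allele outcomes at the published per-sample counts;
coordinates and unnamed animal identities in those files are synthetic.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .variant_model import Cohort, FounderAllele, GuideDesign, read_founder_table, read_variant_table

#: sgRNA guide sequence targeting mouse Ntrk1 (protospacer-matching 20-mer).
NTRK1_GUIDE_SEQ = "ACTGTGGGTTCTCCATGATG"

#: 120-nt single-stranded donor oligodeoxynucleotide carrying the E495K
#: codon change and a silent TfiI (GAWTC) site for genotyping.
NTRK1_DONOR_SEQ = (
    "GGGTGGCAGTTCTCTTTCCCCTACTGAGGGCAAAGGCTCCGGACTCCAGGGCCACATCATGAAGAATCC"
    "ACAGTACTTCAGTGATACCTGTGAGGAACTGTTATAGTAGGCGAGTGTGAG"
)

#: TfiI recognition site (IUPAC; W = A or T).
TFII_SITE = "GAWTC"

NTRK1_GUIDE = GuideDesign(
    guide_seq=NTRK1_GUIDE_SEQ,
    pam="NGG",
    cut_offset=3,
    donor_seq=NTRK1_DONOR_SEQ,
    target_gene="Ntrk1",
)

#: PCR cleavage-template lengths (bp) for the in-vitro digestion assay:
#: the on-target region, the three unintended InDel regions, and the
#: paralogous Ntrk2 negative control.
CLEAVAGE_TEMPLATE_LENGTHS = {
    "Ntrk1": 1949,
    "Zfp365": 1955,
    "Alox12": 1990,
    "Aspa": 1907,
    "Ntrk2": 1951,
}

#: Annotation categories of the first-selection list (non-synonymous and
#: splice-site calls retained from the raw multi-sample calling).
FIRST_SELECTION_CATEGORY_COUNTS = {
    "missense": 1102,
    "nonsense": 37,
    "insertion": 3,
    "deletion": 4,
    "frameshift": 24,
    "splice_donor": 51,
    "splice_acceptor": 30,
}

#: Reported size of the first-selection list.
FIRST_SELECTION_TOTAL = 1251


def first_selection_total(categories: dict[str, int] | None = None) -> int:
    """Sum the annotation-category counts of the first-selection list."""
    return sum((categories or FIRST_SELECTION_CATEGORY_COUNTS).values())


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ki_audit").joinpath("data", name)))


def load_confirmed_cohort() -> Cohort:
    """The cohort's confirmed-variant table (synthetic coordinates).

    22 variants — 3 InDels (a 2-bp Zfp365 insertion, a 17-bp Alox12
    deletion, a 3-bp Aspa insertion) and 19 SNVs — distributed over the
    five samples at the audited per-sample counts.
    """
    return read_variant_table(
        _data_path("confirmed_cohort_synthetic.vcf"),
        _data_path("confirmed_samples.tsv"),
    )


def load_founder_alleles() -> list[FounderAllele]:
    """Allele outcomes for the 81 genotyped founders (162 alleles).

    156 alleles mutated, of which 6 carry the intended knockin; 2 of the
    6 KI alleles are mosaic.  Identities beyond the named founders are
    synthetic.
    """
    return read_founder_table(_data_path("founder_alleles_synthetic.tsv"))


def load_f0_site_genotypes():
    """Colony-wide Sanger presence calls at the three InDel sites."""
    import pandas as pd

    return pd.read_csv(_data_path("f0_site_genotypes_synthetic.tsv"), sep="\t", dtype=str)
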