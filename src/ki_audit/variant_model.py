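"""Domain types and file I/O for the knockin-mouse exome audit.

The audit operates on a small cohort (a handful of F1 heterozygous knockin
mice plus one wild-type control) genotyped at exome scale.  This module
defines the in-memory model — guide design, samples, per-sample read
observations, cohort variant records, founder alleles — and the readers and
writers for the plain-text formats the pipeline exchanges:

* variant tables: a VCF v4.2 subset with ``INFO GENE=, EFFECT=`` and
  ``FORMAT GT:DP:AD`` (``AD`` = ref,alt); a variant is "known" (catalogued
  upstream, e.g. in dbSNP) iff its ID column is not ``.``;
* sample sheets, founder-allele tables and founder site-genotype tables as
  TSV;
* sequences as FASTA.

Coordinates are 1-based inclusive throughout, the VCF convention.  InDels
use anchor-base representation (first base of ref and alt identical when
the allele lengths differ).  Multi-allelic VCF lines are split into
biallelic records at read time, since every downstream rule is stated per
variant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Generation",
    "Genotype",
    "AlleleState",
    "Effect",
    "GuideDesign",
    "MouseSample",
    "SampleObservation",
    "VariantRecord",
    "FounderAllele",
    "Cohort",
    "VariantTableError",
    "read_variant_table",
    "write_variant_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_founder_table",
    "write_founder_table",
    "read_fasta",
    "write_fasta",
    "normalize_variant",
]

_DNA = set("ACGT")


def _check_dna(seq: str, what: str) -> None:
    if not seq or set(seq) - _DNA:
        raise ValueError(f"{what} must be non-empty A/C/G/T, got {seq!r}")


class Generation(str, enum.Enum):
    F0 = "F0"
    F1 = "F1"
    CONTROL = "control"


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class AlleleState(str, enum.Enum):
    WILD_TYPE = "wild_type"
    INDEL = "indel"
    KI = "ki"


#: Effect classes retained by the first selection (non-synonymous + splice site).
NONSYNONYMOUS_EFFECTS = frozenset(
    {
        "missense",
        "nonsense",
        "insertion",
        "deletion",
        "frameshift",
        "splice_donor",
        "splice_acceptor",
    }
)

#: All recognised effect classes.
Effect = frozenset(NONSYNONYMOUS_EFFECTS | {"synonymous", "other"})


@dataclass(frozen=True)
class GuideDesign:
    """An SpCas9 guide: 20-nt protospacer-complementary sequence plus PAM.

    ``cut_offset`` is the blunt-cut position in bp upstream of the PAM
    (SpCas9 cleaves ~3 bp upstream, between protospacer positions 17 and
    18).  ``donor_seq`` is the single-stranded repair template, when the
    design is a knockin.
    """

    guide_seq: str
    pam: str = "NGG"
    cut_offset: int = 3
    donor_seq: str | None = None
    target_gene: str = ""

    def __post_init__(self) -> None:
        if len(self.guide_seq) != 20:
            raise ValueError(f"guide must be 20 nt, got {len(self.guide_seq)}")
        _check_dna(self.guide_seq, "guide_seq")
        if self.donor_seq is not None:
            _check_dna(self.donor_seq, "donor_seq")
        if self.cut_offset < 1:
            raise ValueError("cut_offset must be >= 1")


@dataclass(frozen=True)
class MouseSample:
    sample_id: str
    generation: Generation
    parent_f0: str | None = None
    is_ki: bool = False

    def __post_init__(self) -> None:
        if self.generation is Generation.F1 and not self.parent_f0:
            raise ValueError(f"F1 sample {self.sample_id} must name a parent_f0")
        if self.generation is Generation.CONTROL and self.is_ki:
            raise ValueError(f"control sample {self.sample_id} cannot be KI")


@dataclass(frozen=True)
class SampleObservation:
    """Read support for one sample at one site."""

    depth: int
    alt_reads: int
    ref_reads: int
    genotype: Genotype

    def __post_init__(self) -> None:
        if min(self.depth, self.alt_reads, self.ref_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads + self.ref_reads > self.depth:
            raise ValueError(
                f"alt_reads + ref_reads ({self.alt_reads}+{self.ref_reads}) "
                f"exceeds depth {self.depth}"
            )

    @property
    def carries_alt(self) -> bool:
        return self.genotype in (Genotype.HET, Genotype.HOM_ALT)


@dataclass
class VariantRecord:
    """One biallelic site across the cohort."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    effect: str
    known: bool
    observations: dict[str, SampleObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        _check_dna(self.ref_allele, "ref_allele")
        _check_dna(self.alt_allele, "alt_allele")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.effect not in Effect:
            raise ValueError(f"unknown effect class {self.effect!r}")
        if self.is_indel and self.ref_allele[0] != self.alt_allele[0]:
            raise ValueError(
                f"InDel at {self.chrom}:{self.pos} not in anchor-base "
                f"representation ({self.ref_allele}>{self.alt_allele})"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def indel_length(self) -> int:
        """Signed inserted (+) / deleted (-) length; 0 for substitutions."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def variant_class(self) -> str:
        """'insertion', 'deletion' or 'snv' from the allele lengths."""
        if self.indel_length > 0:
            return "insertion"
        if self.indel_length < 0:
            return "deletion"
        return "snv"

    @property
    def is_frameshift(self) -> bool:
        """Loss-of-function proxy: length change not a multiple of 3."""
        return self.effect == "frameshift" or (
            self.is_indel and self.indel_length % 3 != 0
        )

    def carriers(self) -> list[str]:
        return [s for s, o in self.observations.items() if o.carries_alt]


@dataclass(frozen=True)
class FounderAllele:
    mouse_id: str
    allele_index: int
    state: AlleleState
    mosaic: bool = False

    def __post_init__(self) -> None:
        if self.allele_index not in (1, 2):
            raise ValueError("allele_index must be 1 or 2")
        if self.mosaic and self.state is AlleleState.WILD_TYPE:
            raise ValueError("mosaic flag is meaningless on a wild-type allele")


@dataclass
class Cohort:
    """A variant table joined to its sample sheet."""

    variants: list[VariantRecord]
    samples: dict[str, MouseSample]

    def sample_ids(self) -> list[str]:
        return list(self.samples)

    def control_ids(self) -> list[str]:
        return [
            s for s, m in self.samples.items() if m.generation is Generation.CONTROL
        ]

    def ki_ids(self) -> list[str]:
        return [s for s, m in self.samples.items() if m.is_ki]


class VariantTableError(ValueError):
    """Malformed variant table input; message carries the offending line."""


# ---------------------------------------------------------------------------
# VCF-dialect reading and writing (via pysam)
# ---------------------------------------------------------------------------

_GT_MAP = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def _genotype_for_alt(gt: tuple, alt_index: int) -> Genotype:
    if gt is None or len(gt) == 0 or all(a is None for a in gt):
        return Genotype.MISSING
    n = sum(1 for a in gt if a == alt_index)
    if n == 0:
        return Genotype.HOM_REF
    if n == 1:
        return Genotype.HET
    return Genotype.HOM_ALT


def read_sample_sheet(path: str | Path) -> dict[str, MouseSample]:
    """Read a TSV sample sheet (sample_id, generation, parent_f0, is_ki)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "generation", "parent_f0", "is_ki"}
    missing = required - set(df.columns)
    if missing:
        raise VariantTableError(f"sample sheet missing columns: {sorted(missing)}")
    samples: dict[str, MouseSample] = {}
    for row in df.itertuples(index=False):
        parent = None if pd.isna(row.parent_f0) or row.parent_f0 == "." else row.parent_f0
        samples[row.sample_id] = MouseSample(
            sample_id=row.sample_id,
            generation=Generation(row.generation),
            parent_f0=parent,
            is_ki=str(row.is_ki).lower() in ("true", "1", "yes"),
        )
    return samples


def write_sample_sheet(samples: Mapping[str, MouseSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "generation": m.generation.value,
            "parent_f0": m.parent_f0 or ".",
            "is_ki": str(m.is_ki).lower(),
        }
        for m in samples.values()
    ]
    pd.DataFrame(rows, columns=["sample_id", "generation", "parent_f0", "is_ki"]).to_csv(
        path, sep="\t", index=False
    )


def read_variant_table(path: str | Path, sample_sheet: str | Path | Mapping[str, MouseSample]) -> Cohort:
    """Parse the VCF-dialect variant table against its sample sheet.

    Every sample column in the file must appear in the sheet; sheet samples
    absent from the file get a missing observation (depth 0).  Multi-allelic
    lines are split into biallelic records.  Raises
    :class:`VariantTableError` with the 1-based file line for malformed
    records.
    """
    if isinstance(sample_sheet, (str, Path)):
        samples = read_sample_sheet(sample_sheet)
    else:
        samples = dict(sample_sheet)

    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VariantTableError(f"malformed variant table header: {exc}") from exc

    vcf_samples = list(vf.header.samples)
    unknown = [s for s in vcf_samples if s not in samples]
    if unknown:
        raise VariantTableError(
            f"sample(s) {unknown} in variant table but absent from the sample sheet"
        )
    try:  # count header lines as they appear in the file (plain-text dialect)
        with open(path) as fh:
            n_header = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                n_header += 1
    except UnicodeDecodeError:  # compressed input: fall back to parsed header
        n_header = str(vf.header).count("\n")

    variants: list[VariantRecord] = []
    for i, rec in enumerate(vf):
        line_no = n_header + i + 1
        gene = rec.info.get("GENE", "")
        effect = rec.info.get("EFFECT", "other")
        known = rec.id is not None and rec.id != "."
        if rec.alts is None:
            continue
        for alt_index, alt in enumerate(rec.alts, start=1):
            obs: dict[str, SampleObservation] = {}
            for sid in samples:
                if sid not in vcf_samples:
                    obs[sid] = SampleObservation(0, 0, 0, Genotype.MISSING)
                    continue
                call = rec.samples[sid]
                dp = call.get("DP")
                dp = 0 if dp is None else int(dp)
                ad = call.get("AD")
                if ad is None or all(a is None for a in ad):
                    ref_n = alt_n = 0
                else:
                    ref_n = int(ad[0] or 0)
                    alt_n = int(ad[alt_index] or 0)
                gt = _genotype_for_alt(call.get("GT"), alt_index)
                if dp == 0:
                    gt = Genotype.MISSING
                try:
                    obs[sid] = SampleObservation(dp, alt_n, ref_n, gt)
                except ValueError as exc:
                    raise VariantTableError(f"line {line_no}, sample {sid}: {exc}") from exc
            try:
                variants.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        gene=str(gene),
                        effect=str(effect),
                        known=known,
                        observations=obs,
                    )
                )
            except ValueError as exc:
                raise VariantTableError(f"line {line_no}: {exc}") from exc
    vf.close()
    return Cohort(variants=variants, samples=samples)


def _vcf_header(cohort: Cohort) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect class">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">')
    seen: list[str] = []
    for v in cohort.variants:
        if v.chrom not in seen:
            seen.append(v.chrom)
    for chrom in seen:
        header.add_line(f"##contig=<ID={chrom}>")
    for sid in cohort.samples:
        header.add_sample(sid)
    return header


def write_variant_table(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort back to the VCF dialect (inverse of the reader)."""
    header = _vcf_header(cohort)
    out = pysam.VariantFile(str(path), "w", header=header)
    for v in cohort.variants:
        rec = out.new_record(
            contig=v.chrom,
            start=v.pos - 1,
            alleles=(v.ref_allele, v.alt_allele),
        )
        rec.id = "rs0" if v.known else None
        rec.info["GENE"] = v.gene
        rec.info["EFFECT"] = v.effect
        for sid, o in v.observations.items():
            call = rec.samples[sid]
            call["GT"] = _GT_MAP[o.genotype]
            call["DP"] = o.depth
            call["AD"] = (o.ref_reads, o.alt_reads)
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# Founder tables and FASTA
# ---------------------------------------------------------------------------

def read_founder_table(path: str | Path) -> list[FounderAllele]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    alleles = [
        FounderAllele(
            mouse_id=row.mouse_id,
            allele_index=int(row.allele_index),
            state=AlleleState(row.state),
            mosaic=str(row.mosaic).lower() in ("true", "1", "yes"),
        )
        for row in df.itertuples(index=False)
    ]
    counts = pd.Series([a.mouse_id for a in alleles]).value_counts()
    bad = counts[counts != 2]
    if len(bad):
        raise ValueError(f"each founder must contribute exactly 2 alleles; bad: {list(bad.index)}")
    return alleles


def write_founder_table(alleles: Iterable[FounderAllele], path: str | Path) -> None:
    rows = [
        {
            "mouse_id": a.mouse_id,
            "allele_index": a.allele_index,
            "state": a.state.value,
            "mosaic": str(a.mosaic).lower(),
        }
        for a in alleles
    ]
    pd.DataFrame(rows, columns=["mouse_id", "allele_index", "state", "mosaic"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize_variant(record: VariantRecord, contig_seq: str | None = None) -> VariantRecord:
    """Left-align and trim an InDel to its canonical representation.

    Substitutions are returned unchanged.  When ``contig_seq`` (the full
    contig, 1-based addressing) is given, the InDel is shifted to the
    leftmost equivalent position; without it only redundant shared bases are
    trimmed.  Idempotent.
    """
    _check_dna(record.ref_allele, "ref_allele")
    _check_dna(record.alt_allele, "alt_allele")
    ref, alt, pos = record.ref_allele, record.alt_allele, record.pos
    if len(ref) == len(alt):
        return record

    # vt-style normalisation: shift left while trailing bases agree, then
    # trim shared leading bases.
    while ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            if contig_seq is None or pos == 1:
                break
            prev = contig_seq[pos - 2].upper()
            ref, alt, pos = prev + ref, prev + alt, pos - 1
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1

    if ref == record.ref_allele and alt == record.alt_allele and pos == record.pos:
        return record
    return VariantRecord(
        chrom=record.chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        gene=record.gene,
        effect=record.effect,
        known=record.known,
        observations=dict(record.observations),
    )
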