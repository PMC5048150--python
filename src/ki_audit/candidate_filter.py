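"""First selection and the six-rule candidate filter.

The audit narrows the raw multi-sample calls in two stages.  The *first
selection* keeps coding-consequential calls only: non-synonymous
(missense, nonsense, insertion, deletion, frameshift) and splice-site
(donor/acceptor) variants.  Six rules then remove calls that cannot be
bona-fide novel heterozygous mutations in an F1 animal:

R1  gene recurrence — all variants in a gene are dropped when >= 3
    distinct variant sites fall in that gene (clustered calls are mapping
    artifacts);
R2  known — catalogued variants are dropped to focus on novel mutations;
R3  minimum depth — variants with < 10 reads in all samples are dropped
    (unreliable everywhere);
R4  control-shared — variants shared between a KI sample and a control
    are strain background, not induced;
R5  zygosity — homozygous calls in an F1 are dropped (an F1 from a
    wild-type cross must be heterozygous for any novel allele);
R6  allele ratio — calls with mutated/non-mutated read ratio < 0.5 in
    the carrying sample are dropped.

Every first-selection variant receives a :class:`FilterTrace`; the first
failing rule in canonical order R1..R6 is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_model import (
    Cohort,
    Generation,
    Genotype,
    MouseSample,
    NONSYNONYMOUS_EFFECTS,
    SampleObservation,
    VariantRecord,
)

__all__ = [
    "FilterConfig",
    "FilterTrace",
    "FilterResult",
    "first_selection",
    "rule_gene_recurrence",
    "rule_known",
    "rule_min_depth",
    "rule_control_shared",
    "rule_zygosity",
    "rule_allele_ratio",
    "run_filter_pipeline",
    "SUMMARY_ROWS",
]

RULES = ("R1_gene_recurrence", "R2_known", "R3_min_depth",
         "R4_control_shared", "R5_homozygous", "R6_allele_ratio")

SUMMARY_ROWS = ("Insertion", "Deletion", "Total InDels", "Total SNVs", "Total Variants")


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds of the six rules.

    ``min_depth_mode``: 'all' drops a variant only when *no* sample
    reaches ``min_depth`` (the variant is unreliable everywhere); 'any'
    drops it when any sample is below threshold.
    """

    gene_recurrence_k: int = 3
    min_depth: int = 10
    min_depth_mode: str = "all"
    allele_ratio_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.gene_recurrence_k < 1:
            raise ValueError("gene_recurrence_k must be >= 1")
        if self.min_depth_mode not in ("all", "any"):
            raise ValueError("min_depth_mode must be 'all' or 'any'")


@dataclass
class FilterTrace:
    variant_id: str
    outcome: str  # retained | excluded
    failed_rule: str  # none | R1.. R6
    detail: str = ""

    def __post_init__(self) -> None:
        if (self.failed_rule == "none") != (self.outcome == "retained"):
            raise ValueError("failed_rule is 'none' iff the variant is retained")


@dataclass
class FilterResult:
    candidates: list[VariantRecord]
    traces: list[FilterTrace]
    per_sample_summary: pd.DataFrame
    #: surviving carriages: variant_id -> sample ids whose carriage passed R4-R6
    surviving_carriers: dict[str, list[str]] = field(default_factory=dict)


def first_selection(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep non-synonymous and splice-site variants, order preserved."""
    return [v for v in variants if v.effect in NONSYNONYMOUS_EFFECTS]


def rule_gene_recurrence(selection: Sequence[VariantRecord], k: int = 3) -> set[str]:
    """Variant ids excluded because their gene holds >= k distinct sites.

    Sites are counted cohort-wide on the first-selection list, all samples
    pooled; the same site seen in several samples counts once.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sites_per_gene: dict[str, set[tuple]] = {}
    for v in selection:
        sites_per_gene.setdefault(v.gene, set()).add((v.chrom, v.pos, v.ref_allele, v.alt_allele))
    recurrent = {g for g, sites in sites_per_gene.items() if len(sites) >= k}
    return {v.variant_id for v in selection if v.gene in recurrent}


def rule_known(record: VariantRecord) -> bool:
    """True = exclude: the variant is in a known-variant catalogue."""
    return record.known


def rule_min_depth(record: VariantRecord, min_depth: int = 10, mode: str = "all") -> bool:
    """True = exclude on insufficient read depth.

    mode 'all': exclude only when every sample is below ``min_depth``;
    mode 'any': exclude when any sample is below it.
    """
    depths = [o.depth for o in record.observations.values()]
    if not depths:
        return True
    if mode == "all":
        return max(depths) < min_depth
    if mode == "any":
        return min(depths) < min_depth
    raise ValueError(f"unknown min_depth mode {mode!r}")


def rule_control_shared(record: VariantRecord, control_ids: Sequence[str]) -> bool:
    """True = exclude: a control animal carries the variant.

    A control genotype that is missing (depth 0) does not count as
    carriage; such variants are conservatively retained.
    """
    if not control_ids:
        raise ValueError("control_ids must be non-empty")
    for cid in control_ids:
        if cid not in record.observations:
            raise KeyError(f"control sample {cid} absent from cohort observations")
        if record.observations[cid].carries_alt:
            return True
    return False


def rule_zygosity(
    record: VariantRecord,
    ki_sample_id: str,
    samples: Mapping[str, MouseSample] | None = None,
) -> bool:
    """True = exclude: the carrying F1 sample is homozygous for the alt.

    F1 animals from a wild-type outcross cannot be homozygous for a novel
    allele; a hom-alt call is an artifact or a strain variant.
    """
    if samples is not None:
        sample = samples.get(ki_sample_id)
        if sample is None or sample.generation is not Generation.F1:
            raise ValueError(f"sample {ki_sample_id} is not an F1 sample")
    obs = record.observations[ki_sample_id]
    return obs.genotype is Genotype.HOM_ALT


def rule_allele_ratio(obs: SampleObservation, threshold: float = 0.5) -> bool:
    """True = exclude: mutated/non-mutated read ratio below threshold.

    The ratio is alt_reads / ref_reads (not VAF).  With no reference
    reads the ratio is +inf and the variant is kept; with no reads at all
    there is no evidence to judge and a ValueError is raised.
    """
    if obs.alt_reads == 0 and obs.ref_reads == 0:
        raise ValueError("no supporting reads: allele ratio undefined")
    if obs.ref_reads == 0:
        return False
    return obs.alt_reads / obs.ref_reads < threshold


def _carriage_failure(
    record: VariantRecord,
    sid: str,
    sample: MouseSample,
    control_ids: Sequence[str],
    ki_ids: Sequence[str],
    config: FilterConfig,
) -> str | None:
    """First failing carriage rule (R4/R5/R6) for one carrying sample."""
    if sample.generation is Generation.CONTROL:
        # a control carriage is strain background when shared with a KI sample
        if any(record.observations[k].carries_alt for k in ki_ids):
            return "R4_control_shared"
    else:
        if rule_control_shared(record, control_ids):
            return "R4_control_shared"
        if sample.generation is Generation.F1 and rule_zygosity(record, sid):
            return "R5_homozygous"
    try:
        if rule_allele_ratio(record.observations[sid], config.allele_ratio_threshold):
            return "R6_allele_ratio"
    except ValueError:
        return "R6_allele_ratio"
    return None


def run_filter_pipeline(cohort: Cohort, config: FilterConfig | None = None) -> FilterResult:
    """Run the first selection and rules R1-R6 over the cohort.

    Rules R1-R3 act per variant; R4-R6 act per carrying sample, and a
    variant is retained when at least one carriage survives.  A variant
    private to the control (the control's own novel mutation) passes R4:
    only carriage shared between control and KI samples marks strain
    background.  The per-sample summary counts surviving carriages in
    the shape of the audit's confirmed-variant table.
    """
    config = config or FilterConfig()
    control_ids = cohort.control_ids()
    if not control_ids:
        raise ValueError("cohort must contain at least one control sample")
    ki_ids = cohort.ki_ids()

    selection = first_selection(cohort.variants)
    r1_excluded = rule_gene_recurrence(selection, config.gene_recurrence_k)

    candidates: list[VariantRecord] = []
    traces: list[FilterTrace] = []
    surviving: dict[str, list[str]] = {}

    for v in selection:
        vid = v.variant_id
        if vid in r1_excluded:
            traces.append(FilterTrace(vid, "excluded", "R1_gene_recurrence",
                                      f"gene {v.gene} has >= {config.gene_recurrence_k} distinct sites"))
            continue
        if rule_known(v):
            traces.append(FilterTrace(vid, "excluded", "R2_known", "catalogued variant"))
            continue
        if rule_min_depth(v, config.min_depth, config.min_depth_mode):
            traces.append(FilterTrace(vid, "excluded", "R3_min_depth",
                                      f"< {config.min_depth} reads ({config.min_depth_mode} samples)"))
            continue

        carriers = v.carriers()
        if not carriers:
            raise ValueError(f"variant {vid} is carried by no sample")
        failures: list[str] = []
        notes: list[str] = []
        survivors: list[str] = []
        for sid in carriers:
            fail = _carriage_failure(v, sid, cohort.samples[sid], control_ids, ki_ids, config)
            if fail is None:
                survivors.append(sid)
            else:
                failures.append(fail)
                notes.append(f"{sid}:{fail}")
        for cid in control_ids:
            if v.observations[cid].genotype is Genotype.MISSING:
                notes.append(f"{cid}:control_untyped_kept")
        if survivors:
            candidates.append(v)
            surviving[vid] = survivors
            traces.append(FilterTrace(vid, "retained", "none", "; ".join(notes)))
        else:
            first_fail = min(failures, key=RULES.index)
            traces.append(FilterTrace(vid, "excluded", first_fail, "; ".join(notes)))

    summary = _summarize(candidates, surviving, cohort.sample_ids())
    return FilterResult(candidates=candidates, traces=traces,
                        per_sample_summary=summary, surviving_carriers=surviving)


def _summarize(
    candidates: Sequence[VariantRecord],
    surviving: Mapping[str, Sequence[str]],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=list(SUMMARY_ROWS), columns=list(sample_ids))
    for v in candidates:
        row = {"insertion": "Insertion", "deletion": "Deletion", "snv": "Total SNVs"}[v.variant_class]
        for sid in surviving[v.variant_id]:
            counts.loc[row, sid] += 1
    counts.loc["Total InDels"] = counts.loc["Insertion"] + counts.loc["Deletion"]
    counts.loc["Total Variants"] = counts.loc["Total InDels"] + counts.loc["Total SNVs"]
    return counts


def traces_to_frame(traces: Sequence[FilterTrace]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"variant_id": t.variant_id, "outcome": t.outcome,
             "failed_rule": t.failed_rule, "detail": t.detail}
            for t in traces
        ],
        columns=["variant_id", "outcome", "failed_rule", "detail"],
    )
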