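"""Founder-efficiency and cohort variant-rate summaries.

Two summary families close the audit: founder statistics (what fraction
of injected-zygote alleles were mutated, how many carried the intended
knockin, how often KI alleles were mosaic) and per-cohort variant rates
(unintended InDels, loss-of-function InDels and SNVs per KI mouse, SNVs
in the control).  Percentages are rounded half-up to whole percent for
reporting; exact ratios are kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .candidate_filter import SUMMARY_ROWS
from .variant_model import AlleleState, FounderAllele, MouseSample, VariantRecord

__all__ = [
    "FounderSummary",
    "RateSummary",
    "founder_summary",
    "variant_count_table",
    "rate_summary",
    "lof_indel_counts",
    "cohort_rate_summary",
    "round_percent",
]


def round_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded half-up to the nearest integer."""
    if denominator == 0:
        return 0
    return int(100 * numerator / denominator + 0.5)


@dataclass(frozen=True)
class FounderSummary:
    n_mice: int
    n_alleles: int
    n_mutated_alleles: int
    pct_mutated: int
    n_ki_alleles: int
    pct_ki: int
    n_mosaic_ki: int

    def __post_init__(self) -> None:
        if self.n_alleles != 2 * self.n_mice:
            raise ValueError("each mouse contributes exactly 2 alleles")
        if not 0 <= self.n_ki_alleles <= self.n_mutated_alleles <= self.n_alleles:
            raise ValueError("0 <= KI <= mutated <= total alleles must hold")


@dataclass(frozen=True)
class RateSummary:
    indels_per_ki_mouse: float
    lof_indels_per_ki_mouse: float
    snvs_per_ki_mouse: float
    snvs_control: int
    n_ki_mice: int
    total_indels: int
    total_lof_indels: int
    total_snvs_ki: int


def founder_summary(alleles: Sequence[FounderAllele]) -> FounderSummary:
    """Count mutated / KI / mosaic-KI alleles over the founder cohort."""
    per_mouse: dict[str, int] = {}
    for a in alleles:
        per_mouse[a.mouse_id] = per_mouse.get(a.mouse_id, 0) + 1
    odd = [m for m, n in per_mouse.items() if n != 2]
    if odd:
        raise ValueError(f"founders with allele count != 2: {odd}")
    n_mice = len(per_mouse)
    n_alleles = len(alleles)
    n_mut = sum(a.state is not AlleleState.WILD_TYPE for a in alleles)
    n_ki = sum(a.state is AlleleState.KI for a in alleles)
    n_mosaic_ki = sum(a.state is AlleleState.KI and a.mosaic for a in alleles)
    return FounderSummary(
        n_mice=n_mice,
        n_alleles=n_alleles,
        n_mutated_alleles=n_mut,
        pct_mutated=round_percent(n_mut, n_alleles),
        n_ki_alleles=n_ki,
        pct_ki=round_percent(n_ki, n_alleles),
        n_mosaic_ki=n_mosaic_ki,
    )


def variant_count_table(
    variants: Iterable[VariantRecord],
    samples: Mapping[str, MouseSample],
    carriers: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-sample counts of insertions, deletions, InDels, SNVs, totals.

    ``carriers`` restricts counting to given sample ids per variant (e.g.
    the filter pipeline's surviving carriages); by default every carrying
    sample counts.  A variant carried by no sample is an error.
    """
    table = pd.DataFrame(0, index=list(SUMMARY_ROWS), columns=list(samples))
    for v in variants:
        who = list(carriers[v.variant_id]) if carriers is not None else v.carriers()
        if not who:
            raise ValueError(f"variant {v.variant_id} carried by no sample")
        row = {"insertion": "Insertion", "deletion": "Deletion", "snv": "Total SNVs"}[
            v.variant_class
        ]
        for sid in who:
            table.loc[row, sid] += 1
    table.loc["Total InDels"] = table.loc["Insertion"] + table.loc["Deletion"]
    table.loc["Total Variants"] = table.loc["Total InDels"] + table.loc["Total SNVs"]
    return table


def lof_indel_counts(
    variants: Iterable[VariantRecord],
    samples: Mapping[str, MouseSample],
    carriers: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, int]:
    """Per-sample counts of frameshifting (loss-of-function) InDels."""
    counts = {sid: 0 for sid in samples}
    for v in variants:
        if not (v.is_indel and v.is_frameshift):
            continue
        who = list(carriers[v.variant_id]) if carriers is not None else v.carriers()
        for sid in who:
            counts[sid] += 1
    return counts


def rate_summary(
    count_table: pd.DataFrame,
    lof_counts: Mapping[str, int],
    ki_sample_ids: Sequence[str],
    control_ids: Sequence[str],
) -> RateSummary:
    """Mean variant burdens over the KI mice plus the control SNV count."""
    if not ki_sample_ids:
        raise ValueError("ki_sample_ids must be non-empty")
    n_ki = len(ki_sample_ids)
    indels = int(count_table.loc["Total InDels", list(ki_sample_ids)].sum())
    snvs = int(count_table.loc["Total SNVs", list(ki_sample_ids)].sum())
    lof = int(sum(lof_counts.get(s, 0) for s in ki_sample_ids))
    ctrl_snvs = int(count_table.loc["Total SNVs", list(control_ids)].sum()) if control_ids else 0
    return RateSummary(
        indels_per_ki_mouse=indels / n_ki,
        lof_indels_per_ki_mouse=lof / n_ki,
        snvs_per_ki_mouse=snvs / n_ki,
        snvs_control=ctrl_snvs,
        n_ki_mice=n_ki,
        total_indels=indels,
        total_lof_indels=lof,
        total_snvs_ki=snvs,
    )


def cohort_rate_summary(
    variants: Sequence[VariantRecord],
    samples: Mapping[str, MouseSample],
    carriers: Mapping[str, Sequence[str]] | None = None,
) -> RateSummary:
    """Convenience wrapper: count table + LoF counts + rates in one call."""
    ki_ids = [s for s, m in samples.items() if m.is_ki]
    control_ids = [s for s, m in samples.items() if m.generation.value == "control"]
    table = variant_count_table(variants, samples, carriers)
    lof = lof_indel_counts(variants, samples, carriers)
    return rate_summary(table, lof, ki_ids, control_ids)
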