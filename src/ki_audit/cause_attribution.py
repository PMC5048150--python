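"""Cause attribution for confirmed unintended variants.

An unintended InDel in an F1 knockin mouse can have three origins:

* **carried over** — a rare variant segregating in the breeding colony,
  transmitted through the parents.  Evidence: the identical allele is
  found in at least one founder *outside* the variant's own lineage
  (colony-wide Sanger genotyping), as in the audited Zfp365 insertion
  independently found in an unrelated founder.
* **off-target** — Cas9 cleavage at a guide-like site.  Evidence: a
  protospacer near-match with PAM inside the scan window around the
  variant, or a positive in-vitro cleavage assay (the Aspa route, whose
  14-mismatch similarity is beyond any sequence threshold).
* **de novo** — a spontaneous mutation; the default when colony typing
  is complete and negative and no guide-like site is found (the Alox12
  deletion).

Carrier evidence outranks sequence similarity by default.  Mosaicism is
flagged when the F1 carries an allele absent from its parent founder's
somatic (tail) genotype — editing after the first zygotic division
leaves the germline and soma discordant.

Founder site genotypes are a tidy table with columns ``variant_id``,
``mouse_id``, ``presence`` (present | absent | untyped); a missing row
means untyped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .offtarget_scan import OffTargetHit, find_protospacers
from .variant_model import GuideDesign, MouseSample, VariantRecord

__all__ = [
    "AttributionConfig",
    "CauseCall",
    "ParentUntypedError",
    "genotype_presence",
    "detect_mosaic_origin",
    "classify_cause",
    "scan_variant_flanks",
    "attribute_candidates",
]

PRESENT, ABSENT, UNTYPED = "present", "absent", "untyped"


class ParentUntypedError(ValueError):
    """The parent founder's somatic genotype is untyped at this site."""


@dataclass(frozen=True)
class AttributionConfig:
    """Decision thresholds and precedence for cause classification.

    ``max_mismatch`` bounds the bulge-adjusted mismatch count
    (mismatches + bulges) for a protospacer hit to qualify as off-target
    evidence; ``window`` is the half-width in bp of the flank scanned
    around a variant; ``precedence`` orders the evidence classes.
    """

    max_mismatch: int = 4
    window: int = 50
    precedence: tuple[str, ...] = ("carried_over", "off_target")

    def __post_init__(self) -> None:
        if set(self.precedence) != {"carried_over", "off_target"}:
            raise ValueError("precedence must order carried_over and off_target")


@dataclass
class CauseCall:
    variant_id: str
    cause: str  # carried_over | de_novo | off_target | undetermined
    evidence: dict = field(default_factory=dict)
    mosaic_origin: bool = False

    def __post_init__(self) -> None:
        if self.cause == "carried_over" and not self.evidence.get("nonparental_carriers"):
            raise ValueError("carried_over requires at least one non-parental carrier")
        if self.cause == "off_target" and not (
            self.evidence.get("best_hit") or self.evidence.get("cleavage_positive")
        ):
            raise ValueError("off_target requires a qualifying hit or cleavage evidence")
        if self.cause != "undetermined" and not self.evidence:
            raise ValueError("evidence must not be empty for a determined cause")


def genotype_presence(
    variant_id: str, mouse_id: str, f0_table: pd.DataFrame
) -> str:
    """Presence of the identical allele in one founder's somatic genotype."""
    rows = f0_table[
        (f0_table["variant_id"] == variant_id) & (f0_table["mouse_id"] == mouse_id)
    ]
    if rows.empty:
        return UNTYPED
    value = rows["presence"].iloc[0]
    if value not in (PRESENT, ABSENT, UNTYPED):
        raise ValueError(f"bad presence value {value!r}")
    return value


def detect_mosaic_origin(
    variant: VariantRecord, f1_sample: MouseSample, f0_table: pd.DataFrame
) -> bool:
    """True when the F1 carries an allele absent from its parent's soma."""
    if f1_sample.parent_f0 is None:
        raise ParentUntypedError(f"sample {f1_sample.sample_id} has no parent founder")
    parent = genotype_presence(variant.variant_id, f1_sample.parent_f0, f0_table)
    if parent == UNTYPED:
        raise ParentUntypedError(
            f"parent {f1_sample.parent_f0} untyped at {variant.variant_id}"
        )
    obs = variant.observations.get(f1_sample.sample_id)
    f1_carries = obs is not None and obs.carries_alt
    return f1_carries and parent == ABSENT


def _qualifying_hit(
    hits: Sequence[OffTargetHit], config: AttributionConfig
) -> OffTargetHit | None:
    qualifying = [
        h for h in hits if h.bulges <= 1 and h.mismatches + h.bulges <= config.max_mismatch
    ]
    if not qualifying:
        return None
    return min(qualifying, key=lambda h: (h.mismatches + h.bulges, h.mismatches))


def classify_cause(
    variant: VariantRecord,
    samples: Mapping[str, MouseSample],
    f0_table: pd.DataFrame,
    offtarget_hits: Sequence[OffTargetHit],
    config: AttributionConfig | None = None,
    cleavage_positive: bool = False,
) -> CauseCall:
    """Attribute one confirmed variant to a cause.

    ``offtarget_hits`` must come from scanning the variant's flanking
    sequence (see :func:`scan_variant_flanks`).  ``cleavage_positive``
    injects wet-lab in-vitro digestion evidence, which qualifies the
    off-target route even without a below-threshold hit.
    """
    config = config or AttributionConfig()
    vid = variant.variant_id

    carrier_f1s = [
        samples[sid]
        for sid in variant.carriers()
        if sid in samples and samples[sid].parent_f0 is not None
    ]
    parental = {s.parent_f0 for s in carrier_f1s}

    site = f0_table[f0_table["variant_id"] == vid]
    typed = site[site["presence"] != UNTYPED]
    nonparental = typed[~typed["mouse_id"].isin(parental)]
    nonparental_carriers = sorted(
        nonparental.loc[nonparental["presence"] == PRESENT, "mouse_id"]
    )

    best_hit = _qualifying_hit(offtarget_hits, config)

    mosaic = False
    mosaic_note = None
    if carrier_f1s:
        try:
            mosaic = detect_mosaic_origin(variant, carrier_f1s[0], f0_table)
        except ParentUntypedError as exc:
            mosaic_note = str(exc)

    evidence: dict = {
        "nonparental_carriers": nonparental_carriers,
        "best_hit": best_hit,
        "parental_absent_in_soma": mosaic,
        "cleavage_positive": cleavage_positive,
    }
    if mosaic_note:
        evidence["mosaic_note"] = mosaic_note

    routes = {
        "carried_over": bool(nonparental_carriers),
        "off_target": best_hit is not None or cleavage_positive,
    }
    for route in config.precedence:
        if routes[route]:
            return CauseCall(vid, route, evidence, mosaic)

    # neither route fired: de novo only if colony typing actually rules
    # carriers out; with no typed non-parental founder, stay undetermined
    if nonparental.empty:
        return CauseCall(vid, "undetermined", evidence, mosaic)
    return CauseCall(vid, "de_novo", evidence, mosaic)


def scan_variant_flanks(
    variant: VariantRecord,
    reference: Mapping[str, str],
    guide: GuideDesign,
    config: AttributionConfig | None = None,
    allow_bulge: bool = True,
) -> list[OffTargetHit]:
    """Scan +/- window bp around a variant for guide-like sites.

    Hit coordinates are reported in contig coordinates (window offset
    added back).
    """
    config = config or AttributionConfig()
    contig = reference.get(variant.chrom)
    if contig is None:
        raise KeyError(f"contig {variant.chrom} absent from reference")
    lo = max(1, variant.pos - config.window)
    hi = min(len(contig), variant.pos + config.window)
    flank = contig[lo - 1:hi]
    if len(flank) < 23:
        return []
    hits = find_protospacers(
        flank, guide, max_mismatch=config.max_mismatch, allow_bulge=allow_bulge,
        seq_id=variant.chrom,
    )
    shifted = []
    for h in hits:
        shifted.append(
            OffTargetHit(
                seq_id=h.seq_id,
                protospacer_start=h.protospacer_start + lo - 1,
                strand=h.strand,
                protospacer_seq=h.protospacer_seq,
                pam_seq=h.pam_seq,
                mismatches=h.mismatches,
                bulges=h.bulges,
                predicted_cut=h.predicted_cut + lo - 1,
            )
        )
    return shifted


def attribute_candidates(
    candidates: Sequence[VariantRecord],
    samples: Mapping[str, MouseSample],
    f0_table: pd.DataFrame,
    reference: Mapping[str, str],
    guide: GuideDesign,
    config: AttributionConfig | None = None,
) -> list[CauseCall]:
    """Scan flanks and classify every candidate variant."""
    config = config or AttributionConfig()
    calls = []
    for v in candidates:
        hits = scan_variant_flanks(v, reference, guide, config)
        calls.append(classify_cause(v, samples, f0_table, hits, config))
    return calls


def causes_to_frame(calls: Sequence[CauseCall]) -> pd.DataFrame:
    import json

    rows = []
    for c in calls:
        ev = dict(c.evidence)
        hit = ev.get("best_hit")
        if hit is not None:
            ev["best_hit"] = {
                "seq_id": hit.seq_id, "start": hit.protospacer_start,
                "strand": hit.strand, "mismatches": hit.mismatches,
                "bulges": hit.bulges, "cut": hit.predicted_cut,
            }
        rows.append(
            {"variant_id": c.variant_id, "cause": c.cause,
             "mosaic_origin": c.mosaic_origin, "evidence_json": json.dumps(ev)}
        )
    return pd.DataFrame(rows, columns=["variant_id", "cause", "mosaic_origin", "evidence_json"])
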