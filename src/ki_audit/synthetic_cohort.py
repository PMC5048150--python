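"""Synthetic cohort generator with a ground-truth channel.

The audited study's raw reads are not public, so every pipeline stage is
exercised against a simulated cohort built to the study's statistical
structure: a miniature exome (~0.2 Mb; all rates are per exome, not per
bp, so headline expectations transfer), a founder generation with the
observed mutation/KI/mosaic rates, and F1 exomes carrying

* strain-shared (catalogued or control-shared) background variants,
* rare colony variants transmitted Mendelianly ("carried over"),
* de novo SNVs (Poisson, ~3 per exome) and de novo InDels (Poisson,
  <0.1 per exome, matching the whole-genome rate scaled to exome),
* off-target InDels planted at guide-like protospacer sites,
* the intended on-target knockin allele, heterozygous in every F1.

Depth is negative-binomial around 110x (s.d. ~ 0.25 x mean, the usual
overdispersion of capture data); heterozygous allele balance is
binomial with a Beta(50, 50) site-specific rate, so the allele-ratio
filter has a realistic operating point.

Every planted variant is recorded in a :class:`TruthRecord` stating its
class, whether it should survive the six-rule filter (computed from the
planted genotypes, depths and flags), and its true cause, enabling exact
end-to-end recovery tests.  All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .offtarget_scan import find_protospacers, hamming_mismatches
from .variant_model import (
    Cohort,
    FounderAllele,
    AlleleState,
    Generation,
    Genotype,
    GuideDesign,
    MouseSample,
    SampleObservation,
    VariantRecord,
    write_fasta,
    write_founder_table,
    write_sample_sheet,
    write_variant_table,
)
from .ntrk1_study import NTRK1_GUIDE

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "PlantedSite",
    "SimulatedData",
    "simulate_reference",
    "plant_offtarget_sites",
    "simulate_founders",
    "simulate_f1_variants",
    "simulate",
    "emit_truth_table",
    "read_truth_table",
    "load_config",
]

NONSYN = "missense"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the audited study: 81 genotyped founders, 4 F1 KI
    mice plus one control at 100-120x depth, 96% mutated founder
    alleles of which 6/162 carry the knockin, mosaicism on 2/6 KI
    alleles, ~3 de novo SNVs and <0.1 de novo InDels per exome, and a
    colony allele frequency of 5% for rare carried-over variants.
    """

    seed: int
    n_genes: int = 200
    exons_per_gene: int = 5
    exon_length: int = 200
    n_f0: int = 81
    n_f1_ki: int = 4
    founder_mutation_rate: float = 0.96
    founder_ki_rate: float = 6 / 162
    ki_mosaic_rate: float = 2 / 6
    mean_depth: float = 110.0
    de_novo_snv_mean: float = 3.0
    de_novo_indel_mean: float = 0.1
    colony_variant_freq: float = 0.05
    planted_offtargets: tuple[tuple[int, bool], ...] = ((2, True), (3, True), (14, True))
    known_variant_rate: float = 0.9
    n_strain_shared: int = 25
    n_colony_sites: int = 40
    depth_sd_frac: float = 0.25
    het_beta: float = 50.0
    attribution_max_mismatch: int = 4
    scan_window: int = 50

    def __post_init__(self) -> None:
        for name in ("founder_mutation_rate", "founder_ki_rate", "ki_mosaic_rate",
                     "colony_variant_freq", "known_variant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_genes", "exons_per_gene", "exon_length", "n_f0", "n_f1_ki"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.founder_ki_rate > self.founder_mutation_rate:
            raise ValueError("founder_ki_rate cannot exceed founder_mutation_rate")

    @property
    def gene_length(self) -> int:
        return self.exons_per_gene * self.exon_length


@dataclass(frozen=True)
class PlantedSite:
    """A protospacer-like site written into the reference."""

    seq_id: str
    start: int  # 1-based, + strand, protospacer window start
    mismatches: int
    with_pam: bool
    cut: int  # base immediately 5' of the predicted cut


@dataclass
class TruthRecord:
    variant_id: str
    planted_class: str  # strain_shared | carried_over | de_novo_snv |
    #                     de_novo_indel | off_target_indel | on_target_ki
    should_survive_filter: bool
    true_cause: str | None
    carriers: tuple[str, ...] = ()


@dataclass
class SimulatedData:
    config: SimulationConfig
    reference: dict[str, str]
    on_target: PlantedSite
    planted_sites: list[PlantedSite]
    founders: list[FounderAllele]
    cohort: Cohort
    truth: list[TruthRecord]
    f0_site_genotypes: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant_id": t.variant_id,
                    "planted_class": t.planted_class,
                    "should_survive_filter": str(t.should_survive_filter).lower(),
                    "true_cause": t.true_cause or "none",
                    "carriers": ",".join(t.carriers),
                }
                for t in self.truth
            ],
            columns=["variant_id", "planted_class", "should_survive_filter",
                     "true_cause", "carriers"],
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, out / "reference.fa")
        write_variant_table(self.cohort, out / "cohort.vcf")
        write_sample_sheet(self.cohort.samples, out / "samples.tsv")
        write_founder_table(self.founders, out / "f0_alleles.tsv")
        self.f0_site_genotypes.to_csv(out / "f0_site_genotypes.tsv", sep="\t", index=False)
        emit_truth_table(self.truth, out / "truth.tsv")


# ---------------------------------------------------------------------------
# Reference and planted sites
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_reference(
    config: SimulationConfig, guide: GuideDesign = NTRK1_GUIDE
) -> tuple[dict[str, str], PlantedSite]:
    """Random miniature exome with the on-target locus planted once.

    Returns the reference (one contig per gene) and the on-target site
    registry entry.  Deterministic given the config seed.
    """
    ss = np.random.SeedSequence([config.seed, 101])
    rng = np.random.default_rng(ss)
    glen = config.gene_length
    if glen < len(guide.guide_seq) + len(guide.pam) + 2 * config.scan_window:
        raise ValueError("gene too short to place the on-target locus")
    reference = {
        f"gene{i:03d}": _random_seq(rng, glen) for i in range(1, config.n_genes + 1)
    }
    target_gene = f"gene{(config.n_genes // 2):03d}"
    margin = config.scan_window + 25
    start0 = int(rng.integers(margin, glen - margin - 23))  # 0-based window start
    payload = guide.guide_seq + "AGG"
    while True:
        seq = reference[target_gene]
        reference[target_gene] = seq[:start0] + payload + seq[start0 + len(payload):]
        extra = [
            h
            for name, s in reference.items()
            for h in find_protospacers(s, guide, max_mismatch=0, seq_id=name)
        ]
        if len(extra) == 1:
            break
        # astronomically rare: a random exact match elsewhere; redraw that gene
        for h in extra:
            if not (h.seq_id == target_gene and h.protospacer_start == start0 + 1):
                reference[h.seq_id] = _random_seq(rng, glen)
    on_target = PlantedSite(
        seq_id=target_gene,
        start=start0 + 1,
        mismatches=0,
        with_pam=True,
        cut=start0 + 1 + len(guide.guide_seq) - guide.cut_offset - 1,
    )
    return reference, on_target


def plant_offtarget_sites(
    reference: Mapping[str, str],
    guide: GuideDesign,
    specs: Sequence[tuple[int, bool]],
    seed: int,
    avoid: Sequence[PlantedSite] = (),
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Write guide-like windows at exact Hamming distances into the reference.

    Each spec is ``(mismatches, with_pam)``.  Placement avoids the
    on-target locus and previously planted sites; every planted window
    is verified post hoc to sit at exactly the requested distance with
    the requested PAM status.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    reference = dict(reference)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for site in avoid:
        occupied.setdefault(site.seq_id, []).append((site.start - 60, site.start + 83))
    planted: list[PlantedSite] = []
    names = sorted(reference)
    n = len(guide.guide_seq)
    for mism, with_pam in specs:
        if not 0 <= mism <= n:
            raise ValueError(f"mismatch count {mism} out of range")
        for _attempt in range(200):
            gene = names[int(rng.integers(0, len(names)))]
            glen = len(reference[gene])
            start0 = int(rng.integers(60, glen - 60 - n - 3))
            span = (start0 - 60, start0 + n + 3 + 60)
            if any(a < span[1] and span[0] < b for a, b in occupied.get(gene, [])):
                continue
            window = list(guide.guide_seq)
            pos_choices = rng.choice(n, size=mism, replace=False)
            for p in pos_choices:
                others = [b for b in "ACGT" if b != window[p]]
                window[p] = others[int(rng.integers(0, 3))]
            pam = "AGG" if with_pam else "ATC"
            payload = "".join(window) + pam
            seq = reference[gene]
            reference[gene] = seq[:start0] + payload + seq[start0 + len(payload):]
            site_seq = reference[gene][start0:start0 + n]
            assert hamming_mismatches(guide.guide_seq, site_seq) == mism
            site = PlantedSite(
                seq_id=gene,
                start=start0 + 1,
                mismatches=mism,
                with_pam=with_pam,
                cut=start0 + 1 + n - guide.cut_offset - 1,
            )
            planted.append(site)
            occupied.setdefault(gene, []).append(span)
            break
        else:
            raise RuntimeError(f"could not place off-target spec ({mism}, {with_pam})")
    return reference, planted


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimulationConfig) -> list[FounderAllele]:
    """Draw 2 allele outcomes per founder at the configured rates."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    alleles: list[FounderAllele] = []
    for i in range(1, config.n_f0 + 1):
        mouse = f"F0-{i:03d}"
        for allele_index in (1, 2):
            u = rng.random()
            if u < config.founder_ki_rate:
                state = AlleleState.KI
                mosaic = bool(rng.random() < config.ki_mosaic_rate)
            elif u < config.founder_mutation_rate:
                state = AlleleState.INDEL
                mosaic = False
            else:
                state = AlleleState.WILD_TYPE
                mosaic = False
            alleles.append(FounderAllele(mouse, allele_index, state, mosaic))
    return alleles


# ---------------------------------------------------------------------------
# F1 cohort
# ---------------------------------------------------------------------------

class _SiteAllocator:
    """Draws variant positions; keeps them unique and, on request,
    guaranteed free of guide-like hits in the scan window."""

    def __init__(self, reference: Mapping[str, str], guide: GuideDesign,
                 config: SimulationConfig, rng: np.random.Generator):
        self.reference = reference
        self.guide = guide
        self.config = config
        self.rng = rng
        self.used: dict[str, set[int]] = {}
        self.genes = sorted(reference)

    def _flank_clean(self, gene: str, pos: int) -> bool:
        seq = self.reference[gene]
        w = self.config.scan_window
        lo = max(1, pos - w)
        hi = min(len(seq), pos + w)
        flank = seq[lo - 1:hi]
        if len(flank) < 23:
            return True
        hits = find_protospacers(
            flank, self.guide, max_mismatch=self.config.attribution_max_mismatch,
            allow_bulge=True,
        )
        return not any(
            h.mismatches + h.bulges <= self.config.attribution_max_mismatch for h in hits
        )

    def draw(self, min_margin: int = 25, require_clean: bool = False,
             gene: str | None = None, pos: int | None = None) -> tuple[str, int]:
        if gene is not None and pos is not None:
            self.used.setdefault(gene, set()).add(pos)
            return gene, pos
        for _ in range(500):
            g = self.genes[int(self.rng.integers(0, len(self.genes)))]
            glen = len(self.reference[g])
            p = int(self.rng.integers(min_margin, glen - min_margin))
            if p in self.used.get(g, set()):
                continue
            if require_clean and not self._flank_clean(g, p):
                continue
            self.used.setdefault(g, set()).add(p)
            return g, p
        raise RuntimeError("could not allocate a variant site")


def _nb_depth(rng: np.random.Generator, config: SimulationConfig) -> int:
    mu = config.mean_depth
    var = (config.depth_sd_frac * mu) ** 2
    if var <= mu:
        return max(1, int(rng.poisson(mu)))
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return max(1, int(rng.negative_binomial(r, p)))


def _het_obs(rng: np.random.Generator, config: SimulationConfig) -> SampleObservation:
    depth = _nb_depth(rng, config)
    p = rng.beta(config.het_beta, config.het_beta)
    alt = int(rng.binomial(depth, p))
    if depth >= 2:
        alt = min(max(alt, 1), depth - 1)
    return SampleObservation(depth, alt, depth - alt, Genotype.HET)


def _hom_alt_obs(rng: np.random.Generator, config: SimulationConfig) -> SampleObservation:
    depth = _nb_depth(rng, config)
    return SampleObservation(depth, depth, 0, Genotype.HOM_ALT)


def _hom_ref_obs(rng: np.random.Generator, config: SimulationConfig) -> SampleObservation:
    depth = _nb_depth(rng, config)
    return SampleObservation(depth, 0, depth, Genotype.HOM_REF)


def _make_variant(
    reference: Mapping[str, str], gene: str, pos: int, kind: str,
    rng: np.random.Generator, effect: str | None = None, indel_len: int | None = None,
) -> VariantRecord:
    """Build a record consistent with the reference sequence.

    kind: 'snv', 'insertion' or 'deletion'; InDel alleles are anchored at
    ``pos``.
    """
    seq = reference[gene]
    anchor = seq[pos - 1]
    if kind == "snv":
        alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
        ref_allele, alt_allele = anchor, alt
        effect = effect or NONSYN
    elif kind == "insertion":
        k = indel_len or int(rng.integers(1, 4))
        ins = "".join(_BASES[rng.integers(0, 4, size=k)])
        ref_allele, alt_allele = anchor, anchor + ins
        effect = effect or "insertion"
    elif kind == "deletion":
        k = indel_len or int(rng.integers(1, 6))
        k = min(k, len(seq) - pos)
        ref_allele, alt_allele = seq[pos - 1:pos + k], anchor
        effect = effect or "deletion"
    else:
        raise ValueError(kind)
    return VariantRecord(
        chrom=gene, pos=pos, ref_allele=ref_allele, alt_allele=alt_allele,
        gene=gene, effect=effect, known=False, observations={},
    )


def _expected_survival(
    v: VariantRecord, samples: Mapping[str, MouseSample], gene_site_counts: Mapping[str, int]
) -> bool:
    """Ground-truth filter outcome from the planted record itself.

    Mirrors the six rules' stated conditions on the drawn genotypes and
    read counts (first selection; gene recurrence >= 3 sites; known;
    max depth < 10 everywhere; control/KI sharing; F1 homozygosity;
    alt/ref ratio < 0.5).
    """
    from .variant_model import NONSYNONYMOUS_EFFECTS

    if v.effect not in NONSYNONYMOUS_EFFECTS:
        return False
    if gene_site_counts.get(v.gene, 0) >= 3:
        return False
    if v.known:
        return False
    if max((o.depth for o in v.observations.values()), default=0) < 10:
        return False
    control_ids = [s for s, m in samples.items() if m.generation is Generation.CONTROL]
    ki_ids = [s for s, m in samples.items() if m.is_ki]
    control_carries = any(v.observations[c].carries_alt for c in control_ids)
    ki_carries = any(v.observations[k].carries_alt for k in ki_ids)
    for sid in v.carriers():
        m = samples[sid]
        if m.generation is Generation.CONTROL:
            if ki_carries:
                continue
        else:
            if control_carries:
                continue
            if m.generation is Generation.F1 and v.observations[sid].genotype is Genotype.HOM_ALT:
                continue
        o = v.observations[sid]
        if o.alt_reads == 0 and o.ref_reads == 0:
            continue
        if o.ref_reads > 0 and o.alt_reads / o.ref_reads < 0.5:
            continue
        return True
    return False


def simulate_f1_variants(
    config: SimulationConfig,
    reference: Mapping[str, str],
    founders: Sequence[FounderAllele],
    guide: GuideDesign = NTRK1_GUIDE,
    planted_sites: Sequence[PlantedSite] = (),
    on_target: PlantedSite | None = None,
) -> tuple[Cohort, list[TruthRecord], pd.DataFrame]:
    """Generate the F1 + control variant table, truth table and colony genotypes."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))

    # --- samples: the F1 mice come from founders carrying a KI allele ---
    by_mouse: dict[str, list[FounderAllele]] = {}
    for a in founders:
        by_mouse.setdefault(a.mouse_id, []).append(a)
    ki_parents = sorted(m for m, al in by_mouse.items() if any(x.state is AlleleState.KI for x in al))
    if len(ki_parents) < config.n_f1_ki:  # fall back to mutated founders
        extra = sorted(
            m for m, al in by_mouse.items()
            if m not in ki_parents and any(x.state is not AlleleState.WILD_TYPE for x in al)
        )
        ki_parents = ki_parents + extra
    parents = ki_parents[: config.n_f1_ki]
    if len(parents) < config.n_f1_ki:
        raise RuntimeError("not enough mutated founders to breed the F1 cohort")

    samples: dict[str, MouseSample] = {}
    for p in parents:
        sid = f"{p}-1"
        samples[sid] = MouseSample(sid, Generation.F1, parent_f0=p, is_ki=True)
    control_id = "B6J-ctrl"
    samples[control_id] = MouseSample(control_id, Generation.CONTROL, None, False)
    f1_ids = [s for s in samples if s != control_id]
    f0_ids = sorted(by_mouse)

    alloc = _SiteAllocator(reference, guide, config, rng)
    variants: list[VariantRecord] = []
    meta: list[dict] = []  # parallel: planted_class, true_cause, parent_presence rows

    def _obs_for(carrier_ids: Sequence[str], zygosity: Genotype) -> dict[str, SampleObservation]:
        obs = {}
        for sid in samples:
            if sid in carrier_ids:
                obs[sid] = _hom_alt_obs(rng, config) if zygosity is Genotype.HOM_ALT else _het_obs(rng, config)
            else:
                obs[sid] = _hom_ref_obs(rng, config)
        return obs

    # --- strain-shared background (known catalogue / B6J sub-strain) ---
    for _ in range(config.n_strain_shared):
        gene, pos = alloc.draw()
        kind = "snv" if rng.random() < 0.85 else ("insertion" if rng.random() < 0.5 else "deletion")
        effect = "synonymous" if (kind == "snv" and rng.random() < 0.2) else None
        v = _make_variant(reference, gene, pos, kind, rng, effect=effect)
        v.known = bool(rng.random() < config.known_variant_rate)
        zyg = Genotype.HOM_ALT if rng.random() < 0.5 else Genotype.HET
        v.observations = _obs_for(list(samples), zyg)
        variants.append(v)
        meta.append({"class": "strain_shared", "cause": None, "f0": None})

    # --- colony (carried-over) variants ---
    parent_set = set(parents)
    per_mouse_rate = 1 - (1 - config.colony_variant_freq) ** 2
    for _ in range(config.n_colony_sites):
        gene, pos = alloc.draw(require_clean=True)
        carriers_f0 = [m for m in f0_ids if rng.random() < per_mouse_rate]
        nonparental = [m for m in carriers_f0 if m not in parent_set]
        while len(carriers_f0) < 2 or not nonparental:
            candidates = [m for m in f0_ids if m not in carriers_f0 and m not in parent_set]
            pick = candidates[int(rng.integers(0, len(candidates)))]
            carriers_f0.append(pick)
            nonparental.append(pick)
        control_carries = rng.random() < per_mouse_rate
        transmitted = [
            sid for sid in f1_ids
            if samples[sid].parent_f0 in carriers_f0 and rng.random() < 0.5
        ]
        sample_carriers = transmitted + ([control_id] if control_carries else [])
        if not sample_carriers:
            continue  # not observed in any sequenced animal; never called
        kind = "snv" if rng.random() < 0.7 else ("insertion" if rng.random() < 0.5 else "deletion")
        v = _make_variant(reference, gene, pos, kind, rng, indel_len=2 if kind != "snv" else None)
        v.observations = _obs_for(sample_carriers, Genotype.HET)
        # somatic mosaicism: a transmitting parent may lack the allele in soma
        somatic_absent: set[str] = set()
        for sid in transmitted:
            p = samples[sid].parent_f0
            if rng.random() < config.ki_mosaic_rate:
                somatic_absent.add(p)
        variants.append(v)
        meta.append({
            "class": "carried_over", "cause": "carried_over",
            "f0": {m: ("absent" if m in somatic_absent else "present") if m in carriers_f0
                   else "absent" for m in f0_ids},
        })

    # --- de novo SNVs and InDels (every sequenced exome, control included) ---
    for sid in list(f1_ids) + [control_id]:
        parent = samples[sid].parent_f0
        for _ in range(int(rng.poisson(config.de_novo_snv_mean))):
            gene, pos = alloc.draw(require_clean=True)
            v = _make_variant(reference, gene, pos, "snv", rng)
            v.observations = _obs_for([sid], Genotype.HET)
            variants.append(v)
            meta.append({
                "class": "de_novo_snv", "cause": "de_novo",
                "f0": _f0_presence(f0_ids, parent, rng, config),
            })
        for _ in range(int(rng.poisson(config.de_novo_indel_mean))):
            gene, pos = alloc.draw(require_clean=True)
            kind = "insertion" if rng.random() < 0.5 else "deletion"
            v = _make_variant(reference, gene, pos, kind, rng)
            v.observations = _obs_for([sid], Genotype.HET)
            variants.append(v)
            meta.append({
                "class": "de_novo_indel", "cause": "de_novo",
                "f0": _f0_presence(f0_ids, parent, rng, config),
            })

    # --- off-target InDels at attributable planted sites ---
    attributable = [
        s for s in planted_sites
        if s.with_pam and s.mismatches <= config.attribution_max_mismatch
    ]
    for i, site in enumerate(attributable):
        sid = f1_ids[i % len(f1_ids)]
        parent = samples[sid].parent_f0
        pos = site.cut
        alloc.draw(gene=site.seq_id, pos=pos)
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        v = _make_variant(reference, site.seq_id, pos, kind, rng)
        v.observations = _obs_for([sid], Genotype.HET)
        variants.append(v)
        meta.append({
            "class": "off_target_indel", "cause": "off_target",
            "f0": _f0_presence(f0_ids, parent, rng, config),
        })

    # --- the intended on-target knockin, heterozygous in every F1 ---
    if on_target is not None:
        pos = on_target.cut
        alloc.draw(gene=on_target.seq_id, pos=pos)
        v = _make_variant(reference, on_target.seq_id, pos, "snv", rng)
        v.observations = _obs_for(f1_ids, Genotype.HET)
        variants.append(v)
        ki_founders = {
            m for m, al in by_mouse.items() if any(x.state is AlleleState.KI for x in al)
        }
        meta.append({
            "class": "on_target_ki", "cause": None,
            "f0": {m: "present" if m in ki_founders else "absent" for m in f0_ids},
        })

    # --- truth: expected filter outcome from the planted data ---
    from .variant_model import NONSYNONYMOUS_EFFECTS

    gene_sites: dict[str, set] = {}
    for v in variants:
        if v.effect in NONSYNONYMOUS_EFFECTS:
            gene_sites.setdefault(v.gene, set()).add((v.chrom, v.pos, v.ref_allele, v.alt_allele))
    gene_counts = {g: len(s) for g, s in gene_sites.items()}

    truth: list[TruthRecord] = []
    genotype_rows: list[dict] = []
    for v, m in zip(variants, meta):
        truth.append(
            TruthRecord(
                variant_id=v.variant_id,
                planted_class=m["class"],
                should_survive_filter=_expected_survival(v, samples, gene_counts),
                true_cause=m["cause"],
                carriers=tuple(v.carriers()),
            )
        )
        if m["f0"] is not None:
            for mouse, presence in m["f0"].items():
                genotype_rows.append(
                    {"variant_id": v.variant_id, "mouse_id": mouse, "presence": presence}
                )
    f0_table = pd.DataFrame(genotype_rows, columns=["variant_id", "mouse_id", "presence"])
    return Cohort(variants=variants, samples=samples), truth, f0_table


def _f0_presence(
    f0_ids: Sequence[str], parent: str | None, rng: np.random.Generator,
    config: SimulationConfig,
) -> dict[str, str]:
    """Somatic presence map for a variant that arose during F0 production."""
    mosaic = rng.random() < config.ki_mosaic_rate
    out = {m: "absent" for m in f0_ids}
    if parent is not None and not mosaic:
        out[parent] = "present"
    return out


def simulate(config: SimulationConfig, guide: GuideDesign = NTRK1_GUIDE) -> SimulatedData:
    """End-to-end generation: reference, planted sites, founders, cohort."""
    reference, on_target = simulate_reference(config, guide)
    reference, planted = plant_offtarget_sites(
        reference, guide, config.planted_offtargets, config.seed, avoid=[on_target]
    )
    founders = simulate_founders(config)
    cohort, truth, f0_table = simulate_f1_variants(
        config, reference, founders, guide, planted, on_target
    )
    return SimulatedData(
        config=config, reference=reference, on_target=on_target,
        planted_sites=planted, founders=founders, cohort=cohort,
        truth=truth, f0_site_genotypes=f0_table,
    )


# ---------------------------------------------------------------------------
# Truth table I/O and config files
# ---------------------------------------------------------------------------

def emit_truth_table(truth: Sequence[TruthRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "variant_id": t.variant_id,
                "planted_class": t.planted_class,
                "should_survive_filter": str(t.should_survive_filter).lower(),
                "true_cause": t.true_cause or "none",
                "carriers": ",".join(t.carriers),
            }
            for t in truth
        ],
        columns=["variant_id", "planted_class", "should_survive_filter", "true_cause", "carriers"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        TruthRecord(
            variant_id=row.variant_id,
            planted_class=row.planted_class,
            should_survive_filter=row.should_survive_filter == "true",
            true_cause=None if row.true_cause == "none" else row.true_cause,
            carriers=tuple(c for c in row.carriers.split(",") if c),
        )
        for row in df.itertuples(index=False)
    ]


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML file mirroring the SimulationConfig field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "planted_offtargets" in raw:
        raw["planted_offtargets"] = tuple(
            (int(m), bool(p)) for m, p in raw["planted_offtargets"]
        )
    return SimulationConfig(**raw)
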