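import pytest

from ki_audit.ntrk1_study import (
    load_confirmed_cohort,
    load_f0_site_genotypes,
    load_founder_alleles,
)
from ki_audit.synthetic_cohort import SimulationConfig, simulate
from ki_audit.variant_model import (
    Cohort,
    Generation,
    Genotype,
    MouseSample,
    SampleObservation,
    VariantRecord,
)


@pytest.fixture(scope="session")
def confirmed_cohort():
    """Packaged reconstruction of the audited confirmed-variant table."""
    return load_confirmed_cohort()


@pytest.fixture(scope="session")
def founder_alleles():
    return load_founder_alleles()


@pytest.fixture(scope="session")
def f0_site_genotypes():
    return load_f0_site_genotypes()


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic cohort, shared across tests (read-only)."""
    return simulate(SimulationConfig(seed=11))


def het(depth=100, alt=None):
    alt = depth // 2 if alt is None else alt
    return SampleObservation(depth, alt, depth - alt, Genotype.HET)


def hom_ref(depth=100):
    return SampleObservation(depth, 0, depth, Genotype.HOM_REF)


def hom_alt(depth=100):
    return SampleObservation(depth, depth, 0, Genotype.HOM_ALT)


def missing():
    return SampleObservation(0, 0, 0, Genotype.MISSING)


def make_variant(chrom="chr1", pos=100, ref="A", alt="T", gene="Gene1",
                 effect="missense", known=False, observations=None):
    return VariantRecord(chrom, pos, ref, alt, gene, effect, known, observations or {})


def two_sample_cohort(variants):
    """Minimal cohort: one F1 KI mouse + one control."""
    samples = {
        "ki-1": MouseSample("ki-1", Generation.F1, parent_f0="f0-1", is_ki=True),
        "ctrl": MouseSample("ctrl", Generation.CONTROL),
    }
    return Cohort(variants, samples)
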