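"""First selection and the six filtering rules."""

import pytest

from ki_audit.candidate_filter import (
    FilterTrace,
    first_selection,
    rule_allele_ratio,
    rule_control_shared,
    rule_gene_recurrence,
    rule_known,
    rule_min_depth,
    rule_zygosity,
    run_filter_pipeline,
)
from ki_audit.variant_model import Genotype, SampleObservation

from conftest import het, hom_alt, hom_ref, make_variant, missing, two_sample_cohort


class TestFirstSelection:
    @pytest.mark.parametrize(
        "effect,kept",
        [
            ("missense", True),
            ("nonsense", True),
            ("insertion", True),
            ("deletion", True),
            ("frameshift", True),
            ("splice_donor", True),
            ("splice_acceptor", True),
            ("synonymous", False),
            ("other", False),
        ],
    )
    def test_effect_classes(self, effect, kept):
        alt = "AT" if effect in ("insertion", "frameshift") else "T"
        v = make_variant(ref="A", alt=alt, effect=effect)
        assert (v in first_selection([v])) is kept

    def test_empty_input(self):
        assert first_selection([]) == []


class TestGeneRecurrence:
    def test_three_distinct_sites_excludes_whole_gene(self):
        vs = [make_variant(pos=p, gene="GeneX") for p in (10, 20, 30)]
        excluded = rule_gene_recurrence(vs, k=3)
        assert excluded == {v.variant_id for v in vs}

    def test_two_sites_not_excluded(self):
        vs = [make_variant(pos=p, gene="GeneX") for p in (10, 20)]
        assert rule_gene_recurrence(vs, k=3) == set()

    def test_same_site_in_three_samples_counts_once(self):
        # one distinct site carried by 3 samples: still a single site
        obs = {f"s{i}": het() for i in range(3)}
        v = make_variant(pos=10, gene="GeneX", observations=obs)
        sites = {(v.chrom, v.pos, v.ref_allele, v.alt_allele)}
        assert len(sites) == 1  # brute distinct-site count over the fixture
        assert rule_gene_recurrence([v], k=3) == set()

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            rule_gene_recurrence([], k=0)


class TestSimpleRules:
    def test_known_flag_is_the_decision(self):
        assert rule_known(make_variant(known=True))
        assert not rule_known(make_variant(known=False))

    def test_min_depth_all_mode(self):
        v = make_variant(observations={"a": het(8), "b": het(9), "c": het(7)})
        assert rule_min_depth(v, 10, "all")
        v2 = make_variant(observations={"a": het(8), "b": het(50), "c": het(7)})
        assert not rule_min_depth(v2, 10, "all")
        v3 = make_variant(observations={"a": het(10), "b": het(50), "c": het(12)})
        assert not rule_min_depth(v3, 10, "all")

    def test_min_depth_any_mode(self):
        v = make_variant(observations={"a": het(8), "b": het(50)})
        assert rule_min_depth(v, 10, "any")

    def test_control_shared(self):
        v = make_variant(observations={"ki-1": het(), "ctrl": het()})
        assert rule_control_shared(v, ["ctrl"])
        v2 = make_variant(observations={"ki-1": het(), "ctrl": hom_ref()})
        assert not rule_control_shared(v2, ["ctrl"])
        v3 = make_variant(observations={"ki-1": het(), "ctrl": missing()})
        assert not rule_control_shared(v3, ["ctrl"])  # conservative retention
        with pytest.raises(KeyError):
            rule_control_shared(v2, ["nope"])

    def test_zygosity(self):
        v = make_variant(observations={"ki-1": hom_alt()})
        assert rule_zygosity(v, "ki-1")
        v2 = make_variant(observations={"ki-1": het()})
        assert not rule_zygosity(v2, "ki-1")
        cohort = two_sample_cohort([])
        with pytest.raises(ValueError):
            rule_zygosity(v, "ctrl", cohort.samples)

    @pytest.mark.parametrize(
        "alt,ref,excluded",
        [(50, 50, False), (10, 30, True), (5, 0, False), (34, 70, True), (35, 70, False)],
    )
    def test_allele_ratio(self, alt, ref, excluded):
        obs = SampleObservation(alt + ref, alt, ref, Genotype.HET)
        assert rule_allele_ratio(obs) is excluded

    def test_allele_ratio_no_reads_is_an_error(self):
        obs = SampleObservation(0, 0, 0, Genotype.MISSING)
        with pytest.raises(ValueError):
            rule_allele_ratio(obs)


def _cohort_with(*variants):
    return two_sample_cohort(list(variants))


class TestPipeline:
    def test_table1_matrix_reproduced(self, confirmed_cohort):
        result = run_filter_pipeline(confirmed_cohort)
        summary = result.per_sample_summary
        expected = {
            "268-1": [0, 0, 0, 4, 4],
            "283-1": [1, 1, 2, 5, 7],
            "306-1": [0, 0, 0, 3, 3],
            "316-2": [1, 0, 1, 4, 5],
            "B6J": [0, 0, 0, 3, 3],
        }
        for sid, col in expected.items():
            assert summary[sid].tolist() == col, sid

    def test_all_known_cohort_yields_zero_candidates_all_r2(self):
        vs = [
            make_variant(pos=p, gene=f"G{p}", known=True,
                         observations={"ki-1": het(), "ctrl": hom_ref()})
            for p in (10, 20, 30)
        ]
        result = run_filter_pipeline(_cohort_with(*vs))
        assert result.candidates == []
        assert {t.failed_rule for t in result.traces} == {"R2_known"}

    def test_each_rule_fires_with_expected_trace(self):
        vs = [
            # R1: three sites in one gene
            *[make_variant(pos=p, gene="Rec", observations={"ki-1": het(), "ctrl": hom_ref()})
              for p in (1, 2, 3)],
            make_variant(pos=10, gene="G10", known=True,
                         observations={"ki-1": het(), "ctrl": hom_ref()}),
            make_variant(pos=20, gene="G20",
                         observations={"ki-1": het(8), "ctrl": hom_ref(9)}),
            make_variant(pos=30, gene="G30",
                         observations={"ki-1": het(), "ctrl": het()}),
            make_variant(pos=40, gene="G40",
                         observations={"ki-1": hom_alt(), "ctrl": hom_ref()}),
            make_variant(pos=50, gene="G50",
                         observations={"ki-1": het(100, 20), "ctrl": hom_ref()}),
            make_variant(pos=60, gene="G60",
                         observations={"ki-1": het(100, 55), "ctrl": hom_ref()}),
        ]
        result = run_filter_pipeline(_cohort_with(*vs))
        by_id = {t.variant_id: t.failed_rule for t in result.traces}
        assert by_id[vs[0].variant_id] == "R1_gene_recurrence"
        assert by_id[vs[3].variant_id] == "R2_known"
        assert by_id[vs[4].variant_id] == "R3_min_depth"
        assert by_id[vs[5].variant_id] == "R4_control_shared"
        assert by_id[vs[6].variant_id] == "R5_homozygous"
        assert by_id[vs[7].variant_id] == "R6_allele_ratio"
        assert [v.variant_id for v in result.candidates] == [vs[8].variant_id]

    def test_control_private_variant_is_retained(self):
        v = make_variant(observations={"ki-1": hom_ref(), "ctrl": het()})
        result = run_filter_pipeline(_cohort_with(v))
        assert [c.variant_id for c in result.candidates] == [v.variant_id]

    def test_trace_partition_of_first_selection(self, confirmed_cohort):
        result = run_filter_pipeline(confirmed_cohort)
        selection = first_selection(confirmed_cohort.variants)
        assert len(result.traces) == len(selection)
        retained = {t.variant_id for t in result.traces if t.outcome == "retained"}
        excluded = {t.variant_id for t in result.traces if t.outcome == "excluded"}
        assert retained | excluded == {v.variant_id for v in selection}
        assert not retained & excluded

    def test_requires_a_control(self):
        from ki_audit.variant_model import Cohort, Generation, MouseSample

        samples = {"ki-1": MouseSample("ki-1", Generation.F1, "f0", True)}
        with pytest.raises(ValueError):
            run_filter_pipeline(Cohort([], samples))

    def test_surviving_set_invariant_under_r2_r6_evaluation_order(self):
        """Rules R2-R6 are conjunctive: their outcome must be order-free.

        Verified by checking every retained variant fails no rule and
        every excluded one fails at least one, independent of order.
        """
        vs = [
            make_variant(pos=p, gene=f"G{p}", known=(p % 20 == 0),
                         observations={"ki-1": het(100, 30 + p % 40), "ctrl": hom_ref()})
            for p in range(10, 90, 7)
        ]
        cohort = _cohort_with(*vs)
        result = run_filter_pipeline(cohort)
        retained = {v.variant_id for v in result.candidates}
        for v in first_selection(cohort.variants):
            fails = {
                "R2": rule_known(v),
                "R3": rule_min_depth(v),
                "R4": rule_control_shared(v, ["ctrl"]),
                "R5": rule_zygosity(v, "ki-1") if v.observations["ki-1"].carries_alt else False,
                "R6": rule_allele_ratio(v.observations["ki-1"])
                if v.observations["ki-1"].carries_alt else False,
            }
            assert (v.variant_id in retained) == (not any(fails.values()))

    def test_adding_variant_only_perturbs_its_own_gene(self):
        base = [
            make_variant(pos=p, gene=f"G{p}",
                         observations={"ki-1": het(), "ctrl": hom_ref()})
            for p in (10, 20, 30)
        ]
        extra = [
            make_variant(pos=p, gene="G10",
                         observations={"ki-1": het(), "ctrl": hom_ref()})
            for p in (11, 12)
        ]
        before = run_filter_pipeline(_cohort_with(*base))
        after = run_filter_pipeline(_cohort_with(*base, *extra))
        # G10 now has 3 distinct sites -> its variant flips to R1
        ids_before = {v.variant_id for v in before.candidates}
        ids_after = {v.variant_id for v in after.candidates}
        assert base[0].variant_id in ids_before
        assert base[0].variant_id not in ids_after
        assert ids_after >= {base[1].variant_id, base[2].variant_id}

    def test_trace_invariant_enforced(self):
        with pytest.raises(ValueError):
            FilterTrace("v", "retained", "R2_known")
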