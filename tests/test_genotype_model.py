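"""Cohort loading, rarity filtering and biallelic enumeration."""

import pytest
from hypothesis import given, settings, strategies as st

import rnuscan as r

from conftest import het, hom, make_variant, write_groups, write_ped, write_vcf


class TestLoadCohort:
    def test_pass_variant_yields_one_call_per_carrier(self, tiny_cohort_files):
        cohort = r.load_cohort(*tiny_cohort_files)
        v1_calls = [
            c for calls in cohort.calls.values() for c in calls.values()
            if c.variant_id == "v1"
        ]
        assert len(v1_calls) == 2
        assert all(c.zygosity == "het" for c in v1_calls)

    def test_non_pass_variant_emits_no_calls(self, tiny_cohort_files):
        cohort = r.load_cohort(*tiny_cohort_files)
        assert not any(
            c.variant_id == "v2"
            for calls in cohort.calls.values()
            for c in calls.values()
        )
        assert "v2" not in cohort.variants

    def test_phased_separator_preserved_as_statistical_phase(
        self, tiny_cohort_files
    ):
        cohort = r.load_cohort(*tiny_cohort_files)
        s1 = cohort.calls["S1"]["v1"]
        s2 = cohort.calls["S2"]["v1"]
        assert s1.phased and s1.haplotype == 1
        assert s2.phased and s2.haplotype == 0

    def test_ped_with_unknown_sample_raises(self, tmp_path, tiny_cohort_files):
        vcf, _, groups = tiny_cohort_files
        bad_ped = write_ped(
            tmp_path / "bad.ped",
            [("F9", "GHOST", "S1", "S2", 1, 2)],
        )
        with pytest.raises(r.ReferentialError, match="GHOST"):
            r.load_cohort(vcf, bad_ped, groups)

    def test_group_sample_absent_from_vcf_raises(self, tmp_path, tiny_cohort_files):
        vcf, ped, _ = tiny_cohort_files
        bad_groups = write_groups(
            tmp_path / "bad.groups.tsv", [("NOPE", "control", "F1")]
        )
        with pytest.raises(r.ReferentialError, match="NOPE"):
            r.load_cohort(vcf, ped, bad_groups)

    def test_malformed_ped_names_line(self, tmp_path, tiny_cohort_files):
        vcf, _, groups = tiny_cohort_files
        bad = tmp_path / "malformed.ped"
        bad.write_text("F1\tS1\t0\n")
        with pytest.raises(r.ParseError, match="line 1"):
            r.load_cohort(vcf, bad, groups)


class TestRareFilter:
    @pytest.mark.parametrize(
        "af,kept",
        [(0.0005, True), (0.01, False), (0.001, False)],
        ids=["below", "above", "at-boundary"],
    )
    def test_strict_threshold(self, af, kept):
        calls = [het("S", "v1")]
        out = r.filter_rare_variants(calls, {"v1": af})
        assert (len(out) == 1) is kept

    def test_inclusive_boundary_flag(self):
        calls = [het("S", "v1")]
        assert r.filter_rare_variants(calls, {"v1": 0.001}, inclusive=True)

    def test_missing_af_errors_by_default(self):
        with pytest.raises(KeyError):
            r.filter_rare_variants([het("S", "vX")], {})

    def test_missing_af_zero_policy_warns_and_keeps(self):
        with pytest.warns(UserWarning, match="missing AF"):
            out = r.filter_rare_variants([het("S", "vX")], {}, missing_af="zero")
        assert len(out) == 1

    def test_af_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            r.filter_rare_variants([het("S", "v1")], {"v1": 1.5})

    @given(
        afs=st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False), min_size=0,
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_filter_is_idempotent(self, afs):
        table = {f"v{i}": af for i, af in enumerate(afs)}
        calls = [het("S", vid) for vid in table]
        once = r.filter_rare_variants(calls, table)
        twice = r.filter_rare_variants(once, table)
        assert once == twice


class TestEnumerateBiallelic:
    def test_hom_alt_yields_homozygous_genotype(self):
        out = r.enumerate_biallelic_genotypes({"S": [hom("S", "v1")]})
        assert len(out) == 1
        g = out[0]
        assert g.genotype_class == "homozygous" and g.is_confident

    def test_trans_phased_pair_is_confident_compound_het(self):
        calls = {"S": [het("S", "v1", hap=0), het("S", "v2", hap=1)]}
        out = r.enumerate_biallelic_genotypes(calls)
        assert [g.phase for g in out] == ["trans"]
        assert out[0].is_confident

    def test_cis_phased_pair_is_not_confident(self):
        calls = {"S": [het("S", "v1", hap=0), het("S", "v2", hap=0)]}
        out = r.enumerate_biallelic_genotypes(calls)
        assert [g.phase for g in out] == ["cis"]
        assert not out[0].is_confident

    def test_unphased_pair_has_unknown_phase(self):
        calls = {"S": [het("S", "v1"), het("S", "v2")]}
        out = r.enumerate_biallelic_genotypes(calls)
        assert out[0].phase == "unknown" and not out[0].is_confident

    def test_read_backed_assessment_overrides_statistical(self):
        calls = {"S": [het("S", "v1", hap=0), het("S", "v2", hap=0)]}
        key = r.pair_key("S", "v1", "v2")
        out = r.enumerate_biallelic_genotypes(
            calls, phase_assessments={key: ("trans", "read_backed")}
        )
        assert out[0].phase == "trans" and out[0].evidence == "read_backed"

    def test_empty_input_empty_output(self):
        assert r.enumerate_biallelic_genotypes({}) == []


class TestControlCombinationFilter:
    CASE = [
        r.BiallelicGenotype("S1", "compound_het", frozenset({"v1", "v2"}), "trans"),
        r.BiallelicGenotype("S2", "homozygous", frozenset({"v1"})),
    ]

    def test_same_combination_in_controls_removes_case(self):
        controls = [
            r.BiallelicGenotype("C1", "compound_het", frozenset({"v2", "v1"}), "trans")
        ]
        kept = r.filter_by_control_combinations(self.CASE, controls)
        assert [g.sample for g in kept] == ["S2"]

    def test_different_combination_retained(self):
        controls = [
            r.BiallelicGenotype("C1", "compound_het", frozenset({"v1", "v3"}), "trans")
        ]
        assert len(r.filter_by_control_combinations(self.CASE, controls)) == 2

    def test_het_only_control_carriage_does_not_remove_homozygote(self):
        # controls carrying v1 heterozygously contribute no biallelic key
        kept = r.filter_by_control_combinations(
            self.CASE, [], external_combinations=[]
        )
        assert len(kept) == 2

    def test_empty_controls_remove_nothing_full_overlap_removes_all(self):
        assert r.filter_by_control_combinations(self.CASE, []) == self.CASE
        assert (
            r.filter_by_control_combinations(
                self.CASE, external_combinations=[{"v1", "v2"}, {"v1"}]
            )
            == []
        )

    def test_combination_key_is_order_invariant(self):
        a = r.BiallelicGenotype("X", "compound_het", frozenset({"v1", "v2"}), "trans")
        b = r.BiallelicGenotype("Y", "compound_het", frozenset({"v2", "v1"}), "trans")
        assert a.combination_key == b.combination_key


class TestRegionConstraint:
    VARIANTS = {
        "v35": make_variant("v35", 35),
        "v80": make_variant("v80", 80),
        "v100": make_variant("v100", 100),
        "v120": make_variant("v120", 120),
        "v150": make_variant("v150", 150),
    }

    def pair(self, va, vb):
        return r.BiallelicGenotype(
            "S", "compound_het", frozenset({va, vb}), "trans"
        )

    @pytest.mark.parametrize(
        "pair,kept",
        [
            (("v35", "v150"), True),  # n.35 in the 5' constrained region
            (("v80", "v150"), False),  # neither variant in a region
            (("v100", "v120"), True),  # n.100 in the Sm site
        ],
    )
    def test_compound_het_region_rule(self, pair, kept):
        out = r.apply_region_constraint([self.pair(*pair)], self.VARIANTS)
        assert (len(out) == 1) is kept

    def test_homozygous_passes_unconditionally_by_default(self):
        g = r.BiallelicGenotype("S", "homozygous", frozenset({"v150"}))
        assert r.apply_region_constraint([g], self.VARIANTS) == [g]
        assert (
            r.apply_region_constraint(
                [g], self.VARIANTS, include_homozygous=True
            )
            == []
        )

    def test_out_of_bounds_position_flagged(self):
        bad = {"vb": make_variant("vb", 200)}
        g = r.BiallelicGenotype("S", "homozygous", frozenset({"vb"}))
        with pytest.raises(ValueError, match="outside transcript"):
            r.apply_region_constraint(
                [g], bad, transcript=r.RNU2_2_TRANSCRIPT
            )

    def test_constraint_is_idempotent(self):
        genos = [self.pair("v35", "v150"), self.pair("v80", "v150")]
        once = r.apply_region_constraint(genos, self.VARIANTS)
        assert r.apply_region_constraint(once, self.VARIANTS) == once


class TestDistributionEligibility:
    def test_snv_pair_inside_transcript_eligible(self):
        variants = {
            "a": make_variant("a", 10),
            "b": make_variant("b", 180),
        }
        g = r.BiallelicGenotype("S", "compound_het", frozenset({"a", "b"}), "trans")
        assert r.eligible_for_distribution_analysis(g, variants)

    def test_long_deletion_ineligible(self):
        variants = {"d": make_variant("d", 50, ref="ACGTAC", alt="A")}
        g = r.BiallelicGenotype("S", "homozygous", frozenset({"d"}))
        assert not r.eligible_for_distribution_analysis(g, variants)

    def test_two_nt_indel_eligible(self):
        variants = {"d": make_variant("d", 50, ref="ACG", alt="A")}
        g = r.BiallelicGenotype("S", "homozygous", frozenset({"d"}))
        assert r.eligible_for_distribution_analysis(g, variants)

    def test_ref_allele_extending_past_transcript_end_ineligible(self):
        variants = {"d": make_variant("d", 190, ref="ACG", alt="A")}
        g = r.BiallelicGenotype("S", "homozygous", frozenset({"d"}))
        assert not r.eligible_for_distribution_analysis(g, variants)


class TestDomainTypes:
    def test_named_default_regions(self):
        assert (r.RNU2_2_TRANSCRIPT.start, r.RNU2_2_TRANSCRIPT.end) == (1, 191)
        assert (r.CONSTRAINED_5P.start, r.CONSTRAINED_5P.end) == (1, 67)
        assert (r.SM_SITE.start, r.SM_SITE.end) == (97, 107)

    def test_variant_validation(self):
        with pytest.raises(ValueError):
            r.Variant("v", "g", 1, "A", "")
        with pytest.raises(ValueError):
            r.Variant("v", "g", 1, "A", "G", af=1.2)

    def test_compound_het_needs_two_distinct_variants(self):
        with pytest.raises(ValueError):
            r.BiallelicGenotype("S", "compound_het", frozenset({"v1"}), "trans")
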