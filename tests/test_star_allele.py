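"""Diplotype calling, phenotype classification and cohort frequency tables."""

from itertools import combinations_with_replacement

import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from tamoxmr.star_allele import (
    Activity,
    ConfigurationError,
    CopyNumberCall,
    CopyNumberQCError,
    Diplotype,
    InconsistentCallsError,
    IndeterminateUMError,
    PhenotypeCategory,
    VariantState,
    call_diplotype,
    classify_phenotype,
    default_allele_definitions,
    genotype_frequency_table,
    load_allele_definitions,
    load_reference_cohort,
)
from tamoxmr.simulate import simulate_assay_calls

HOM_REF = VariantState.HOM_REF
HET = VariantState.HET
HOM_ALT = VariantState.HOM_ALT
NO_CALL = VariantState.NO_CALL


def all_ref(defs, **overrides):
    calls = {v: HOM_REF for v in defs.panel_variants}
    calls.update(overrides)
    return calls


class TestDefinitionLoading:
    def test_shipped_table_has_eleven_alleles_with_default_star1(self, defs):
        assert len(defs) == 11
        assert defs["*1"].defining_variants == frozenset()
        assert defs["*5"].is_deletion
        assert len(defs.panel_variants) == 11

    def test_activity_classes_follow_the_functional_grouping(self, defs):
        assert {s for s in defs.alleles if defs.activity(s) is Activity.PM} == {
            "*3", "*4", "*5", "*6", "*7",
        }
        assert {s for s in defs.alleles if defs.activity(s) is Activity.IM} == {
            "*9", "*10", "*17", "*41",
        }
        assert {s for s in defs.alleles if defs.activity(s) is Activity.EM} == {
            "*1", "*2",
        }

    def test_missing_default_allele_is_a_configuration_error(self, tmp_path):
        cfg = {
            "panel": ["1846G>A"],
            "alleles": {"*4": {"activity": "PM", "variants": ["1846G>A"]}},
        }
        path = tmp_path / "defs.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ConfigurationError, match=r"\*1"):
            load_allele_definitions(path)

    def test_duplicate_star_names_are_rejected(self, tmp_path):
        cfg = {
            "panel": ["1846G>A"],
            "alleles": [
                {"star_name": "*1", "activity": "EM", "variants": []},
                {"star_name": "*4", "activity": "PM", "variants": ["1846G>A"]},
                {"star_name": "*4", "activity": "PM", "variants": ["1846G>A"]},
            ],
        }
        path = tmp_path / "defs.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ConfigurationError, match="duplicate"):
            load_allele_definitions(path)

    def test_unknown_variant_reference_is_rejected(self, tmp_path):
        cfg = {
            "panel": ["1846G>A"],
            "alleles": {
                "*1": {"activity": "EM", "variants": []},
                "*4": {"activity": "PM", "variants": ["9999X>Y"]},
            },
        }
        path = tmp_path / "defs.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ConfigurationError, match="unknown variant"):
            load_allele_definitions(path)


class TestDiplotypeCalling:
    def test_all_reference_calls_give_wild_type_homozygote(self, defs):
        d = call_diplotype(all_ref(defs), CopyNumberCall(2), defs)
        assert (d.allele_a, d.allele_b) == ("*1", "*1")
        assert not d.duplicated and not d.is_ambiguous

    def test_het_at_the_star4_variant_gives_star1_star4(self, defs):
        d = call_diplotype(
            all_ref(defs, **{"1846G>A": HET}), CopyNumberCall(2), defs
        )
        assert (d.allele_a, d.allele_b) == ("*1", "*4")
        assert not d.is_ambiguous

    def test_hom_alt_star4_at_one_copy_is_hemizygous_star4_star5(self, defs):
        d = call_diplotype(
            all_ref(defs, **{"1846G>A": HOM_ALT}), CopyNumberCall(1), defs
        )
        assert (d.allele_a, d.allele_b) == ("*4", "*5")

    def test_zero_copies_is_homozygous_deletion(self, defs):
        calls = {v: NO_CALL for v in defs.panel_variants}
        d = call_diplotype(calls, CopyNumberCall(0), defs)
        assert (d.allele_a, d.allele_b) == ("*5", "*5")

    def test_duplication_flag_set_at_three_copies(self, defs):
        d = call_diplotype(
            all_ref(defs, **{"2850C>T": HET, "4180G>C": HET}),
            CopyNumberCall(3),
            defs,
        )
        assert (d.allele_a, d.allele_b) == ("*1", "*2")
        assert d.duplicated

    def test_two_het_defining_variants_of_different_alleles(self, defs):
        d = call_diplotype(
            all_ref(defs, **{"1846G>A": HET, "100C>T": HET}),
            CopyNumberCall(2),
            defs,
        )
        assert (d.allele_a, d.allele_b) == ("*4", "*10")

    def test_inconsistent_states_raise_with_conflicting_ids(self, defs):
        # hom-alt at two mutually exclusive defining variants cannot be
        # explained by any pair at 2 copies
        with pytest.raises(InconsistentCallsError) as err:
            call_diplotype(
                all_ref(defs, **{"1846G>A": HOM_ALT, "100C>T": HOM_ALT}),
                CopyNumberCall(2),
                defs,
            )
        assert set(err.value.conflicting_variants) == {"1846G>A", "100C>T"}

    def test_failed_copy_number_qc_is_fatal(self, defs):
        with pytest.raises(CopyNumberQCError):
            call_diplotype(all_ref(defs), CopyNumberCall(2, pass_qc=False), defs)

    def test_no_call_excludes_affected_alleles_and_flags_low_confidence(self, defs):
        # with *4's variant uncallable, a het *41 signature is still resolved,
        # but the call is marked low-confidence
        d = call_diplotype(
            all_ref(defs, **{"1846G>A": NO_CALL, "2988G>A": HET}),
            CopyNumberCall(2),
            defs,
        )
        assert (d.allele_a, d.allele_b) == ("*1", "*41")
        assert d.low_confidence

    def test_nondefining_panel_variant_alt_calls_are_inconsistent(self, defs):
        # 1661G>C defines no allele in the shipped table: an alt call there
        # cannot be explained
        with pytest.raises(InconsistentCallsError):
            call_diplotype(
                all_ref(defs, **{"1661G>C": HOM_ALT}), CopyNumberCall(2), defs
            )


class TestBruteForceOracle:
    """The caller must agree with independent exhaustive enumeration."""

    @staticmethod
    def _enumerate(calls, copies, defs):
        observed = {
            v: s.alt_dosage for v, s in calls.items() if s is not VariantState.NO_CALL
        }
        alleles = defs.non_deletion_alleles()
        results = []
        if copies == 1:
            for a in alleles:
                expect = {
                    v: (2 if v in a.defining_variants else 0) for v in observed
                }
                if expect == observed:
                    results.append((a.priority, tuple(sorted([a.star_name, "*5"]))))
        else:
            for a, b in combinations_with_replacement(alleles, 2):
                expect = {
                    v: int(v in a.defining_variants) + int(v in b.defining_variants)
                    for v in observed
                }
                if expect == observed:
                    results.append(
                        (a.priority + b.priority, tuple(sorted([a.star_name, b.star_name])))
                    )
        if not results:
            return None
        best = max(p for p, _ in results)
        return {pair for p, pair in results if p == best}

    def test_caller_matches_enumeration_on_all_single_and_double_alt_panels(self, defs):
        states = [HOM_REF, HET, HOM_ALT]
        panel = list(defs.panel_variants)
        cases = []
        for i, v in enumerate(panel):
            for s in (HET, HOM_ALT):
                cases.append({v: s})
            for w in panel[i + 1:]:
                for s1 in (HET, HOM_ALT):
                    for s2 in (HET, HOM_ALT):
                        cases.append({v: s1, w: s2})
        for copies in (1, 2):
            for overrides in cases:
                calls = {v: HOM_REF for v in panel}
                calls.update(overrides)
                expected = self._enumerate(calls, copies, defs)
                if expected is None:
                    with pytest.raises(InconsistentCallsError):
                        call_diplotype(calls, CopyNumberCall(copies), defs)
                else:
                    d = call_diplotype(calls, CopyNumberCall(copies), defs)
                    got = {tuple(sorted((d.allele_a, d.allele_b)))} | {
                        tuple(sorted(p)) for p in d.ambiguous_alternatives
                    }
                    assert got == expected, f"{overrides} copies={copies}"


class TestPhenotypeClassification:
    @pytest.mark.parametrize(
        "a,b,dup,label",
        [
            ("*4", "*4", False, "PM/PM"),
            ("*1", "*41", False, "EM/IM"),
            ("*1", "*2", True, "EM/UM"),
            ("*1", "*1", False, "EM/EM"),
            ("*1", "*4", False, "EM/PM"),
            ("*4", "*41", False, "IM/PM"),
            ("*10", "*41", False, "IM/IM"),
            ("*4", "*5", False, "PM/PM"),
        ],
    )
    def test_activity_pairs_map_to_the_seven_categories(self, defs, a, b, dup, label):
        assert classify_phenotype(Diplotype(a, b, duplicated=dup), defs).label == label

    def test_classification_is_symmetric_in_the_two_alleles(self, defs):
        stars = list(defs.alleles)
        for a in stars:
            for b in stars:
                assert (
                    classify_phenotype(Diplotype(a, b), defs).label
                    == classify_phenotype(Diplotype(b, a), defs).label
                )

    def test_duplication_with_non_em_allele_is_indeterminate(self, defs):
        with pytest.raises(IndeterminateUMError):
            classify_phenotype(Diplotype("*1", "*4", duplicated=True), defs)

    def test_category_ranks_are_totally_ordered(self):
        ranks = [PhenotypeCategory(c).rank for c in
                 ("PM/PM", "IM/PM", "IM/IM", "EM/PM", "EM/IM", "EM/EM", "EM/UM")]
        assert ranks == list(range(7))


class TestFrequencyTable:
    def test_single_patient_cohort_is_one_hundred_percent(self, defs):
        by_dip, by_cat = genotype_frequency_table([Diplotype("*1", "*1")], defs)
        assert by_cat.set_index("category").loc["EM/EM", "percent"] == 100.0

    def test_category_counts_partition_the_cohort(self, defs):
        dips = load_reference_cohort()
        by_dip, by_cat = genotype_frequency_table(dips, defs)
        assert by_cat["count"].sum() == len(dips) == 279
        assert by_dip["count"].sum() == len(dips)
        assert by_cat["percent"].sum() == pytest.approx(100.0)
        # category counts equal the sum of member diplotype counts
        merged = by_dip.groupby("category")["count"].sum()
        for cat, n in merged.items():
            assert by_cat.set_index("category").loc[cat, "count"] == n


# -- round-trip property: simulated assay calls are recovered exactly ------

_star = st.sampled_from(
    ["*1", "*2", "*3", "*4", "*5", "*6", "*7", "*9", "*10", "*17", "*41"]
)


@settings(max_examples=200, derandomize=True)
@given(a=_star, b=_star, dup=st.booleans())
def test_simulated_calls_round_trip_to_the_same_diplotype(a, b, dup):
    defs = default_allele_definitions()
    em_pair = defs.activity(a) is Activity.EM and defs.activity(b) is Activity.EM
    d = Diplotype(a, b, duplicated=dup and em_pair)
    calls, cn = simulate_assay_calls(d, defs)
    recovered = call_diplotype(calls, cn, defs)
    assert (recovered.allele_a, recovered.allele_b) == (d.allele_a, d.allele_b)
    assert recovered.duplicated == d.duplicated
    assert not recovered.is_ambiguous
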