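"""Treatment ranking: the evidence weight formula, profile matching,
and equivalence with a brute-force re-summation oracle."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from trkit import (
    Concept,
    Effect,
    EvidenceLevel,
    EvidenceModel,
    PatientProfile,
    TTDAssertion,
    assertion_weight,
    match_assertions,
    rank_treatments,
)
from trkit.trex import DEFAULT_LEVEL_WEIGHTS, load_level_weights

from _oracles import brute_force_ranking
from conftest import random_assertion


def _assertion(level, cases, effect=Effect.SENSITIVITY, drug=None, biomarker=None,
               disease=None):
    return TTDAssertion(
        biomarker=biomarker or Concept("B:1", "marker1", "ALTERATION"),
        drug=drug or Concept("D:1", "drug1", "DRUG"),
        effect=effect,
        model=EvidenceModel.HUMAN_CLINICAL,
        evidence_level=level,
        cases=cases,
        source_bce="synthetic",
        disease=disease,
    )


class TestAssertionWeight:
    def test_single_case_report_weight(self):
        # log10(1) = 0, so the weight is exactly the level multiplier
        assert assertion_weight(_assertion(EvidenceLevel.CASE_REPORT, 1)) == 3.0

    def test_rct_with_200_patients(self):
        w = assertion_weight(_assertion(EvidenceLevel.PHASE_III_RCT, 200))
        assert w == pytest.approx(6 * (1 + math.log10(200)))
        assert w == pytest.approx(19.807, abs=1e-3)

    @pytest.mark.parametrize("level", list(EvidenceLevel))
    def test_tenfold_cases_doubles_the_multiplier(self, level):
        w1 = assertion_weight(_assertion(level, 1))
        w10 = assertion_weight(_assertion(level, 10))
        assert w10 == pytest.approx(2 * w1)

    def test_strictly_increasing_in_level_at_fixed_cases(self):
        for cases in (1, 7, 100):
            weights = [
                assertion_weight(_assertion(level, cases)) for level in EvidenceLevel
            ]
            assert all(a < b for a, b in zip(weights, weights[1:]))

    def test_missing_level_in_table_errors(self):
        table = {EvidenceLevel.IN_VITRO: 1.0}
        with pytest.raises(ValueError, match="missing"):
            assertion_weight(_assertion(EvidenceLevel.PHASE_II, 5), table)

    def test_bundled_table_matches_defaults(self):
        from trkit.corpus import _data_path

        with __import__("importlib").resources.as_file(
            _data_path("level_weights.tsv")
        ) as p:
            assert load_level_weights(p) == dict(DEFAULT_LEVEL_WEIGHTS)


class TestMatching:
    def test_example_assertions_match_matching_profile(self, compiled_examples):
        kb = [a for group in compiled_examples for a in group]
        profile = PatientProfile(
            diagnosis=kb[0].disease,
            biomarkers=frozenset({kb[0].biomarker}),
        )
        assert match_assertions(profile, kb) == kb

    def test_empty_biomarker_set_matches_nothing(self, compiled_examples):
        kb = [a for group in compiled_examples for a in group]
        profile = PatientProfile(diagnosis=kb[0].disease, biomarkers=frozenset())
        assert match_assertions(profile, kb) == []

    def test_disease_restriction_is_exact(self):
        marker = Concept("B:1", "marker1", "ALTERATION")
        nsclc = Concept("X:nsclc", "NSCLC", "DISEASE")
        melanoma = Concept("X:mel", "Melanoma", "DISEASE")
        restricted = _assertion(EvidenceLevel.PHASE_I, 5, biomarker=marker, disease=nsclc)
        unrestricted = _assertion(EvidenceLevel.PHASE_I, 5, biomarker=marker)
        profile = PatientProfile(diagnosis=melanoma, biomarkers=frozenset({marker}))
        assert match_assertions(profile, [restricted, unrestricted]) == [unrestricted]


class TestRanking:
    def test_empty_kb_empty_ranking(self):
        profile = PatientProfile(
            diagnosis=Concept("X:1", "d", "DISEASE"),
            biomarkers=frozenset({Concept("B:1", "m", "ALTERATION")}),
        )
        assert rank_treatments(profile, []) == []

    def test_example_kb_ranks_ceritinib_first(self, compiled_examples):
        kb = [a for group in compiled_examples for a in group]
        profile = PatientProfile(
            diagnosis=kb[0].disease, biomarkers=frozenset({kb[0].biomarker})
        )
        ranking = rank_treatments(profile, kb)
        assert ranking[0].drug.preferred_name == "Ceritinib"
        assert ranking[0].score == pytest.approx(3.0 + 6 * (1 + math.log10(200)))
        assert len(ranking[0].pro) == 2 and not ranking[0].contra

    def test_equal_pro_and_contra_cancel(self):
        pro = _assertion(EvidenceLevel.PHASE_II, 30)
        contra = _assertion(EvidenceLevel.PHASE_II, 30, effect=Effect.RESISTANCE)
        profile = PatientProfile(
            diagnosis=Concept("X:1", "d", "DISEASE"),
            biomarkers=frozenset({pro.biomarker}),
        )
        (ranked,) = rank_treatments(profile, [pro, contra])
        assert ranked.score == pytest.approx(0.0, abs=1e-9)
        assert len(ranked.pro) == len(ranked.contra) == 1

    def test_score_decomposes_into_evidence_lists(self, make_random_kb):
        kb = make_random_kb(5, 20)
        profile = PatientProfile(
            diagnosis=Concept("X:0", "disease0", "DISEASE"),
            biomarkers=frozenset(a.biomarker for a in kb),
        )
        for r in rank_treatments(profile, kb):
            total = sum(w for _, w in r.pro) - sum(w for _, w in r.contra)
            assert r.score == pytest.approx(total, abs=1e-9)
            pro_ws = [w for _, w in r.pro]
            assert pro_ws == sorted(pro_ws, reverse=True)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_summation(self, seed, make_random_kb):
        kb = make_random_kb(seed, random.Random(seed).randint(0, 20))
        profile = PatientProfile(
            diagnosis=Concept("X:0", "disease0", "DISEASE"),
            biomarkers=frozenset(
                {Concept("B:0", "marker0", "ALTERATION"),
                 Concept("B:1", "marker1", "ALTERATION"),
                 Concept("B:2", "marker2", "ALTERATION")}
            ),
        )
        ranking = rank_treatments(profile, kb)
        oracle = brute_force_ranking(profile, kb, DEFAULT_LEVEL_WEIGHTS)
        assert [(r.drug.concept_id, r.drug.preferred_name) for r in ranking] == [
            (cid, name) for cid, name, _ in oracle
        ]
        for r, (_, _, score) in zip(ranking, oracle):
            assert r.score == pytest.approx(score, abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_added_pro_evidence_never_lowers_a_drugs_score(self, seed):
        rng = random.Random(seed)
        kb = [random_assertion(rng) for _ in range(rng.randint(0, 12))]
        profile = PatientProfile(
            diagnosis=Concept("X:0", "disease0", "DISEASE"),
            biomarkers=frozenset(
                Concept(f"B:{i}", f"marker{i}", "ALTERATION") for i in range(5)
            ),
        )
        extra = random_assertion(rng, effect=Effect.SENSITIVITY)
        extra = TTDAssertion(**{**extra.__dict__, "disease": None})

        def score_of(kb_, drug_id):
            for r in rank_treatments(profile, kb_):
                if r.drug.concept_id == drug_id:
                    return r.score
            return 0.0

        before = score_of(kb, extra.drug.concept_id)
        after = score_of(kb + [extra], extra.drug.concept_id)
        assert after >= before - 1e-12

        contra = TTDAssertion(**{**extra.__dict__, "effect": Effect.RESISTANCE})
        worse = score_of(kb + [contra], contra.drug.concept_id)
        assert worse <= before + 1e-12

    def test_deterministic_ordering_with_ties(self):
        m = Concept("B:1", "marker1", "ALTERATION")
        a1 = _assertion(EvidenceLevel.PHASE_I, 10, drug=Concept("D:a", "abraxane", "DRUG"), biomarker=m)
        a2 = _assertion(EvidenceLevel.PHASE_I, 10, drug=Concept("D:z", "zanubrutinib", "DRUG"), biomarker=m)
        profile = PatientProfile(
            diagnosis=Concept("X:1", "d", "DISEASE"), biomarkers=frozenset({m})
        )
        first = rank_treatments(profile, [a2, a1])
        second = rank_treatments(profile, [a1, a2])
        assert [r.drug.concept_id for r in first] == ["D:a", "D:z"]
        assert [r.drug.concept_id for r in first] == [r.drug.concept_id for r in second]
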