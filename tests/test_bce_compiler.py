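"""Compiler: slot extraction from parses, evidence classification,
citation link-outs, and the lossless source-text guarantee."""

import pytest

from trkit import (
    Effect,
    EvidenceLevel,
    EvidenceModel,
    MissingSlotError,
    compile_tree,
    parse_grammar,
    parse_text,
)
from trkit.bce_compiler import (
    EvidenceTable,
    SlotFrame,
    SlotValue,
    classify_evidence,
    extract_citation,
)


class TestWorkedExamples:
    """The two bundled worked-example sentences compile to the expected
    targeted-therapy rows (expectations hand-derived from the declared
    slot and evidence rules)."""

    def test_trial_sentence(self, compiled_examples, examples):
        assertions = compiled_examples[0]
        assert len(assertions) == 1
        a = assertions[0]
        assert a.cases == 200
        assert a.drug.preferred_name == "Ceritinib"
        assert a.effect == Effect.SENSITIVITY
        assert a.evidence_level == EvidenceLevel.PHASE_III_RCT
        assert a.model == EvidenceModel.HUMAN_CLINICAL
        assert a.biomarker.preferred_name == "EIF2AK3-alk fusion"
        assert a.biomarker.concept_id.startswith("LOCAL:")
        assert a.disease is not None and a.disease.concept_id == "NCIT:C2926"
        assert a.stage == 4
        assert a.citation is not None
        assert a.citation.text == (
            "(Won, Mambetsariev, and Salgia, BMC Cancer. 2016 Aug 2;16:568)"
        )
        assert a.source_bce == examples[0]
        assert not a.evidence_assumed

    def test_case_report_sentence(self, compiled_examples, examples):
        assertions = compiled_examples[1]
        assert len(assertions) == 1
        a = assertions[0]
        assert a.cases == 1
        assert a.model == EvidenceModel.HUMAN_CLINICAL
        assert a.evidence_level == EvidenceLevel.CASE_REPORT
        assert a.age == 50
        assert a.sex == "male"
        assert a.stage == 4
        assert a.effect == Effect.SENSITIVITY
        assert a.drug.preferred_name == "Ceritinib"
        assert a.disease is not None and a.disease.concept_id == "NCIT:C2926"
        assert a.source_bce == examples[1]

    def test_both_sentences_share_biomarker_concept(self, compiled_examples):
        # "EIF2AK3-alk fusion" gets the same local content-hash id in both,
        # so the two rows stay joinable for ranking
        a, b = compiled_examples[0][0], compiled_examples[1][0]
        assert a.biomarker.concept_id == b.biomarker.concept_id


class TestSlotRules:
    def test_missing_drug_slot(self, lexicon, evidence_table):
        # a fragment grammar that accepts a drug-less sentence: compiling
        # its parse must name the absent required slot
        g = parse_grammar(
            "S -> BIOMARKER in @DISEASE\nBIOMARKER -> @GENE @ALTERATION"
        )
        text = "BRAF V600E in melanoma"
        trees = parse_text(text, g, lexicon=lexicon)
        assert trees
        with pytest.raises(MissingSlotError) as exc:
            compile_tree(trees[0], text, lexicon=lexicon, evidence_table=evidence_table)
        assert exc.value.slot == "drug"

    def test_conjoined_drugs_make_one_assertion_each(self, grammar, lexicon, evidence_table):
        text = "ALK fusion in NSCLC confers sensitivity to crizotinib and ceritinib"
        trees = parse_text(text, grammar, lexicon=lexicon)
        assertions = compile_tree(trees[0], text, lexicon=lexicon, evidence_table=evidence_table)
        assert [a.drug.preferred_name for a in assertions] == ["Crizotinib", "Ceritinib"]
        # shared evidence fields
        assert len({(a.evidence_level, a.cases, a.effect) for a in assertions}) == 1

    def test_hedged_narrative_is_still_sensitivity(self, grammar, lexicon, evidence_table):
        # "apparently sensitized" keeps the hedge in the source text but
        # does not change the compiled effect
        text = "This 44 year old female’s melanoma tumor was apparently sensitized to dabrafenib by a BRAF mutation."
        trees = parse_text(text, grammar, lexicon=lexicon)
        (a,) = compile_tree(trees[0], text, lexicon=lexicon, evidence_table=evidence_table)
        assert a.effect == Effect.SENSITIVITY
        assert "apparently" in a.source_bce

    def test_compile_is_deterministic(self, grammar, lexicon, evidence_table, examples):
        for text in examples:
            tree = parse_text(text, grammar, lexicon=lexicon)[0]
            first = compile_tree(tree, text, lexicon=lexicon, evidence_table=evidence_table)
            second = compile_tree(tree, text, lexicon=lexicon, evidence_table=evidence_table)
            assert [a.to_dict() for a in first] == [a.to_dict() for a in second]

    def test_source_text_is_lossless(self, grammar, lexicon, evidence_table):
        texts = [
            "T790M confers resistance to gefitinib",
            "This 70 year old male’s stage 2 gastric cancer tumor was sensitized to imatinib by a KIT mutation.",
        ]
        for text in texts:
            tree = parse_text(text, grammar, lexicon=lexicon)[0]
            for a in compile_tree(tree, text, lexicon=lexicon, evidence_table=evidence_table):
                assert a.source_bce == text


def _frame(**kw):
    f = SlotFrame()
    for k, v in kw.items():
        if k == "narrative":
            f.narrative = v
        elif v is not None:
            setattr(f, k, SlotValue(v, (0, 1)))
    return f


class TestClassifyEvidence:
    @pytest.mark.parametrize(
        "frame_kw,expected",
        [
            (
                dict(trial_phrase="randomized controlled trial", cases=200),
                (EvidenceLevel.PHASE_III_RCT, 200, EvidenceModel.HUMAN_CLINICAL),
            ),
            (
                dict(narrative=True),
                (EvidenceLevel.CASE_REPORT, 1, EvidenceModel.HUMAN_CLINICAL),
            ),
            (
                dict(trial_phrase="cell line study"),
                (EvidenceLevel.IN_VITRO, 1, EvidenceModel.PRECLINICAL),
            ),
            (
                dict(trial_phrase="cell line study", cases=12),
                (EvidenceLevel.IN_VITRO, 12, EvidenceModel.PRECLINICAL),
            ),
            (
                dict(trial_phrase="phase ii trial", cases=85),
                (EvidenceLevel.PHASE_II, 85, EvidenceModel.HUMAN_CLINICAL),
            ),
            (
                dict(trial_phrase="clinical series", cases=9),
                (EvidenceLevel.CASE_REPORT, 9, EvidenceModel.HUMAN_CLINICAL),
            ),
        ],
    )
    def test_declared_mappings(self, evidence_table, frame_kw, expected):
        call = classify_evidence(_frame(**frame_kw), evidence_table)
        assert (call.level, call.cases, call.model) == expected

    def test_no_evidence_cue_defaults_conservatively_with_flag(self, evidence_table):
        call = classify_evidence(_frame(), evidence_table)
        assert (call.level, call.cases) == (EvidenceLevel.CASE_REPORT, 1)
        assert call.assumed

    def test_narrative_is_not_flagged_as_assumed(self, evidence_table):
        assert not classify_evidence(_frame(narrative=True), evidence_table).assumed

    def test_nonpositive_case_count_errors(self, evidence_table):
        with pytest.raises(ValueError):
            classify_evidence(_frame(trial_phrase="phase i trial", cases=0), evidence_table)

    def test_longest_pattern_wins(self):
        table = EvidenceTable(
            [("phase i", EvidenceLevel.PHASE_I), ("phase iii", EvidenceLevel.PHASE_III_RCT)]
        )
        assert table.classify("phase iii clinical trial") == EvidenceLevel.PHASE_III_RCT
        assert table.classify("phase i clinical trial") == EvidenceLevel.PHASE_I


class TestCitations:
    def test_verbatim_text_and_encoded_url(self):
        text = "(Won, Mambetsariev, and Salgia, BMC Cancer. 2016 Aug 2;16:568)"
        cit = extract_citation(_frame(citation=text))
        assert cit.text == text
        assert cit.url and " " not in cit.url

    def test_absent_when_no_citation_token(self):
        assert extract_citation(_frame()) is None

    def test_url_is_query_encoded(self):
        cit = extract_citation(_frame(citation="(Smith and Jones, J Clin Oncol. 2001;5:44)"))
        assert " " not in cit.url and "%" in cit.url or "+" in cit.url
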