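import random

import pytest
from hypothesis import HealthCheck, settings

from trkit import (
    Concept,
    Effect,
    EvidenceLevel,
    EvidenceModel,
    TTDAssertion,
    compile_tree,
    default_evidence_table,
    default_grammar,
    default_lexicon,
    example_sentences,
    parse_text,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def grammar():
    return default_grammar()


@pytest.fixture(scope="session")
def evidence_table():
    return default_evidence_table()


@pytest.fixture(scope="session")
def examples():
    """The two bundled worked-example sentences (trial form, case form)."""
    sentences = example_sentences()
    assert len(sentences) == 2
    return sentences


@pytest.fixture(scope="session")
def compiled_examples(examples, grammar, lexicon):
    """The two example sentences compiled through the full pipeline."""
    out = []
    for i, text in enumerate(examples):
        trees = parse_text(text, grammar, lexicon=lexicon)
        assert trees, f"example sentence failed to parse: {text!r}"
        out.append(compile_tree(trees[0], text, lexicon=lexicon, provenance_id=f"ex-{i}"))
    return out


LEVELS = list(EvidenceLevel)

_DRUGS = [Concept(f"D:{i}", f"drug{i}", "DRUG") for i in range(6)]
_MARKERS = [Concept(f"B:{i}", f"marker{i}", "ALTERATION") for i in range(5)]
_DISEASES = [Concept(f"X:{i}", f"disease{i}", "DISEASE") for i in range(3)]


def random_assertion(rng: random.Random, effect=None) -> TTDAssertion:
    """A structurally valid random assertion for property tests."""
    level = rng.choice(LEVELS)
    return TTDAssertion(
        biomarker=rng.choice(_MARKERS),
        drug=rng.choice(_DRUGS),
        effect=effect or rng.choice(list(Effect)),
        model=(
            EvidenceModel.PRECLINICAL
            if level in (EvidenceLevel.IN_VITRO, EvidenceLevel.IN_VIVO)
            else EvidenceModel.HUMAN_CLINICAL
        ),
        evidence_level=level,
        cases=rng.randint(1, 500),
        source_bce=f"synthetic assertion {rng.random():.6f}",
        disease=rng.choice(_DISEASES + [None]),
    )


@pytest.fixture
def make_random_kb():
    def _make(seed: int, size: int):
        rng = random.Random(seed)
        return [random_assertion(rng) for _ in range(size)]

    return _make
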