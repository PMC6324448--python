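import pytest

from bleednlp import GenParams, default_lexicon, generate_corpus


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def clean_corpus():
    """Small clean corpus: no distractors, no adversarial phrasing."""
    return generate_corpus(
        GenParams(n_notes=120, prevalence=0.25, distractor_rate=0.0, seed=42)
    )


@pytest.fixture(scope="session")
def noisy_corpus():
    """Corpus with distractor sentences and de-identification noise."""
    return generate_corpus(GenParams(n_notes=120, prevalence=0.25, seed=43))
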