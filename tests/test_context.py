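"""Sentence segmentation and mention-level context classification."""

import numpy as np
import pytest

from bleednlp.context import (
    ABSENT,
    PRESENT,
    Note,
    find_mentions,
    segment_sentences,
)
from bleednlp.lexicon import Lexicon


class TestSegmentation:
    @pytest.mark.parametrize(
        "text,n",
        [
            ("Patient denies bleeding. No melena.", 2),
            ("", 0),
            ("PMH:\n- GI bleed 2005\n- HTN", 3),
            ("One sentence without terminator", 1),
            ("Stable.  Improving.  Discharged.", 3),
            ("HPI:\nwrapped line\ncontinues here.", 2),
        ],
    )
    def test_segment_counts(self, text, n):
        assert len(segment_sentences(text)) == n

    def test_spans_cover_non_whitespace(self):
        text = "First sentence. Second!\nA/P:\n- item one\n- item two"
        spans = segment_sentences(text)
        covered = set()
        for s in spans:
            covered.update(range(s.start, s.end))
        for i, ch in enumerate(text):
            if not ch.isspace():
                assert i in covered
        # spans sorted and non-overlapping
        for a, b in zip(spans, spans[1:]):
            assert a.end <= b.start


class TestPaperPhrases:
    @pytest.mark.parametrize(
        "text,polarity,category",
        [
            ("patient denies bleeding", ABSENT, "negation"),
            ("no BRBPR", ABSENT, "negation"),
            ("history of bleeding ulcer", ABSENT, "historical"),
            ("transfuse if patient bleeds", ABSENT, "hypothetical"),
        ],
    )
    def test_absent_mentions(self, lexicon, text, polarity, category):
        ms = find_mentions(Note("n", text), lexicon)
        assert len(ms) == 1
        assert ms[0].polarity == polarity
        assert category in {c for c, _ in ms[0].applied_modifiers}

    @pytest.mark.parametrize(
        "text,stem",
        [
            ("right femoral hematoma", "hematoma"),
            ("brisk bleeding from the wound", "bleed"),
            ("CT shows SAH", "sah"),
        ],
    )
    def test_present_mentions(self, lexicon, text, stem):
        ms = find_mentions(Note("n", text), lexicon)
        assert [(m.stem_id, m.polarity) for m in ms] == [(stem, PRESENT)]

    def test_modifier_does_not_cross_sentence_boundary(self, lexicon):
        ms = find_mentions(Note("n", "Patient denies pain. Bleeding noted."), lexicon)
        assert [m.polarity for m in ms] == [PRESENT]

    def test_deid_placeholder_is_opaque(self, lexicon):
        ms = find_mentions(Note("n", "Seen at [**Hospital bleeding 1**] today."), lexicon)
        assert ms == []

    def test_span_indexes_original_text(self, lexicon):
        text = "HPI:\nActive bleeding noted after [**2101-04-12**]."
        (m,) = find_mentions(Note("n", text), lexicon)
        assert text[m.start : m.end].lower() == "bleeding"

    def test_backward_modifier(self, lexicon):
        (m,) = find_mentions(Note("n", "GI bleed prophylaxis"), lexicon)
        assert m.polarity == ABSENT

    def test_determinism(self, lexicon, noisy_corpus):
        note = noisy_corpus.notes[0]
        assert find_mentions(note, lexicon) == find_mentions(note, lexicon)


# ---------------------------------------------------------------------------
# Brute-force scope oracle


def _oracle_polarities(text: str, lexicon: Lexicon):
    """Literal application of the scope definition, sentence by sentence."""
    out = []
    for span in segment_sentences(text):
        sent = text[span.start : span.end]
        # all target matches, longest-then-leftmost non-overlapping
        cands = sorted(
            (
                (m.start(), m.end(), t.stem_id)
                for t in lexicon.targets
                for m in t.regex.finditer(sent)
            ),
            key=lambda c: (-(c[1] - c[0]), c[0]),
        )
        targets = []
        for s, e, stem in cands:
            if all(e <= s2 or s >= e2 for s2, e2, _ in targets):
                targets.append((s, e, stem))
        mods = [
            (m.start(), m.end(), r.direction)
            for r in lexicon.modifiers
            for m in r.regex.finditer(sent)
            if not any(m.start() < e and m.end() > s for s, e, _ in targets)
        ]
        for ts, te, stem in sorted(targets):
            absent = False
            for ms, me, direction in mods:
                if direction == "forward":
                    lo, hi = me, len(sent)
                elif direction == "backward":
                    lo, hi = 0, ms
                else:
                    lo, hi = 0, len(sent)
                if ts < hi and te > lo:
                    absent = True
            out.append((stem, ABSENT if absent else PRESENT))
    return out


TOKEN_BANK = (
    "patient denies bleeding no melena stable history of prior ulcer "
    "transfuse if bleeds BRBPR hematoma resolved today and SDH epistaxis "
    "without reports overnight hemorrhage not"
).split()


def test_polarity_matches_brute_force_oracle(lexicon):
    """Engine polarity equals literal scope enumeration on short sentences."""
    rng = np.random.default_rng(2024)
    for _ in range(400):
        n_tok = int(rng.integers(1, 13))
        sent = " ".join(rng.choice(TOKEN_BANK, size=n_tok))
        got = [
            (m.stem_id, m.polarity) for m in find_mentions(Note("n", sent), lexicon)
        ]
        assert got == _oracle_polarities(sent, lexicon), sent


def test_removing_modifiers_only_flips_absent_to_present(lexicon, noisy_corpus):
    stripped = Lexicon(lexicon.targets, (), version="stripped")
    for note in noisy_corpus.notes[:40]:
        with_mods = find_mentions(note, lexicon)
        without = find_mentions(note, stripped)
        assert [(m.start, m.end) for m in with_mods] == [
            (m.start, m.end) for m in without
        ]
        for a, b in zip(with_mods, without):
            assert b.polarity == PRESENT or a.polarity == b.polarity


def test_mentions_stay_inside_their_sentence(lexicon, noisy_corpus):
    for note in noisy_corpus.notes[:40]:
        spans = segment_sentences(note.text)
        for m in find_mentions(note, lexicon):
            s = spans[m.sentence_index]
            assert s.start <= m.start < m.end <= s.end
            for _, (ms, me) in m.applied_modifiers:
                assert s.start <= ms < me <= s.end
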