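"""Mention-level context classification of bleeding references.

Given a clinical note and a lexicon, the engine locates every target match
and assigns it a polarity: *present* if no context modifier is in scope,
*absent* if a negation, historical or hypothetical modifier covers it.
Modifier scope never crosses a sentence boundary: a forward modifier scopes
from its end to the end of the sentence, a backward modifier from the start
of the sentence to its own start, and a bidirectional modifier over the
whole sentence.

Bracketed de-identification placeholders (``[**2101-4-12**]``) are treated
as opaque tokens: they never match targets or modifiers, but character
offsets always index the original note text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional

from .lexicon import Lexicon

__all__ = [
    "Note",
    "SentenceSpan",
    "Mention",
    "segment_sentences",
    "find_mentions",
]

PRESENT = "present"
ABSENT = "absent"


@dataclass(frozen=True)
class Note:
    note_id: str
    text: str
    gold_label: Optional[int] = None  # 1 = bleeding present, 0 = absent


@dataclass(frozen=True)
class SentenceSpan:
    """Half-open character offsets [start, end) into the note text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid sentence span ({self.start}, {self.end})")


@dataclass(frozen=True)
class Mention:
    """One located bleeding reference with its context classification."""

    note_id: str
    sentence_index: int
    start: int
    end: int
    stem_id: str
    polarity: str
    applied_modifiers: tuple[tuple[str, tuple[int, int]], ...] = ()


# Sentence terminators followed by whitespace end a sentence.  A newline also
# ends a sentence when the next line opens a list item ("- ", "* ", "1.") or
# a short section header ("PMH:", "A/P:").
_TERMINATOR = re.compile(r"[.!?]+(?=\s)")
_LINE_BREAKER = re.compile(
    r"\n(?=\s*(?:[-*•]\s|\d+[.)]\s|[A-Za-z][A-Za-z0-9 /&]{0,30}:))"
)
_HEADER_LINE = re.compile(r"^[A-Za-z][A-Za-z0-9 /&]{0,30}:[ \t]*\n", re.MULTILINE)
_DEID = re.compile(r"\[\*\*.*?\*\*\]")


def segment_sentences(text: str) -> List[SentenceSpan]:
    """Split note text into sentence spans covering all non-whitespace text."""
    if not text:
        return []
    cut_points = {0, len(text)}
    for m in _TERMINATOR.finditer(text):
        cut_points.add(m.end())
    for m in _LINE_BREAKER.finditer(text):
        cut_points.add(m.start() + 1)  # cut after the newline
    for m in _HEADER_LINE.finditer(text):
        cut_points.add(m.end())  # a section header is its own segment
    bounds = sorted(cut_points)
    spans: List[SentenceSpan] = []
    for a, b in zip(bounds, bounds[1:]):
        chunk = text[a:b]
        stripped = chunk.strip()
        if not stripped:
            continue
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        spans.append(SentenceSpan(a + lead, b - trail))
    return spans


def _mask_deid(text: str) -> str:
    """Replace de-identification placeholders with spaces, preserving length."""
    return _DEID.sub(lambda m: " " * (m.end() - m.start()), text)


def _target_matches(sentence: str, offset: int, lexicon: Lexicon):
    """Non-overlapping target matches: longest match wins, leftmost on ties."""
    candidates = []
    for rule in lexicon.targets:
        for m in rule.regex.finditer(sentence):
            candidates.append((m.start() + offset, m.end() + offset, rule.stem_id))
    # longest first, then leftmost, then lexicon order (stable by stem list)
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    chosen: List[tuple[int, int, str]] = []
    for start, end, stem in candidates:
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, stem))
    chosen.sort(key=lambda c: c[0])
    return chosen


def _modifier_scope(direction: str, mstart: int, mend: int, sstart: int, send: int):
    if direction == "forward":
        return mend, send
    if direction == "backward":
        return sstart, mstart
    return sstart, send  # bidirectional


def find_mentions(note: Note, lexicon: Lexicon) -> List[Mention]:
    """Locate target mentions and classify each as present or absent.

    A mention is *absent* iff at least one modifier's scope overlaps the
    target span within the same sentence; all such modifiers are recorded in
    ``applied_modifiers``.  Modifier matches that overlap a target span do
    not fire (so ``no`` inside a matched target never negates it).
    """
    masked = _mask_deid(note.text)
    mentions: List[Mention] = []
    for s_idx, span in enumerate(segment_sentences(note.text)):
        sentence = masked[span.start : span.end]
        targets = _target_matches(sentence, span.start, lexicon)
        if not targets:
            continue
        modifiers = []
        for rule in lexicon.modifiers:
            for m in rule.regex.finditer(sentence):
                mstart, mend = m.start() + span.start, m.end() + span.start
                if any(mstart < te and mend > ts for ts, te, _ in targets):
                    continue  # overlaps a target match
                modifiers.append((rule.category, rule.direction, mstart, mend))
        for tstart, tend, stem in targets:
            applied = []
            for category, direction, mstart, mend in modifiers:
                lo, hi = _modifier_scope(
                    direction, mstart, mend, span.start, span.end
                )
                if tstart < hi and tend > lo:
                    applied.append((category, (mstart, mend)))
            mentions.append(
                Mention(
                    note_id=note.note_id,
                    sentence_index=s_idx,
                    start=tstart,
                    end=tend,
                    stem_id=stem,
                    polarity=ABSENT if applied else PRESENT,
                    applied_modifiers=tuple(applied),
                )
            )
    return mentions
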