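"""Synthetic clinical-note corpora with gold labels and gold mention spans.

The generator emulates the structure of ICU notes: section headers (HPI,
PMH, ALLERGIES, A/P), affirmed bleeding phrases, negated / historical /
hypothetical bleeding references, distractor sentences, and bracketed
de-identification placeholders.  Every bleeding phrase is instantiated from
a fixed template bank with a target surface form drawn from the lexicon, so
the gold mention span and polarity are known exactly at generation time.
A note's gold label is positive iff it contains at least one gold
present-polarity mention.

Generation is fully deterministic for a given parameter set (including the
seed): regenerating with equal ``GenParams`` yields byte-identical corpora.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .context import ABSENT, PRESENT, Mention, Note, segment_sentences
from .lexicon import Lexicon, default_lexicon

__all__ = [
    "GenParams",
    "GoldCorpus",
    "generate_corpus",
    "corpus_to_jsonl",
    "read_corpus_jsonl",
]


@dataclass(frozen=True)
class GenParams:
    """Controls for corpus generation.

    ``prevalence`` defaults to 0.225 — the bleeding-present rate of adult
    ICU notes this generator emulates.  ``adversarial`` enables templates
    that split the context modifier and the target across sentences, which
    any same-sentence scope rule must misread (a regression canary).
    """

    n_notes: int = 500
    prevalence: float = 0.225
    mean_present_mentions: float = 1.6
    p_negated: float = 0.35
    p_historical: float = 0.2
    p_hypothetical: float = 0.2
    distractor_rate: float = 3.0
    adversarial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 10:
            raise ValueError("n_notes must be >= 10")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly between 0 and 1")
        for name in ("p_negated", "p_historical", "p_hypothetical"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_present_mentions < 1:
            raise ValueError("mean_present_mentions must be >= 1")
        if self.distractor_rate < 0:
            raise ValueError("distractor_rate must be >= 0")


@dataclass
class GoldCorpus:
    notes: List[Note]
    gold_mentions: List[Mention]
    params: Optional[GenParams] = None

    def labels(self) -> List[int]:
        return [int(n.gold_label) for n in self.notes]


def _load_templates() -> Dict[str, List[str]]:
    bank: Dict[str, List[str]] = {}
    path = resources.files("bleednlp.data") / "note_templates.tsv"
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for row in reader:
            if not row or row[0].lstrip().startswith("#"):
                continue
            bank.setdefault(row[0].strip(), []).append(row[1])
    return bank


def _surface_forms(lexicon: Lexicon) -> List[Tuple[str, str]]:
    return [(t.stem_id, ex) for t in lexicon.targets for ex in t.examples]


class _NoteBuilder:
    """Accumulates note lines while tracking gold mention spans."""

    def __init__(self, note_id: str):
        self.note_id = note_id
        self.lines: List[str] = []
        self.offset = 0
        self.raw_mentions: List[Tuple[int, int, str, str]] = []

    def add_line(self, line: str) -> None:
        self.lines.append(line)
        self.offset += len(line) + 1  # newline

    def add_template(self, template: str, stem: str, surface: str, polarity: str):
        pos = template.index("{T}")
        line = template.replace("{T}", surface)
        start = self.offset + pos
        self.raw_mentions.append((start, start + len(surface), stem, polarity))
        self.add_line(line)

    def finish(self, gold_label: int) -> Tuple[Note, List[Mention]]:
        text = "\n".join(self.lines)
        note = Note(self.note_id, text, gold_label)
        spans = segment_sentences(text)
        mentions = []
        for start, end, stem, polarity in self.raw_mentions:
            s_idx = next(
                i for i, sp in enumerate(spans) if sp.start <= start < sp.end
            )
            mentions.append(
                Mention(self.note_id, s_idx, start, end, stem, polarity)
            )
        return note, mentions


def generate_corpus(
    params: GenParams, lexicon: Optional[Lexicon] = None
) -> GoldCorpus:
    """Generate a labeled synthetic corpus under the given parameters.

    Exactly ``round(n_notes * prevalence)`` (half-up) notes are positive.
    Positive notes embed at least one affirmed bleeding template; negative
    notes contain only absent-type or no bleeding templates.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    bank = _load_templates()
    surfaces = _surface_forms(lexicon)
    rng = np.random.default_rng(params.seed)

    n_pos = int(np.floor(params.n_notes * params.prevalence + 0.5))
    labels = np.zeros(params.n_notes, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    def pick(seq):
        return seq[rng.integers(len(seq))]

    notes: List[Note] = []
    gold: List[Mention] = []
    for i, label in enumerate(labels):
        b = _NoteBuilder(f"note-{i:05d}")
        b.add_line("HPI:")
        if label == 1:
            extra = rng.poisson(params.mean_present_mentions - 1.0)
            for _ in range(1 + int(extra)):
                stem, surface = pick(surfaces)
                b.add_template(pick(bank["present"]), stem, surface, PRESENT)
        if rng.random() < params.p_negated:
            stem, surface = pick(surfaces)
            b.add_template(pick(bank["negated"]), stem, surface, ABSENT)
        if params.adversarial and label == 0 and rng.random() < 0.5:
            stem, surface = pick(surfaces)
            first, second = pick(bank["adversarial"]).split("|")
            b.add_template(first, stem, surface, ABSENT)
            b.add_line(second)
        n_distract = int(rng.poisson(params.distractor_rate))
        for _ in range(n_distract):
            b.add_line(pick(bank["distractor"]))

        b.add_line("PMH:")
        b.add_line(pick(bank["pmh_item"]))
        if rng.random() < params.p_historical:
            stem, surface = pick(surfaces)
            b.add_template(pick(bank["historical"]), stem, surface, ABSENT)
        b.add_line(pick(bank["pmh_item"]))

        b.add_line("ALLERGIES:")
        b.add_line("NKDA.")

        b.add_line("A/P:")
        if rng.random() < params.p_hypothetical:
            stem, surface = pick(surfaces)
            b.add_template(pick(bank["hypothetical"]), stem, surface, ABSENT)
        b.add_line(pick(bank["distractor"]))

        note, mentions = b.finish(int(label))
        notes.append(note)
        gold.extend(mentions)
    return GoldCorpus(notes=notes, gold_mentions=gold, params=params)


# ---------------------------------------------------------------------------
# JSONL serialization


def corpus_to_jsonl(
    corpus: GoldCorpus, notes_path: str | Path, mentions_path: Optional[str | Path] = None
) -> None:
    """Write notes (and optionally gold mentions) as JSONL files."""
    notes_path = Path(notes_path)
    with notes_path.open("w", encoding="utf-8") as fh:
        for n in corpus.notes:
            rec = {"note_id": n.note_id, "text": n.text, "label": n.gold_label}
            fh.write(json.dumps(rec) + "\n")
    if mentions_path is not None:
        with Path(mentions_path).open("w", encoding="utf-8") as fh:
            for m in corpus.gold_mentions:
                fh.write(
                    json.dumps(
                        {
                            "note_id": m.note_id,
                            "sentence_index": m.sentence_index,
                            "start": m.start,
                            "end": m.end,
                            "stem_id": m.stem_id,
                            "polarity": m.polarity,
                            "modifiers": [
                                {"category": c, "start": s[0], "end": s[1]}
                                for c, s in m.applied_modifiers
                            ],
                        }
                    )
                    + "\n"
                )


def read_corpus_jsonl(
    notes_path: str | Path, mentions_path: Optional[str | Path] = None
) -> GoldCorpus:
    """Read a corpus back; malformed lines raise with their line number."""
    notes: List[Note] = []
    with Path(notes_path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                notes.append(
                    Note(
                        note_id=rec["note_id"],
                        text=rec["text"],
                        gold_label=rec.get("label"),
                    )
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(
                    f"{notes_path}: malformed JSONL at line {lineno}: {exc}"
                ) from exc
    mentions: List[Mention] = []
    if mentions_path is not None:
        with Path(mentions_path).open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    mentions.append(
                        Mention(
                            note_id=rec["note_id"],
                            sentence_index=rec["sentence_index"],
                            start=rec["start"],
                            end=rec["end"],
                            stem_id=rec["stem_id"],
                            polarity=rec["polarity"],
                            applied_modifiers=tuple(
                                (d["category"], (d["start"], d["end"]))
                                for d in rec.get("modifiers", [])
                            ),
                        )
                    )
                except (json.JSONDecodeError, KeyError) as exc:
                    raise ValueError(
                        f"{mentions_path}: malformed JSONL at line {lineno}: {exc}"
                    ) from exc
    return GoldCorpus(notes=notes, gold_mentions=mentions)
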