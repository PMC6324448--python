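"""Bleeding knowledge base: target stems and context modifiers.

The rules engine is driven by two kinds of lexicon entries.  *Targets* are
regular expressions for the words and abbreviations clinicians use for
bleeding (``bleed``, ``hemorr``, ``BRBPR``, ...), grouped into stems so that
``bleeding``, ``bleed`` and ``bled`` all count as the same concept.
*Modifiers* are context cues — negation (``denies``), historical
(``history of``) and hypothetical (``if``) phrases — that flip an in-scope
target mention from bleeding-present to bleeding-absent.

Lexicons are stored as tab-separated text so they can be reviewed and edited
in a spreadsheet.  ``default_lexicon`` returns the packaged bleeding
knowledge base of 16 target stems.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, List

__all__ = [
    "TargetRule",
    "ModifierRule",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "write_lexicon",
    "default_lexicon",
    "MODIFIER_CATEGORIES",
    "MODIFIER_DIRECTIONS",
]

MODIFIER_CATEGORIES = ("negation", "historical", "hypothetical")
MODIFIER_DIRECTIONS = ("forward", "backward", "bidirectional")


class LexiconError(ValueError):
    """Raised when a lexicon file or rule fails validation."""


@dataclass(frozen=True)
class TargetRule:
    """A bleeding target stem: one case-insensitive pattern per concept."""

    stem_id: str
    pattern: str
    examples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.pattern:
            raise LexiconError(f"target {self.stem_id!r}: empty pattern")
        try:
            rx = re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise LexiconError(
                f"target {self.stem_id!r}: pattern {self.pattern!r} does not compile: {exc}"
            ) from exc
        for ex in self.examples:
            if not rx.search(ex):
                raise LexiconError(
                    f"target {self.stem_id!r}: example {ex!r} not matched by its own pattern"
                )

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)


@dataclass(frozen=True)
class ModifierRule:
    """A context cue that marks in-scope bleeding mentions as absent."""

    category: str
    pattern: str
    direction: str
    examples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in MODIFIER_CATEGORIES:
            raise LexiconError(
                f"unknown modifier category {self.category!r}; "
                f"expected one of {MODIFIER_CATEGORIES}"
            )
        if self.direction not in MODIFIER_DIRECTIONS:
            raise LexiconError(
                f"unknown modifier direction {self.direction!r}; "
                f"expected one of {MODIFIER_DIRECTIONS}"
            )
        try:
            rx = re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise LexiconError(
                f"modifier pattern {self.pattern!r} does not compile: {exc}"
            ) from exc
        for ex in self.examples:
            if not rx.search(ex):
                raise LexiconError(
                    f"modifier {self.category!r}: example {ex!r} not matched by pattern"
                )

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)


@dataclass(frozen=True)
class Lexicon:
    targets: tuple[TargetRule, ...]
    modifiers: tuple[ModifierRule, ...]
    version: str = "0"

    def __post_init__(self) -> None:
        if not self.targets:
            raise LexiconError("a lexicon needs at least one target rule")
        seen = set()
        for t in self.targets:
            if t.stem_id in seen:
                raise LexiconError(f"duplicate target stem_id {t.stem_id!r}")
            seen.add(t.stem_id)

    @property
    def stem_ids(self) -> tuple[str, ...]:
        return tuple(t.stem_id for t in self.targets)


_COLUMNS = ["kind", "id_or_category", "pattern", "direction", "examples"]


def _split_examples(cell: str) -> tuple[str, ...]:
    return tuple(e for e in (s.strip() for s in cell.split(";")) if e)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon from a tab-separated file.

    The file has a header row naming the columns ``kind``, ``id_or_category``,
    ``pattern``, ``direction`` (empty for targets) and ``examples``
    (semicolon-separated surface forms).  Lines starting with ``#`` are
    comments.  Rules are preserved in file order.  Validation failures raise
    :class:`LexiconError` naming the offending line.
    """
    path = Path(path)
    targets: List[TargetRule] = []
    modifiers: List[ModifierRule] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:4]] != _COLUMNS[:4]:
            raise LexiconError(
                f"{path}: expected header columns {_COLUMNS[:4]}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or row[0].lstrip().startswith("#") or not "".join(row).strip():
                continue
            row = list(row) + [""] * (len(_COLUMNS) - len(row))
            kind, ident, pattern, direction, examples = (c.strip() for c in row[:5])
            try:
                if kind == "target":
                    targets.append(
                        TargetRule(ident, pattern, _split_examples(examples))
                    )
                elif kind == "modifier":
                    modifiers.append(
                        ModifierRule(ident, pattern, direction, _split_examples(examples))
                    )
                else:
                    raise LexiconError(f"unknown kind {kind!r}")
            except LexiconError as exc:
                raise LexiconError(f"{path}:{lineno}: {exc}") from exc
    return Lexicon(tuple(targets), tuple(modifiers), version=path.stem)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon back to TSV; ``load_lexicon`` round-trips it."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_COLUMNS)
        for t in lexicon.targets:
            writer.writerow(["target", t.stem_id, t.pattern, "", ";".join(t.examples)])
        for m in lexicon.modifiers:
            writer.writerow(
                ["modifier", m.category, m.pattern, m.direction, ";".join(m.examples)]
            )


def default_lexicon() -> Lexicon:
    """The packaged bleeding knowledge base (16 target stems)."""
    with resources.as_file(
        resources.files("bleednlp.data") / "bleeding_lexicon.tsv"
    ) as p:
        return load_lexicon(p)


def iter_surface_forms(lexicon: Lexicon) -> Iterable[tuple[str, str]]:
    """Yield (stem_id, surface form) pairs for every stored example."""
    for t in lexicon.targets:
        for ex in t.examples:
            yield t.stem_id, ex
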