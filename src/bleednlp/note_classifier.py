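"""Note-level classification from mention counts.

Three per-note quantities drive the document-level decision: the number of
bleeding-present mentions, the number of bleeding-absent mentions, and the
total number of mentions.  A heuristic labels a note positive when its
chosen quantity meets an integer threshold; heuristics are compared by ROC
sweep and the sensitivity-maximizing one selected.  The operating rule that
emerges on realistic corpora is "one or more bleeding-present mentions".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .context import PRESENT, Mention

__all__ = [
    "NoteCounts",
    "Heuristic",
    "count_mentions",
    "classify_note",
    "roc_curve",
    "select_heuristic",
    "DEFAULT_HEURISTIC",
    "QUANTITIES",
]

# quantity order used for tie-breaking in heuristic selection
QUANTITIES = ("n_present", "n_total", "n_absent")


@dataclass(frozen=True)
class NoteCounts:
    note_id: str
    n_present: int
    n_absent: int

    def __post_init__(self) -> None:
        if self.n_present < 0 or self.n_absent < 0:
            raise ValueError("mention counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_present + self.n_absent

    def quantity(self, name: str) -> int:
        if name not in QUANTITIES:
            raise ValueError(f"unknown quantity {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class Heuristic:
    """Label a note positive iff ``quantity >= threshold``."""

    quantity: str = "n_present"
    threshold: int = 1

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


#: One or more bleeding-present mentions -> note positive.
DEFAULT_HEURISTIC = Heuristic("n_present", 1)


def count_mentions(
    mentions: Sequence[Mention], note_ids: Sequence[str]
) -> List[NoteCounts]:
    """Tally present/absent mentions per note, zeros for mention-free notes."""
    known = list(dict.fromkeys(note_ids))
    present: Dict[str, int] = {nid: 0 for nid in known}
    absent: Dict[str, int] = {nid: 0 for nid in known}
    for m in mentions:
        if m.note_id not in present:
            raise KeyError(f"mention references unknown note_id {m.note_id!r}")
        if m.polarity == PRESENT:
            present[m.note_id] += 1
        else:
            absent[m.note_id] += 1
    return [NoteCounts(nid, present[nid], absent[nid]) for nid in known]


def classify_note(counts: NoteCounts, heuristic: Heuristic = DEFAULT_HEURISTIC) -> int:
    """Binary note label under a count heuristic (1 = bleeding present)."""
    return int(counts.quantity(heuristic.quantity) >= heuristic.threshold)


def _check_two_classes(gold: Sequence[int]) -> np.ndarray:
    g = np.asarray(gold, dtype=int)
    if g.size == 0 or len(np.unique(g)) < 2:
        raise ValueError("C statistic undefined: gold labels contain a single class")
    return g


def roc_curve(scores: Sequence[int], gold: Sequence[int]):
    """Integer-threshold ROC sweep plus the C statistic.

    Returns ``(points, c)`` where ``points`` is a list of
    ``(threshold, sensitivity, specificity)`` for thresholds 0..max(score)+1
    and ``c`` is the probability that a random positive note scores higher
    than a random negative one, ties counted one half.
    """
    g = _check_two_classes(gold)
    s = np.asarray(scores, dtype=int)
    if s.shape != g.shape:
        raise ValueError("scores and gold must have equal length")
    pos, neg = (g == 1).sum(), (g == 0).sum()
    points = []
    for thr in range(int(s.max()) + 2):
        pred = (s >= thr).astype(int)
        tp = int(((pred == 1) & (g == 1)).sum())
        tn = int(((pred == 0) & (g == 0)).sum())
        points.append((thr, tp / pos, tn / neg))
    c = float(roc_auc_score(g, s))
    return points, c


def select_heuristic(
    counts: Sequence[NoteCounts], gold: Sequence[int]
) -> Heuristic:
    """Pick the count heuristic with the highest sensitivity.

    Thresholds below 1 are excluded (threshold 0 labels everything positive);
    ties are broken by higher specificity, then lower threshold, then by
    quantity order n_present, n_total, n_absent.  If no threshold >= 1
    detects any positive note (all scores zero), the degenerate threshold-0
    rule is returned, which has sensitivity 1 by construction.
    """
    g = _check_two_classes(gold)
    best = None
    for q_idx, quantity in enumerate(QUANTITIES):
        scores = [c.quantity(quantity) for c in counts]
        points, _ = roc_curve(scores, g)
        for thr, sens, spec in points:
            if thr < 1:
                continue
            key = (-sens, -spec, thr, q_idx)
            if best is None or key < best[0]:
                best = (key, Heuristic(quantity, thr))
    assert best is not None
    if best[0][0] == 0.0:  # sensitivity 0 everywhere: degenerate corpus
        return Heuristic(QUANTITIES[0], 0)
    return best[1]
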