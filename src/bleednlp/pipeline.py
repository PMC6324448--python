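"""End-to-end orchestration: annotate a corpus, train and evaluate models.

``annotate_corpus`` runs the rules-based arm (segment, find mentions, count,
classify).  ``train_eval`` produces the full comparison report: the
rules-based classifier plus six supervised variants (SVM, extra trees and
CNN, each trained on the full training set and on a class-balanced
down-sampled subset), every model scored on the held-out test set, and a
McNemar comparison between the best-sensitivity supervised model and the
rules-based one.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .context import Mention, Note, find_mentions
from .evalstats import confusion, mcnemar, metrics
from .lexicon import Lexicon, default_lexicon, load_lexicon
from .ml import (
    ModelSpec,
    chi2_select,
    downsample,
    fit_tfidf,
    train_classic,
    train_cnn,
)
from .note_classifier import (
    DEFAULT_HEURISTIC,
    Heuristic,
    NoteCounts,
    classify_note,
    count_mentions,
    roc_curve,
    select_heuristic,
)

__all__ = ["RunConfig", "annotate_corpus", "train_eval", "write_predictions_csv"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a training/evaluation run.

    ``k`` is the number of chi-square-selected n-gram features; selection is
    refit inside each cross-validation fold unless ``select_once`` asks for
    the simpler select-once-on-train variant.  ``cnn`` holds hyperparameter
    overrides for the conv-net (epochs, filters, widths, max_len, ...).
    """

    lexicon_path: Optional[str] = None
    heuristic: Optional[Tuple[str, int]] = None  # None -> select on training set
    k: int = 100
    seed: int = 0
    select_once: bool = False
    cv_folds: int = 10
    families: Tuple[str, ...] = ("svm", "extra_trees", "cnn")
    grids: Optional[Dict[str, Dict[str, list]]] = None
    cnn: Dict[str, object] = field(default_factory=dict)

    def lexicon(self) -> Lexicon:
        if self.lexicon_path is None:
            return default_lexicon()
        return load_lexicon(self.lexicon_path)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def annotate_corpus(
    notes: Sequence[Note],
    lexicon: Optional[Lexicon] = None,
    heuristic: Heuristic = DEFAULT_HEURISTIC,
) -> Tuple[List[Mention], List[NoteCounts], List[int]]:
    """Rules-based arm: mentions, per-note counts and note labels."""
    lexicon = lexicon if lexicon is not None else default_lexicon()
    mentions: List[Mention] = []
    for note in notes:
        mentions.extend(find_mentions(note, lexicon))
    counts = count_mentions(mentions, [n.note_id for n in notes])
    labels = [classify_note(c, heuristic) for c in counts]
    n_present = sum(c.n_present for c in counts)
    n_absent = sum(c.n_absent for c in counts)
    log.info(
        "identified %d bleeding-present mentions and %d bleeding-absent "
        "mentions in %d notes",
        n_present,
        n_absent,
        len(notes),
    )
    return mentions, counts, labels


def write_predictions_csv(
    path: str | Path,
    counts: Sequence[NoteCounts],
    predicted: Sequence[int],
    gold: Optional[Sequence[Optional[int]]] = None,
) -> None:
    frame = pd.DataFrame(
        {
            "note_id": [c.note_id for c in counts],
            "n_present": [c.n_present for c in counts],
            "n_absent": [c.n_absent for c in counts],
            "n_total": [c.n_total for c in counts],
            "predicted_label": list(predicted),
        }
    )
    if gold is not None:
        frame["gold_label"] = list(gold)
    frame.to_csv(path, index=False)


def _require_labels(notes: Sequence[Note], name: str) -> np.ndarray:
    labels = [n.gold_label for n in notes]
    if any(l is None for l in labels):
        raise ValueError(f"{name} corpus is missing gold labels")
    return np.asarray(labels, dtype=int)


def _metrics_dict(pred: np.ndarray, gold: np.ndarray) -> dict:
    return metrics(confusion(pred, gold)).as_dict()


def train_eval(
    train_notes: Sequence[Note],
    test_notes: Sequence[Note],
    config: RunConfig = RunConfig(),
) -> dict:
    """Train all model variants and evaluate them on the held-out test set.

    Returns a report with one row of diagnostic metrics per model (six
    supervised variants plus the rules-based classifier), the ROC/C-statistic
    summary of the count heuristics on the training set, and the McNemar
    comparison of the best-sensitivity supervised model against the
    rules-based one.  The report is a plain dict and serializes to identical
    JSON for identical inputs.
    """
    y_train = _require_labels(train_notes, "train")
    y_test = _require_labels(test_notes, "test")
    lexicon = config.lexicon()

    # --- rules-based arm -------------------------------------------------
    _, train_counts, _ = annotate_corpus(train_notes, lexicon)
    if config.heuristic is not None:
        heuristic = Heuristic(*config.heuristic)
    else:
        heuristic = select_heuristic(train_counts, y_train)
    c_stats = {}
    for quantity in ("n_present", "n_total", "n_absent"):
        _, c = roc_curve([c.quantity(quantity) for c in train_counts], y_train)
        c_stats[quantity] = c
    _, test_counts, rb_pred = annotate_corpus(test_notes, lexicon, heuristic)
    rb_pred = np.asarray(rb_pred, dtype=int)

    predictions: Dict[str, np.ndarray] = {"rules_based": rb_pred}
    rows: Dict[str, dict] = {"rules_based": _metrics_dict(rb_pred, y_test)}
    extras: Dict[str, dict] = {}

    # --- supervised arm --------------------------------------------------
    X_train_full, featurizer = fit_tfidf(train_notes)
    X_test = featurizer.transform(test_notes)
    ds_idx = downsample(y_train, config.seed)
    log.info(
        "down-sampled training subset: %d notes (%d per class)",
        ds_idx.size,
        int(y_train[ds_idx].sum()),
    )
    samples = {"fs": np.arange(len(train_notes)), "ds": ds_idx}

    for family in config.families:
        for tag, idx in samples.items():
            name = f"{family}_{tag}"
            sample = "down_sampled" if tag == "ds" else "full"
            spec = ModelSpec(family, sample, seed=config.seed)
            if family == "cnn":
                sub_notes = [train_notes[i] for i in idx]
                fitted = train_cnn(spec, sub_notes, y_train[idx], **config.cnn)
                pred = fitted.predict(test_notes)
                extras[name] = {"val_sensitivity": fitted.val_sensitivity}
            else:
                grid = (config.grids or {}).get(family)
                if config.select_once:
                    _, cols = chi2_select(X_train_full, y_train, k=config.k)
                    Xtr = X_train_full.values[idx][:, cols]
                    Xte = X_test.values[:, cols]
                    fitted = train_classic(
                        spec, Xtr, y_train[idx], grid=grid, cv_folds=config.cv_folds
                    )
                    pred = fitted.predict(Xte)
                else:
                    fitted = train_classic(
                        spec,
                        X_train_full.values[idx],
                        y_train[idx],
                        grid=grid,
                        cv_folds=config.cv_folds,
                        select_k=config.k,
                    )
                    pred = fitted.predict(X_test.values)
                extras[name] = {
                    "best_params": fitted.best_params,
                    "cv_sensitivity": fitted.cv_sensitivity,
                }
            predictions[name] = np.asarray(pred, dtype=int)
            rows[name] = _metrics_dict(predictions[name], y_test)

    # --- paired comparison ----------------------------------------------
    ml_names = [n for n in rows if n != "rules_based"]
    comparison = None
    if ml_names:
        best_ml = max(
            ml_names,
            key=lambda n: (
                -1.0 if rows[n]["sensitivity"] is None else rows[n]["sensitivity"]
            ),
        )
        pc = mcnemar(predictions[best_ml], rb_pred, y_test)
        comparison = {
            "best_ml_model": best_ml,
            "discordant_b": pc.discordant_b,
            "discordant_c": pc.discordant_c,
            "statistic": pc.statistic,
            "p_value": pc.p_value,
            "sensitivity_difference": pc.sensitivity_difference,
            "ci_95": [pc.ci_low, pc.ci_high],
            "exact": pc.exact,
        }

    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_train": len(train_notes),
        "n_test": len(test_notes),
        "heuristic": {"quantity": heuristic.quantity, "threshold": heuristic.threshold},
        "c_statistics": c_stats,
        "models": rows,
        "model_details": extras,
        "mcnemar": comparison,
        "predictions": {k: v.tolist() for k, v in predictions.items()},
    }
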