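"""Feature construction, selection, down-sampling and model training."""

import math

import numpy as np
import pytest

from bleednlp.context import Note
from bleednlp.ml import (
    ModelSpec,
    TextCNN,
    build_ngrams,
    chi2_select,
    downsample,
    fit_tfidf,
    train_classic,
    train_cnn,
)
from bleednlp.ml.classic import CLASSIC_GRIDS

SMALL_GRIDS = {
    "svm": {"clf__C": [1, 10], "clf__kernel": ["linear"]},
    "extra_trees": {"clf__n_estimators": [50], "clf__max_depth": [None, 10]},
}


def _separable_corpus(n=60, seed=0):
    """Positives always contain 'bleeding'; negatives never mention it."""
    rng = np.random.default_rng(seed)
    filler = ["stable", "afebrile", "diet", "ambulating", "plan", "renal"]
    notes, labels = [], []
    for i in range(n):
        words = list(rng.choice(filler, size=6))
        label = i % 2
        if label:
            words[3] = "bleeding"
        notes.append(Note(f"n{i}", " ".join(words), label))
        labels.append(label)
    return notes, np.array(labels)


class TestBuildNgrams:
    def test_combinatorial_count(self):
        grams = build_ngrams("no active bleeding")
        assert len(grams) == 6
        assert "no active bleeding" in grams
        assert "active bleeding" in grams

    def test_empty(self):
        assert build_ngrams("") == []

    def test_case_and_punctuation_normalized(self):
        assert set(build_ngrams("Bleeding.")) == set(build_ngrams("bleeding"))


class TestTfidf:
    def test_idf_of_term_in_half_the_corpus(self):
        notes = [Note("a", "bleeding noted"), Note("b", "stable exam")]
        fm, feat = fit_tfidf(notes)
        idx = fm.vocabulary.index("bleeding")
        assert feat.idf[idx] == pytest.approx(math.log(3 / 2) + 1)

    def test_ubiquitous_term_has_minimal_idf(self):
        notes = [Note(str(i), "bleeding stopped") for i in range(4)]
        fm, feat = fit_tfidf(notes)
        assert feat.idf[fm.vocabulary.index("bleeding")] == pytest.approx(1.0)

    def test_out_of_vocabulary_note_is_zero_row(self):
        notes = [Note("a", "bleeding noted"), Note("b", "stable exam")]
        _, feat = fit_tfidf(notes)
        row = feat.transform([Note("c", "entirely novel words")])
        assert row.values.nnz == 0

    def test_rows_l2_normalized(self):
        notes = [Note("a", "bleeding noted today"), Note("b", "stable exam today")]
        fm, _ = fit_tfidf(notes)
        norms = np.sqrt(np.asarray(fm.values.multiply(fm.values).sum(axis=1)))
        assert np.allclose(norms.ravel(), 1.0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_tfidf([])


class TestChi2Select:
    def _matrix(self):
        notes = [Note(f"p{i}", "bleeding active site") for i in range(10)]
        notes += [Note(f"n{i}", "stable renal diet") for i in range(10)]
        gold = [1] * 10 + [0] * 10
        fm, _ = fit_tfidf(notes)
        return fm, gold

    def test_discriminative_feature_ranked_first(self):
        fm, gold = self._matrix()
        selected, cols, scores = chi2_select(fm, gold, k=3, return_scores=True)
        top = fm.vocabulary[int(np.argmax(scores))]
        assert top in {"bleeding", "active", "site", "bleeding active",
                       "active site", "bleeding active site"}
        assert selected.shape[1] == 3

    def test_k_larger_than_vocabulary_keeps_all(self):
        fm, gold = self._matrix()
        selected, _ = chi2_select(fm, gold, k=10_000)
        assert selected.shape[1] == fm.shape[1]

    def test_binary_two_by_two_statistic(self):
        """Feature in 20/20 positives and 0/20 negatives: chi-square 40."""
        notes = [Note(f"p{i}", "marker") for i in range(20)]
        notes += [Note(f"n{i}", "other") for i in range(20)]
        gold = [1] * 20 + [0] * 20
        fm, _ = fit_tfidf(notes)
        _, _, scores = chi2_select(fm, gold, k=1, binary=True, return_scores=True)
        assert scores[fm.vocabulary.index("marker")] == pytest.approx(40.0)

    def test_selected_columns_subset_of_vocabulary(self):
        fm, gold = self._matrix()
        selected, cols = chi2_select(fm, gold, k=4)
        assert set(selected.vocabulary) <= set(fm.vocabulary)
        assert selected.shape[1] == min(4, fm.shape[1])

    def test_single_class_rejected(self):
        fm, _ = self._matrix()
        with pytest.raises(ValueError):
            chi2_select(fm, [1] * 20, k=3)


class TestDownsample:
    def test_paper_scale_contract(self):
        gold = np.array([1] * 225 + [0] * 765)
        idx = downsample(gold, seed=0)
        assert idx.size == 450
        assert gold[idx].sum() == 225

    def test_balanced_input_is_identity(self):
        gold = np.array([1, 0] * 10)
        assert np.array_equal(downsample(gold, seed=1), np.arange(20))

    def test_deterministic(self):
        gold = np.array([1] * 5 + [0] * 30)
        assert np.array_equal(downsample(gold, 9), downsample(gold, 9))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.ones(10, dtype=int), 0)


class TestTrainClassic:
    @pytest.mark.parametrize("family", ["svm", "extra_trees"])
    def test_separable_corpus_high_training_sensitivity(self, family):
        notes, y = _separable_corpus()
        fm, _ = fit_tfidf(notes)
        model = train_classic(
            ModelSpec(family, seed=0), fm.values, y,
            grid=SMALL_GRIDS[family], cv_folds=5,
        )
        pred = model.predict(fm.values)
        sens = pred[y == 1].mean()
        assert sens >= 0.95

    def test_constant_labels_rejected(self):
        notes, _ = _separable_corpus()
        fm, _ = fit_tfidf(notes)
        with pytest.raises(ValueError):
            train_classic(ModelSpec("svm"), fm.values, np.ones(len(notes), int))

    def test_best_params_belong_to_declared_grid(self):
        notes, y = _separable_corpus()
        fm, _ = fit_tfidf(notes)
        model = train_classic(ModelSpec("svm", seed=0), fm.values, y, cv_folds=3)
        assert model.best_params["C"] in CLASSIC_GRIDS["svm"]["clf__C"]
        assert model.best_params["kernel"] in CLASSIC_GRIDS["svm"]["clf__kernel"]

    def test_deterministic_predictions(self):
        notes, y = _separable_corpus()
        fm, _ = fit_tfidf(notes)
        runs = [
            train_classic(
                ModelSpec("extra_trees", seed=4), fm.values, y,
                grid=SMALL_GRIDS["extra_trees"], cv_folds=3,
            ).predict(fm.values)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0], runs[1])


CNN_HP = dict(epochs=40, lr=3e-3, max_len=24, filters=16, embed_dim=24, patience=8)


class TestTrainCnn:
    def test_architecture_alternates_conv_and_pool(self):
        net = TextCNN({"<pad>": 0, "<oov>": 1, "bleeding": 2})
        assert net.n_hidden_layers == 4
        hidden = net.layer_summary[1:-1]
        assert hidden == ["conv1d(relu)", "max_pool", "conv1d(relu)", "global_max_pool"]
        assert net.layer_summary[-1] == "dense(1, sigmoid)"

    def test_separable_corpus_validation_sensitivity(self):
        notes, y = _separable_corpus(n=80, seed=3)
        fitted = train_cnn(ModelSpec("cnn", seed=1), notes, y, **CNN_HP)
        assert fitted.val_sensitivity >= 0.9

    def test_output_in_unit_interval(self):
        notes, y = _separable_corpus(n=60, seed=4)
        fitted = train_cnn(ModelSpec("cnn", seed=2), notes, y, epochs=2, **{
            k: v for k, v in CNN_HP.items() if k != "epochs"
        })
        probs = fitted.predict_proba(notes)
        assert np.all((probs > 0) & (probs < 1))

    def test_too_small_corpus_rejected(self):
        notes, y = _separable_corpus(n=20)
        with pytest.raises(ValueError, match="at least 50"):
            train_cnn(ModelSpec("cnn"), notes, y)
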