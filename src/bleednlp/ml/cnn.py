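"""Word-embedding convolutional network for note classification.

Notes are encoded as sequences of word embeddings and fed through four
hidden layers alternating one-dimensional convolution (ReLU) and max
pooling; the second pool is global over the remaining sequence so the
output layer — a single dense unit with sigmoid activation — sees a
fixed-size vector.  The loss is binary cross-entropy.  Embeddings are
trainable parameters learned from the corpus jointly with the filters, so
no external embedding file is needed; hyperparameters are validated on a
fixed, seeded 80/20 train/validation split with early stopping on
validation loss.

The network is implemented directly on numpy (forward and backward passes,
Adam updates), which keeps training deterministic for a given seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from ..context import Note
from .classic import ModelSpec

__all__ = ["TextCNN", "train_cnn"]

_TOKEN = re.compile(r"[a-z0-9]+")

PAD, OOV = 0, 1

DEFAULTS = dict(
    embed_dim=100,
    filters=64,
    widths=(3, 5),
    max_len=100,
    epochs=30,
    batch_size=32,
    lr=1e-3,
    patience=3,
    min_df=1,
)


def _tokenize(text: str) -> List[str]:
    return _TOKEN.findall(text.lower())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    # X: (B, L, Din); W: (w, Din, F) -> (B, L-w+1, F)
    w = W.shape[0]
    L_out = X.shape[1] - w + 1
    C = np.broadcast_to(b, (X.shape[0], L_out, W.shape[2])).copy()
    for j in range(w):
        C += X[:, j : j + L_out, :] @ W[j]
    return C


def _conv_backward(X, W, dC):
    w = W.shape[0]
    L_out = dC.shape[1]
    dX = np.zeros_like(X)
    dW = np.zeros_like(W)
    for j in range(w):
        seg = X[:, j : j + L_out, :]
        dW[j] = np.einsum("btd,btf->df", seg, dC)
        dX[:, j : j + L_out, :] += dC @ W[j].T
    db = dC.sum(axis=(0, 1))
    return dX, dW, db


class TextCNN:
    """conv1d -> max-pool -> conv1d -> global max-pool -> dense(1, sigmoid)."""

    def __init__(self, vocab: Dict[str, int], seed: int = 0, **hp):
        self.hp = {**DEFAULTS, **hp}
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        D = self.hp["embed_dim"]
        F = self.hp["filters"]
        w1, w2 = self.hp["widths"]
        V = max(vocab.values()) + 1
        s = rng.standard_normal
        self.params: Dict[str, np.ndarray] = {
            "E": 0.1 * s((V, D)),
            "W1": s((w1, D, F)) * np.sqrt(2.0 / (w1 * D)),
            "b1": np.zeros(F),
            "W2": s((w2, F, F)) * np.sqrt(2.0 / (w2 * F)),
            "b2": np.zeros(F),
            "wd": s(F) * np.sqrt(1.0 / F),
            "bd": np.zeros(1),
        }
        self.params["E"][PAD] = 0.0

    # -- layer bookkeeping -------------------------------------------------
    @property
    def layer_summary(self) -> List[str]:
        return [
            "embedding",
            "conv1d(relu)",
            "max_pool",
            "conv1d(relu)",
            "global_max_pool",
            "dense(1, sigmoid)",
        ]

    @property
    def n_hidden_layers(self) -> int:
        return 4  # conv/pool alternation between embedding and output

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        L = self.hp["max_len"]
        ids = np.full((len(texts), L), PAD, dtype=np.int64)
        for i, text in enumerate(texts):
            toks = _tokenize(text)[:L]
            for j, t in enumerate(toks):
                ids[i, j] = self.vocab.get(t, OOV)
        return ids

    def _forward(self, ids: np.ndarray, cache: bool = False):
        p = self.params
        X = p["E"][ids]  # (B, L, D)
        C1 = _conv_forward(X, p["W1"], p["b1"])
        A1 = np.maximum(C1, 0.0)
        B, L1, F = A1.shape
        L1p = L1 // 2
        A1p = A1[:, : 2 * L1p].reshape(B, L1p, 2, F)
        pool1_arg = A1p.argmax(axis=2)
        P1 = np.take_along_axis(A1p, pool1_arg[:, :, None, :], axis=2)[:, :, 0, :]
        C2 = _conv_forward(P1, p["W2"], p["b2"])
        A2 = np.maximum(C2, 0.0)
        pool2_arg = A2.argmax(axis=1)
        P2 = np.take_along_axis(A2, pool2_arg[:, None, :], axis=1)[:, 0, :]
        z = P2 @ p["wd"] + p["bd"]
        prob = _sigmoid(z)
        if not cache:
            return prob
        return prob, dict(
            ids=ids, X=X, C1=C1, A1=A1, L1p=L1p, pool1_arg=pool1_arg,
            P1=P1, C2=C2, A2=A2, pool2_arg=pool2_arg, P2=P2,
        )

    def _backward(self, prob: np.ndarray, y: np.ndarray, c: dict):
        p = self.params
        B = y.size
        dz = (prob - y) / B  # BCE + sigmoid
        grads: Dict[str, np.ndarray] = {}
        grads["wd"] = c["P2"].T @ dz
        grads["bd"] = np.array([dz.sum()])
        dP2 = np.outer(dz, p["wd"])
        dA2 = np.zeros_like(c["A2"])
        np.put_along_axis(dA2, c["pool2_arg"][:, None, :], dP2[:, None, :], axis=1)
        dC2 = dA2 * (c["C2"] > 0)
        dP1, grads["W2"], grads["b2"] = _conv_backward(c["P1"], p["W2"], dC2)
        F = dP1.shape[2]
        dA1p = np.zeros((B, c["L1p"], 2, F))
        np.put_along_axis(dA1p, c["pool1_arg"][:, :, None, :], dP1[:, :, None, :], axis=2)
        dA1 = np.zeros_like(c["A1"])
        dA1[:, : 2 * c["L1p"]] = dA1p.reshape(B, 2 * c["L1p"], F)
        dC1 = dA1 * (c["C1"] > 0)
        dX, grads["W1"], grads["b1"] = _conv_backward(c["X"], p["W1"], dC1)
        dE = np.zeros_like(p["E"])
        np.add.at(dE, c["ids"], dX)
        dE[PAD] = 0.0
        grads["E"] = dE
        return grads

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        return self._forward(self.encode(texts))

    def predict(self, texts: Sequence[str]) -> np.ndarray:
        return (self.predict_proba(texts) >= 0.5).astype(int)


def _build_vocab(texts: Sequence[str], min_df: int) -> Dict[str, int]:
    df: Dict[str, int] = {}
    for text in texts:
        for tok in set(_tokenize(text)):
            df[tok] = df.get(tok, 0) + 1
    vocab = {"<pad>": PAD, "<oov>": OOV}
    for tok in sorted(df):
        if df[tok] >= min_df:
            vocab[tok] = len(vocab)
    return vocab


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))


@dataclass
class FittedCNN:
    spec: ModelSpec
    net: TextCNN
    history: List[dict] = field(default_factory=list)
    val_sensitivity: float = float("nan")

    def predict(self, notes: Sequence[Note]) -> np.ndarray:
        return self.net.predict([n.text for n in notes])

    def predict_proba(self, notes: Sequence[Note]) -> np.ndarray:
        return self.net.predict_proba([n.text for n in notes])


def train_cnn(
    spec: ModelSpec, corpus: Sequence[Note], gold: Sequence[int], **hp
) -> FittedCNN:
    """Train the conv-net on a labeled corpus.

    Uses a fixed, seeded 80/20 train/validation split; stops early when
    validation loss has not improved for ``patience`` epochs and restores
    the best parameters.  Requires at least 50 notes with both classes.
    """
    if spec.family != "cnn":
        raise ValueError("train_cnn requires spec.family == 'cnn'")
    y = np.asarray(gold, dtype=float)
    if len(corpus) != y.size:
        raise ValueError("corpus and labels must have equal length")
    if len(corpus) < 50:
        raise ValueError("need at least 50 notes to train the CNN")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")

    params = {**DEFAULTS, **spec.hyperparameters, **hp}
    rng = np.random.default_rng(spec.seed)
    n = len(corpus)
    order = rng.permutation(n)
    n_val = max(1, int(round(0.2 * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("train split lost a class; corpus too small or skewed")

    texts = [note.text for note in corpus]
    vocab = _build_vocab([texts[i] for i in train_idx], params["min_df"])
    net = TextCNN(vocab, seed=spec.seed, **{
        k: params[k] for k in ("embed_dim", "filters", "widths", "max_len")
    })
    ids = net.encode(texts)
    opt = _Adam(net.params, params["lr"])

    best_loss, best_params, since_best = np.inf, None, 0
    history = []
    bs = params["batch_size"]
    for epoch in range(params["epochs"]):
        perm = rng.permutation(train_idx)
        for start in range(0, perm.size, bs):
            batch = perm[start : start + bs]
            prob, cache = net._forward(ids[batch], cache=True)
            grads = net._backward(prob, y[batch], cache)
            opt.step(net.params, grads)
        val_prob = net._forward(ids[val_idx])
        val_loss = _bce(val_prob, y[val_idx])
        history.append({"epoch": epoch, "val_loss": val_loss})
        if val_loss < best_loss - 1e-6:
            best_loss, since_best = val_loss, 0
            best_params = {k: v.copy() for k, v in net.params.items()}
        else:
            since_best += 1
            if since_best >= params["patience"]:
                break
    if best_params is not None:
        net.params = best_params

    val_pred = (net._forward(ids[val_idx]) >= 0.5).astype(int)
    val_y = y[val_idx].astype(int)
    pos = val_y == 1
    val_sens = float((val_pred[pos] == 1).mean()) if pos.any() else float("nan")
    return FittedCNN(spec=spec, net=net, history=history, val_sensitivity=val_sens)
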