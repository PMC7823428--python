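"""Few-shot classifier heads.

Three classifiers operate on embedder features:

* a linear-softmax head (the transfer-learning "Baseline"),
* a cosine-similarity prototype head ("Baseline++"), where each class is
  represented by a weight vector compared to features by cosine similarity,
* a one-vs-all linear SVM (soft margin C=1), fitted on support embeddings
  after metric learning.

The two softmax heads are trainable (they expose parameters and gradients
for the training pipelines); the SVM wraps scikit-learn's LinearSVC.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import LinearSVC

from . import nn


class LinearSoftmaxHead:
    """Linear layer + softmax over class logits."""

    def __init__(self, dim: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.linear = nn.Linear(dim, n_classes, bias=True, rng=rng)
        self.dim, self.n_classes = dim, n_classes

    def parameters(self) -> list[nn.Param]:
        return self.linear.parameters()

    def logits(self, f: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(f))
        if f.shape[1] != self.dim:
            raise ValueError(f"feature dim {f.shape[1]} != head dim {self.dim}")
        return self.linear.forward(f)

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        return self.linear.backward(grad_logits)

    def predict_proba(self, f: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(f))

    def predict(self, f: np.ndarray) -> np.ndarray:
        return self.logits(f).argmax(axis=1)


def linear_forward(head: LinearSoftmaxHead, f: np.ndarray) -> np.ndarray:
    """Class probabilities softmax(W^T f) for a single feature vector."""
    return head.predict_proba(f)[0] if np.asarray(f).ndim == 1 else head.predict_proba(f)


class CosineHead:
    """Per-class prototype vectors scored by cosine similarity.

    Classification probabilities are the softmax of the similarity vector.
    An optional temperature rescales similarities before the softmax; it is
    off (1.0) by default.
    """

    def __init__(self, dim: int, n_classes: int, seed: int = 0, temperature: float = 1.0):
        rng = np.random.default_rng(seed)
        self.prototypes = nn.Param(rng.normal(0.0, np.sqrt(1.0 / dim), size=(n_classes, dim)))
        self.dim, self.n_classes = dim, n_classes
        self.temperature = temperature

    def parameters(self) -> list[nn.Param]:
        return [self.prototypes]

    def scores(self, f: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(f, dtype=np.float64))
        if f.shape[1] != self.dim:
            raise ValueError(f"feature dim {f.shape[1]} != head dim {self.dim}")
        fn = np.linalg.norm(f, axis=1)
        wn = np.linalg.norm(self.prototypes.data, axis=1)
        if np.any(fn == 0) or np.any(wn == 0):
            raise ValueError("cosine similarity undefined for zero-norm vectors")
        cs = (f @ self.prototypes.data.T.astype(np.float64)) / (fn[:, None] * wn[None, :])
        self._cache = (f, fn, wn, cs)
        return cs

    def logits(self, f: np.ndarray) -> np.ndarray:
        return self.scores(f) * self.temperature

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        """Gradient through the cosine scores to prototypes and features."""
        f, fn, wn, cs = self._cache
        g = np.asarray(grad_logits, dtype=np.float64) * self.temperature
        w = self.prototypes.data.astype(np.float64)
        fhat = f / fn[:, None]
        what = w / wn[:, None]
        # d cs_ij / d w_j = (fhat_i - cs_ij * what_j) / ||w_j||
        gw = (g.T @ fhat) - (g * cs).sum(axis=0)[:, None] * what
        self.prototypes.grad += (gw / wn[:, None]).astype(np.float32)
        # d cs_ij / d f_i = (what_j - cs_ij * fhat_i) / ||f_i||
        gf = (g @ what) - (g * cs).sum(axis=1)[:, None] * fhat
        return (gf / fn[:, None]).astype(np.float32)

    def predict_proba(self, f: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(f))

    def predict(self, f: np.ndarray) -> np.ndarray:
        return self.logits(f).argmax(axis=1)


def cosine_scores(head: CosineHead, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cosine similarities of ``f`` to every prototype, and their softmax."""
    single = np.asarray(f).ndim == 1
    cs = head.scores(f)
    probs = nn.softmax(cs * head.temperature)
    return (cs[0], probs[0]) if single else (cs, probs)


class SvmModel:
    """One-vs-all linear SVM over feature vectors (soft margin C=1)."""

    def __init__(self, C: float = 1.0, normalize: bool = False):
        self.C = C
        self.normalize = normalize
        self._svc: LinearSVC | None = None

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.normalize:
            X = X / (np.linalg.norm(X, axis=1, keepdims=True) + 1e-12)
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SvmModel":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("SVM needs at least two classes")
        # dual=False -> deterministic primal liblinear solve
        self._svc = LinearSVC(C=self.C, dual=False)
        self._svc.fit(self._prep(X), y)
        return self

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        assert self._svc is not None, "fit first"
        return self._svc.decision_function(self._prep(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        assert self._svc is not None, "fit first"
        return self._svc.predict(self._prep(X))


def svm_fit(features: np.ndarray, labels: np.ndarray, C: float = 1.0,
            normalize: bool = False) -> SvmModel:
    return SvmModel(C=C, normalize=normalize).fit(features, labels)


def svm_predict(model: SvmModel, features: np.ndarray) -> np.ndarray:
    single = np.asarray(features).ndim == 1
    pred = model.predict(features)
    return pred[0] if single else pred
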