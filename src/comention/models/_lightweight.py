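"""A fast linear classifier over bag-of-token-id counts.

This is a desk-scale stand-in that lets the whole pipeline run in seconds;
it honors the same contract as the neural classifiers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression

from ..preprocessing import PAD_ID, EncodedExample
from ._nn import _examples_to_matrix, _labels


class LightweightClassifier:
    """Logistic regression on token-id count vectors (pad excluded)."""

    def __init__(self, C: float = 1.0):
        self.C = C
        self._clf: LogisticRegression | None = None
        self._n_features: int | None = None
        self._L: int | None = None

    def _featurize(self, X: np.ndarray) -> sparse.csr_matrix:
        n, L = X.shape
        rows = np.repeat(np.arange(n), L)
        cols = X.ravel()
        data = (cols != PAD_ID).astype(np.float64)
        m = sparse.csr_matrix((data, (rows, cols)), shape=(n, self._n_features))
        m.sum_duplicates()
        return m

    def fit(self, examples: Sequence[EncodedExample], cfg) -> "LightweightClassifier":
        X = _examples_to_matrix(examples)
        y = _labels(examples)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self._L = X.shape[1]
        self._n_features = int(X.max()) + 1
        self._clf = LogisticRegression(C=self.C, max_iter=1000, random_state=cfg.seed)
        self._clf.fit(self._featurize(X), y)
        return self

    def predict_proba(self, examples: Sequence[EncodedExample]) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("classifier not fitted")
        X = _examples_to_matrix(examples)
        if X.shape[1] != self._L:
            raise ValueError(f"encoded length {X.shape[1]} != fitted length {self._L}")
        X = np.where(X >= self._n_features, PAD_ID, X)  # drop ids unseen in training
        raw = self._clf.predict_proba(self._featurize(X))
        out = np.zeros((raw.shape[0], 2))
        for i, cls in enumerate(self._clf.classes_):
            out[:, int(cls)] = raw[:, i]
        return out

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "L": self._L,
            "n_features": self._n_features,
            "coef": self._clf.coef_.tolist(),
            "intercept": self._clf.intercept_.tolist(),
            "classes": self._clf.classes_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightweightClassifier":
        obj = cls(C=d["C"])
        obj._L = d["L"]
        obj._n_features = d["n_features"]
        clf = LogisticRegression(C=d["C"], max_iter=1000)
        clf.coef_ = np.asarray(d["coef"])
        clf.intercept_ = np.asarray(d["intercept"])
        clf.classes_ = np.asarray(d["classes"])
        obj._clf = clf
        return obj
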