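"""Classifier contract, concrete classifiers and the probability-averaging
ensemble.

A classifier is anything with ``fit(examples, cfg)`` and
``predict_proba(examples) -> (n, 2) array``: rows are probability vectors,
``fit`` is deterministic given ``cfg.seed`` and ``predict_proba`` is
deterministic after ``fit``.  The ensemble combines members by the
unweighted arithmetic mean of their probability vectors; its confidence is
the mean positive-class probability.

An optional pretrained-transformer classifier can be plugged in at runtime
with :func:`register_base_classifier`; no pretrained weights are required
to build or test the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from ..preprocessing import EncodedExample
from ._lightweight import LightweightClassifier
from ._nn import CNNClassifier, RNNClassifier

__all__ = [
    "Classifier",
    "TrainConfig",
    "Prediction",
    "EnsembleModel",
    "train_classifier",
    "predict_proba",
    "ensemble_predict",
    "register_base_classifier",
    "save_model",
    "load_model",
    "CNNClassifier",
    "RNNClassifier",
    "LightweightClassifier",
]


@runtime_checkable
class Classifier(Protocol):
    def fit(self, examples: Sequence[EncodedExample], cfg: "TrainConfig") -> "Classifier": ...

    def predict_proba(self, examples: Sequence[EncodedExample]) -> np.ndarray: ...


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters shared by all classifier kinds.

    The CNN/RNN models train for ``epochs_cnn_rnn`` epochs with
    cross-entropy loss under Adam; a pluggable pretrained base model
    fine-tunes for ``epochs_base`` epochs.
    """

    epochs_cnn_rnn: int = 20
    epochs_base: int = 4
    seed: int = 0
    embedding_dim: int = 100
    cnn_filter_widths: tuple[int, ...] = (3, 4, 5)
    cnn_filters_per_width: int = 100
    rnn_hidden_size: int = 128
    batch_size: int = 32
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.epochs_cnn_rnn < 1 or self.epochs_base < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class Prediction:
    """Class probabilities plus the derived label and confidence.

    ``predicted_class`` is the argmax with ties resolved to class 0 (do not
    assert a relation on a tie); ``confidence`` is the positive-class
    probability.
    """

    probs: tuple[float, float]
    predicted_class: int
    confidence: float


_KIND_FACTORIES: dict[str, Callable[[TrainConfig], Classifier]] = {
    "cnn": lambda cfg: CNNClassifier(cfg.embedding_dim, cfg.cnn_filter_widths, cfg.cnn_filters_per_width),
    "rnn": lambda cfg: RNNClassifier(cfg.embedding_dim, cfg.rnn_hidden_size),
    "lightweight": lambda cfg: LightweightClassifier(),
}

_BASE_FACTORY: Callable[[TrainConfig], Classifier] | None = None


def register_base_classifier(factory: Callable[[TrainConfig], Classifier]) -> None:
    """Register a factory for the optional pretrained base model (kind
    ``"base"``), e.g. a transformer fine-tuner."""
    global _BASE_FACTORY
    _BASE_FACTORY = factory


def train_classifier(
    train: Sequence[EncodedExample], kind: str, cfg: TrainConfig = TrainConfig()
) -> Classifier:
    """Build and fit a classifier of the given kind on labeled examples."""
    if kind == "base":
        if _BASE_FACTORY is None:
            raise RuntimeError(
                "no base classifier registered; call register_base_classifier() "
                "with a pretrained-model factory, or use kind 'cnn', 'rnn' or 'lightweight'"
            )
        model = _BASE_FACTORY(cfg)
    elif kind in _KIND_FACTORIES:
        model = _KIND_FACTORIES[kind](cfg)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    model.fit(train, cfg)
    return model


def predict_proba(model: Classifier, examples: Sequence[EncodedExample]) -> np.ndarray:
    """Per-example probability vectors, order preserved, rows summing to 1."""
    probs = np.asarray(model.predict_proba(examples), dtype=np.float64)
    if probs.shape != (len(examples), 2):
        raise ValueError(f"expected shape {(len(examples), 2)}, got {probs.shape}")
    if len(examples) and not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("probability rows must sum to 1")
    return probs


@dataclass
class EnsembleModel:
    """An ordered collection of fitted classifiers combined by averaging."""

    members: list = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble requires at least one member")
        if self.kinds and len(self.kinds) != len(self.members):
            raise ValueError("kinds must align with members")

    def predict_proba(self, examples: Sequence[EncodedExample]) -> np.ndarray:
        stacked = np.stack([predict_proba(m, examples) for m in self.members])
        return stacked.mean(axis=0)


def _to_prediction(row: np.ndarray) -> Prediction:
    predicted = 1 if row[1] > row[0] else 0
    return Prediction(probs=(float(row[0]), float(row[1])), predicted_class=predicted, confidence=float(row[1]))


def ensemble_predict(ensemble: EnsembleModel, examples: Sequence[EncodedExample]) -> list[Prediction]:
    """Average member probabilities and derive class/confidence per example."""
    return [_to_prediction(row) for row in ensemble.predict_proba(examples)]


def classifier_predict(model: Classifier, examples: Sequence[EncodedExample]) -> list[Prediction]:
    """Predictions from a single classifier (same derivation as the ensemble)."""
    return [_to_prediction(row) for row in predict_proba(model, examples)]


# ---------------------------------------------------------------------------
# serialization: one JSON archive per model (weights + optional extras)
# ---------------------------------------------------------------------------

_SERIAL_KINDS = {
    "cnn": CNNClassifier,
    "rnn": RNNClassifier,
    "lightweight": LightweightClassifier,
}


def _member_to_dict(model: Classifier) -> dict:
    for kind, cls in _SERIAL_KINDS.items():
        if isinstance(model, cls):
            return {"kind": kind, "state": model.to_dict()}
    raise TypeError(f"cannot serialize classifier of type {type(model).__name__}")


def _member_from_dict(d: dict) -> Classifier:
    return _SERIAL_KINDS[d["kind"]].from_dict(d["state"])


def save_model(model: Classifier | EnsembleModel, path: str | Path, extras: dict | None = None) -> None:
    """Write a model (single classifier or ensemble) to a JSON archive.

    ``extras`` may carry the vocabulary and preprocessing config so one file
    is a self-contained scoring artifact.
    """
    if isinstance(model, EnsembleModel):
        payload = {"type": "ensemble", "members": [_member_to_dict(m) for m in model.members]}
    else:
        payload = {"type": "single", "model": _member_to_dict(model)}
    if extras:
        payload["extras"] = extras
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> tuple[Classifier | EnsembleModel, dict]:
    """Inverse of :func:`save_model`; returns (model, extras)."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    extras = payload.get("extras", {})
    if payload["type"] == "ensemble":
        members = [_member_from_dict(d) for d in payload["members"]]
        kinds = [d["kind"] for d in payload["members"]]
        return EnsembleModel(members=members, kinds=kinds), extras
    return _member_from_dict(payload["model"]), extras
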