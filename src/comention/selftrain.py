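"""Self-training pipeline: fit a base classifier on the small labeled set,
pseudo-label an unlabeled pool, add a validation-tuned number of confident
predictions to the training set, and train the CNN+RNN averaging ensemble
on the expanded set.

"Top predictions" is operationalized as threshold-then-sample: the
confidence threshold tau defines the candidate set, and k members are drawn
from it uniformly at random (seeded).  Under the default
``preserve_labeled_ratio`` policy the per-class quotas follow the labeled
training set's class ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._seeding import derive_seed
from .evaluation import compute_auroc, compute_metrics
from .models import (
    Classifier,
    EnsembleModel,
    Prediction,
    TrainConfig,
    classifier_predict,
    ensemble_predict,
    train_classifier,
)
from .preprocessing import EncodedExample

logger = logging.getLogger(__name__)

__all__ = [
    "SelfTrainConfig",
    "PseudoLabeledSet",
    "select_pseudolabels",
    "choose_added_size",
    "run_pipeline",
    "train_ensemble",
]

DEFAULT_ADDED_SIZES = (1000, 2000, 3000, 5000, 10000)


@dataclass(frozen=True)
class SelfTrainConfig:
    """Pseudo-label selection threshold, candidate added sizes and policy."""

    confidence_threshold: float = 0.9
    candidate_added_sizes: tuple[int, ...] = DEFAULT_ADDED_SIZES
    default_k: int = 5000
    class_ratio_policy: str = "preserve_labeled_ratio"
    selection_repeats: int = 1
    rounds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must be in (0.5, 1]")
        if any(k <= 0 for k in self.candidate_added_sizes):
            raise ValueError("candidate added sizes must be positive")
        if self.default_k != 0 and self.default_k not in self.candidate_added_sizes:
            raise ValueError("default_k must be 0 or one of candidate_added_sizes")
        if self.class_ratio_policy not in ("preserve_labeled_ratio", "natural"):
            raise ValueError(f"unknown class_ratio_policy {self.class_ratio_policy!r}")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass(frozen=True)
class PseudoLabeledSet:
    """Pool examples selected for training, relabeled with the base model's
    predicted class; ``confidences`` are the predicted-class probabilities."""

    examples: tuple[EncodedExample, ...]
    confidences: tuple[float, ...]
    pool_indices: tuple[int, ...]
    shortfall: bool = False

    def __len__(self) -> int:
        return len(self.examples)

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {0: 0, 1: 0}
        for e in self.examples:
            counts[e.label] += 1
        return counts


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_pseudolabels(
    pool: Sequence[EncodedExample],
    pool_predictions: Sequence[Prediction],
    k: int,
    cfg: SelfTrainConfig = SelfTrainConfig(),
    labeled_positive_fraction: float | None = None,
) -> PseudoLabeledSet:
    """Select up to ``k`` confident pool predictions as pseudo-labeled examples.

    Candidates are pool members whose predicted-class probability reaches
    ``cfg.confidence_threshold``; ``k`` of them are sampled uniformly at
    random (seeded).  Under ``preserve_labeled_ratio`` the positive quota is
    round-half-up(k * labeled_positive_fraction); a class whose candidate
    pool falls short contributes everything it has (no backfill) and the
    shortfall is logged.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if len(pool) != len(pool_predictions):
        raise ValueError("pool and predictions must align")
    tau = cfg.confidence_threshold
    cand: dict[int, list[int]] = {0: [], 1: []}
    for i, pred in enumerate(pool_predictions):
        if pred.probs[pred.predicted_class] >= tau:
            cand[pred.predicted_class].append(i)
    n_cand = len(cand[0]) + len(cand[1])
    if n_cand == 0 or k == 0:
        if n_cand == 0 and k > 0:
            logger.warning("no pool predictions reach threshold %.3f; empty selection", tau)
        return PseudoLabeledSet((), (), (), shortfall=k > 0)

    rng = np.random.default_rng(derive_seed(cfg.seed, "select_pseudolabels"))
    if cfg.class_ratio_policy == "preserve_labeled_ratio":
        if labeled_positive_fraction is None:
            raise ValueError("preserve_labeled_ratio policy requires labeled_positive_fraction")
        quotas = {1: _round_half_up(k * labeled_positive_fraction)}
        quotas[0] = k - quotas[1]
    else:
        quotas = None

    chosen: list[int] = []
    shortfall = False
    if quotas is None:
        all_cand = np.array(cand[0] + cand[1])
        take = min(k, len(all_cand))
        shortfall = take < k
        chosen = sorted(rng.choice(all_cand, size=take, replace=False).tolist())
    else:
        for cls in (1, 0):
            pool_cls = np.array(cand[cls], dtype=np.int64)
            take = min(quotas[cls], len(pool_cls))
            if take < quotas[cls]:
                shortfall = True
                logger.warning(
                    "class %d: only %d candidates for quota %d; taking all (no backfill)",
                    cls, len(pool_cls), quotas[cls],
                )
            if take:
                chosen.extend(rng.choice(pool_cls, size=take, replace=False).tolist())
        chosen.sort()

    examples = []
    confidences = []
    for i in chosen:
        pred = pool_predictions[i]
        examples.append(replace(pool[i], label=pred.predicted_class))
        confidences.append(pred.probs[pred.predicted_class])
    return PseudoLabeledSet(tuple(examples), tuple(confidences), tuple(chosen), shortfall=shortfall)


def _positive_fraction(examples: Sequence[EncodedExample]) -> float:
    labels = [e.label for e in examples]
    return sum(labels) / len(labels)


def train_ensemble(
    train: Sequence[EncodedExample],
    kinds: Sequence[str],
    tcfg: TrainConfig,
) -> EnsembleModel:
    """Fit one classifier per kind with per-member derived seeds."""
    members = [
        train_classifier(train, kind, replace(tcfg, seed=derive_seed(tcfg.seed, f"member:{i}:{kind}")))
        for i, kind in enumerate(kinds)
    ]
    return EnsembleModel(members=members, kinds=list(kinds))


def _f1_on(model, examples: Sequence[EncodedExample]) -> float:
    preds = ensemble_predict(model, examples) if isinstance(model, EnsembleModel) else classifier_predict(model, examples)
    labels = [e.label for e in examples]
    predicted = [p.predicted_class for p in preds]
    _, _, _, f1 = compute_metrics(labels, predicted)
    return f1


def choose_added_size(
    base: Classifier,
    pool: Sequence[EncodedExample],
    train: Sequence[EncodedExample],
    validation: Sequence[EncodedExample],
    cfg: SelfTrainConfig = SelfTrainConfig(),
    tcfg: TrainConfig = TrainConfig(),
    ensemble_kinds: Sequence[str] = ("cnn", "rnn"),
) -> int:
    """Pick the added size k* maximizing mean validation F1 of the downstream
    ensemble, over candidates plus the k=0 baseline; ties go to the smallest k.
    """
    train_keys = {id(e.source) for e in train if e.source is not None}
    val_keys = {id(e.source) for e in validation if e.source is not None}
    if train_keys and val_keys and train_keys & val_keys:
        raise ValueError("validation set must be disjoint from train")
    candidates = sorted(set(cfg.candidate_added_sizes) | {0})
    if not cfg.candidate_added_sizes:
        return 0
    pool_predictions = classifier_predict(base, pool)
    pos_frac = _positive_fraction(train)
    best_k, best_f1 = 0, -1.0
    for k in candidates:
        f1s = []
        for rep in range(cfg.selection_repeats):
            rep_seed = derive_seed(cfg.seed, f"choose_added_size:{k}:{rep}")
            selection = select_pseudolabels(
                pool, pool_predictions, k, replace(cfg, seed=rep_seed), pos_frac
            )
            expanded = list(train) + list(selection.examples)
            ensemble = train_ensemble(expanded, ensemble_kinds, replace(tcfg, seed=rep_seed))
            f1s.append(_f1_on(ensemble, validation))
        mean_f1 = float(np.mean(f1s))
        if mean_f1 > best_f1 + 1e-12:
            best_k, best_f1 = k, mean_f1
    return best_k


def run_pipeline(
    train: Sequence[EncodedExample],
    validation: Sequence[EncodedExample],
    pool: Sequence[EncodedExample],
    k: int,
    cfg: SelfTrainConfig = SelfTrainConfig(),
    tcfg: TrainConfig = TrainConfig(),
    base_kind: str = "lightweight",
    ensemble_kinds: Sequence[str] = ("cnn", "rnn"),
) -> tuple[EnsembleModel, dict]:
    """Run one self-training round and train the final ensemble.

    With ``k=0`` the pseudo-labeling stages are skipped entirely, so the
    result is identical to a purely supervised run with the same seed.
    Returns the fitted ensemble and a JSON-serializable run report.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    val_keys = {e.source.key() for e in validation if e.source is not None}
    train_keys = {e.source.key() for e in train if e.source is not None}
    if val_keys & train_keys:
        raise ValueError("validation records leak into the training set")

    report: dict = {
        "k": k,
        "base_kind": base_kind if k > 0 else None,
        "ensemble_kinds": list(ensemble_kinds),
        "seed": cfg.seed,
        "train_size": len(train),
        "train_class_counts": _class_counts(train),
        "rounds": cfg.rounds if k > 0 else 0,
    }

    expanded = list(train)
    selections: list[dict] = []
    if k > 0:
        pos_frac = _positive_fraction(train)
        for round_i in range(cfg.rounds):
            base_seed = derive_seed(cfg.seed, f"base:{round_i}")
            base = train_classifier(expanded, base_kind, replace(tcfg, seed=base_seed))
            pool_predictions = classifier_predict(base, pool)
            selection = select_pseudolabels(
                pool,
                pool_predictions,
                k,
                replace(cfg, seed=derive_seed(cfg.seed, f"select:{round_i}")),
                pos_frac,
            )
            # never re-add the same pool item across rounds
            pool = [e for i, e in enumerate(pool) if i not in set(selection.pool_indices)]
            expanded.extend(selection.examples)
            selections.append(
                {
                    "round": round_i,
                    "selected": len(selection),
                    "selected_class_counts": selection.class_counts,
                    "shortfall": selection.shortfall,
                }
            )
    report["selections"] = selections
    report["expanded_size"] = len(expanded)
    report["expanded_class_counts"] = _class_counts(expanded)

    ensemble = train_ensemble(expanded, ensemble_kinds, tcfg)

    if validation:
        preds = ensemble_predict(ensemble, validation)
        labels = [e.label for e in validation]
        predicted = [p.predicted_class for p in preds]
        _, precision, recall, f1 = compute_metrics(labels, predicted)
        scores = [p.confidence for p in preds]
        try:
            auroc = compute_auroc(labels, scores)
        except ValueError:
            auroc = None
        report["validation"] = {"precision": precision, "recall": recall, "f1": f1, "auroc": auroc}
    return ensemble, report


def _class_counts(examples: Sequence[EncodedExample]) -> dict[str, int]:
    counts = {"0": 0, "1": 0}
    for e in examples:
        counts[str(e.label)] += 1
    return counts
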