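"""Precision/recall/F1/AUROC metrics, the repeated hold-out protocol and
paired significance testing.

Conventions: metrics with a zero denominator are defined as 0; AUROC uses
the rank-statistic (Mann-Whitney) formulation, which is exact under ties;
SD across repeats uses the population (n) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ComparisonReport",
    "compute_metrics",
    "compute_auroc",
    "repeated_holdout",
    "paired_ttest",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Mean/SD of each metric over repeats, with the per-repeat values kept
    in seed order so reports can be paired for significance testing."""

    per_repeat: tuple[dict, ...]
    seeds: tuple[int, ...]

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    def values(self, metric: str) -> list[float]:
        return [r[metric] for r in self.per_repeat]

    def mean(self, metric: str) -> float:
        return float(np.mean(self.values(metric)))

    def sd(self, metric: str) -> float:
        # population (n) denominator, matching a single SD over the repeats
        return float(np.std(self.values(metric)))

    def summary(self) -> dict:
        out: dict = {"n_repeats": self.n_repeats, "seeds": list(self.seeds)}
        for m in ("precision", "recall", "f1", "auroc"):
            vals = [v for v in self.values(m) if v is not None]
            if vals:
                out[m] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
        out["per_repeat"] = list(self.per_repeat)
        return out


@dataclass(frozen=True)
class ComparisonReport:
    name_x: str
    name_y: str
    metric: str
    x: tuple[float, ...]
    y: tuple[float, ...]
    t_statistic: float
    p_value: float


def compute_metrics(
    labels: Sequence[int], predicted: Sequence[int]
) -> tuple[ConfusionCounts, float, float, float]:
    """Confusion counts plus precision, recall and F1.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); any metric
    with a zero denominator is 0.
    """
    if len(labels) != len(predicted):
        raise ValueError("labels and predictions must have equal length")
    if len(labels) == 0:
        raise ValueError("need at least one example")
    y = np.asarray(labels, dtype=np.int64)
    p = np.asarray(predicted, dtype=np.int64)
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ConfusionCounts(tp, fp, fn, tn), precision, recall, f1


def compute_auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AUROC as the probability a random positive outranks a random negative,
    ties counting 1/2 (computed from rank sums; exact under ties)."""
    y = np.asarray(labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = stats.rankdata(s)  # average ranks under ties
    pos_rank_sum = float(ranks[y == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def repeated_holdout(
    pipeline_factory: Callable[[int], tuple[Sequence[int], Sequence[int], Sequence[float]]],
    seeds: Sequence[int],
) -> MetricsReport:
    """Run the pipeline once per seed on the SAME fixed partition.

    ``pipeline_factory(seed)`` must train with the given seed and return
    (test labels, predicted labels, positive-class scores) — the data split
    itself stays fixed across repeats; only model seeds vary.  Per-repeat
    metrics are retained in seed order for later pairing.
    """
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    if not seeds:
        raise ValueError("need at least one seed")
    per_repeat = []
    for seed in seeds:
        labels, predicted, scores = pipeline_factory(seed)
        _, precision, recall, f1 = compute_metrics(labels, predicted)
        try:
            auroc = compute_auroc(labels, scores)
        except ValueError:
            auroc = None
        per_repeat.append(
            {"seed": seed, "precision": precision, "recall": recall, "f1": f1, "auroc": auroc}
        )
    return MetricsReport(per_repeat=tuple(per_repeat), seeds=tuple(seeds))


def paired_ttest(
    x: Sequence[float],
    y: Sequence[float],
    name_x: str = "x",
    name_y: str = "y",
    metric: str = "f1",
) -> ComparisonReport:
    """Two-sided paired t-test on aligned per-seed metric vectors.

    Degenerate conventions: all-zero differences -> t=0, p=1; nonzero
    differences with zero variance -> p=0.
    """
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    n = len(d)
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        t_stat, p = (0.0, 1.0) if mean == 0.0 else (float(np.inf) if mean > 0 else float(-np.inf), 0.0)
    else:
        t_stat = mean / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    return ComparisonReport(
        name_x=name_x, name_y=name_y, metric=metric,
        x=tuple(map(float, x)), y=tuple(map(float, y)),
        t_statistic=float(t_stat), p_value=float(p),
    )
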