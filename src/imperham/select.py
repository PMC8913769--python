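"""Greedy mRMR screening of the representation pool into nested input sets.

The criterion is the classic MID (mutual-information difference) scheme:
the first feature maximises relevance I(x; y); each subsequent pick maximises
relevance minus the mean mutual information with the features already chosen.
Continuous features are discretised into three bins split at mean +/- one
standard deviation; continuous targets into three equal-frequency bins;
integer class labels are used as-is.  Ties always resolve to the lower column
index, so rankings are reproducible and invariant to sample order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .featurize import FeatureMatrix

__all__ = [
    "SelectionResult",
    "mutual_information",
    "discretize_feature",
    "discretize_target",
    "mrmr_select",
    "parse_sizes",
]


@dataclass
class SelectionResult:
    """Ranked columns plus the nested per-size candidate sets (prefixes)."""

    ranked_columns: list[str]
    scores: list[float]
    sizes: list[int]
    per_size_sets: dict[int, list[str]]

    def __post_init__(self) -> None:
        for k, cols in self.per_size_sets.items():
            if cols != self.ranked_columns[:k]:
                raise ValueError(f"per_size_sets[{k}] is not a ranking prefix")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ranked_columns": self.ranked_columns,
                    "scores": self.scores,
                    "sizes": self.sizes,
                    "per_size_sets": {str(k): v for k, v in self.per_size_sets.items()},
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            ranked_columns=d["ranked_columns"],
            scores=d["scores"],
            sizes=d["sizes"],
            per_size_sets={int(k): v for k, v in d["per_size_sets"].items()},
        )


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information, in nats, between two discrete vectors.

    I(x; y) = sum_ab p(a,b) ln[p(a,b) / (p(a) p(b))] with empirical joint
    probabilities; I(x; x) equals the empirical entropy of x.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if x.size < 2:
        raise ValueError("need at least two samples")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (px @ py)[mask])))


def discretize_feature(x: np.ndarray) -> np.ndarray:
    """Three levels split at mean - std and mean + std (constant -> one level)."""
    x = np.asarray(x, dtype=float)
    mu, sigma = x.mean(), x.std()
    return np.digitize(x, [mu - sigma, mu + sigma])


def discretize_target(y: np.ndarray) -> np.ndarray:
    """Class labels pass through; continuous targets get 3 equal-frequency bins."""
    y = np.asarray(y)
    if y.dtype.kind in "ib" or np.all(y == np.round(y)) and np.unique(y).size <= 10:
        return y
    edges = np.quantile(y, [1 / 3, 2 / 3])
    return np.digitize(y, edges)


def mrmr_select(
    fm: FeatureMatrix,
    target: np.ndarray,
    sizes: Sequence[int],
) -> SelectionResult:
    """Rank columns by greedy MID mRMR and return nested candidate sets.

    Deterministic: the incumbent at each step is the first column (original
    order) attaining the maximal score.
    """
    target = np.asarray(target)
    if target.shape != (fm.n_samples,):
        raise ValueError("target length must match the sample count")
    if np.unique(target).size < 2:
        raise ValueError("target is constant")
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes:
        raise ValueError("no sizes requested")
    if sizes[0] < 1 or sizes[-1] > len(fm.columns):
        raise ValueError(
            f"sizes must lie in [1, {len(fm.columns)}], got {sizes[0]}..{sizes[-1]}"
        )
    k_max = sizes[-1]

    disc = np.column_stack([discretize_feature(fm.values[:, j])
                            for j in range(len(fm.columns))])
    y = discretize_target(target)

    n_cols = disc.shape[1]
    relevance = np.array([mutual_information(disc[:, j], y) for j in range(n_cols)])
    redundancy_sum = np.zeros(n_cols)
    selected: list[int] = []
    scores: list[float] = []
    available = np.ones(n_cols, dtype=bool)
    for _ in range(k_max):
        if selected:
            score = relevance - redundancy_sum / len(selected)
        else:
            score = relevance.copy()
        score[~available] = -np.inf
        pick = int(np.argmax(score))  # argmax -> lowest index on ties
        selected.append(pick)
        scores.append(float(score[pick]))
        available[pick] = False
        mi_new = np.array(
            [mutual_information(disc[:, j], disc[:, pick]) if available[j] else 0.0
             for j in range(n_cols)]
        )
        redundancy_sum += mi_new

    ranked = [fm.columns[j] for j in selected]
    return SelectionResult(
        ranked_columns=ranked,
        scores=scores,
        sizes=list(sizes),
        per_size_sets={k: ranked[:k] for k in sizes},
    )


def parse_sizes(spec: str) -> list[int]:
    """CLI grammar: '4:45' inclusive range, or comma list '4,8,16'."""
    if ":" in spec:
        lo, hi = spec.split(":")
        return list(range(int(lo), int(hi) + 1))
    return [int(s) for s in spec.split(",")]
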