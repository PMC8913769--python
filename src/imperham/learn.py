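"""Capacity-controlled learning protocols on representation matrices.

Regression uses deliberately small single-hidden-layer networks (tanh hidden,
linear output) whose size is capped so that the training partition supplies
roughly ten samples per adjustable constant.  A candidate architecture only
becomes the incumbent after *replica validation*: retrained from its
optimised weights under many fresh random 60/15/25 splits, it is accepted
only when a Welch t-test finds no significant difference between training
and validation unsigned errors in at least 80% of replicas — a direct guard
against accepting an overfit network.  Classification uses a soft-margin
linear SVM with unit box constraint.  Splits are optionally group-aware:
all conformers of one parent system land in the same partition so that
reported test errors are not interpolation artefacts.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .chem_io import ConformerGroup
from .featurize import FeatureMatrix

__all__ = [
    "mue",
    "rmse",
    "bayes_mue",
    "DatasetSplit",
    "make_split",
    "max_hidden_units",
    "parameter_count",
    "AnnModel",
    "TrainResult",
    "train_ann",
    "protocol_search",
    "ReplicaValidationReport",
    "replica_validate",
    "train_svm",
    "PresenceReport",
    "presence_analysis",
]


# ---------------------------------------------------------------------------
# Error metrics (kcal/mol throughout the regression tasks)
# ---------------------------------------------------------------------------

def _check_pair(y_exp: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape or y_exp.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if y_exp.size == 0:
        raise ValueError("empty vectors")
    return y_exp, y_pred


def mue(y_exp: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean unsigned error: (1/N) sum |y_exp - y_pred|."""
    y_exp, y_pred = _check_pair(y_exp, y_pred)
    return float(np.mean(np.abs(y_exp - y_pred)))


def rmse(y_exp: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error: sqrt((1/N) sum (y_exp - y_pred)^2)."""
    y_exp, y_pred = _check_pair(y_exp, y_pred)
    return float(np.sqrt(np.mean((y_exp - y_pred) ** 2)))


def bayes_mue(sigma: float) -> float:
    """MUE of the optimal predictor under additive Gaussian noise: sigma*sqrt(2/pi)."""
    return float(sigma) * math.sqrt(2.0 / math.pi)


# ---------------------------------------------------------------------------
# Dataset partitioning
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    """Disjoint train/validation/test id lists covering the full dataset."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int
    group_aware: bool = False

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if total != len(parts[0] | parts[1] | parts[2]):
            raise ValueError("split partitions overlap")

    def indices(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pos = {s: i for i, s in enumerate(sample_ids)}
        return (
            np.array([pos[s] for s in self.train_ids], dtype=int),
            np.array([pos[s] for s in self.val_ids], dtype=int),
            np.array([pos[s] for s in self.test_ids], dtype=int),
        )


def make_split(
    ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.60, 0.15, 0.25),
    groups: Mapping[str, str] | Sequence[ConformerGroup] | None = None,
    seed: int = 0,
) -> DatasetSplit:
    """Seeded 60/15/25 split; with ``groups``, whole groups stay together.

    Groups are shuffled and assigned greedily, each to the partition with the
    largest remaining sample-count deficit, so realized sizes track the
    requested fractions as closely as atomic groups allow.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    ids = [str(s) for s in ids]
    rng = np.random.default_rng(seed)

    if groups is None:
        blocks = [[s] for s in ids]
    else:
        if isinstance(groups, Mapping):
            by_group: dict[str, list[str]] = {}
            for s in ids:
                by_group.setdefault(str(groups[s]), []).append(s)
            blocks = list(by_group.values())
        else:
            blocks = [list(g.members) for g in groups]
            covered = {m for b in blocks for m in b}
            if covered != set(ids):
                raise ValueError("groups do not cover exactly the given ids")

    order = rng.permutation(len(blocks))
    n = len(ids)
    targets = [f * n for f in fractions]
    counts = [0.0, 0.0, 0.0]
    parts: tuple[list[str], list[str], list[str]] = ([], [], [])
    for bi in order:
        block = blocks[bi]
        if any(len(block) > t for t in targets):
            warnings.warn(
                f"group of size {len(block)} exceeds a partition target; "
                "assigned atomically anyway"
            )
        deficits = [t - c for t, c in zip(targets, counts)]
        p = int(np.argmax(deficits))  # ties -> train, then val, then test
        parts[p].extend(block)
        counts[p] += len(block)
    return DatasetSplit(
        train_ids=parts[0], val_ids=parts[1], test_ids=parts[2],
        seed=int(seed), group_aware=groups is not None,
    )


# ---------------------------------------------------------------------------
# Capacity rule
# ---------------------------------------------------------------------------

def parameter_count(n_inputs: int, hidden: int) -> int:
    """Adjustable constants of a d-input, h-hidden, 1-output network:
    (d+1)h input-side weights and biases plus (h+1) output-side."""
    return (n_inputs + 1) * hidden + (hidden + 1)


def max_hidden_units(
    n_train: int, n_inputs: int, samples_per_param: float = 10.0
) -> int:
    """Largest h >= 1 with parameter_count <= n_train / samples_per_param.

    Returns 0 when even a single hidden unit would violate the bound.  The
    default of ten training samples per constant is a soft cap against
    memorization; callers may relax it (with a loud warning at train time).
    """
    if n_train < 1 or n_inputs < 1:
        raise ValueError("n_train and n_inputs must be >= 1")
    budget = n_train / samples_per_param
    h = int((budget - 1.0) / (n_inputs + 2))
    return max(h, 0)


# ---------------------------------------------------------------------------
# Single-hidden-layer ANN regression
# ---------------------------------------------------------------------------

@dataclass
class AnnModel:
    """A fitted d-input single-hidden-layer tanh network with linear output.

    Inputs are standardized per column with training-partition statistics;
    the target is standardized internally and predictions are returned on the
    original scale.
    """

    input_columns: list[str]
    hidden_units: int
    w1: np.ndarray  # (h, d)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h,)
    b2: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    seed: int

    @property
    def n_parameters(self) -> int:
        return parameter_count(len(self.input_columns), self.hidden_units)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = (np.asarray(x, dtype=float) - self.x_mean) / self.x_std
        h = np.tanh(x @ self.w1.T + self.b1)
        return (h @ self.w2 + self.b2) * self.y_std + self.y_mean

    def predict_fm(self, fm: FeatureMatrix) -> np.ndarray:
        return self.predict(fm.subset_columns(self.input_columns).values)

    def weights_vector(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2, [self.b2]])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "input_columns": self.input_columns,
            "hidden_units": self.hidden_units,
            "w1": self.w1.ravel().tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "seed": self.seed,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnModel":
        d = json.loads(Path(path).read_text())
        h, ncol = d["hidden_units"], len(d["input_columns"])
        return cls(
            input_columns=d["input_columns"],
            hidden_units=h,
            w1=np.array(d["w1"]).reshape(h, ncol),
            b1=np.array(d["b1"]),
            w2=np.array(d["w2"]),
            b2=float(d["b2"]),
            x_mean=np.array(d["x_mean"]),
            x_std=np.array(d["x_std"]),
            y_mean=float(d["y_mean"]),
            y_std=float(d["y_std"]),
            seed=int(d["seed"]),
        )


@dataclass
class TrainResult:
    model: AnnModel
    train_mue: float
    val_mue: float
    test_mue: float
    train_rmse: float
    val_rmse: float
    test_rmse: float
    epochs_run: int


class TrainingFailure(RuntimeError):
    """Loss became non-finite; carries diagnostic state."""


def _init_weights(d: int, h: int, rng: np.random.Generator):
    w1 = rng.normal(0.0, 1.0 / math.sqrt(d), size=(h, d))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, 1.0 / math.sqrt(h), size=h)
    b2 = 0.0
    return w1, b1, w2, b2


def train_ann(
    fm: FeatureMatrix,
    target: np.ndarray,
    selection: Sequence[str],
    hidden: int,
    split: DatasetSplit,
    init_seed: int = 0,
    *,
    warm_start: AnnModel | None = None,
    samples_per_param: float = 10.0,
    allow_over_capacity: bool = False,
    learning_rate: float = 0.02,
    max_epochs: int = 2000,
    patience: int = 50,
    early_stopping: bool = True,
) -> TrainResult:
    """Fit one capacity-checked network on a fixed split.

    Full-batch Adam on mean-squared error, early stopping on validation MUE
    with the given patience; the weights achieving the best validation MUE
    are restored at the end.  With ``early_stopping=False`` the network runs
    all ``max_epochs`` and keeps its final weights — no validation-based
    selection at all, which is how a deliberately over-fitted reference
    configuration is produced.  Deterministic given (init_seed, split) — or
    given the warm-start weights, which override the seeded initialization.
    """
    cols = list(selection)
    target = np.asarray(target, dtype=float)
    d = len(cols)
    if hidden < 1:
        raise ValueError("hidden must be >= 1")
    sub = fm.subset_columns(cols)
    tr, va, te = split.indices(fm.sample_ids)
    cap = max_hidden_units(len(tr), d, samples_per_param)
    if hidden > cap:
        if not allow_over_capacity:
            raise ValueError(
                f"hidden={hidden} exceeds capacity cap {cap} for n_train={len(tr)}, "
                f"d={d}; pass allow_over_capacity=True to override"
            )
        warnings.warn(
            f"OVER-CAPACITY network requested: hidden={hidden} > cap {cap} "
            f"({parameter_count(d, hidden)} parameters for {len(tr)} training samples)"
        )

    x = sub.values
    x_mean = x[tr].mean(axis=0)
    x_std = x[tr].std(axis=0)
    x_std[x_std == 0] = 1.0
    y_mean = float(target[tr].mean())
    y_std = float(target[tr].std()) or 1.0
    xs = (x - x_mean) / x_std
    ys = (target - y_mean) / y_std

    if warm_start is not None:
        if warm_start.input_columns != cols or warm_start.hidden_units != hidden:
            raise ValueError("warm_start model does not match the requested architecture")
        w1, b1, w2, b2 = (warm_start.w1.copy(), warm_start.b1.copy(),
                          warm_start.w2.copy(), float(warm_start.b2))
    else:
        rng = np.random.default_rng(init_seed)
        w1, b1, w2, b2 = _init_weights(d, hidden, rng)

    params = [w1, b1, w2, np.array([b2])]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8

    x_tr, y_tr = xs[tr], ys[tr]
    x_va, y_va_orig = xs[va], target[va]
    n_tr = len(tr)

    def predict_std(xm: np.ndarray) -> np.ndarray:
        hdn = np.tanh(xm @ params[0].T + params[1])
        return hdn @ params[2] + params[3][0]

    best_val = np.inf
    best_params = [p.copy() for p in params]
    best_epoch = 0
    wait = 0
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        hdn = np.tanh(x_tr @ params[0].T + params[1])
        pred = hdn @ params[2] + params[3][0]
        err = pred - y_tr
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise TrainingFailure(
                f"non-finite loss at epoch {epoch} (lr={learning_rate}, h={hidden})"
            )
        g_out = 2.0 * err / n_tr
        g_w2 = hdn.T @ g_out
        g_b2 = np.array([g_out.sum()])
        g_h = np.outer(g_out, params[2]) * (1.0 - hdn**2)
        g_w1 = g_h.T @ x_tr
        g_b1 = g_h.sum(axis=0)
        grads = [g_w1, g_b1, g_w2, g_b2]
        for i, (p, g) in enumerate(zip(params, grads)):
            m_t[i] = beta1 * m_t[i] + (1 - beta1) * g
            v_t[i] = beta2 * v_t[i] + (1 - beta2) * g**2
            m_hat = m_t[i] / (1 - beta1**epoch)
            v_hat = v_t[i] / (1 - beta2**epoch)
            p -= learning_rate * m_hat / (np.sqrt(v_hat) + eps_adam)

        if early_stopping:
            val_pred = predict_std(x_va) * y_std + y_mean
            val_mue = float(np.mean(np.abs(val_pred - y_va_orig))) if len(va) else loss
            if val_mue < best_val - 1e-12:
                best_val = val_mue
                best_params = [p.copy() for p in params]
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break

    if not early_stopping:
        best_params = params
        best_epoch = epoch
    w1, b1, w2, b2v = best_params
    model = AnnModel(
        input_columns=cols, hidden_units=hidden,
        w1=w1, b1=b1, w2=w2, b2=float(b2v[0]),
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        seed=int(init_seed),
    )
    preds = model.predict(x)
    return TrainResult(
        model=model,
        train_mue=mue(target[tr], preds[tr]),
        val_mue=mue(target[va], preds[va]) if len(va) else float("nan"),
        test_mue=mue(target[te], preds[te]) if len(te) else float("nan"),
        train_rmse=rmse(target[tr], preds[tr]),
        val_rmse=rmse(target[va], preds[va]) if len(va) else float("nan"),
        test_rmse=rmse(target[te], preds[te]) if len(te) else float("nan"),
        epochs_run=best_epoch,
    )


# ---------------------------------------------------------------------------
# Replica validation
# ---------------------------------------------------------------------------

@dataclass
class ReplicaValidationReport:
    """Statistical acceptance evidence for one candidate architecture."""

    n_replicas: int
    train_mues: list[float]
    val_mues: list[float]
    p_values: list[float]
    fraction_nonsignificant: float
    accepted: bool
    alpha: float
    threshold: float
    notes: list[str] = field(default_factory=list)


def replica_validate(
    model: AnnModel,
    fm: FeatureMatrix,
    target: np.ndarray,
    groups: Mapping[str, str] | None = None,
    n_replicas: int = 100,
    alpha: float = 0.05,
    threshold: float = 0.80,
    seed: int = 0,
    compare: str = "val",
    **train_kwargs,
) -> ReplicaValidationReport:
    """Retrain a candidate from its optimised weights under fresh random
    splits and test whether training and validation errors stay statistically
    indistinguishable.

    Per replica: a new seeded 60/15/25 (group-aware when groups are given)
    split, retraining warm-started from ``model``, then a two-sided Welch
    t-test on the per-sample unsigned errors of the training partition versus
    the comparison partition (``val`` by default, ``test`` optionally).
    Non-significant means p >= alpha; the candidate is accepted when the
    non-significant fraction reaches the threshold (0.80 at alpha 0.05 by
    default).  Replicas where both error samples have zero variance count as
    non-significant with a logged note.
    """
    if compare not in ("val", "test"):
        raise ValueError("compare must be 'val' or 'test'")
    target = np.asarray(target, dtype=float)
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=n_replicas)
    train_mues, val_mues, p_values, notes = [], [], [], []
    for r in range(n_replicas):
        split = make_split(fm.sample_ids, groups=groups, seed=int(split_seeds[r]))
        res = train_ann(
            fm, target, model.input_columns, model.hidden_units, split,
            warm_start=model, **train_kwargs,
        )
        tr, va, te = split.indices(fm.sample_ids)
        other = va if compare == "val" else te
        preds = res.model.predict_fm(fm)
        err_tr = np.abs(target[tr] - preds[tr])
        err_other = np.abs(target[other] - preds[other])
        train_mues.append(float(err_tr.mean()))
        val_mues.append(float(err_other.mean()))
        if err_tr.std() == 0.0 and err_other.std() == 0.0:
            p = 1.0
            notes.append(f"replica {r}: zero-variance errors in both partitions")
        else:
            p = float(stats.ttest_ind(err_tr, err_other, equal_var=False).pvalue)
            if not np.isfinite(p):
                p = 1.0
                notes.append(f"replica {r}: degenerate t-test, counted non-significant")
        p_values.append(p)
    frac = float(np.mean([p >= alpha for p in p_values]))
    return ReplicaValidationReport(
        n_replicas=n_replicas,
        train_mues=train_mues,
        val_mues=val_mues,
        p_values=p_values,
        fraction_nonsignificant=frac,
        accepted=frac >= threshold,
        alpha=alpha,
        threshold=threshold,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Protocol search over (input-set size, hidden units, division, init)
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    best_model: AnnModel | None
    best_result: TrainResult | None
    best_report: ReplicaValidationReport | None
    trial_log: list[dict]


def protocol_search(
    fm: FeatureMatrix,
    target: np.ndarray,
    per_size_sets: Mapping[int, Sequence[str]],
    groups: Mapping[str, str] | None = None,
    n_divisions: int = 40,
    n_inits: int = 100,
    hidden_grid: Sequence[int] | None = None,
    samples_per_param: float = 10.0,
    replica_budget: int = 100,
    alpha: float = 0.05,
    threshold: float = 0.80,
    seed: int = 0,
    **train_kwargs,
) -> ProtocolResult:
    """Grid search over input-set sizes and hidden-layer widths under the
    capacity cap, with many data divisions and weight initializations.

    Every trial that beats the incumbent's validation MUE is sent to replica
    validation; only an accepted candidate replaces the incumbent.  The first
    completed trial seeds the incumbent.  Returns the accepted incumbent (or
    None if nothing was ever accepted) plus the complete trial log.
    """
    if n_divisions < 1 or n_inits < 1:
        raise ValueError("budgets must be >= 1")
    if not per_size_sets:
        raise ValueError("empty selection grid")
    target = np.asarray(target, dtype=float)
    rng = np.random.default_rng(seed)
    division_seeds = rng.integers(0, 2**31 - 1, size=n_divisions)
    init_seeds = rng.integers(0, 2**31 - 1, size=n_inits)
    replica_seed = int(rng.integers(0, 2**31 - 1))

    trial_log: list[dict] = []
    best: TrainResult | None = None
    best_report: ReplicaValidationReport | None = None
    # "best found" validation MUE: seeded by the first completed trial and
    # lowered by every replica-checked trial, accepted or not; the returned
    # incumbent model additionally requires replica acceptance.
    incumbent_val = np.inf

    for size in sorted(per_size_sets):
        cols = list(per_size_sets[size])
        for div_i in range(n_divisions):
            split = make_split(fm.sample_ids, groups=groups,
                               seed=int(division_seeds[div_i]))
            cap = max_hidden_units(len(split.train_ids), len(cols), samples_per_param)
            if cap < 1:
                continue
            widths = [h for h in (hidden_grid or range(1, cap + 1)) if h <= cap]
            for h in widths:
                for init_i in range(n_inits):
                    res = train_ann(
                        fm, target, cols, h, split,
                        init_seed=int(init_seeds[init_i]),
                        samples_per_param=samples_per_param, **train_kwargs,
                    )
                    entry = {
                        "size": size, "hidden": h,
                        "division": div_i, "init": init_i,
                        "columns": cols,
                        "train_mue": res.train_mue,
                        "val_mue": res.val_mue,
                        "test_mue": res.test_mue,
                        "metric": res.val_mue,
                        "replica_checked": False,
                        "accepted": False,
                    }
                    if res.val_mue < incumbent_val:
                        report = replica_validate(
                            res.model, fm, target, groups=groups,
                            n_replicas=replica_budget, alpha=alpha,
                            threshold=threshold, seed=replica_seed,
                            **train_kwargs,
                        )
                        entry["replica_checked"] = True
                        entry["accepted"] = report.accepted
                        incumbent_val = res.val_mue
                        if report.accepted:
                            best, best_report = res, report
                    trial_log.append(entry)
    return ProtocolResult(
        best_model=best.model if best else None,
        best_result=best,
        best_report=best_report,
        trial_log=trial_log,
    )


# ---------------------------------------------------------------------------
# SVM classification
# ---------------------------------------------------------------------------

def train_svm(
    fm: FeatureMatrix,
    labels: np.ndarray,
    selection: Sequence[str] | None = None,
    split: DatasetSplit | None = None,
    train_ids: Sequence[str] | None = None,
    test_ids: Sequence[str] | None = None,
) -> tuple[SVC, dict[str, float]]:
    """Soft-margin linear SVM (box constraint 1, no feature standardization).

    Accepts either a :class:`DatasetSplit` (validation ids join the training
    side) or explicit external train/test id lists, mirroring benchmarks that
    ship a fixed train/test partition.  Returns the fitted classifier and
    train/test accuracies (fraction correctly classified).
    """
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if split is not None:
        train_ids = list(split.train_ids) + list(split.val_ids)
        test_ids = list(split.test_ids)
    if train_ids is None or test_ids is None:
        raise ValueError("provide a split or explicit train/test id lists")
    cols = list(selection) if selection is not None else list(fm.columns)
    sub = fm.subset_columns(cols)
    pos = {s: i for i, s in enumerate(fm.sample_ids)}
    tr = np.array([pos[s] for s in train_ids], dtype=int)
    te = np.array([pos[s] for s in test_ids], dtype=int)
    if np.unique(labels[tr]).size < 2:
        raise ValueError("training data contains a single class")
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(sub.values[tr], labels[tr])
    acc = {
        "train_accuracy": float(np.mean(clf.predict(sub.values[tr]) == labels[tr])),
        "test_accuracy": float(np.mean(clf.predict(sub.values[te]) == labels[te]))
        if len(te) else float("nan"),
    }
    return clf, acc


# ---------------------------------------------------------------------------
# Top-decile ensemble presence analysis
# ---------------------------------------------------------------------------

@dataclass
class PresenceReport:
    """How often each medium / attribute appears among the most accurate models."""

    medium_presence: dict[str, float]
    attribute_presence: dict[int, float]
    n_models_considered: int
    top_fraction: float


def presence_analysis(
    trial_log: Sequence[Mapping],
    top_fraction: float = 0.10,
    higher_is_better: bool = False,
) -> PresenceReport:
    """Presence percentages of media and attributes in the top models.

    The best ceil(top_fraction * N) entries by ``metric`` are selected (ties
    resolve to the earlier trial); a model contains a medium or attribute iff
    at least one of its columns derives from it.
    """
    from .featurize import DIELECTRIC_COLUMN, split_label

    if not trial_log:
        raise ValueError("empty trial log")
    n = len(trial_log)
    k = math.ceil(top_fraction * n)
    sign = -1.0 if higher_is_better else 1.0
    order = sorted(range(n), key=lambda i: (sign * float(trial_log[i]["metric"]), i))
    top = [trial_log[i] for i in order[:k]]

    media_counts: dict[str, int] = {}
    attr_counts: dict[int, int] = {}
    for entry in top:
        media_here, attrs_here = set(), set()
        for col in entry["columns"]:
            medium, attr = split_label(col)
            if medium != DIELECTRIC_COLUMN:
                media_here.add(medium)
            if attr is not None:
                attrs_here.add(attr)
        for m in media_here:
            media_counts[m] = media_counts.get(m, 0) + 1
        for a in attrs_here:
            attr_counts[a] = attr_counts.get(a, 0) + 1
    return PresenceReport(
        medium_presence={m: 100.0 * c / k for m, c in sorted(media_counts.items())},
        attribute_presence={a: 100.0 * c / k for a, c in sorted(attr_counts.items())},
        n_models_considered=k,
        top_fraction=top_fraction,
    )
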