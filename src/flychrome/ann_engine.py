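"""Small feed-forward classifiers trained by maximum conditional likelihood.

The classifier is a fully connected k→3→1 network: k photoreceptor
excitations in, three hidden units, one logistic output unit whose value is
read as the probability of the positive class ('animal' or 'shaded').
Training minimizes the conditional negative log-likelihood (cross-entropy)
with a small quadratic weight penalty, using L-BFGS with analytic gradients.

The ensemble protocol: split the stimulus set 60/40 into training and test
subsets, train 100 networks from independent random initializations, keep
the one with the best training-set likelihood, record its held-out test
accuracy; repeat 20 times with fresh random splits.  The 20 selected
networks are the ensemble used by all downstream interpretation and fabric
evaluation.  All randomness derives from one master seed via seed-sequence
spawning, so a full ensemble is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .receptor_model import RECEPTOR_COLUMNS, ExcitationDataset
from .synthetic_data import RECEPTOR_IDS

logger = logging.getLogger(__name__)

_EPS = 1e-12

TASKS = ("animal", "shaded")


@dataclass(frozen=True)
class TaskSpec:
    """Which binary classification to run and on which receptor inputs.

    ``animal``: positive class is ``class_label == "animal"`` regardless of
    illuminant (output 0 means 'leaf').  ``shaded``: positive class is
    ``condition == "shade"`` regardless of stimulus type (0 means
    'unshaded').
    """

    task: str
    input_subset: tuple[str, ...] = RECEPTOR_IDS

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if not self.input_subset:
            raise ValueError("input_subset must be non-empty")
        unknown = [r for r in self.input_subset if r not in RECEPTOR_IDS]
        if unknown:
            raise ValueError(f"unknown receptor id(s) {unknown}")

    @property
    def input_columns(self) -> list[str]:
        return [RECEPTOR_COLUMNS[r] for r in self.input_subset]

    def labels(self, frame: pd.DataFrame) -> np.ndarray:
        if self.task == "animal":
            return (frame["class_label"] == "animal").to_numpy(dtype=float)
        return (frame["condition"] == "shade").to_numpy(dtype=float)

    def design(self, frame: pd.DataFrame) -> np.ndarray:
        return frame[self.input_columns].to_numpy(dtype=float)


@dataclass(frozen=True)
class TrainConfig:
    """Training and ensemble-protocol parameters.

    ``n_inits``/``n_reps``/``train_frac`` encode the best-of-100 ×
    20-repetition, 60/40-split protocol; the optimizer settings
    (``max_iter``, ``weight_decay``, ``init_scale``) are package choices for
    stable convergence of these tiny networks and are exposed here.
    """

    n_inits: int = 100
    n_reps: int = 20
    train_frac: float = 0.60
    n_hidden: int = 3
    max_iter: int = 500
    weight_decay: float = 1e-2
    init_scale: float = 0.1
    master_seed: int = 0
    hidden_activation: str = "logistic"  # or "tanh"
    select_on: str = "train"  # selection likelihood: "train" or "test"
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_inits < 1 or self.n_reps < 1:
            raise ValueError("n_inits and n_reps must be >= 1")
        if self.hidden_activation not in ("logistic", "tanh"):
            raise ValueError(f"unknown hidden activation {self.hidden_activation!r}")
        if self.select_on not in ("train", "test"):
            raise ValueError("select_on must be 'train' or 'test'")


@dataclass
class MLPModel:
    """Weights of one trained k→3→1 network with named inputs."""

    input_ids: tuple[str, ...]
    W1: np.ndarray  # (k, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_hidden,)
    b2: float
    hidden_activation: str = "logistic"
    training_nll: float = float("nan")

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]

    def to_dict(self) -> dict:
        return {
            "input_ids": list(self.input_ids),
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
            "hidden_activation": self.hidden_activation,
            "training_nll": self.training_nll,
        }

    @staticmethod
    def from_dict(d: dict) -> "MLPModel":
        return MLPModel(
            tuple(d["input_ids"]), np.asarray(d["W1"], float), np.asarray(d["b1"], float),
            np.asarray(d["W2"], float), float(d["b2"]), d.get("hidden_activation", "logistic"),
            float(d.get("training_nll", float("nan"))),
        )


def _hidden(z: np.ndarray, activation: str) -> np.ndarray:
    return expit(z) if activation == "logistic" else np.tanh(z)


def forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Output probability p ∈ (0,1) for each row of ``X`` (n, k) or a single vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.input_ids):
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {len(model.input_ids)}"
        )
    h = _hidden(X @ model.W1 + model.b1, model.hidden_activation)
    return expit(h @ model.W2 + model.b2)


def classify(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Binary classification: 1 iff the output probability is >= 0.5.

    The tie p = 0.5 (e.g. an all-zero network) classifies as 1.
    """
    return (forward(model, X) >= 0.5).astype(int)


def nll(model: MLPModel, X: np.ndarray, y: np.ndarray) -> float:
    """Conditional negative log-likelihood of labels ``y`` ∈ {0,1} under the model."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty data")
    p = np.clip(forward(model, X), _EPS, 1.0 - _EPS)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def accuracy(model: MLPModel, X: np.ndarray, y: np.ndarray) -> float:
    """Proportion of correct classifications (true positives + true negatives)."""
    return float(np.mean(classify(model, X) == np.asarray(y, int)))


# ---------------------------------------------------------------------------
# parameter packing and the penalized objective


def _shapes(k: int, n_hidden: int) -> int:
    return k * n_hidden + n_hidden + n_hidden + 1


def _unpack(theta: np.ndarray, k: int, n_hidden: int):
    i = k * n_hidden
    W1 = theta[:i].reshape(k, n_hidden)
    b1 = theta[i : i + n_hidden]
    W2 = theta[i + n_hidden : i + 2 * n_hidden]
    b2 = theta[i + 2 * n_hidden]
    return W1, b1, W2, b2


def _objective(theta: np.ndarray, X: np.ndarray, y: np.ndarray, n_hidden: int,
               decay: float, activation: str):
    """Penalized NLL and its analytic gradient."""
    k = X.shape[1]
    W1, b1, W2, b2 = _unpack(theta, k, n_hidden)
    z1 = X @ W1 + b1
    h = _hidden(z1, activation)
    p = expit(h @ W2 + b2)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    value = -np.sum(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    value += decay * (np.sum(W1 * W1) + np.sum(W2 * W2))

    delta2 = p - y  # (n,)
    gW2 = h.T @ delta2 + 2.0 * decay * W2
    gb2 = delta2.sum()
    dh = np.outer(delta2, W2)
    dz1 = dh * (h * (1.0 - h) if activation == "logistic" else 1.0 - h * h)
    gW1 = X.T @ dz1 + 2.0 * decay * W1
    gb1 = dz1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2, [gb2]])
    return value, grad


def train_single(X: np.ndarray, y: np.ndarray, input_ids: tuple[str, ...],
                 config: TrainConfig, init_seed) -> MLPModel:
    """Train one network from a random initialization drawn from ``init_seed``.

    Weights start uniform in ±``init_scale``; L-BFGS minimizes the penalized
    NLL.  The stored ``training_nll`` is the unpenalized conditional NLL at
    the optimum (used for model selection).
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    k, n_hidden = X.shape[1], config.n_hidden
    rng = np.random.default_rng(init_seed)
    theta0 = rng.uniform(-config.init_scale, config.init_scale, _shapes(k, n_hidden))
    result = minimize(
        _objective, theta0, jac=True,
        args=(X, y, n_hidden, config.weight_decay, config.hidden_activation),
        method="L-BFGS-B", options={"maxiter": config.max_iter},
    )
    if not result.success and "ITERATIONS" not in str(result.message).upper():
        logger.warning("optimizer stopped early: %s", result.message)
    W1, b1, W2, b2 = _unpack(result.x, k, n_hidden)
    model = MLPModel(tuple(input_ids), W1.copy(), b1.copy(), W2.copy(), float(b2),
                     config.hidden_activation)
    model.training_nll = nll(model, X, y)
    return model


def train_best_of(X: np.ndarray, y: np.ndarray, input_ids: tuple[str, ...],
                  config: TrainConfig, rep_seed,
                  X_select: np.ndarray | None = None,
                  y_select: np.ndarray | None = None) -> MLPModel:
    """Train ``n_inits`` networks and return the one with the best selection likelihood.

    Selection uses the training-set conditional likelihood by default;
    ``X_select``/``y_select`` (used with ``select_on="test"``) substitute a
    held-out set.
    """
    seq = rep_seed if isinstance(rep_seed, np.random.SeedSequence) else np.random.SeedSequence(rep_seed)
    best: MLPModel | None = None
    best_score = np.inf
    for init_seq in seq.spawn(config.n_inits):
        model = train_single(X, y, input_ids, config, init_seq)
        if X_select is not None:
            score = nll(model, X_select, y_select)
        else:
            # the fitting criterion includes the weight penalty, so the
            # "best-fitting" model is judged on the same penalized value
            score = model.training_nll + config.weight_decay * (
                np.sum(model.W1**2) + np.sum(model.W2**2))
        if score < best_score:
            best, best_score = model, score
    assert best is not None
    return best


@dataclass
class EnsembleResult:
    """The 20 selected networks with their per-repetition held-out accuracies."""

    task_spec: TaskSpec
    config: TrainConfig
    models: list[MLPModel]
    accuracies: np.ndarray
    splits: list[tuple[np.ndarray, np.ndarray]]

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "task": self.task_spec.task,
            "input_subset": list(self.task_spec.input_subset),
            "config": {k: getattr(self.config, k) for k in (
                "n_inits", "n_reps", "train_frac", "n_hidden", "max_iter",
                "weight_decay", "init_scale", "master_seed", "hidden_activation",
                "select_on", "stratified")},
            "accuracies": self.accuracies.tolist(),
            "models": [m.to_dict() for m in self.models],
            "splits": [[tr.tolist(), te.tolist()] for tr, te in self.splits],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "EnsembleResult":
        d = json.loads(Path(path).read_text())
        return EnsembleResult(
            TaskSpec(d["task"], tuple(d["input_subset"])),
            TrainConfig(**d["config"]),
            [MLPModel.from_dict(m) for m in d["models"]],
            np.asarray(d["accuracies"], float),
            [(np.asarray(tr, int), np.asarray(te, int)) for tr, te in d["splits"]],
        )


def _random_split(rng: np.random.Generator, y: np.ndarray, train_frac: float,
                  stratified: bool, max_tries: int = 100):
    """60/40-style random split; resplit (logged) if training lacks a class."""
    n = y.size
    n_train = int(round(train_frac * n))
    if stratified:
        train_idx: list[int] = []
        for cls in np.unique(y):
            idx = np.where(y == cls)[0]
            idx = rng.permutation(idx)
            n_cls = int(round(train_frac * idx.size))
            train_idx.extend(idx[:n_cls])
        train = np.sort(np.asarray(train_idx, int))
        test = np.setdiff1d(np.arange(n), train)
        return train, test
    for attempt in range(max_tries):
        perm = rng.permutation(n)
        train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if len(np.unique(y[train])) == 2 and len(np.unique(y[test])) == 2:
            return train, test
        logger.info("resplitting: attempt %d lacked a class in train or test", attempt + 1)
    raise ValueError("could not produce a split containing both classes")


def run_ensemble(dataset: ExcitationDataset | pd.DataFrame, task_spec: TaskSpec,
                 config: TrainConfig) -> EnsembleResult:
    """The full ensemble protocol on one task.

    Per repetition: a fresh random 60/40 split, best-of-``n_inits`` training
    on the 60%, held-out accuracy on the 40%.  Returns the ``n_reps``
    selected models and their accuracies.
    """
    frame = dataset.frame if isinstance(dataset, ExcitationDataset) else dataset
    X = task_spec.design(frame)
    y = task_spec.labels(frame)
    if len(np.unique(y)) < 2:
        raise ValueError(f"dataset contains a single class for task {task_spec.task!r}")

    master = np.random.SeedSequence(config.master_seed)
    models: list[MLPModel] = []
    accuracies = np.empty(config.n_reps)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for rep, rep_seq in enumerate(master.spawn(config.n_reps)):
        split_seq, init_seq = rep_seq.spawn(2)
        rng = np.random.default_rng(split_seq)
        train, test = _random_split(rng, y, config.train_frac, config.stratified)
        kwargs = {}
        if config.select_on == "test":
            kwargs = {"X_select": X[test], "y_select": y[test]}
        model = train_best_of(X[train], y[train], task_spec.input_subset, config,
                              init_seq, **kwargs)
        models.append(model)
        accuracies[rep] = accuracy(model, X[test], y[test])
        splits.append((train, test))
    return EnsembleResult(task_spec, config, models, accuracies, splits)


def default_input_subsets(full: tuple[str, ...] = RECEPTOR_IDS) -> list[tuple[str, ...]]:
    """The full set, all 4-subsets, all 2-subsets and all singletons (21 subsets)."""
    subsets: list[tuple[str, ...]] = [tuple(full)]
    for size in (4, 2, 1):
        subsets.extend(combinations(full, size))
    return subsets


def subset_experiment(dataset: ExcitationDataset | pd.DataFrame, task: str,
                      config: TrainConfig,
                      subsets: list[tuple[str, ...]] | None = None) -> pd.DataFrame:
    """Ensemble accuracy for each photoreceptor input subset.

    Runs :func:`run_ensemble` for every subset (default: full set, all
    4-subsets, all 2-subsets, all singletons) and tabulates mean ± sd
    held-out accuracy.  Each subset gets an independent child seed of the
    master seed, so the table is reproducible as a whole.
    """
    if subsets is None:
        subsets = default_input_subsets()
    master = np.random.SeedSequence(config.master_seed)
    rows = []
    for subset, child in zip(subsets, master.spawn(len(subsets))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sub_config = replace(config, master_seed=sub_seed)
        result = run_ensemble(dataset, TaskSpec(task, tuple(subset)), sub_config)
        rows.append({
            "inputs": "+".join(subset),
            "n_inputs": len(subset),
            "mean_accuracy": result.mean_accuracy,
            "sd_accuracy": result.sd_accuracy,
        })
        logger.info("subset %s: %.3f ± %.3f", "+".join(subset),
                    result.mean_accuracy, result.sd_accuracy)
    return pd.DataFrame(rows)


__all__ = [
    "EnsembleResult",
    "MLPModel",
    "TASKS",
    "TaskSpec",
    "TrainConfig",
    "accuracy",
    "classify",
    "default_input_subsets",
    "forward",
    "nll",
    "run_ensemble",
    "subset_experiment",
    "train_best_of",
    "train_single",
]
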