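"""Balanced Ensemble Subset Learning.

The 1:20 class imbalance of EP-pair benchmarks biases a single classifier
toward the negative majority.  BESL instead (i) computes the
negative:positive ratio of the training set, (ii) partitions the negatives
into ``ratio`` disjoint subsets by a seeded shuffle + round robin, (iii)
trains one sub-model per subset on all positives plus that subset — a 1:1
balanced training set — with an internal 80/20 train/validation split and
early stopping on validation loss (patience 5, best weights restored),
(iv) averages the sub-model probabilities at prediction time, and (v)
wraps the whole procedure in stratified k-fold cross-validation, so every
pair is predicted exactly once by an ensemble that never saw it.

Sub-models are duck-typed: anything exposing ``fit_epoch(data, idx)``,
``loss_on(data, idx)``, ``predict_proba(data, idx)`` and ``get_state`` /
``set_state`` trains here, which keeps the protocol testable with stub
models and scripted loss schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .config import RunConfig
from .errors import DivergenceError, ModelStateError, ValidationError


def compute_ratio(labels: Sequence[int]) -> int:
    """Negatives per positive, rounded half-even, floored at 1."""
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("need at least one positive and one negative")
    return max(1, round(n_neg / n_pos))


@dataclass
class BeslPlan:
    """Assignment of every negative sample to exactly one subset."""

    ratio: int
    subset_assignments: dict[int, int]      # negative index -> subset id
    seed: int

    def subsets(self) -> list[np.ndarray]:
        out: list[list[int]] = [[] for _ in range(self.ratio)]
        for idx, sub in self.subset_assignments.items():
            out[sub].append(idx)
        return [np.array(sorted(s), dtype=np.int64) for s in out]


def partition_negatives(negative_indices: Sequence[int], ratio: int,
                        seed: int) -> BeslPlan:
    """Seeded shuffle + round-robin split into ``ratio`` disjoint subsets.

    Subset sizes differ by at most one and their union is every negative.
    """
    negative_indices = np.asarray(negative_indices, dtype=np.int64)
    if ratio < 1:
        raise ValidationError(f"ratio must be >= 1, got {ratio}")
    if ratio > negative_indices.size:
        raise ValidationError(
            f"ratio {ratio} exceeds the {negative_indices.size} negatives"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(negative_indices)
    assignments = {int(idx): i % ratio for i, idx in enumerate(shuffled)}
    return BeslPlan(ratio=ratio, subset_assignments=assignments, seed=seed)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0                     # 1-based
    stopped_epoch: int = 0


def train_submodel(model, data, train_idx, val_idx, patience: int = 5,
                   max_epochs: int = 100) -> tuple[object, TrainingHistory]:
    """Train with early stopping on validation loss; restore best weights.

    Training stops once the validation loss has failed to improve (strictly
    decrease) for ``patience`` consecutive epochs; the returned model carries
    the weights of the best-validation-loss epoch.
    """
    if patience <= 0:
        raise ValidationError(f"patience must be positive, got {patience}")
    history = TrainingHistory()
    best_loss = np.inf
    best_state = model.get_state()
    stall = 0
    for epoch in range(1, max_epochs + 1):
        train_loss = model.fit_epoch(data, train_idx)
        if not np.isfinite(train_loss):
            raise DivergenceError(epoch)
        val_loss = model.loss_on(data, val_idx)
        if not np.isfinite(val_loss):
            raise DivergenceError(epoch)
        history.train_loss.append(float(train_loss))
        history.val_loss.append(float(val_loss))
        history.stopped_epoch = epoch
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            history.best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    model.set_state(best_state)
    return model, history


@dataclass
class BeslEnsemble:
    """The trained sub-models with their negative-subset plan."""

    sub_models: list
    histories: list[TrainingHistory]
    plan: BeslPlan
    training_sets: list[np.ndarray]         # per sub-model training indices

    def __len__(self) -> int:
        return len(self.sub_models)


def besl_fit(data, train_idx: Sequence[int], model_factory: Callable[[int], object],
             config: RunConfig, seed: int | None = None) -> BeslEnsemble:
    """Fit one balanced ensemble on the training indices of ``data``.

    ``model_factory(seed)`` must yield a fresh trainable classifier.  Each
    sub-model trains on all positives plus its negative subset, split
    80/20 (stratified, seeded) into an early-stopping train/validation pair.
    """
    train_idx = np.asarray(train_idx, dtype=np.int64)
    seed = config.seed if seed is None else seed
    labels = data.y[train_idx]
    pos = train_idx[labels == 1]
    neg = train_idx[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("training set must contain both classes")
    ratio = config.besl_ratio or compute_ratio(labels)
    plan = partition_negatives(neg, ratio, seed)
    rng = np.random.default_rng(seed)
    sub_models, histories, training_sets = [], [], []
    for subset in plan.subsets():
        members = np.concatenate([pos, subset])
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        tr, va = train_test_split(
            members, test_size=config.val_fraction, random_state=sub_seed % (2 ** 32),
            stratify=data.y[members])
        model = model_factory(sub_seed)
        model, history = train_submodel(model, data, tr, va,
                                        patience=config.patience,
                                        max_epochs=config.max_epochs)
        sub_models.append(model)
        histories.append(history)
        training_sets.append(np.sort(members))
    return BeslEnsemble(sub_models=sub_models, histories=histories, plan=plan,
                        training_sets=training_sets)


def besl_predict(ensemble: BeslEnsemble, data, idx: Sequence[int]) -> np.ndarray:
    """Unweighted mean of the sub-model probabilities; values in [0, 1]."""
    if len(ensemble) == 0:
        raise ModelStateError("empty ensemble")
    idx = np.asarray(idx, dtype=np.int64)
    return np.mean([m.predict_proba(data, idx) for m in ensemble.sub_models],
                   axis=0)


@dataclass
class FoldResult:
    fold: int
    test_idx: np.ndarray
    scores: np.ndarray
    ensemble_size: int


def cross_validate(labels: Sequence[int],
                   dataset_builder: Callable[[np.ndarray], object],
                   model_factory_builder: Callable[[object], Callable[[int], object]],
                   config: RunConfig, seed: int | None = None
                   ) -> list[FoldResult]:
    """Stratified k-fold CV with a freshly fitted BESL ensemble per fold.

    ``dataset_builder(train_idx)`` must return the encoded dataset with every
    train-data-dependent state (PCPS, embedding, normalization) fitted on the
    training indices only; ``model_factory_builder(dataset)`` adapts model
    dimensions to that dataset.  Every pair is predicted exactly once.
    """
    labels = np.asarray(labels)
    seed = config.seed if seed is None else seed
    if config.folds < 2:
        raise ValidationError("need at least 2 folds")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < config.folds:
        raise ValidationError(
            f"cannot stratify {counts.min()} minority samples into "
            f"{config.folds} folds"
        )
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=seed % (2 ** 32))
    results = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(labels.size), labels)):
        data = dataset_builder(tr)
        factory = model_factory_builder(data)
        ensemble = besl_fit(data, tr, factory, config,
                            seed=seed + 1000 * (fold + 1))
        scores = besl_predict(ensemble, data, te)
        results.append(FoldResult(fold=fold, test_idx=te, scores=scores,
                                  ensemble_size=len(ensemble)))
    return results
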