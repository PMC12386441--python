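"""End-to-end orchestration: encode, fit, predict, evaluate.

Leakage discipline is centralized here: everything fitted from data — the
PCPS conservation/score model, the k-mer embedding, and the genomic
min-max normalization — is fitted on training indices only and then
applied to all pairs.  Cross-validation therefore re-fits the encoders per
outer fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import besl as besl_mod
from .besl import BeslEnsemble, besl_fit, besl_predict, train_submodel
from .config import RunConfig
from .encoding import FittedEncoders, four_encode
from .features import MinMaxNormalizer, stack_feature_matrices
from .io import EPPair
from .mcanet import MCANet, model_factory
from .metrics import EvaluationReport, summarize


@dataclass
class EncodedDataset:
    """Stacked model-ready arrays for a set of pairs."""

    enh: np.ndarray         # (n, rows, conv channels)
    prom: np.ndarray
    vec: np.ndarray         # (n, dense features), enhancer then promoter
    gen: np.ndarray         # (n, 4, 2) normalized genomic features
    gen_mask: np.ndarray    # (n, 4) validity
    y: np.ndarray
    pair_ids: list[str]
    manifest: tuple

    def __len__(self) -> int:
        return self.y.size

    @property
    def conv_channels(self) -> int:
        return self.enh.shape[2]

    @property
    def vec_dim(self) -> int:
        return self.vec.shape[1]


def encode_dataset(pairs: Sequence[EPPair], encoders: FittedEncoders,
                   tracks: Mapping[str, object] | None,
                   normalizer: MinMaxNormalizer | None = None,
                   allow_missing_tracks: bool = False) -> EncodedDataset:
    """Encode all pairs with already-fitted encoders and normalizer."""
    config = encoders.config
    encoded = [four_encode(p, encoders, config) for p in pairs]
    enh = np.stack([e.enhancer_conv for e in encoded])
    prom = np.stack([e.promoter_conv for e in encoded])
    vec = np.stack([np.concatenate([e.enhancer_vec, e.promoter_vec])
                    for e in encoded])
    gen, mask = stack_feature_matrices(pairs, tracks,
                                       allow_missing=allow_missing_tracks)
    if normalizer is not None:
        gen = normalizer.transform(gen)
    y = np.array([p.label for p in pairs], dtype=np.int64)
    return EncodedDataset(enh=enh, prom=prom, vec=vec, gen=gen, gen_mask=mask,
                          y=y, pair_ids=[p.pair_id for p in pairs],
                          manifest=encoded[0].manifest)


def build_dataset(pairs: Sequence[EPPair], train_idx: Sequence[int],
                  tracks: Mapping[str, object] | None, config: RunConfig,
                  seed: int = 0,
                  allow_missing_tracks: bool = False) -> EncodedDataset:
    """Fit every data-dependent component on ``train_idx`` and encode all."""
    train_idx = np.asarray(train_idx, dtype=np.int64)
    train_pairs = [pairs[i] for i in train_idx]
    encoders = FittedEncoders.fit(train_pairs, config, seed=seed)
    raw_gen, _ = stack_feature_matrices(train_pairs, tracks,
                                        allow_missing=allow_missing_tracks)
    normalizer = MinMaxNormalizer().fit(raw_gen)
    return encode_dataset(pairs, encoders, tracks, normalizer,
                          allow_missing_tracks=allow_missing_tracks)


@dataclass
class HoldoutResult:
    metrics: dict[str, float]
    scores: np.ndarray
    test_idx: np.ndarray
    ensemble: BeslEnsemble
    dataset: EncodedDataset


def holdout_run(pairs: Sequence[EPPair], tracks, config: RunConfig,
                seed: int = 0, test_fraction: float = 0.2) -> HoldoutResult:
    """Stratified train/test split, BESL fit on train, metrics on test."""
    labels = np.array([p.label for p in pairs])
    idx = np.arange(labels.size)
    tr, te = train_test_split(idx, test_size=test_fraction,
                              random_state=seed % (2 ** 32), stratify=labels)
    data = build_dataset(pairs, tr, tracks, config, seed=seed)
    factory = model_factory(data.conv_channels, data.vec_dim, config)
    ensemble = besl_fit(data, tr, factory, config, seed=seed)
    scores = besl_predict(ensemble, data, te)
    return HoldoutResult(metrics=summarize(scores, data.y[te], config.threshold),
                         scores=scores, test_idx=te, ensemble=ensemble,
                         dataset=data)


def single_model_run(data: EncodedDataset, train_idx, test_idx,
                     config: RunConfig, seed: int = 0) -> np.ndarray:
    """Ablation arm: one model on the raw imbalanced training set.

    Same architecture, optimizer and early-stopping protocol as a BESL
    sub-model — only the balancing is removed.
    """
    train_idx = np.asarray(train_idx)
    tr, va = train_test_split(train_idx, test_size=config.val_fraction,
                              random_state=seed % (2 ** 32),
                              stratify=data.y[train_idx])
    model = MCANet(data.conv_channels, data.vec_dim, config, seed=seed)
    model, _ = train_submodel(model, data, tr, va, patience=config.patience,
                              max_epochs=config.max_epochs)
    return model.predict_proba(data, test_idx)


@dataclass
class AblationResult:
    seed: int
    besl_metrics: dict[str, float]
    single_metrics: dict[str, float]


def besl_vs_single_ablation(pairs: Sequence[EPPair], tracks,
                            config: RunConfig, seeds: Sequence[int]
                            ) -> list[AblationResult]:
    """Paired comparison: BESL ensemble vs one imbalanced-trained model.

    Both arms share the train/test split, the encoded dataset and the
    network configuration for each seed.
    """
    labels = np.array([p.label for p in pairs])
    idx = np.arange(labels.size)
    out = []
    for seed in seeds:
        tr, te = train_test_split(idx, test_size=0.2,
                                  random_state=seed % (2 ** 32),
                                  stratify=labels)
        data = build_dataset(pairs, tr, tracks, config, seed=seed)
        factory = model_factory(data.conv_channels, data.vec_dim, config)
        ensemble = besl_fit(data, tr, factory, config, seed=seed)
        besl_scores = besl_predict(ensemble, data, te)
        single_scores = single_model_run(data, tr, te, config, seed=seed)
        out.append(AblationResult(
            seed=seed,
            besl_metrics=summarize(besl_scores, data.y[te], config.threshold),
            single_metrics=summarize(single_scores, data.y[te],
                                     config.threshold)))
    return out


def cross_validate_pairs(pairs: Sequence[EPPair], tracks, config: RunConfig,
                         seed: int | None = None
                         ) -> tuple[list, EvaluationReport]:
    """Standard entry point: stratified 5-fold CV of the full pipeline."""
    labels = np.array([p.label for p in pairs])
    seed = config.seed if seed is None else seed

    def dataset_builder(train_idx):
        return build_dataset(pairs, train_idx, tracks, config, seed=seed)

    def factory_builder(data):
        return model_factory(data.conv_channels, data.vec_dim, config)

    folds = besl_mod.cross_validate(labels, dataset_builder, factory_builder,
                                    config, seed=seed)
    report = EvaluationReport.from_folds(
        [f.scores for f in folds], [labels[f.test_idx] for f in folds],
        config.threshold)
    return folds, report
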