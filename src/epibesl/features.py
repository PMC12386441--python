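"""Four-channel genomic feature input per EP pair.

Row order is fixed and documented — (RAD21, ATAC-seq, H3K27ac, Distance) —
so attention weights over rows stay interpretable.  Signal rows hold the
(enhancer window statistic, promoter window statistic) pair; the distance
row holds (log10 of 1 + midpoint separation, 0).  Min-max normalization
constants are fitted on training folds only and applied with clipping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, TransPairError, ValidationError
from .io import EPPair, GenomicInterval

FEATURE_ROWS = ("rad21", "atac", "h3k27ac", "distance")
SIGNAL_ROWS = FEATURE_ROWS[:3]


@dataclass
class GenomicFeatureMatrix:
    """4 x 2 per-pair feature matrix plus a per-row validity mask."""

    values: np.ndarray               # (4, 2)
    valid: np.ndarray                # (4,) bool; masked rows are suppressed

    def __post_init__(self):
        if self.values.shape != (4, 2) or self.valid.shape != (4,):
            raise ValidationError("feature matrix must be 4x2 with a 4-long mask")


def signal_stat(track, interval: GenomicInterval, stat: str = "mean") -> tuple[float, bool]:
    """Summary statistic of per-base signal over ``interval``.

    Returns ``(value, covered)``; an interval with no covered bases reports
    0.0 with ``covered=False`` so the caller can mask it.
    """
    if len(interval) == 0:
        raise ValidationError("zero-length interval")
    vals, covered = track.values(interval.chrom, interval.start, interval.end)
    if not covered.any():
        return 0.0, False
    if stat == "mean":
        return float(vals.mean()), True
    if stat == "max":
        return float(vals.max()), True
    if stat == "sum":
        return float(vals.sum()), True
    raise ValidationError(f"unknown statistic {stat!r}")


def log_distance(enhancer: GenomicInterval, promoter: GenomicInterval) -> float:
    """log10(1 + |midpoint separation|); symmetric; cis pairs only."""
    if enhancer.chrom != promoter.chrom:
        raise TransPairError(
            f"trans pair: {enhancer.chrom} vs {promoter.chrom}; pairs must be cis"
        )
    return float(np.log10(1.0 + abs(enhancer.midpoint - promoter.midpoint)))


def build_feature_matrix(pair: EPPair, tracks: Mapping[str, object],
                         stat: str = "mean",
                         allow_missing: bool = False) -> GenomicFeatureMatrix:
    """Assemble the fixed-order 4x2 genomic feature matrix for one pair."""
    if pair.enhancer is None or pair.promoter is None:
        raise ValidationError(f"pair {pair.pair_id} has no genomic intervals")
    values = np.zeros((4, 2))
    valid = np.zeros(4, dtype=bool)
    for row, name in enumerate(SIGNAL_ROWS):
        track = tracks.get(name)
        if track is None:
            if not allow_missing:
                raise ConfigError(
                    f"track {name!r} missing; pass allow_missing=True to mask it"
                )
            continue
        e_val, e_ok = signal_stat(track, pair.enhancer, stat)
        p_val, p_ok = signal_stat(track, pair.promoter, stat)
        values[row] = (e_val, p_val)
        valid[row] = e_ok or p_ok
    values[3, 0] = log_distance(pair.enhancer, pair.promoter)
    valid[3] = True
    return GenomicFeatureMatrix(values=values, valid=valid)


@dataclass
class MinMaxNormalizer:
    """Per-entry min-max scaler for stacked (n, 4, 2) feature matrices.

    Fitted once on training-fold pairs; transformed values are clipped to
    [0, 1] so unseen test extremes cannot leak range information.
    Degenerate constant entries normalize to 0.
    """

    lo: np.ndarray | None = None
    hi: np.ndarray | None = None

    def fit(self, stacked: np.ndarray) -> "MinMaxNormalizer":
        if stacked.ndim != 3 or stacked.shape[1:] != (4, 2):
            raise ValidationError("expected an (n, 4, 2) feature stack")
        self.lo = stacked.min(axis=0)
        self.hi = stacked.max(axis=0)
        return self

    def transform(self, stacked: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise ValidationError("normalizer not fitted")
        span = self.hi - self.lo
        span = np.where(span == 0, 1.0, span)
        return np.clip((stacked - self.lo) / span, 0.0, 1.0)


def stack_feature_matrices(pairs: Sequence[EPPair],
                           tracks: Mapping[str, object] | None,
                           stat: str = "mean",
                           allow_missing: bool = False
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Raw (n, 4, 2) feature stack and (n, 4) validity mask for many pairs.

    With ``tracks=None`` (sequence-only runs without coordinates) all rows
    are zero and only pairs with intervals get a valid distance row.
    """
    n = len(pairs)
    values = np.zeros((n, 4, 2))
    valid = np.zeros((n, 4), dtype=bool)
    for i, pair in enumerate(pairs):
        if tracks is None:
            if pair.enhancer is not None and pair.promoter is not None:
                values[i, 3, 0] = log_distance(pair.enhancer, pair.promoter)
                valid[i, 3] = True
            continue
        gfm = build_feature_matrix(pair, tracks, stat=stat,
                                   allow_missing=allow_missing)
        values[i] = gfm.values
        valid[i] = gfm.valid
    return values, valid
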