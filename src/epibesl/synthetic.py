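"""Synthetic EP-pair datasets with controllable planted signal.

The generator emulates the structure of cell-line EPI benchmarks so every
pipeline stage is exercisable offline: a 1:20 positive:negative imbalance,
short fixed-width element windows, a pair of co-occurring sequence motifs
planted at fixed offsets in positive pairs (an E-box-like enhancer motif
and a TATA-like promoter motif, both 6-mers so the conservation/PSM path
has a recoverable target), label-correlated per-base signal tracks
(positive windows elevated by an effect size delta over Gaussian noise),
and log-spaced enhancer-promoter distances drawn per class.

All randomness flows from the ``seed`` field of :class:`SyntheticSpec`;
two runs with the same spec are identical.  ``SyntheticSpec.null()`` removes every class signal —
no motifs, no track elevation, identical distance distributions — so null
calibration checks are honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import ArrayTrack, EPPair, GenomicInterval

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated dataset."""

    n_pos: int = 50
    ratio: int = 20
    enhancer_length: int = 200
    promoter_length: int = 150
    enhancer_motif: str = "CACGTG"
    promoter_motif: str = "TATAAA"
    enhancer_motif_offset: int = 97
    promoter_motif_offset: int = 40
    p_plant: float = 1.0
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mu0: float = 1.0              # track baseline
    sigma: float = 0.5            # per-base track noise SD
    delta: float = 1.5            # positive-window elevation (default 3*sigma)
    log10_dist_pos: tuple[float, float] = (4.3, 0.4)   # (mean, sd) in log10 bp
    log10_dist_neg: tuple[float, float] = (4.8, 0.4)
    cell_line: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        for name in ("p_plant",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValidationError("base_probs must sum to 1")
        if len(self.enhancer_motif) > self.enhancer_length:
            raise ValidationError("enhancer motif longer than the element")
        if len(self.promoter_motif) > self.promoter_length:
            raise ValidationError("promoter motif longer than the element")
        if (self.enhancer_motif_offset + len(self.enhancer_motif)
                > self.enhancer_length):
            raise ValidationError("enhancer motif does not fit at its offset")
        if (self.promoter_motif_offset + len(self.promoter_motif)
                > self.promoter_length):
            raise ValidationError("promoter motif does not fit at its offset")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SyntheticSpec":
        """No class signal at all: the AUROC of any predictor should sit
        near 0.5."""
        base = dict(p_plant=0.0, delta=0.0,
                    log10_dist_pos=(4.5, 0.4), log10_dist_neg=(4.5, 0.4),
                    seed=seed)
        base.update(overrides)
        return cls(**base)


@dataclass
class TruthRecord:
    """Where the signal was planted, for recovery checks."""

    enhancer_motif_positions: dict[str, int] = field(default_factory=dict)
    promoter_motif_positions: dict[str, int] = field(default_factory=dict)
    spec: SyntheticSpec | None = None


def _random_seq(rng: np.random.Generator, length: int, probs) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(probs))


def generate_pairs(spec: SyntheticSpec) -> tuple[list[EPPair], TruthRecord]:
    """Generate ``n_pos * (1 + ratio)`` pairs on one synthetic chromosome.

    Positives carry both motifs (each with probability ``p_plant``) at the
    spec's fixed offsets; negatives are pure background.  Elements are laid
    out left to right with their class-conditional midpoint distances, so
    interval coordinates are usable for distance and track features.
    """
    rng = np.random.default_rng(spec.seed)
    n_neg = spec.n_pos * spec.ratio
    labels = np.concatenate([np.ones(spec.n_pos, dtype=int),
                             np.zeros(n_neg, dtype=int)])
    truth = TruthRecord(spec=spec)
    pairs: list[EPPair] = []
    cursor = 1000
    chrom = "chrS"
    for i, label in enumerate(labels):
        pair_id = f"pair{i:05d}"
        enh_codes = _random_seq(rng, spec.enhancer_length, spec.base_probs)
        prom_codes = _random_seq(rng, spec.promoter_length, spec.base_probs)
        if label == 1:
            if rng.random() < spec.p_plant:
                off = spec.enhancer_motif_offset
                enh_codes[off:off + len(spec.enhancer_motif)] = [
                    "ACGT".index(b) for b in spec.enhancer_motif]
                truth.enhancer_motif_positions[pair_id] = off
            if rng.random() < spec.p_plant:
                off = spec.promoter_motif_offset
                prom_codes[off:off + len(spec.promoter_motif)] = [
                    "ACGT".index(b) for b in spec.promoter_motif]
                truth.promoter_motif_positions[pair_id] = off
        mu, sd = spec.log10_dist_pos if label == 1 else spec.log10_dist_neg
        dist = int(10 ** rng.normal(mu, sd))
        dist = max(dist, spec.enhancer_length + spec.promoter_length)
        enh_iv = GenomicInterval(chrom, cursor, cursor + spec.enhancer_length)
        prom_start = int(enh_iv.midpoint + dist - spec.promoter_length / 2)
        prom_iv = GenomicInterval(chrom, prom_start,
                                  prom_start + spec.promoter_length)
        cursor = prom_iv.end + 500
        pairs.append(EPPair(
            pair_id=pair_id,
            enhancer_seq="".join(_BASES[enh_codes]),
            promoter_seq="".join(_BASES[prom_codes]),
            label=int(label), enhancer=enh_iv, promoter=prom_iv,
            cell_line=spec.cell_line,
        ))
    return pairs, truth


def generate_tracks(spec: SyntheticSpec,
                    pairs: list[EPPair]) -> dict[str, ArrayTrack]:
    """Label-correlated per-base tracks for RAD21 / ATAC / H3K27ac.

    Each element window holds N(mu0, sigma) noise, elevated by ``delta``
    for positive pairs; only element windows are materialized (the regions
    a real pipeline would query), and the three assays get independent
    noise streams.
    """
    rng = np.random.default_rng(spec.seed + 1)
    chrom_end = max(p.promoter.end for p in pairs) + 1000
    tracks = {name: ArrayTrack({"chrS": chrom_end})
              for name in ("rad21", "atac", "h3k27ac")}
    seen: set[tuple[int, int]] = set()
    for pair in pairs:
        lift = spec.delta if pair.label == 1 else 0.0
        for interval in (pair.enhancer, pair.promoter):
            key = (interval.start, interval.end)
            if key in seen:
                raise ValidationError(
                    f"overlapping element windows at {key}; layout invalid"
                )
            seen.add(key)
            for track in tracks.values():
                values = rng.normal(spec.mu0 + lift, spec.sigma, len(interval))
                track.add(interval.chrom, interval.start, values)
    return tracks


def generate_dataset(spec: SyntheticSpec):
    """Convenience: pairs, tracks and truth in one call."""
    pairs, truth = generate_pairs(spec)
    tracks = generate_tracks(spec, pairs)
    return pairs, tracks, truth
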