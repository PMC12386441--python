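"""Run configuration: every tunable the pipeline reads, with defaults.

Defaults mirror the published network scale (1000x8 pooled embedding,
64/32/64 convolution filters, 128-wide genomic dense layer, patience 5,
5-fold CV).  :meth:`RunConfig.reduced` is the package's validation-scale
configuration: same architecture and protocol, smaller tensors, so the
whole pipeline runs end-to-end on one CPU core in seconds per sub-model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    # sequence windows
    enhancer_length: int = 3000
    promoter_length: int = 2000

    # KNF
    knf_k: tuple[int, ...] = (1, 2, 3, 4)
    knf_mode: str = "frequency"          # "frequency" | "onehot"

    # TPCP
    tpcp_table: str | None = None        # None -> packaged synthetic default

    # PCPS
    pcps_k: int = 6
    pcps_m: int = 10
    pcps_f0: float = 1.0 / 200.0

    # k-mer embedding
    embed_k: int = 5
    embed_dim: int = 8
    embed_window: int = 5
    embed_epochs: int = 2
    embed_negatives: int = 5
    embed_max_pairs: int = 200_000
    embed_lr: float = 0.025

    # fusion
    pooled_length: int = 1000
    encoders: tuple[str, ...] = ("knf", "tpcp", "pcps", "dna2vec")

    # BESL / CV
    besl_ratio: int | None = None        # None -> computed from the data
    folds: int = 5
    patience: int = 5
    max_epochs: int = 100
    val_fraction: float = 0.2

    # network
    conv_filters: tuple[int, int, int, int] = (64, 32, 64, 64)
    pool_width: int = 4
    dropout_conv: float = 0.2
    dropout_dense: float = 0.5
    att_dim: int = 32
    heads: int = 4
    att_eps: float = 1e-8
    genomic_dense: int = 128
    seqvec_dense: int = 64
    fusion_dense: int = 128
    sequence_only: bool = False

    # optimization
    batch_size: int = 64
    lr: float = 1e-3
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        positives = {
            "enhancer_length": self.enhancer_length,
            "promoter_length": self.promoter_length,
            "pcps_k": self.pcps_k, "pcps_m": self.pcps_m,
            "embed_k": self.embed_k, "embed_dim": self.embed_dim,
            "pooled_length": self.pooled_length, "folds": self.folds,
            "patience": self.patience, "max_epochs": self.max_epochs,
            "batch_size": self.batch_size, "heads": self.heads,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not 0 < self.val_fraction < 1:
            raise ConfigError("val_fraction must lie in (0,1)")
        if self.att_eps <= 0:
            raise ConfigError("att_eps must be positive")
        if self.knf_mode not in ("frequency", "onehot"):
            raise ConfigError(f"unknown knf_mode {self.knf_mode!r}")
        unknown = set(self.encoders) - {"knf", "tpcp", "pcps", "dna2vec", "onehot"}
        if unknown:
            raise ConfigError(f"unknown encoders {sorted(unknown)}")

    @classmethod
    def reduced(cls, **overrides) -> "RunConfig":
        """Desk-scale configuration used throughout validation runs."""
        base = dict(
            enhancer_length=200, promoter_length=150,
            pooled_length=24, pool_width=2,
            conv_filters=(16, 8, 16, 32),
            att_dim=8, genomic_dense=32, seqvec_dense=32, fusion_dense=32,
            max_epochs=15, batch_size=32,
            embed_epochs=1, embed_max_pairs=30_000,
        )
        base.update(overrides)
        return cls(**base)

    # -- (de)serialization --------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("knf_k", "encoders", "conv_filters"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)
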