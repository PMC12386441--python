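"""The four fused DNA sequence encoders.

* KNF - k-mer nucleotide frequency: for K in {1,2,3,4} each position carries
  a frequency-weighted indicator of the k-mer starting there, blocks
  concatenated to 4+16+64+256 = 340 columns.
* TPCP - trinucleotide physicochemical properties: frequency of each of the
  64 trinucleotides times each of 11 normalized property values (704 long).
* PCPS - position conservation and position-specific scoring: a chi-square
  style conservation profile C_k(i) over fitted positions, the top-M most
  conserved positions, and a pseudocount position score matrix with log-odds
  scores PSF = ln(m/f0) against background f0.
* DNA2vec - k-mer word embedding with adaptive pooling (see ``embedding``).

Positional encoders (KNF, DNA2vec, optional one-hot) are pooled to a common
row count and concatenated along the feature axis; per-sequence encoders
(TPCP, PCPS) concatenate into a dense vector routed past the convolutional
path.  A channel manifest records which columns belong to which encoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .embedding import (KmerEmbeddingModel, adaptive_pool, encode_dna2vec,
                        tokenize_kmers, train_kmer_embedding)
from .errors import ConfigError, ModelStateError, ValidationError
from .io import EPPair, standardize_sequence

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


def sequence_codes(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, N=-1."""
    try:
        return np.array([_BASE_CODE[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"non-ACGTN character {exc.args[0]!r} in sequence")


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic index of the k-mer starting at each position; -1 if it
    contains N."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        seg = codes[j:j + n]
        out = out * 4 + np.where(seg < 0, 0, seg)
        valid &= seg >= 0
    out[~valid] = -1
    return out


# ---------------------------------------------------------------------------
# KNF
# ---------------------------------------------------------------------------

@dataclass
class KnfMatrix:
    """Concatenated per-K frequency pattern matrix (rows x sum(4^K))."""

    values: np.ndarray
    k_list: tuple[int, ...]

    @property
    def block_widths(self) -> tuple[int, ...]:
        return tuple(4 ** k for k in self.k_list)


def encode_knf(seq: str, k_list: Sequence[int] = (1, 2, 3, 4),
               mode: str = "frequency") -> KnfMatrix:
    """k-mer nucleotide frequency encoding.

    Row ``i`` of block ``K`` holds, at the lexicographic index of the k-mer
    starting at ``i``, either that k-mer's whole-sequence frequency
    (``mode="frequency"``) or 1 (``mode="onehot"``).  Blocks for larger K
    have fewer defined rows and are right-padded with zeros to a common
    height of ``L - min(K) + 1``.  k-mers containing N contribute nothing.
    """
    k_list = tuple(k_list)
    if not k_list or any(k <= 0 for k in k_list):
        raise ValidationError(f"k_list must be positive integers, got {k_list}")
    if mode not in ("frequency", "onehot"):
        raise ValidationError(f"unknown KNF mode {mode!r}")
    codes = sequence_codes(seq)
    if codes.size < max(k_list):
        raise ValidationError(
            f"sequence of length {codes.size} shorter than max k {max(k_list)}"
        )
    n_rows = codes.size - min(k_list) + 1
    width = sum(4 ** k for k in k_list)
    out = np.zeros((n_rows, width), dtype=np.float64)
    offset = 0
    for k in k_list:
        kc = kmer_codes(codes, k)
        valid = kc >= 0
        if valid.any():
            if mode == "frequency":
                counts = np.bincount(kc[valid], minlength=4 ** k)
                freqs = counts / valid.sum()
                vals = freqs[kc[valid]]
            else:
                vals = np.ones(valid.sum())
            rows = np.nonzero(valid)[0]
            out[rows, offset + kc[valid]] = vals
        offset += 4 ** k
    return KnfMatrix(values=out, k_list=k_list)


def encode_onehot(seq: str) -> np.ndarray:
    """Plain one-hot base encoding (optional fifth encoder); N rows are zero."""
    codes = sequence_codes(seq)
    out = np.zeros((codes.size, 4))
    valid = codes >= 0
    out[np.nonzero(valid)[0], codes[valid]] = 1.0
    return out


# ---------------------------------------------------------------------------
# TPCP
# ---------------------------------------------------------------------------

TRINUCLEOTIDES = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


def load_property_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a 64-row trinucleotide physicochemical property table.

    With no path, the packaged default is used: a deterministic synthetic
    surrogate of 11 composition/thermodynamic-style descriptors (min-max
    normalized per property), shipped so the encoder is runnable offline.
    Substitute any 64 x P table (CSV, ``trinucleotide`` column + one column
    per property) to use published property sets.
    """
    if path is None:
        ref = resources.files("epibesl.data") / "trinucleotide_properties_synthetic.csv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    if "trinucleotide" not in table.columns:
        raise ValidationError("property table needs a 'trinucleotide' column")
    table = table.set_index("trinucleotide")
    if sorted(table.index) != sorted(TRINUCLEOTIDES):
        raise ValidationError("property table must have exactly the 64 trinucleotides")
    return table.loc[list(TRINUCLEOTIDES)]


@dataclass
class TpcpVector:
    """Per-sequence TPCP feature vector of length 64 * P."""

    values: np.ndarray
    property_names: tuple[str, ...]


def encode_tpcp(seq: str, property_table: pd.DataFrame) -> TpcpVector:
    """Trinucleotide frequency x physicochemical property products.

    Entry (t, p) = pc_p(t) * f_t with f_t the frequency of trinucleotide t
    over N-free windows; layout is trinucleotide-major, so the default
    11-property table yields a 704-long vector.
    """
    if property_table.shape[0] != 64:
        raise ValidationError(
            f"property table must have 64 rows, got {property_table.shape[0]}"
        )
    codes = sequence_codes(seq)
    if codes.size < 3:
        raise ValidationError("sequence shorter than a trinucleotide")
    tri = kmer_codes(codes, 3)
    valid = tri >= 0
    freqs = np.zeros(64)
    if valid.any():
        freqs = np.bincount(tri[valid], minlength=64) / valid.sum()
    pc = property_table.to_numpy(dtype=float)          # (64, P)
    values = (pc * freqs[:, None]).reshape(-1)         # trinucleotide-major
    return TpcpVector(values=values,
                      property_names=tuple(property_table.columns))


# ---------------------------------------------------------------------------
# PCPS
# ---------------------------------------------------------------------------

def fit_conservation(seqs: Sequence[str], k: int,
                     f_e: float | None = None) -> np.ndarray:
    """Per-position conservation C_k(i) of length-k fragments.

    C_k(i) = sum_n (f_i(n) - f_e)^2 / f_e over all 4^k fragments n, where
    f_i(n) is the fraction of sequences whose fragment at position i equals
    n.  The background f_e defaults to 1/4^k, for which C is 0 exactly when
    the empirical fragment distribution is uniform.
    """
    if len(seqs) < 2:
        raise ValidationError("conservation needs at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValidationError(f"sequences must share one length, got {sorted(lengths)}")
    length = lengths.pop()
    if length < k:
        raise ValidationError(f"sequences of length {length} shorter than k={k}")
    if f_e is None:
        f_e = 1.0 / 4 ** k
    frag = np.stack([kmer_codes(sequence_codes(s), k) for s in seqs])  # (n, L-k+1)
    n_pos = frag.shape[1]
    cons = np.zeros(n_pos)
    for i in range(n_pos):
        col = frag[:, i]
        col = col[col >= 0]
        if col.size == 0:
            continue
        freqs = np.bincount(col) / col.size
        # full sum over 4^k fragments: unobserved ones each contribute f_e
        cons[i] = (np.sum(freqs ** 2) - 2 * f_e * np.sum(freqs)) / f_e + 4 ** k * f_e
    return cons


def select_conserved_positions(conservation: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m largest conservation values, ties to the smaller index."""
    if m <= 0:
        raise ValidationError(f"m must be positive, got {m}")
    conservation = np.asarray(conservation, dtype=float)
    if m > conservation.size:
        raise ValidationError(
            f"m={m} exceeds the {conservation.size} available positions"
        )
    return np.argsort(-conservation, kind="stable")[:m]


def fit_position_score_matrix(seqs: Sequence[str], positions: Sequence[int],
                              k: int, f0: float = 1.0 / 200.0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Pseudocount position score matrix and its log-odds transform.

    For fragment x at selected position i, m_xi = (n_xi + f0) / (N_i +
    4^k * f0): every column is an exact probability vector, and a fragment
    whose m equals the background f0 scores PSF = ln(m/f0) = 0.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        raise ValidationError("empty position list")
    frag = np.stack([kmer_codes(sequence_codes(s), k) for s in seqs])
    if positions.max() >= frag.shape[1] or positions.min() < 0:
        raise ValidationError(
            f"positions must lie in [0, {frag.shape[1]}), got {positions.tolist()}"
        )
    n_frag = 4 ** k
    psm = np.zeros((n_frag, positions.size))
    for j, i in enumerate(positions):
        col = frag[:, i]
        col = col[col >= 0]
        counts = np.bincount(col, minlength=n_frag) if col.size else np.zeros(n_frag)
        psm[:, j] = (counts + f0) / (col.size + n_frag * f0)
    psf = np.log(psm / f0)
    return psm, psf


@dataclass
class PCPSModel:
    """Fitted conservation profile + pseudocount position-score matrix."""

    k: int
    f_e: float
    f0: float
    conservation: np.ndarray
    selected_positions: np.ndarray
    psm: np.ndarray                      # (4^k, M)
    psf: np.ndarray                      # ln(psm / f0)
    seq_length: int

    @classmethod
    def fit(cls, seqs: Sequence[str], k: int = 6, m: int = 10,
            f0: float = 1.0 / 200.0, f_e: float | None = None) -> "PCPSModel":
        if f_e is None:
            f_e = 1.0 / 4 ** k
        conservation = fit_conservation(seqs, k, f_e)
        selected = select_conserved_positions(conservation, m)
        psm, psf = fit_position_score_matrix(seqs, selected, k, f0)
        return cls(k=k, f_e=f_e, f0=f0, conservation=conservation,
                   selected_positions=selected, psm=psm, psf=psf,
                   seq_length=len(seqs[0]))


def encode_pcps(seq: str, model: PCPSModel) -> np.ndarray:
    """Length-2M vector: conservation at the M selected positions followed
    by the PSF log-odds of the sequence's fragments there (N fragments
    score 0)."""
    if model is None or model.psf is None:
        raise ModelStateError("PCPS model is not fitted")
    frag = kmer_codes(sequence_codes(seq), model.k)
    if frag.size <= int(model.selected_positions.max()):
        raise ValidationError(
            f"sequence of length {len(seq)} does not cover selected position "
            f"{int(model.selected_positions.max())}"
        )
    cons = model.conservation[model.selected_positions]
    scores = np.zeros(model.selected_positions.size)
    for j, i in enumerate(model.selected_positions):
        code = frag[i]
        if code >= 0:
            scores[j] = model.psf[code, j]
    return np.concatenate([cons, scores])


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    encoder: str
    section: str          # "conv" (positional) or "dense" (per-sequence)
    start: int
    width: int


@dataclass
class EncodedPair:
    """Fused feature blocks for one EP pair.

    ``*_conv`` are the pooled positional feature matrices (rows x channels)
    consumed by the convolutional branch; ``*_vec`` the per-sequence dense
    features.  The manifest is identical for enhancer and promoter.
    """

    pair_id: str
    enhancer_conv: np.ndarray
    promoter_conv: np.ndarray
    enhancer_vec: np.ndarray
    promoter_vec: np.ndarray
    manifest: tuple[ManifestEntry, ...]
    label: int


@dataclass
class FittedEncoders:
    """All training-data-dependent encoder state, fitted on fold-train pairs.

    The conservation/position-score model is fitted on the positive training
    pairs of each element type: conserved regulatory sites characterize the
    interacting class, and the fragment log-odds of a query sequence against
    that profile is the discriminative part of the PCPS feature.
    """

    config: RunConfig
    property_table: pd.DataFrame | None = None
    pcps_enhancer: PCPSModel | None = None
    pcps_promoter: PCPSModel | None = None
    embedding: KmerEmbeddingModel | None = None

    @classmethod
    def fit(cls, train_pairs: Sequence[EPPair], config: RunConfig,
            seed: int = 0) -> "FittedEncoders":
        enc = cls(config=config)
        if "tpcp" in config.encoders:
            enc.property_table = load_property_table(config.tpcp_table)
        enh_seqs = [standardize_sequence(p.enhancer_seq, config.enhancer_length)
                    for p in train_pairs]
        prom_seqs = [standardize_sequence(p.promoter_seq, config.promoter_length)
                     for p in train_pairs]
        if "pcps" in config.encoders:
            pos = [i for i, p in enumerate(train_pairs) if p.label == 1]
            if len(pos) < 2:
                raise ValidationError(
                    "PCPS fitting needs at least 2 positive training pairs"
                )
            enc.pcps_enhancer = PCPSModel.fit(
                [enh_seqs[i] for i in pos], k=config.pcps_k, m=config.pcps_m,
                f0=config.pcps_f0)
            enc.pcps_promoter = PCPSModel.fit(
                [prom_seqs[i] for i in pos], k=config.pcps_k, m=config.pcps_m,
                f0=config.pcps_f0)
        if "dna2vec" in config.encoders:
            corpus = [tokenize_kmers(s, config.embed_k)
                      for s in enh_seqs + prom_seqs]
            enc.embedding = train_kmer_embedding(
                corpus, k=config.embed_k, dim=config.embed_dim,
                window=config.embed_window, epochs=config.embed_epochs,
                negatives=config.embed_negatives,
                max_pairs=config.embed_max_pairs, lr=config.embed_lr,
                pooled_length=config.pooled_length, seed=seed)
        return enc


def _element_features(seq: str, encoders: FittedEncoders, pcps_model,
                      config: RunConfig) -> tuple[np.ndarray, np.ndarray, list]:
    conv_parts, dense_parts, manifest_raw = [], [], []
    for name in config.encoders:
        if name == "knf":
            block = adaptive_pool(encode_knf(seq, config.knf_k,
                                             config.knf_mode).values,
                                  config.pooled_length)
            conv_parts.append(block)
            manifest_raw.append((name, "conv", block.shape[1]))
        elif name == "onehot":
            block = adaptive_pool(encode_onehot(seq), config.pooled_length)
            conv_parts.append(block)
            manifest_raw.append((name, "conv", block.shape[1]))
        elif name == "dna2vec":
            if encoders.embedding is None:
                raise ConfigError("dna2vec requested but embedding not fitted")
            if encoders.embedding.k != config.embed_k:
                raise ConfigError(
                    f"embedding fitted with k={encoders.embedding.k}, "
                    f"config expects k={config.embed_k}"
                )
            block = encode_dna2vec(seq, encoders.embedding, config.pooled_length)
            conv_parts.append(block)
            manifest_raw.append((name, "conv", block.shape[1]))
        elif name == "tpcp":
            vec = encode_tpcp(seq, encoders.property_table).values
            dense_parts.append(vec)
            manifest_raw.append((name, "dense", vec.size))
        elif name == "pcps":
            if pcps_model is None:
                raise ConfigError("pcps requested but model not fitted")
            if pcps_model.k != config.pcps_k:
                raise ConfigError(
                    f"PCPS fitted with k={pcps_model.k}, config expects "
                    f"k={config.pcps_k}"
                )
            vec = encode_pcps(seq, pcps_model)
            dense_parts.append(vec)
            manifest_raw.append((name, "dense", vec.size))
    conv = (np.concatenate(conv_parts, axis=1) if conv_parts
            else np.zeros((config.pooled_length, 0)))
    dense = np.concatenate(dense_parts) if dense_parts else np.zeros(0)
    return conv, dense, manifest_raw


def four_encode(pair: EPPair, encoders: FittedEncoders,
                config: RunConfig | None = None) -> EncodedPair:
    """Encode one pair with every enabled encoder and merge along features."""
    config = config or encoders.config
    enh = standardize_sequence(pair.enhancer_seq, config.enhancer_length)
    prom = standardize_sequence(pair.promoter_seq, config.promoter_length)
    e_conv, e_vec, raw = _element_features(enh, encoders,
                                           encoders.pcps_enhancer, config)
    p_conv, p_vec, _ = _element_features(prom, encoders,
                                         encoders.pcps_promoter, config)
    manifest, offsets = [], {"conv": 0, "dense": 0}
    for name, section, width in raw:
        manifest.append(ManifestEntry(name, section, offsets[section], width))
        offsets[section] += width
    return EncodedPair(pair_id=pair.pair_id, enhancer_conv=e_conv,
                       promoter_conv=p_conv, enhancer_vec=e_vec,
                       promoter_vec=p_vec, manifest=tuple(manifest),
                       label=pair.label)
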