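"""The EPI network: multi-scale convolution over sequence features, multi-head
feature attention over genomic features, and a softmax fusion head.

MCNet (sequence branch) pipeline: an initial kernel-9 convolution with ReLU,
average pooling and dropout; three structurally identical parallel sub-blocks
(conv k=5 -> BN -> ReLU -> dropout -> conv k=3 -> BN -> ReLU); channel
concatenation followed by a kernel-1 convolution, dropout, BN, ReLU and a
second dropout; global average pooling to a fixed-length vector.  Enhancer
and promoter share one tower (they run as a single stacked batch), a
parameter-economy choice — the feature manifest is identical for both.

MANet (genomic branch): the min-max-normalized 4-row feature matrix
(RAD21, ATAC, H3K27ac, distance) is linearly projected to d dimensions;
each head h computes u = tanh(xW_h + b_h), scores u.w_h, masks invalid
rows, and normalizes with a stabilising epsilon in the denominator, so the
per-head weights sum to S/(S+eps) < 1 and masked rows get exactly 0.  Head
outputs are concatenated, batch-normalized and mapped to the genomic dense
width.

Per-sequence features (TPCP, PCPS) are vectors, not position series; they
bypass the convolutional path through one dense layer and join the fusion
concatenation, which ends in a 2-way softmax trained with categorical
cross-entropy.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .errors import ConfigError, DivergenceError, ValidationError
from .nn import (Adam, AvgPool1D, BatchNorm, Conv1D, Dense, Dropout,
                 GlobalAvgPool, Layer, ReLU, Tanh, cross_entropy, softmax)


def min_rows_required(pool_width: int) -> int:
    """Smallest positional-feature height the MCNet receptive field accepts."""
    # kernel 9, pool, kernel 5, kernel 3 with valid padding
    return 8 + pool_width * 7


class McnetTower:
    """Shared multi-scale convolution tower for enhancer/promoter blocks."""

    def __init__(self, channels: int, config: RunConfig, rng: np.random.Generator):
        f0, f1, f2, f3 = config.conv_filters
        self.conv0 = Conv1D(channels, f0, 9, rng)
        self.relu0 = ReLU()
        self.pool = AvgPool1D(config.pool_width)
        self.drop0 = Dropout(config.dropout_conv, rng)
        self.branches = []
        for _ in range(3):
            self.branches.append({
                "convA": Conv1D(f0, f1, 5, rng), "bnA": BatchNorm(f1),
                "reluA": ReLU(), "dropA": Dropout(config.dropout_conv, rng),
                "convB": Conv1D(f1, f2, 3, rng), "bnB": BatchNorm(f2),
                "reluB": ReLU(),
            })
        self.f2 = f2
        self.conv1 = Conv1D(3 * f2, f3, 1, rng)
        self.drop1 = Dropout(config.dropout_conv, rng)
        self.bn1 = BatchNorm(f3)
        self.relu1 = ReLU()
        self.drop2 = Dropout(config.dropout_conv, rng)
        self.gap = GlobalAvgPool()
        self.out_dim = f3
        self.last_preconcat: np.ndarray | None = None

    def layers(self) -> list[Layer]:
        out = [self.conv0, self.relu0, self.pool, self.drop0]
        for br in self.branches:
            out.extend(br.values())
        out.extend([self.conv1, self.drop1, self.bn1, self.relu1, self.drop2,
                    self.gap])
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] < 9:
            raise ValidationError(
                f"positional block has {x.shape[1]} rows; the initial kernel "
                f"needs at least 9 (full tower needs "
                f">= {min_rows_required(self.pool.width)})"
            )
        h = self.drop0.forward(
            self.pool.forward(
                self.relu0.forward(self.conv0.forward(x, training), training),
                training),
            training)
        outs = []
        for br in self.branches:
            a = br["reluA"].forward(
                br["bnA"].forward(br["convA"].forward(h, training), training),
                training)
            a = br["dropA"].forward(a, training)
            a = br["reluB"].forward(
                br["bnB"].forward(br["convB"].forward(a, training), training),
                training)
            outs.append(a)
        merged = np.concatenate(outs, axis=2)
        self.last_preconcat = merged
        z = self.conv1.forward(merged, training)
        z = self.drop1.forward(z, training)
        z = self.bn1.forward(z, training)
        z = self.relu1.forward(z, training)
        z = self.drop2.forward(z, training)
        return self.gap.forward(z, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = self.gap.backward(dy)
        dz = self.drop2.backward(dz)
        dz = self.relu1.backward(dz)
        dz = self.bn1.backward(dz)
        dz = self.drop1.backward(dz)
        dmerged = self.conv1.backward(dz)
        dh = 0.0
        for i, br in enumerate(self.branches):
            da = dmerged[:, :, i * self.f2:(i + 1) * self.f2]
            da = br["convB"].backward(
                br["bnB"].backward(br["reluB"].backward(da)))
            da = br["dropA"].backward(da)
            da = br["convA"].backward(
                br["bnA"].backward(br["reluA"].backward(da)))
            dh = dh + da
        return self.conv0.backward(
            self.relu0.backward(self.pool.backward(self.drop0.backward(dh))))


class ManetBlock:
    """Multi-head tanh attention over the 4 genomic feature rows."""

    def __init__(self, config: RunConfig, rng: np.random.Generator):
        d, h = config.att_dim, config.heads
        self.eps = config.att_eps
        self.proj = Dense(2, d, rng)
        self.head_dense = [Dense(d, d, rng) for _ in range(h)]
        self.head_tanh = [Tanh() for _ in range(h)]
        self.head_w = [Dense(d, 1, rng, bias=False) for _ in range(h)]
        self.bn = BatchNorm(h * d)
        self.drop = Dropout(config.dropout_dense, rng)
        self.out = Dense(h * d, config.genomic_dense, rng)
        self.n_heads = h
        self.d = d
        self.last_attention: np.ndarray | None = None   # (H, b, 4)
        self.last_scores: np.ndarray | None = None

    def layers(self) -> list[Layer]:
        out: list[Layer] = [self.proj]
        for dense, tanh, w in zip(self.head_dense, self.head_tanh, self.head_w):
            out.extend([dense, tanh, w])
        out.extend([self.bn, self.drop, self.out])
        return out

    def forward(self, x: np.ndarray, valid: np.ndarray,
                training: bool = False) -> np.ndarray:
        if (~valid).all(axis=1).any():
            raise ValidationError("degenerate input: a sample has all rows masked")
        self._valid = valid
        xp = self.proj.forward(x, training)                     # (b, 4, d)
        self._xp = xp
        atts, caches, att_weights, scores_all = [], [], [], []
        for dense, tanh, w in zip(self.head_dense, self.head_tanh, self.head_w):
            u = tanh.forward(dense.forward(xp, training), training)
            s = w.forward(u, training)[..., 0]                  # (b, 4)
            e = np.exp(s) * valid
            a = e / (e.sum(axis=1, keepdims=True) + self.eps)
            atts.append(np.einsum("bi,bid->bd", a, xp))
            caches.append(a)
            att_weights.append(a)
            scores_all.append(np.where(valid, s, -np.inf))
        self._head_a = caches
        self.last_attention = np.stack(att_weights)
        self.last_scores = np.stack(scores_all)
        merged = np.concatenate(atts, axis=1)                   # (b, H*d)
        z = self.bn.forward(merged, training)
        z = self.drop.forward(z, training)
        return self.out.forward(z, training)

    def backward(self, dy: np.ndarray) -> None:
        dz = self.out.backward(dy)
        dz = self.drop.backward(dz)
        dmerged = self.bn.backward(dz)
        dxp = np.zeros_like(self._xp)
        for i, (dense, tanh, w) in enumerate(
                zip(self.head_dense, self.head_tanh, self.head_w)):
            datt = dmerged[:, i * self.d:(i + 1) * self.d]       # (b, d)
            a = self._head_a[i]
            da = np.einsum("bd,bid->bi", datt, self._xp)
            dxp += a[..., None] * datt[:, None, :]
            ds = a * (da - (a * da).sum(axis=1, keepdims=True))
            du = w.backward(ds[..., None])
            dxp += dense.backward(tanh.backward(du))
        self.proj.backward(dxp)


class MCANet:
    """Full fusion classifier over encoded EP pairs.

    Duck-typed training interface consumed by the ensemble code:
    ``fit_epoch(data, idx)``, ``loss_on(data, idx)``,
    ``predict_proba(data, idx)``, ``get_state()`` / ``set_state()``.
    """

    def __init__(self, conv_channels: int, vec_dim: int, config: RunConfig,
                 seed: int = 0):
        if config.pooled_length < min_rows_required(config.pool_width):
            raise ConfigError(
                f"pooled_length {config.pooled_length} below the tower's "
                f"receptive field; needs >= {min_rows_required(config.pool_width)}"
            )
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.tower = McnetTower(conv_channels, config, self.rng)
        self.manet = None if config.sequence_only else ManetBlock(config, self.rng)
        self.vec_dense = Dense(max(vec_dim, 1), config.seqvec_dense, self.rng)
        self.vec_relu = ReLU()
        self.vec_dim = vec_dim
        fused = (2 * self.tower.out_dim + config.genomic_dense
                 + config.seqvec_dense)
        self.fuse = Dense(fused, config.fusion_dense, self.rng)
        self.fuse_relu = ReLU()
        self.fuse_drop = Dropout(config.dropout_dense, self.rng)
        self.head = Dense(config.fusion_dense, 2, self.rng)
        self._layers = (self.tower.layers()
                        + (self.manet.layers() if self.manet else [])
                        + [self.vec_dense, self.vec_relu, self.fuse,
                           self.fuse_relu, self.fuse_drop, self.head])
        handles = [(layer, name) for layer in self._layers
                   for name in layer.params]
        self.optimizer = Adam(handles, lr=config.lr)

    # -- forward/backward ---------------------------------------------------

    def forward(self, enh, prom, vec, gen, gen_mask,
                training: bool = False) -> np.ndarray:
        b = enh.shape[0]
        seq = self.tower.forward(np.concatenate([enh, prom], axis=0), training)
        enh_vec, prom_vec = seq[:b], seq[b:]
        if self.vec_dim > 0:
            v = self.vec_relu.forward(self.vec_dense.forward(vec, training),
                                      training)
        else:
            v = self.vec_relu.forward(
                self.vec_dense.forward(np.zeros((b, 1)), training), training)
        if self.manet is not None:
            g = self.manet.forward(gen, gen_mask, training)
        else:
            g = np.zeros((b, self.config.genomic_dense))
        fused = np.concatenate([enh_vec, prom_vec, g, v], axis=1)
        self._split = (enh_vec.shape[1], prom_vec.shape[1], g.shape[1])
        z = self.fuse_relu.forward(self.fuse.forward(fused, training), training)
        z = self.fuse_drop.forward(z, training)
        logits = self.head.forward(z, training)
        return softmax(logits)

    def _backward_from_probs(self, probs: np.ndarray, labels: np.ndarray) -> None:
        b = labels.size
        dlogits = probs.copy()
        dlogits[np.arange(b), labels] -= 1.0
        dlogits /= b
        dz = self.head.backward(dlogits)
        dz = self.fuse_drop.backward(dz)
        dfused = self.fuse.backward(self.fuse_relu.backward(dz))
        n_e, n_p, n_g = self._split
        d_enh = dfused[:, :n_e]
        d_prom = dfused[:, n_e:n_e + n_p]
        d_g = dfused[:, n_e + n_p:n_e + n_p + n_g]
        d_v = dfused[:, n_e + n_p + n_g:]
        self.vec_dense.backward(self.vec_relu.backward(d_v))
        if self.manet is not None:
            self.manet.backward(d_g)
        self.tower.backward(np.concatenate([d_enh, d_prom], axis=0))

    # -- training interface -------------------------------------------------

    def _batch(self, data, idx):
        return (data.enh[idx], data.prom[idx], data.vec[idx],
                data.gen[idx], data.gen_mask[idx], data.y[idx])

    def fit_epoch(self, data, idx) -> float:
        idx = np.asarray(idx)
        order = self.rng.permutation(idx.size)
        losses, weights = [], []
        bs = self.config.batch_size
        for lo in range(0, idx.size, bs):
            sel = idx[order[lo:lo + bs]]
            enh, prom, vec, gen, mask, y = self._batch(data, sel)
            probs = self.forward(enh, prom, vec, gen, mask, training=True)
            losses.append(cross_entropy(probs, y))
            weights.append(sel.size)
            self._backward_from_probs(probs, y)
            self.optimizer.step()
        return float(np.average(losses, weights=weights))

    def predict_proba(self, data, idx) -> np.ndarray:
        idx = np.asarray(idx)
        out = np.empty(idx.size)
        bs = max(self.config.batch_size, 256)
        for lo in range(0, idx.size, bs):
            sel = idx[lo:lo + bs]
            enh, prom, vec, gen, mask, _ = self._batch(data, sel)
            out[lo:lo + bs] = self.forward(enh, prom, vec, gen, mask,
                                           training=False)[:, 1]
        return out

    def loss_on(self, data, idx) -> float:
        idx = np.asarray(idx)
        losses, weights = [], []
        bs = max(self.config.batch_size, 256)
        for lo in range(0, idx.size, bs):
            sel = idx[lo:lo + bs]
            enh, prom, vec, gen, mask, y = self._batch(data, sel)
            probs = self.forward(enh, prom, vec, gen, mask, training=False)
            losses.append(cross_entropy(probs, y))
            weights.append(sel.size)
        loss = float(np.average(losses, weights=weights))
        if not np.isfinite(loss):
            raise DivergenceError(epoch=-1, message="non-finite validation loss")
        return loss

    # -- state --------------------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        state = [layer.params[name].copy()
                 for layer, name in self.optimizer.handles]
        for layer in self._layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
                state.append(np.array([layer.n_updates]))
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        k = len(self.optimizer.handles)
        for (layer, name), value in zip(self.optimizer.handles, state[:k]):
            layer.params[name] = value.copy()
        extra = iter(state[k:])
        for layer in self._layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(extra).copy()
                layer.running_var = next(extra).copy()
                layer.n_updates = int(next(extra)[0])


def model_factory(conv_channels: int, vec_dim: int, config: RunConfig):
    """Factory of factories: BESL asks for a fresh model per sub-model seed."""
    def build(seed: int) -> MCANet:
        return MCANet(conv_channels, vec_dim, config, seed=seed)
    return build
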