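"""Network behavior: determinism, shapes, attention algebra, loss,
gradient flow, and the structural identity of the three conv branches."""

from types import SimpleNamespace

import numpy as np
import pytest

from epibesl.config import RunConfig
from epibesl.errors import ConfigError, ValidationError
from epibesl.mcanet import MCANet, ManetBlock, McnetTower, min_rows_required
from epibesl.nn import cross_entropy, softmax


def random_data(n=24, rows=24, channels=10, vec_dim=6, seed=0):
    rng = np.random.default_rng(seed)
    return SimpleNamespace(
        enh=rng.random((n, rows, channels)),
        prom=rng.random((n, rows, channels)),
        vec=rng.random((n, vec_dim)),
        gen=rng.random((n, 4, 2)),
        gen_mask=np.ones((n, 4), dtype=bool),
        y=rng.integers(0, 2, n),
    )


@pytest.fixture
def config():
    return RunConfig.reduced()


@pytest.fixture
def data():
    return random_data()


class TestForward:
    def test_inference_deterministic(self, config, data):
        model = MCANet(10, 6, config, seed=1)
        a = model.predict_proba(data, np.arange(len(data.y)))
        b = model.predict_proba(data, np.arange(len(data.y)))
        assert np.array_equal(a, b)

    def test_probabilities_sum_to_one(self, config, data):
        model = MCANet(10, 6, config, seed=1)
        probs = model.forward(data.enh, data.prom, data.vec, data.gen,
                              data.gen_mask)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_output_length_independent_of_rows(self, config):
        tower = McnetTower(5, config, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        short = tower.forward(rng.random((3, 24, 5)))
        long = tower.forward(rng.random((3, 48, 5)))
        assert short.shape == long.shape == (3, config.conv_filters[3])

    def test_input_below_receptive_field_rejected(self, config):
        tower = McnetTower(5, config, np.random.default_rng(0))
        with pytest.raises(ValidationError, match=str(min_rows_required(2))):
            tower.forward(np.zeros((2, 8, 5)))
        with pytest.raises(ConfigError):
            MCANet(5, 6, RunConfig.reduced(pooled_length=12), seed=0)

    def test_sequence_only_mode_is_valid(self, data):
        cfg = RunConfig.reduced(sequence_only=True)
        model = MCANet(10, 6, cfg, seed=0)
        probs = model.forward(data.enh, data.prom, data.vec, data.gen,
                              data.gen_mask)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_shift_invariance(self):
        logits = np.array([[1.0, -2.0], [0.3, 0.4]])
        assert np.allclose(softmax(logits), softmax(logits + 7.5))


class TestAttention:
    @pytest.fixture
    def block(self, config):
        return ManetBlock(config, np.random.default_rng(3))

    def test_weights_nonnegative_masked_zero_sum_below_one(self, block, config):
        rng = np.random.default_rng(4)
        x = rng.random((8, 4, 2))
        valid = np.ones((8, 4), dtype=bool)
        valid[2, 1] = valid[2, 3] = valid[5, 0] = False
        block.forward(x, valid)
        for a, s in zip(block.last_attention, block.last_scores):
            assert np.all(a >= 0)
            assert np.all(a[~valid] == 0)
            exp_sum = np.where(valid, np.exp(s), 0).sum(axis=1)
            assert np.allclose(a.sum(axis=1),
                               exp_sum / (exp_sum + config.att_eps))
            assert np.all(a.sum(axis=1) < 1.0)

    def test_identical_rows_get_uniform_attention(self, block):
        x = np.tile([[0.3, 0.7]], (5, 4, 1))
        block.forward(x, np.ones((5, 4), dtype=bool))
        for a in block.last_attention:
            assert np.allclose(a, a[:, :1])      # equal within each sample

    def test_single_unmasked_row_dominates(self, block, config):
        rng = np.random.default_rng(6)
        x = rng.random((3, 4, 2))
        valid = np.zeros((3, 4), dtype=bool)
        valid[:, 2] = True
        out = block.forward(x, valid)
        for a, s in zip(block.last_attention, block.last_scores):
            e = np.exp(s[:, 2])
            assert np.allclose(a[:, 2], e / (e + config.att_eps))
        assert out.shape == (3, config.genomic_dense)

    def test_matches_independent_recomputation(self, block, config):
        """Re-derive the whole attention block with plain numpy from the
        block's own weight matrices."""
        rng = np.random.default_rng(7)
        x = rng.random((4, 4, 2))
        valid = np.ones((4, 4), dtype=bool)
        valid[1, 0] = False
        got = block.forward(x, valid)
        xp = x @ block.proj.params["W"] + block.proj.params["b"]
        atts = []
        for dense, w in zip(block.head_dense, block.head_w):
            u = np.tanh(xp @ dense.params["W"] + dense.params["b"])
            s = (u @ w.params["W"])[..., 0]
            e = np.exp(s) * valid
            a = e / (e.sum(axis=1, keepdims=True) + config.att_eps)
            atts.append(np.einsum("bi,bid->bd", a, xp))
        merged = np.concatenate(atts, axis=1)
        mean, var = block.bn._running_stats()
        z = ((merged - mean) / np.sqrt(var + block.bn.eps)
             * block.bn.params["gamma"] + block.bn.params["beta"])
        want = z @ block.out.params["W"] + block.out.params["b"]
        assert np.allclose(got, want)

    def test_all_rows_masked_rejected(self, block):
        x = np.zeros((2, 4, 2))
        with pytest.raises(ValidationError):
            block.forward(x, np.zeros((2, 4), dtype=bool))


class TestBranchStructure:
    def test_permuting_branches_permutes_preconcat_channels(self, config):
        tower = McnetTower(6, config, np.random.default_rng(8))
        x = np.random.default_rng(9).random((2, 24, 6))
        tower.forward(x)
        before = tower.last_preconcat.copy()
        tower.branches[0], tower.branches[1] = tower.branches[1], tower.branches[0]
        tower.forward(x)
        after = tower.last_preconcat
        f2 = config.conv_filters[2]
        assert np.array_equal(after[:, :, :f2], before[:, :, f2:2 * f2])
        assert np.array_equal(after[:, :, f2:2 * f2], before[:, :, :f2])
        assert np.array_equal(after[:, :, 2 * f2:], before[:, :, 2 * f2:])


class TestLoss:
    def test_perfect_prediction_is_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(probs, np.array([0, 1])) == pytest.approx(0.0)

    def test_uniform_prediction_is_ln2(self):
        probs = np.full((4, 2), 0.5)
        assert cross_entropy(probs, np.array([0, 1, 0, 1])) == pytest.approx(
            np.log(2))

    def test_monotone_in_true_class_probability(self):
        labels = np.array([1])
        losses = [cross_entropy(np.array([[1 - p, p]]), labels)
                  for p in (0.2, 0.5, 0.8, 0.99)]
        assert losses == sorted(losses, reverse=True)

    def test_zero_probability_clipped_not_infinite(self):
        probs = np.array([[1.0, 0.0]])
        loss = cross_entropy(probs, np.array([1]))
        assert np.isfinite(loss) and loss == pytest.approx(-np.log(1e-7))


class TestTraining:
    def test_gradient_step_reduces_batch_loss(self, config):
        data = random_data(n=16, seed=11)
        model = MCANet(10, 6, config, seed=2)
        probs0 = model.forward(data.enh, data.prom, data.vec, data.gen,
                               data.gen_mask, training=True)
        loss0 = cross_entropy(probs0, data.y)
        model._backward_from_probs(probs0, data.y)
        model.optimizer.step()
        probs1 = model.forward(data.enh, data.prom, data.vec, data.gen,
                               data.gen_mask, training=True)
        assert cross_entropy(probs1, data.y) < loss0

    def test_state_round_trip_restores_predictions(self, config, ):
        data = random_data(n=16, seed=12)
        model = MCANet(10, 6, config, seed=3)
        state = model.get_state()
        before = model.predict_proba(data, np.arange(16))
        for _ in range(3):
            model.fit_epoch(data, np.arange(16))
        assert not np.allclose(model.predict_proba(data, np.arange(16)), before)
        model.set_state(state)
        assert np.array_equal(model.predict_proba(data, np.arange(16)), before)

    def test_learns_separable_genomic_signal(self):
        """Recovery smoke: with class-separated genomic features the network
        reaches high training AUROC within a handful of epochs."""
        from epibesl.metrics import auroc
        cfg = RunConfig.reduced(max_epochs=10)
        rng = np.random.default_rng(13)
        n = 60
        y = np.array([0, 1] * (n // 2))
        gen = rng.normal(0.3, 0.05, (n, 4, 2))
        gen[y == 1] += 0.4
        data = SimpleNamespace(
            enh=rng.random((n, 24, 6)), prom=rng.random((n, 24, 6)),
            vec=rng.random((n, 4)), gen=np.clip(gen, 0, 1),
            gen_mask=np.ones((n, 4), dtype=bool), y=y)
        model = MCANet(6, 4, cfg, seed=4)
        for _ in range(10):
            model.fit_epoch(data, np.arange(n))
        assert auroc(model.predict_proba(data, np.arange(n)), y) >= 0.95
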