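"""Shared fixtures and stub models for the test suite."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from epibesl.config import RunConfig
from epibesl.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def reduced_config() -> RunConfig:
    return RunConfig.reduced()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted dataset (12 positives, 1:4) shared by read-only tests."""
    spec = SyntheticSpec(n_pos=12, ratio=4, seed=3)
    pairs, tracks, truth = generate_dataset(spec)
    return pairs, tracks, truth, spec


class ScheduledModel:
    """Stub classifier driven by a scripted validation-loss schedule.

    ``state`` records the last completed epoch, so tests can verify that
    early stopping restored the weights of the best epoch.
    """

    def __init__(self, val_schedule):
        self.val_schedule = list(val_schedule)
        self.epoch = 0
        self.state = 0

    def fit_epoch(self, data, idx):
        self.epoch += 1
        self.state = self.epoch
        return 1.0 / self.epoch

    def loss_on(self, data, idx):
        return self.val_schedule[min(self.epoch, len(self.val_schedule)) - 1]

    def predict_proba(self, data, idx):
        return np.full(len(idx), 0.5)

    def get_state(self):
        return [np.array([self.state])]

    def set_state(self, state):
        self.state = int(state[0][0])


class ConstantModel:
    """Stub classifier with a fixed output probability; trains instantly."""

    def __init__(self, proba: float = 0.5):
        self.proba = proba

    def fit_epoch(self, data, idx):
        return 1.0

    def loss_on(self, data, idx):
        return 1.0

    def predict_proba(self, data, idx):
        return np.full(len(np.asarray(idx)), self.proba)

    def get_state(self):
        return [np.array([self.proba])]

    def set_state(self, state):
        self.proba = float(state[0][0])


@pytest.fixture
def label_data():
    """Factory for minimal datasets exposing only labels (stub-model runs)."""

    def make(labels):
        return SimpleNamespace(y=np.asarray(labels, dtype=np.int64))

    return make
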