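import numpy as np
import pytest

from flexgpc.config import TrainingConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_config(scheme="RAC", **overrides) -> TrainingConfig:
    """Small widths and short schedules for fast unit tests."""
    base = dict(
        scheme=scheme, k=3, l=16, predictor_hidden=8, transformer_dim=12,
        sigma=1.0, batch_size=16, pretrain_epochs=2, main_epochs=3,
        patience=5, learning_rate=5e-3, seed=0,
        lambda_recons=0.1, lambda_mask=1e-3, lambda_group=1e-2,
    )
    base.update(overrides)
    return TrainingConfig(**base)


@pytest.fixture
def blocky_data(rng):
    """Two-block toy data: instances activate one of two feature blocks."""
    n, d = 60, 12
    owner = rng.integers(0, 2, size=n)
    X = np.zeros((n, d))
    X[owner == 0, :6] = (rng.uniform(size=((owner == 0).sum(), 6)) < 0.8)
    X[owner == 1, 6:] = (rng.uniform(size=((owner == 1).sum(), 6)) < 0.8)
    Y = owner.reshape(-1, 1).astype(float)
    return X, Y, owner
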