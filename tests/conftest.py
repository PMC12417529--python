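import numpy as np
import pytest

from trilightnet import ModelConfig, TrainConfig, gen_cohort
from trilightnet.network import FocalLossConfig
from trilightnet.synthetic import cohort_to_dataset
from trilightnet.train import train_one_fold


@pytest.fixture(scope="session")
def small_cohort_data():
    """32-subject strong-effect synthetic cohort as an in-memory dataset."""
    cohort = gen_cohort(16, 16, seed=42)
    ids = [rec.subject_id for _, _, rec in cohort.subjects]
    return cohort_to_dataset(cohort, ids)


@pytest.fixture(scope="session")
def trained_small_model(small_cohort_data):
    """A briefly trained test-preset model (shared across tests that
    need trained, non-degenerate weights)."""
    data = small_cohort_data
    n = len(data)
    idx = np.arange(n)
    train_idx = idx[: n - 8]
    val_idx = idx[n - 8 :]
    cfg = TrainConfig(
        epochs=6, batch_size=8, lr=1e-3, t_max=50, patience=50, seed=7,
        loss=FocalLossConfig(),
    )
    model, history = train_one_fold(data, train_idx, val_idx, ModelConfig(), cfg)
    return model
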