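import numpy as np
import pytest

from guideoff import (RecurrentOffTargetClassifier, SimulationConfig,
                      encode_pairs, generate_dataset)
from guideoff.training import stratified_split_indices


@pytest.fixture(scope="session")
def rule_dataset():
    """Small noiseless planted-rule dataset (positive iff PAM intact and
    no mismatch at positions 16-20), mild 9:1 imbalance."""
    cfg = SimulationConfig(n_records=4000, imbalance_ratio=9, seed=7)
    ds = generate_dataset(cfg)
    X = encode_pairs(ds.records, channels=4)
    y = ds.labels()
    return ds, X, y


@pytest.fixture(scope="session")
def rule_split(rule_dataset):
    ds, X, y = rule_dataset
    tr, va, te = stratified_split_indices(y, seed=7)
    return {"X": X, "y": y, "train": tr, "val": va, "test": te, "dataset": ds}


@pytest.fixture(scope="session")
def trained_lstm(rule_split):
    """A compact bidirectional LSTM fitted on the planted-rule data;
    shared by training and interpretation tests."""
    s = rule_split
    est = RecurrentOffTargetClassifier(
        cell_type="LSTM", hidden_size=32, n_recurrent_layers=1,
        bidirectional=True, n_hidden_layers=2, dropout_p=0.1,
        batch_size=64, epochs=6, learning_rate=1e-3, random_state=11)
    est.fit(s["X"][s["train"]], s["y"][s["train"]])
    return est
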