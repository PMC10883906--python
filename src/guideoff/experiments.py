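"""End-to-end study: recover a planted seed-region rule from a trained model.

This is the package's integration showcase: generate a noiseless
synthetic benchmark whose label rule is "off-target iff the PAM is intact
and positions 16-20 carry no mismatch", train a compact bidirectional
LSTM on the 60/20/20 split with balanced bootstrapping, and check that
(a) the held-out AUPRC is high and (b) integrated-gradients feature
importance concentrates its top positive-aggregate features on the
PAM-proximal positions 16-20 — the attribution stage re-discovering the
rule that generated the labels.
"""

from __future__ import annotations

import numpy as np

from .encoding import encode_pairs
from .interpret import feature_importance, region_summary, top_features
from .model import RecurrentOffTargetClassifier
from .simulate import SimulationConfig, generate_dataset
from .training import LabeledDataset, evaluate, stratified_split_indices

#: compact LSTM used for the recovery study (all values on the search grids)
RECOVERY_HYPERPARAMETERS = dict(
    cell_type="LSTM", hidden_size=64, n_recurrent_layers=1,
    bidirectional=True, n_hidden_layers=2, dropout_p=0.1,
    batch_size=64, epochs=10, learning_rate=1e-3)


def planted_rule_recovery(n_records: int = 20000, imbalance_ratio: float = 9,
                          seed: int = 0, steps: int = 50,
                          top_k: int = 10) -> dict:
    """Run the full pipeline and summarize what it recovered.

    Returns a dict with the held-out metrics, the top-``top_k``
    positive-aggregate features, how many of them sit on the rule
    positions 16-20, and the region summary table.
    """
    cfg = SimulationConfig(n_records=n_records, imbalance_ratio=imbalance_ratio,
                           label_noise=0.0, seed=seed)
    dataset = generate_dataset(cfg)
    X = encode_pairs(dataset.records, channels=4)
    y = dataset.labels()
    tr, va, te = stratified_split_indices(y, seed=seed)

    est = RecurrentOffTargetClassifier(**RECOVERY_HYPERPARAMETERS,
                                       random_state=seed)
    est.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
    report = evaluate(est, X[te], y[te])

    test_set = LabeledDataset([dataset.records[i] for i in te],
                              provenance="synthetic")
    table = feature_importance(est, test_set, target_class=1, steps=steps)
    top = top_features(table, "positive", k=top_k)
    on_rule = int(((top["position"] >= 16) & (top["position"] <= 20)).sum())
    return {
        "metrics": report,
        "test_auprc": report.auprc,
        "feature_table": table,
        "top_features": top,
        "top_on_rule_positions": on_rule,
        "region_summary": region_summary(table),
        "history": est.history_,
        "n_records": n_records,
    }
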