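"""Training protocol and evaluation metrics.

The benchmark this package targets is extremely imbalanced (roughly one
validated off-target per 230 candidate loci), so training uses *balanced
bootstrapping*: every mini-batch holds the same number of positive and
negative examples, negatives drawn without replacement until exhausted
(which defines one epoch) and positives resampled with replacement.
Evaluation reports accuracy, precision, recall, F1, AUROC and AUPRC;
AUPRC — computed as average precision, without linear interpolation — is
the primary metric under this imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .encoding import GuideTargetPair
from .exceptions import BalancingImpossible, TrainingDiverged, StratificationImpossible
from .network import Adam, RecurrentNet, cross_entropy


@dataclass
class LabeledDataset:
    """A list of labeled guide/target pairs with a provenance tag."""

    records: list[GuideTargetPair]
    provenance: str = "synthetic"

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in idx], self.provenance)


@dataclass(frozen=True)
class SplitConfig:
    """Train/validation/test fractions (default 60/20/20) and seed."""

    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0

    def __post_init__(self):
        if min(self.fractions) <= 0 or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")


def stratified_split_indices(
    y: np.ndarray, fractions=(0.60, 0.20, 0.20), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition indices into train/validation/test, stratified by label.

    The partition is exact (disjoint, exhaustive) with subset sizes fixed
    by rounding the fractions; within each class the assignment is a
    seeded random draw. If any class is too small to stratify, falls back
    to a fully random split with a :class:`StratificationImpossible`
    warning.
    """
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    n_train = n - n_val - n_test

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 3:
        warnings.warn(
            "class too small to stratify; using an unstratified split",
            StratificationImpossible,
        )
        perm = rng.permutation(n)
        return (np.sort(perm[:n_train]), np.sort(perm[n_train:n_train + n_val]),
                np.sort(perm[n_train + n_val:]))

    # largest-remainder apportionment of each class across the subsets
    train, val, test = [], [], []
    targets = np.array([n_train, n_val, n_test], dtype=float)
    for c in classes:
        idx = rng.permutation(np.flatnonzero(y == c))
        quota = targets / n * len(idx)
        base = np.floor(quota).astype(int)
        rem = len(idx) - base.sum()
        order = np.argsort(-(quota - base))
        base[order[:rem]] += 1
        a, b = base[0], base[0] + base[1]
        train.append(idx[:a]); val.append(idx[a:b]); test.append(idx[b:])
    return (np.sort(np.concatenate(train)), np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


def stratified_split(
    data: LabeledDataset, cfg: SplitConfig = SplitConfig()
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Split a dataset into train/validation/test per :class:`SplitConfig`."""
    tr, va, te = stratified_split_indices(data.labels(), cfg.fractions, cfg.seed)
    return data.subset(tr), data.subset(va), data.subset(te)


def balanced_batches(
    y: np.ndarray, batch_size: int, seed: int | np.random.Generator = 0
) -> Iterator[np.ndarray]:
    """Yield index batches with equal class counts (balanced bootstrap).

    Negatives are drawn without replacement until exhausted — one pass
    over the negatives defines the epoch — while positives are resampled
    with replacement to fill each batch. The final batch may be smaller
    but always keeps the classes equal. An odd ``batch_size`` is rounded
    down to the nearest even number.
    """
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise BalancingImpossible("both classes must be present")
    half = max(batch_size // 2, 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    neg = rng.permutation(neg)
    for start in range(0, len(neg), half):
        nb = neg[start:start + half]
        pb = rng.choice(pos, size=len(nb), replace=True)
        batch = np.concatenate([pb, nb])
        yield batch[rng.permutation(len(batch))]


def fit_network(
    net: RecurrentNet,
    X: np.ndarray,
    y: np.ndarray,
    *,
    batch_size: int,
    epochs: int,
    learning_rate: float,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    balanced: bool = True,
) -> list[dict]:
    """Run the Adam / cross-entropy training loop on a network in place.

    Returns a per-epoch history of mean training loss (and validation
    AUPRC when a validation set is supplied). All randomness — batch
    composition, bootstrap resampling, dropout masks — derives from
    ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    ss = np.random.SeedSequence(seed)
    batch_rng, drop_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    opt = Adam(net.params, lr=learning_rate)
    history: list[dict] = []
    for epoch in range(epochs):
        if balanced:
            batches = balanced_batches(y, batch_size, batch_rng)
        else:
            perm = batch_rng.permutation(len(y))
            batches = (perm[i:i + batch_size] for i in range(0, len(y), batch_size))
        losses = []
        for idx in batches:
            logits, cache = net.forward(X[idx], training=True, rng=drop_rng)
            loss, dlogits = cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(epoch)
            net.zero_grads()
            net.backward(dlogits, cache)
            opt.step(net.grads)
            losses.append(loss)
        record = {"epoch": epoch, "loss": float(np.mean(losses))}
        if X_val is not None and y_val is not None:
            score = net.predict_proba(X_val)[:, 1]
            record["val_auprc"] = float(average_precision_score(y_val, score))
        history.append(record)
    return history


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class MetricsReport:
    """Thresholded and ranking metrics for a binary classifier.

    ``auroc``/``auprc`` are None (flagged ``degenerate``) when the
    evaluation data holds a single class.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float = field(default=None)  # recomputed from precision/recall if None
    auroc: float | None = None
    auprc: float | None = None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    degenerate: bool = False

    def __post_init__(self):
        if self.f1 is None:
            self.f1 = f1_from_precision_recall(self.precision, self.recall)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "auroc": self.auroc, "auprc": self.auprc,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "degenerate": self.degenerate,
        }


def evaluate(model, X: np.ndarray, y: np.ndarray) -> MetricsReport:
    """Score a fitted model on labeled data.

    The hard label is the argmax of the two output scores (equivalently a
    0.5 threshold on the softmax positive probability); AUROC and AUPRC
    use the positive-class score, AUPRC as step-wise average precision.
    """
    y = np.asarray(y, dtype=int)
    proba = model.predict_proba(X)
    score = proba[:, 1]
    pred = (score >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    degenerate = len(np.unique(y)) < 2
    auroc = auprc = None
    if not degenerate:
        auroc = float(roc_auc_score(y, score))
        auprc = float(average_precision_score(y, score))
    return MetricsReport(
        accuracy=(tp + tn) / len(y), precision=precision, recall=recall,
        auroc=auroc, auprc=auprc, tp=tp, fp=fp, tn=tn, fn=fn,
        degenerate=degenerate,
    )
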