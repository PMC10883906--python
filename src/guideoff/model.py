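"""Sequence-pair off-target classifier, scikit-learn style.

:class:`RecurrentOffTargetClassifier` wraps the NumPy recurrent network
in a fit/predict estimator parameterized by the hyperparameter genome:
cell type, recurrent depth and directionality, hidden size, halving dense
head, dropout, and the Adam/cross-entropy training protocol with balanced
bootstrap batches. ``build_model`` / ``parameter_count`` expose the bare
network factory.
"""

from __future__ import annotations

import numpy as np

from .encoding import SEQ_LENGTH
from .exceptions import InvalidGenome
from .genome import Genome, SearchSpace
from .network import RecurrentNet
from .training import evaluate, fit_network


def build_model(genome: Genome, input_channels: int = 4,
                seed: int = 0, space: SearchSpace | None = None) -> RecurrentNet:
    """Build the trainable network described by a genome.

    Raises :class:`InvalidGenome` (naming the offending gene) when the
    genome falls outside the search space.
    """
    if input_channels not in (4, 5):
        raise InvalidGenome(f"input_channels must be 4 or 5, got {input_channels}")
    genome.validate(space)
    return RecurrentNet(
        cell_type=genome.cell_type,
        input_size=input_channels,
        hidden_size=genome.hidden_size,
        n_recurrent_layers=genome.n_recurrent_layers,
        bidirectional=genome.bidirectional,
        n_hidden_layers=genome.n_hidden_layers,
        dropout_p=genome.dropout_p,
        seed=seed,
    )


def parameter_count(model_or_genome, input_channels: int = 4) -> int:
    """Exact count of trainable scalars of a network (or of a genome's)."""
    if isinstance(model_or_genome, RecurrentNet):
        return model_or_genome.parameter_count()
    return build_model(model_or_genome, input_channels).parameter_count()


class RecurrentOffTargetClassifier:
    """Recurrent off-target classifier over encoded 23xC pair matrices.

    Parameters mirror the hyperparameter genome; ``fit`` expects
    ``X`` of shape (n, 23, C) or flattened (n, 23*C) and binary ``y``.

    Attributes (after fit)
    ----------------------
    network_ : RecurrentNet
        The trained NumPy network.
    classes_ : ndarray
        Always ``[0, 1]``.
    history_ : list of dict
        Per-epoch training loss (and validation AUPRC when validation
        data was supplied to ``fit``).
    n_channels_ : int
        Input channels inferred from the data.
    """

    def __init__(self, cell_type: str = "LSTM", hidden_size: int = 64,
                 n_recurrent_layers: int = 1, bidirectional: bool = True,
                 n_hidden_layers: int = 2, dropout_p: float = 0.1,
                 batch_size: int = 64, epochs: int = 10,
                 learning_rate: float = 1e-3, balanced: bool = True,
                 random_state: int = 0):
        self.cell_type = cell_type
        self.hidden_size = hidden_size
        self.n_recurrent_layers = n_recurrent_layers
        self.bidirectional = bidirectional
        self.n_hidden_layers = n_hidden_layers
        self.dropout_p = dropout_p
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.balanced = balanced
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------

    _param_names = ("cell_type", "hidden_size", "n_recurrent_layers",
                    "bidirectional", "n_hidden_layers", "dropout_p",
                    "batch_size", "epochs", "learning_rate", "balanced",
                    "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "RecurrentOffTargetClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @classmethod
    def from_genome(cls, genome: Genome, random_state: int = 0,
                    balanced: bool = True) -> "RecurrentOffTargetClassifier":
        return cls(cell_type=genome.cell_type, hidden_size=genome.hidden_size,
                   n_recurrent_layers=genome.n_recurrent_layers,
                   bidirectional=genome.bidirectional,
                   n_hidden_layers=genome.n_hidden_layers,
                   dropout_p=genome.dropout_p, batch_size=genome.batch_size,
                   epochs=genome.epochs, learning_rate=genome.learning_rate,
                   balanced=balanced, random_state=random_state)

    def genome(self) -> Genome:
        return Genome(cell_type=self.cell_type, batch_size=self.batch_size,
                      epochs=self.epochs,
                      n_recurrent_layers=self.n_recurrent_layers,
                      bidirectional=self.bidirectional,
                      dropout_p=self.dropout_p, hidden_size=self.hidden_size,
                      n_hidden_layers=self.n_hidden_layers,
                      learning_rate=self.learning_rate)

    # -- data validation ----------------------------------------------

    def _check_X(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] % SEQ_LENGTH:
                raise ValueError(
                    f"flattened input width {X.shape[1]} is not a multiple "
                    f"of {SEQ_LENGTH}")
            X = X.reshape(len(X), SEQ_LENGTH, X.shape[1] // SEQ_LENGTH)
        if X.ndim != 3 or X.shape[1] != SEQ_LENGTH or X.shape[2] not in (4, 5):
            raise ValueError(
                f"expected (n, {SEQ_LENGTH}, 4|5) encoded pairs, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        if fitted and X.shape[2] != self.n_channels_:
            raise ValueError(
                f"fitted with {self.n_channels_} channels, got {X.shape[2]}")
        return X

    # -- estimator API -------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> "RecurrentOffTargetClassifier":
        X = self._check_X(X)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.n_channels_ = X.shape[2]
        ss = np.random.SeedSequence(self.random_state)
        init_seed, train_seed = (int(c.generate_state(1)[0] % (2 ** 31))
                                 for c in ss.spawn(2))
        self.network_ = build_model(self.genome(), self.n_channels_,
                                    seed=init_seed)
        self.history_ = fit_network(
            self.network_, X, y,
            batch_size=self.batch_size, epochs=self.epochs,
            learning_rate=self.learning_rate, seed=train_seed,
            X_val=None if X_val is None else self._check_X(X_val, fitted=True),
            y_val=y_val, balanced=self.balanced)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = SEQ_LENGTH * self.n_channels_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return self.network_.predict_proba(self._check_X(X, fitted=True))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        self._require_fitted()
        logits = self.network_.logits(self._check_X(X, fitted=True))
        return logits[:, 1] - logits[:, 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Average precision (AUPRC), the primary metric for this task."""
        report = evaluate(self, self._check_X(X, fitted=True), y)
        return report.auprc if report.auprc is not None else 0.0

    def _require_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit first")


def train_model(model, X: np.ndarray, y: np.ndarray, genome: Genome,
                seed: int = 0, X_val=None, y_val=None) -> list[dict]:
    """Train a built network with a genome's protocol; returns history."""
    return fit_network(model, X, y, batch_size=genome.batch_size,
                       epochs=genome.epochs,
                       learning_rate=genome.learning_rate, seed=seed,
                       X_val=X_val, y_val=y_val)
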