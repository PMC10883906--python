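"""Discrete hyperparameter search space and genomes.

Eight tunable values define one candidate model: batch size, training
epochs, number of recurrent layers, bidirectionality, dropout probability,
recurrent hidden size, number of dense hidden layers and learning rate.
The recurrent cell type (RNN, LSTM or GRU) is fixed per search run and is
not a gene. The dense stack halves in width layer by layer starting from
the hidden size, so the admissible number of hidden layers depends on the
hidden size: widths are kept >= 2 and at most six hidden layers are
allowed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

from .exceptions import InvalidGenome

CELL_TYPES = ("RNN", "LSTM", "GRU")

#: gene names in crossover / serialization order
GENE_NAMES = (
    "batch_size",
    "epochs",
    "n_recurrent_layers",
    "bidirectional",
    "dropout_p",
    "hidden_size",
    "n_hidden_layers",
    "learning_rate",
)

MAX_HIDDEN_LAYERS = 6


def max_hidden_layers(hidden_size: int) -> int:
    """Largest admissible number of dense hidden layers for a hidden size.

    Widths halve from ``hidden_size``; every layer must keep width >= 2,
    and the count is capped at 6.
    """
    k = 0
    width = int(hidden_size)
    while k < MAX_HIDDEN_LAYERS and width >= 2:
        k += 1
        width //= 2
    return k


def _default_grids() -> dict[str, tuple]:
    return {
        "batch_size": (32, 64, 128, 256),
        "epochs": tuple(range(10, 101, 10)),
        "n_recurrent_layers": (1, 2),
        "bidirectional": (False, True),
        "dropout_p": tuple(round(0.10 + 0.05 * i, 2) for i in range(9)),
        "hidden_size": (32, 64, 128, 256, 512),
        "n_hidden_layers": tuple(range(0, MAX_HIDDEN_LAYERS + 1)),
        "learning_rate": (1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1, 5e-1),
    }


@dataclass(frozen=True)
class SearchSpace:
    """Ordered value grid per gene.

    The ``n_hidden_layers`` grid lists the global range 0..6; per-genome
    validity additionally requires ``n_hidden_layers <=
    max_hidden_layers(hidden_size)``.
    """

    grids: dict[str, tuple] = field(default_factory=_default_grids)

    def __post_init__(self):
        for name in GENE_NAMES:
            grid = self.grids.get(name)
            if not grid:
                raise ValueError(f"empty grid for gene {name!r}")
            if name != "bidirectional" and list(grid) != sorted(grid):
                raise ValueError(f"grid for {name!r} must be strictly increasing")

    def valid_hidden_layer_counts(self, hidden_size: int) -> tuple[int, ...]:
        cap = max_hidden_layers(hidden_size)
        return tuple(v for v in self.grids["n_hidden_layers"] if v <= cap)


@dataclass(frozen=True)
class Genome:
    """One point of the search space plus the fixed recurrent cell type."""

    cell_type: str
    batch_size: int
    epochs: int
    n_recurrent_layers: int
    bidirectional: bool
    dropout_p: float
    hidden_size: int
    n_hidden_layers: int
    learning_rate: float

    def genes(self) -> dict[str, Any]:
        d = asdict(self)
        d.pop("cell_type")
        return d

    def validate(self, space: SearchSpace | None = None) -> "Genome":
        """Structural validity; with a space, also grid membership.

        Raises :class:`InvalidGenome` naming the offending gene.
        """
        if self.cell_type not in CELL_TYPES:
            raise InvalidGenome(f"cell_type {self.cell_type!r} not in {CELL_TYPES}")
        if self.batch_size < 2 or self.epochs < 0 or self.hidden_size < 2:
            raise InvalidGenome("batch_size/epochs/hidden_size out of range")
        if self.n_recurrent_layers not in (1, 2):
            raise InvalidGenome(
                f"gene n_recurrent_layers={self.n_recurrent_layers} not in (1, 2)")
        if not 0.0 <= self.dropout_p < 1.0 or self.learning_rate < 0:
            raise InvalidGenome("dropout_p/learning_rate out of range")
        if space is not None:
            for name in GENE_NAMES:
                value = getattr(self, name)
                if value not in space.grids[name]:
                    raise InvalidGenome(
                        f"gene {name}={value!r} not in grid {space.grids[name]}"
                    )
        cap = max_hidden_layers(self.hidden_size)
        if self.n_hidden_layers > cap:
            raise InvalidGenome(
                f"gene n_hidden_layers={self.n_hidden_layers} exceeds cap "
                f"{cap} for hidden_size={self.hidden_size}"
            )
        return self

    def replace(self, **kwargs) -> "Genome":
        d = asdict(self)
        d.update(kwargs)
        return Genome(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Genome":
        return cls(**json.loads(text))

    def key(self) -> tuple:
        """Hashable identity used for fitness caching."""
        return (self.cell_type,) + tuple(getattr(self, g) for g in GENE_NAMES)


#: best-model genomes reported for the benchmark, one per cell type
TABLE_GENOMES = {
    "RNN": Genome("RNN", batch_size=256, epochs=60, n_recurrent_layers=2,
                  bidirectional=True, dropout_p=0.4, hidden_size=256,
                  n_hidden_layers=0, learning_rate=1e-3),
    "LSTM": Genome("LSTM", batch_size=64, epochs=50, n_recurrent_layers=1,
                   bidirectional=True, dropout_p=0.4, hidden_size=512,
                   n_hidden_layers=2, learning_rate=1e-4),
    "GRU": Genome("GRU", batch_size=64, epochs=30, n_recurrent_layers=2,
                  bidirectional=True, dropout_p=0.1, hidden_size=128,
                  n_hidden_layers=0, learning_rate=5e-4),
}
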