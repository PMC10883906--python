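"""Exception hierarchy for guideoff.

Every error raised by the package derives from :class:`GuideoffError` so
callers can catch the whole family with one clause.
"""


class GuideoffError(Exception):
    """Base class for all guideoff errors."""


class InvalidSequenceLength(GuideoffError):
    """Sequence is not exactly 23 nucleotides long."""


class InvalidAlphabet(GuideoffError):
    """Sequence contains a character outside {A, C, G, T, N}."""


class InvalidGenome(GuideoffError):
    """A hyperparameter value is not a member of its search-space grid."""


class BalancingImpossible(GuideoffError):
    """Balanced mini-batches require at least one sample of each class."""


class TrainingDiverged(GuideoffError):
    """Non-finite training loss; carries the epoch index."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


class SelectionError(GuideoffError):
    """Tournament size exceeds the population size."""


class CrossoverError(GuideoffError):
    """Crossover attempted between genomes of different recurrent cell types."""


class BaselineShapeError(GuideoffError):
    """Integrated-gradients baseline does not match the input shape."""


class NoHiddenLayers(GuideoffError):
    """Layer attribution requested on a model without dense hidden layers."""


class WildcardPositionError(GuideoffError):
    """Mismatch injection requested at the wildcard position 21."""


class GenerationError(GuideoffError):
    """Synthetic-data generator could not satisfy the requested configuration."""


class SchemaError(GuideoffError):
    """Dataset file is missing a required column."""


class EmptyInput(GuideoffError):
    """Dataset file contains no records."""


class StratificationImpossible(UserWarning):
    """Stratified splitting fell back to an unstratified split."""
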