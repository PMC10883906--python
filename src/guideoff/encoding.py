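"""Pair encoding of sgRNA / target-DNA 23-mers.

A guide and its candidate genomic site are compared position by position
over a 23-nt window whose last three positions (21-23) are the NGG PAM;
position 1 is the PAM-distal end. Each sequence is one-hot encoded over
four channels in the fixed order (A, T, C, G) and the two matrices are
superposed with a logical OR, so a matched position activates one channel
and a substitution mismatch activates two. An optional fifth channel
records the *direction* of a mismatch: it is set when the higher-precedence
base (precedence A > T > C > G) originates from the DNA strand.

The wildcard base N (the convention for position 21 of the guide) carries
no identity: its one-hot row is all zeros and it never counts as a
mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InvalidAlphabet, InvalidSequenceLength

SEQ_LENGTH = 23
#: PAM occupies positions 21-23 (1-based; position 1 is PAM-distal).
PAM_POSITIONS = (21, 22, 23)
#: channel order of the one-hot encoding
CHANNELS = ("A", "T", "C", "G")
#: encoding precedence A > T > C > G (lower index = higher precedence)
_PRECEDENCE = {base: i for i, base in enumerate(CHANNELS)}
_CHANNEL_INDEX = {base: i for i, base in enumerate(CHANNELS)}


def normalize_sequence(seq: str) -> str:
    """Uppercase, map RNA 'U' to 'T', and validate a 23-mer.

    Raises
    ------
    InvalidSequenceLength
        if the sequence is not exactly 23 characters.
    InvalidAlphabet
        if any character falls outside {A, C, G, T, N}.
    """
    s = str(seq).strip().upper().replace("U", "T")
    if len(s) != SEQ_LENGTH:
        raise InvalidSequenceLength(
            f"expected a {SEQ_LENGTH}-mer, got length {len(s)}: {s!r}"
        )
    bad = set(s) - {"A", "C", "G", "T", "N"}
    if bad:
        raise InvalidAlphabet(f"characters {sorted(bad)} not in {{A,C,G,T,N}}: {s!r}")
    return s


@dataclass(frozen=True)
class GuideTargetPair:
    """One sgRNA / target-DNA pair with an optional binary off-target label."""

    sgrna: str
    dna: str
    label: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "sgrna", normalize_sequence(self.sgrna))
        object.__setattr__(self, "dna", normalize_sequence(self.dna))
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a 23-mer as a 23x4 binary matrix (columns A, T, C, G).

    'N' encodes as an all-zero row: a wildcard carries no base identity.
    """
    s = normalize_sequence(seq)
    mat = np.zeros((SEQ_LENGTH, 4))
    for i, base in enumerate(s):
        if base != "N":
            mat[i, _CHANNEL_INDEX[base]] = 1.0
    return mat


def encode_pair_4ch(pair: GuideTargetPair) -> np.ndarray:
    """Superposed encoding: element-wise OR of the two one-hot matrices."""
    return np.maximum(one_hot(pair.sgrna), one_hot(pair.dna))


def encode_pair_5ch(pair: GuideTargetPair) -> np.ndarray:
    """Superposed encoding plus a direction channel.

    Channel 5 is 1 exactly at mismatched positions where the
    higher-precedence base (A > T > C > G) comes from the DNA strand,
    and 0 at every matched or wildcard position.
    """
    mat = np.zeros((SEQ_LENGTH, 5))
    mat[:, :4] = encode_pair_4ch(pair)
    sg, dn = pair.sgrna, pair.dna
    for i in range(SEQ_LENGTH):
        a, b = sg[i], dn[i]
        if a != b and a != "N" and b != "N":
            if _PRECEDENCE[b] < _PRECEDENCE[a]:
                mat[i, 4] = 1.0
    return mat


def mismatch_positions(pair: GuideTargetPair) -> list[int]:
    """1-based positions where the bases differ and neither is N.

    Position 1 is the PAM-distal end; positions 21-23 are the PAM.
    """
    return [
        i + 1
        for i, (a, b) in enumerate(zip(pair.sgrna, pair.dna))
        if a != b and a != "N" and b != "N"
    ]


def decode_position(row4: np.ndarray, ch5: float | None = None) -> tuple[str, str]:
    """Recover the (sgRNA, DNA) base pair at one position from its encoding.

    With four channels the pair is unordered (the lexicographically ordered
    pair by precedence is returned, higher precedence first); the direction
    bit, when given, orders it. All-zero rows decode to ('N', 'N').
    """
    active = [CHANNELS[c] for c in np.flatnonzero(row4[:4])]
    if not active:
        return ("N", "N")
    if len(active) == 1:
        return (active[0], active[0])
    hi, lo = active[0], active[1]  # channel order == precedence order
    if ch5 is not None and ch5 > 0:
        return (lo, hi)  # higher-precedence base came from the DNA
    return (hi, lo)


class PairEncoder:
    """Encode guide/target pairs into stacked 23xC matrices.

    A scikit-learn style (stateless) transformer: ``fit`` is a no-op and
    ``transform`` maps an iterable of :class:`GuideTargetPair` — or of
    ``(sgrna, dna)`` string tuples — to an ``(n, 23, C)`` float array.

    Parameters
    ----------
    channels : {4, 5}
        4 for the superposed OR encoding, 5 to add the direction channel.
    """

    def __init__(self, channels: int = 4):
        self.channels = channels

    def get_params(self, deep: bool = True) -> dict:
        return {"channels": self.channels}

    def set_params(self, **params) -> "PairEncoder":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: Iterable, y=None) -> "PairEncoder":
        if self.channels not in (4, 5):
            raise ValueError(f"channels must be 4 or 5, got {self.channels}")
        self.n_features_in_ = 2
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        if self.channels not in (4, 5):
            raise ValueError(f"channels must be 4 or 5, got {self.channels}")
        enc = encode_pair_4ch if self.channels == 4 else encode_pair_5ch
        mats = [enc(p if isinstance(p, GuideTargetPair) else GuideTargetPair(*p[:2]))
                for p in X]
        if not mats:
            return np.zeros((0, SEQ_LENGTH, self.channels))
        return np.stack(mats)

    def fit_transform(self, X: Iterable, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def encode_pairs(pairs: Sequence[GuideTargetPair], channels: int = 4) -> np.ndarray:
    """Functional wrapper over :class:`PairEncoder`."""
    return PairEncoder(channels=channels).fit_transform(pairs)
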