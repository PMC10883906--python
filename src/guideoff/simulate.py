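"""Synthetic guide/target benchmark generator.

Emulates the statistical shape of the published off-target benchmark —
23-mers with an NGG PAM, up to six substitution mismatches and extreme
class imbalance — with a *planted* positional label rule so the whole
pipeline (encoding, training, model selection, attribution) can be
exercised and validated without external downloads.

Guides are uniform random 20-mers followed by the PAM ``NGG``; position
21 is the wildcard N on the guide side and a concrete random base on the
DNA side, and never counts as a mismatch. Targets are derived from the
guide by injecting substitutions at distinct positions. Labels come from
a :class:`PlantedRule` — per-region mismatch tolerances encoding the
biological picture that mismatches near the PAM suppress cleavage while
PAM-distal mismatches are tolerated — optionally corrupted by symmetric
label noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import GuideTargetPair, SEQ_LENGTH, mismatch_positions
from .exceptions import GenerationError, WildcardPositionError
from .interpret import REGIONS
from .training import LabeledDataset

_BASES = ("A", "C", "G", "T")
#: 1-based positions where a substitution may be injected (21 is the wildcard)
INJECTABLE_POSITIONS = tuple(p for p in range(1, SEQ_LENGTH + 1) if p != 21)


@dataclass(frozen=True)
class PlantedRule:
    """Deterministic label rule over per-region mismatch counts.

    A pair is labeled positive (off-target) exactly when, in every
    region, its number of mismatches does not exceed that region's
    tolerance. The default tolerates any number of distal and seed-core
    mismatches but none in the PAM-proximal region (16-20) nor in the
    PAM (21-23): "PAM intact and no proximal-seed mismatch".
    """

    tolerances: dict = field(default_factory=lambda: {
        "pam_distal": 6, "seed_core": 6, "pam_proximal": 0, "pam": 0})
    regions: dict = field(default_factory=lambda: dict(REGIONS))

    def region_counts(self, positions) -> dict[str, int]:
        return {name: sum(lo <= p <= hi for p in positions)
                for name, (lo, hi) in self.regions.items()}

    def label(self, pair: GuideTargetPair) -> int:
        counts = self.region_counts(mismatch_positions(pair))
        return int(all(counts[r] <= self.tolerances.get(r, SEQ_LENGTH)
                       for r in self.regions))


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror the benchmark's shape."""

    n_records: int = 2310
    imbalance_ratio: float = 230.0
    max_mismatches: int = 6
    rule: PlantedRule = field(default_factory=PlantedRule)
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 0 <= self.max_mismatches <= len(INJECTABLE_POSITIONS):
            raise ValueError("max_mismatches out of range")


def random_sgrna(rng: np.random.Generator) -> str:
    """Uniform 20-mer spacer + 'NGG' PAM (positions 21-23)."""
    return "".join(rng.choice(_BASES, size=20)) + "NGG"


def inject_mismatches(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute a different base at each listed (1-based) position.

    Position 21 is the wildcard and may not be mutated.
    """
    positions = list(positions)
    if len(set(positions)) != len(positions):
        raise ValueError("positions must be distinct")
    chars = list(seq)
    for p in positions:
        if p == 21:
            raise WildcardPositionError("cannot inject at wildcard position 21")
        if not 1 <= p <= SEQ_LENGTH:
            raise ValueError(f"position {p} outside 1..{SEQ_LENGTH}")
        current = chars[p - 1]
        choices = [b for b in _BASES if b != current]
        chars[p - 1] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def propose_target(sgrna: str, rng: np.random.Generator,
                   max_mismatches: int = 6,
                   count_probs=None) -> tuple[str, list[int]]:
    """Draw a target: position 21 concretized, then a sampled number of
    substitutions (uniform over 0..max by default) at distinct positions."""
    dna = list(sgrna)
    dna[20] = _BASES[int(rng.integers(4))]
    dna = "".join(dna)
    counts = np.arange(max_mismatches + 1)
    m = int(rng.choice(counts, p=count_probs))
    positions = sorted(
        rng.choice(INJECTABLE_POSITIONS, size=m, replace=False).tolist())
    return inject_mismatches(dna, positions, rng), positions


def generate_dataset(cfg: SimulationConfig) -> LabeledDataset:
    """Generate a labeled dataset at the configured class ratio.

    Pairs are proposed with a uniform mismatch count and routed by their
    rule label into the positive or negative pool (rule-conditioned
    rejection) until both pools reach their quota; label noise is then
    applied on top of the rule labels. Fully deterministic under the
    seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pos = max(int(round(cfg.n_records / (1.0 + cfg.imbalance_ratio))), 1)
    n_neg = cfg.n_records - n_pos
    pools: dict[int, list[GuideTargetPair]] = {0: [], 1: []}
    quota = {0: n_neg, 1: n_pos}
    budget = 500 * cfg.n_records + 10000
    attempts = 0
    while len(pools[0]) < quota[0] or len(pools[1]) < quota[1]:
        attempts += 1
        if attempts > budget:
            raise GenerationError(
                f"could not reach {n_pos} positives / {n_neg} negatives under "
                f"the rule within {budget} proposals; filled "
                f"{len(pools[1])}/{len(pools[0])}")
        sg = random_sgrna(rng)
        dna, _ = propose_target(sg, rng, cfg.max_mismatches)
        pair = GuideTargetPair(sg, dna)
        lab = cfg.rule.label(pair)
        if len(pools[lab]) < quota[lab]:
            pools[lab].append(GuideTargetPair(sg, dna, lab))
    records = pools[0] + pools[1]
    if cfg.label_noise > 0:
        flip = rng.random(len(records)) < cfg.label_noise
        records = [GuideTargetPair(r.sgrna, r.dna, 1 - r.label) if f else r
                   for r, f in zip(records, flip)]
    order = rng.permutation(len(records))
    return LabeledDataset([records[i] for i in order], provenance="synthetic")
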