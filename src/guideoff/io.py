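"""Dataset and report readers/writers, checkpoints and run manifests.

Datasets are delimited text (TSV by default, comma accepted) with a
header naming the ``sgrna``, ``dna`` and ``label`` columns. Malformed
rows are never silently dropped: they are collected into a rejects table
carrying the offending row and the reason. Reports round-trip through
deterministic text formats — JSON for metrics/genomes/configs, TSV for
attribution tables, CSV for search histories — and model checkpoints are
NumPy ``.npz`` archives holding the parameters, the genome and the seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .encoding import GuideTargetPair
from .exceptions import EmptyInput, GuideoffError, SchemaError
from .ga import GAHistory
from .genome import Genome
from .model import build_model
from .network import RecurrentNet
from .training import LabeledDataset, MetricsReport

REQUIRED_COLUMNS = ("sgrna", "dna", "label")


def read_dataset(path, fmt: str = "auto", column_map: dict | None = None,
                 provenance: str = "benchmark"
                 ) -> tuple[LabeledDataset, pd.DataFrame]:
    """Read a labeled pair table; returns (dataset, rejects).

    ``column_map`` renames file columns onto the required schema, e.g.
    ``{"sgRNA_seq": "sgrna"}``. Rows failing 23-mer validation or with a
    non-binary label land in the rejects frame with a ``reason`` column.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except pd.errors.EmptyDataError:
        raise EmptyInput(f"{path} holds no records")
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing required column(s) {missing}")
    if df.empty:
        raise EmptyInput(f"{path} holds no records")
    records, rejects = [], []
    for i, row in df.iterrows():
        try:
            label = int(row["label"])
            if label not in (0, 1):
                raise ValueError(f"label {row['label']!r} is not binary")
            records.append(GuideTargetPair(row["sgrna"], row["dna"], label))
        except (GuideoffError, ValueError, TypeError) as exc:
            rejects.append({"row": i, "sgrna": row["sgrna"], "dna": row["dna"],
                            "label": row["label"],
                            "reason": type(exc).__name__, "detail": str(exc)})
    return (LabeledDataset(records, provenance),
            pd.DataFrame(rejects,
                         columns=["row", "sgrna", "dna", "label",
                                  "reason", "detail"]))


def write_dataset(dataset: LabeledDataset, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"sgrna": [r.sgrna for r in dataset.records],
         "dna": [r.dna for r in dataset.records],
         "label": [r.label for r in dataset.records]}
    ).to_csv(path, sep="\t", index=False)
    return path


# ----------------------------------------------------------------------
# reports

def write_report(obj, path, kind: str | None = None) -> Path:
    """Write a finalized report object to disk.

    Kinds (inferred from the object when not given): ``metrics`` (JSON),
    ``genome`` (JSON), ``table`` (TSV, fixed float precision),
    ``ga_history`` (CSV).
    """
    path = Path(path)
    if kind is None:
        kind = ("metrics" if isinstance(obj, MetricsReport) else
                "genome" if isinstance(obj, Genome) else
                "ga_history" if isinstance(obj, GAHistory) else
                "table")
    if kind == "metrics":
        path.write_text(json.dumps(obj.to_dict(), indent=2, sort_keys=True) + "\n")
    elif kind == "genome":
        path.write_text(obj.to_json() + "\n")
    elif kind == "ga_history":
        obj.to_dataframe().to_csv(path, index=False)
    elif kind == "table":
        obj.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown report kind {kind!r}")
    return path


def read_metrics(path) -> MetricsReport:
    return MetricsReport(**json.loads(Path(path).read_text()))


def read_genome(path) -> Genome:
    return Genome.from_json(Path(path).read_text())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ga_history(path) -> pd.DataFrame:
    return pd.read_csv(path)


def best_genome_from_history(df: pd.DataFrame) -> Genome:
    """Best-ever genome recorded in a search history frame."""
    row = df.loc[df["fitness"].idxmax()]
    return Genome.from_json(row["genome"])


# ----------------------------------------------------------------------
# checkpoints

def save_checkpoint(net: RecurrentNet, genome: Genome, path,
                    seed: int = 0) -> Path:
    path = Path(path)
    np.savez(path, __genome__=genome.to_json(), __seed__=seed,
             __channels__=net.input_size,
             **{f"param/{k}": v for k, v in net.params.items()})
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path) -> tuple[RecurrentNet, Genome, int]:
    with np.load(path, allow_pickle=False) as data:
        genome = Genome.from_json(str(data["__genome__"]))
        seed = int(data["__seed__"])
        channels = int(data["__channels__"])
        net = build_model(genome, channels, seed=seed)
        net.load_state_dict({k[len("param/"):]: data[k]
                             for k in data.files if k.startswith("param/")})
    return net, genome, seed


# ----------------------------------------------------------------------
# run manifest

@dataclass
class RunManifest:
    """Replay record written alongside every CLI run."""

    command: str
    configuration: dict
    seeds: dict
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def digest_input(self, name: str, path):
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_digests[name] = h

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def start_manifest(command: str, configuration: dict, seeds: dict) -> RunManifest:
    m = RunManifest(command=command, configuration=configuration, seeds=seeds)
    m.started = time.strftime("%Y-%m-%dT%H:%M:%S")
    return m
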