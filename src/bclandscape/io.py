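"""Plain-text readers/writers: TSV tables, GMT gene sets, key-value configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .qcnorm import CountMatrix
from .synthdata import SimulationConfig
from .tnbc import GeneSetCollection


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_count_matrix(cm: CountMatrix, counts_path, classes_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.probe_class.rename("probe_class").to_csv(classes_path, sep="\t")


def read_count_matrix(counts_path, classes_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    classes = pd.read_csv(classes_path, sep="\t", index_col=0)["probe_class"]
    return CountMatrix(counts=counts, probe_class=classes)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """One set per line: name, description placeholder, then gene ids."""
    with open(path, "w") as fh:
        for name in collection.names:
            genes = "\t".join(collection[name])
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets)


def write_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig(**data)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
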