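"""Delimited-text readers and writers for the study's file formats.

All files are tab-delimited with a header row; comment lines starting
with ``#`` carry provenance (seed, config hash) and are skipped on
read.  Formats:

* map:        marker, group, cm
* genotypes:  line in the first column, one column per marker, cells
              'a' / 'b' / '-'
* phenotypes: line, rep, plant, value
* measurements: line, rep, plant, arc_length, split_width, head_height,
              head_circumference, split_layers
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .linkage import GeneticMap, GenotypeMatrix
from .simulate import SimConfig

__all__ = [
    "read_map", "write_map",
    "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_phenotypes",
    "read_table", "write_table",
    "read_truth", "write_truth",
]

SEP = "\t"


def _write_df(df: pd.DataFrame, path, header_lines=(), index=False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=SEP, index=index)


def _read_df(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, comment="#", **kw)


def write_map(gmap: GeneticMap, path, seed=None) -> None:
    header = [f"seed: {seed}"] if seed is not None else []
    _write_df(gmap.table, path, header)


def read_map(path) -> GeneticMap:
    return GeneticMap(_read_df(path))


def write_genotypes(genotypes: GenotypeMatrix, path, seed=None) -> None:
    header = [f"seed: {seed}"] if seed is not None else []
    df = genotypes.frame.copy()
    df.index.name = "line"
    _write_df(df, path, header, index=True)


def read_genotypes(path) -> GenotypeMatrix:
    df = _read_df(path, index_col=0, dtype=str)
    return GenotypeMatrix(df)


def write_phenotypes(phenotypes: pd.DataFrame, path, seed=None) -> None:
    header = [f"seed: {seed}"] if seed is not None else []
    _write_df(phenotypes, path, header)


def read_phenotypes(path) -> pd.DataFrame:
    return _read_df(path)


def write_table(df: pd.DataFrame, path, header_lines=()) -> None:
    _write_df(df, path, header_lines)


def read_table(path, **kw) -> pd.DataFrame:
    return _read_df(path, **kw)


def write_truth(config: SimConfig, path) -> None:
    """Echo the generating parameters as JSON (lists for tuples)."""
    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=2) + "\n")


def read_truth(path) -> SimConfig:
    raw = json.loads(Path(path).read_text())
    raw["chromosomes"] = tuple(tuple(c) for c in raw["chromosomes"])
    raw["major_genes"] = tuple(tuple(g) for g in raw["major_genes"])
    raw["epistasis"] = tuple((tuple(g), e) for g, e in raw["epistasis"])
    return SimConfig(**raw)
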