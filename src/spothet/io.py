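"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices use the 10x-style triplet layout (MatrixMarket coordinate
integer file plus one-column gene and barcode TSVs); spot positions use a
Visium-style CSV extended with zone / glomerulus / sample / condition
columns. Readers validate and reject malformed input instead of coercing;
every reader/writer pair round-trips valid data exactly.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import (
    LATTICE_COLUMNS,
    CountMatrix,
    FractionMatrix,
    SpotLattice,
    ValidationError,
)


class FormatError(ValidationError):
    """Raised when an input file's structure contradicts its own metadata."""


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    modality: str = "spatial",
) -> CountMatrix:
    """Read a MatrixMarket triplet (matrix + genes TSV + barcodes TSV)."""
    for p in (matrix_path, genes_path, barcodes_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    mat = spio.mmread(str(matrix_path))
    genes = _read_id_column(genes_path)
    barcodes = _read_id_column(barcodes_path)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix header declares {mat.shape[0]} x {mat.shape[1]} but identifier "
            f"files list {len(genes)} genes and {len(barcodes)} barcodes")
    return CountMatrix(genes, barcodes, sparse.csr_matrix(mat), modality=modality)


def _read_id_column(path: str | Path) -> list[str]:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def write_counts(matrix: CountMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the triplet layout; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    coo = sparse.coo_matrix(matrix.counts)
    spio.mmwrite(str(paths["matrix"]), coo, field="integer")
    paths["genes"].write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in matrix.sample_ids))
    return paths


def read_lattice(csv_path: str | Path) -> SpotLattice:
    """Read the extended tissue-positions CSV into a validated lattice."""
    table = pd.read_csv(csv_path, dtype={"glomerulus_id": "string"})
    missing = [c for c in LATTICE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"positions file missing columns: {missing}")
    table["glomerulus_id"] = table["glomerulus_id"].astype(object).where(
        table["glomerulus_id"].notna(), None)
    return SpotLattice(table[LATTICE_COLUMNS])


def write_lattice(lattice: SpotLattice, csv_path: str | Path) -> Path:
    path = Path(csv_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lattice.table[LATTICE_COLUMNS].to_csv(path, index=False)
    return path


def write_fractions(fractions: FractionMatrix, path: str | Path) -> Path:
    frame = fractions.to_frame()
    frame.insert(0, "degenerate", np.asarray(fractions.degenerate, dtype=bool))
    if fractions.residual_norm is not None:
        frame["residual_norm"] = fractions.residual_norm
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index_label="spot_id")
    return path


def read_fractions(path: str | Path) -> FractionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="spot_id")
    degenerate = frame.pop("degenerate").to_numpy(dtype=bool)
    residual = frame.pop("residual_norm").to_numpy() if "residual_norm" in frame else None
    return FractionMatrix(
        [str(s) for s in frame.index], list(frame.columns), frame.to_numpy(),
        degenerate=degenerate, residual_norm=residual)


def read_homolog_map(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV (with header) of source -> target gene id pairs."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] != 2:
        raise FormatError(
            f"homolog map must have exactly 2 columns; got {table.shape[1]}")
    if table.isna().any().any():
        raise FormatError("homolog map contains empty cells")
    return list(table.itertuples(index=False, name=None))


def write_table(frame: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> Path:
    """Write a TSV report, optionally prefixed by a config-hash comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=False)
    return path
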