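"""In-memory containers shared by all pipeline stages.

Everything is a light wrapper around numpy / pandas with eager validation:
readers and constructors reject malformed data instead of coercing it, so
downstream stages can assume their contracts hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

ZONES = ("Cortex", "OMOS", "OMIS", "IM")
CONDITIONS = ("Ctrl", "Losa")


class ValidationError(ValueError):
    """Raised when a container or file violates its structural contract."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid, naming the field."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class CountMatrix:
    """Genes x cells-or-spots matrix of non-negative integer counts.

    Parameters
    ----------
    gene_ids : sequence of unique gene identifiers (rows).
    sample_ids : sequence of unique cell barcodes or spot identifiers (columns).
    counts : dense ndarray or scipy sparse matrix, shape (n_genes, n_samples).
    modality : ``"single_cell"`` or ``"spatial"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray | sparse.spmatrix
    modality: str = "single_cell"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.modality not in ("single_cell", "spatial"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        shape = self.counts.shape
        if shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {shape} inconsistent with {len(self.gene_ids)} genes "
                f"x {len(self.sample_ids)} samples"
            )
        data = self.counts.data if sparse.issparse(self.counts) else np.asarray(self.counts)
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative entries in count matrix")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integral entries in count matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        counts = self.counts[:, idx]
        return CountMatrix(list(self.gene_ids), list(keep), counts, self.modality)

    def subset_genes(self, keep: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in keep]
        counts = self.counts[idx, :]
        return CountMatrix(list(keep), list(self.sample_ids), counts, self.modality)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.sample_ids)


#: Required columns of the spot-position table, in canonical order.
LATTICE_COLUMNS = [
    "spot_id",
    "array_row",
    "array_col",
    "zone",
    "glomerulus_id",
    "sample_id",
    "condition",
]


@dataclass
class SpotLattice:
    """Per-spot array coordinates plus histology annotations.

    Follows the Visium array convention: ``array_col`` parity equals
    ``array_row`` parity, so that the six hexagonal neighbours of a spot sit
    at offsets (0, +-2) and (+-1, +-1). Spots from different samples are
    unrelated (separate capture areas).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LATTICE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"lattice table missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        t["spot_id"] = t["spot_id"].astype(str)
        t["array_row"] = t["array_row"].astype(int)
        t["array_col"] = t["array_col"].astype(int)
        _check_unique(list(t["spot_id"]), "spot")
        dup = t.duplicated(subset=["sample_id", "array_row", "array_col"])
        if dup.any():
            bad = t.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate coordinates for spot {bad['spot_id']!r} "
                f"(sample {bad['sample_id']!r}, row {bad['array_row']}, col {bad['array_col']})"
            )
        parity_bad = (t["array_row"] % 2) != (t["array_col"] % 2)
        if parity_bad.any():
            bad = t.loc[parity_bad.idxmax()]
            raise ValidationError(
                f"spot {bad['spot_id']!r} violates hex parity: "
                f"row {bad['array_row']} vs col {bad['array_col']}"
            )
        unknown = set(t["zone"].dropna()) - set(ZONES)
        if unknown:
            raise ValidationError(
                f"unknown zone labels {sorted(unknown)}; allowed: {list(ZONES)}"
            )
        unknown_cond = set(t["condition"].dropna()) - set(CONDITIONS)
        if unknown_cond:
            raise ValidationError(
                f"unknown condition labels {sorted(unknown_cond)}; allowed: {list(CONDITIONS)}"
            )
        self.table = t

    @property
    def spot_ids(self) -> list[str]:
        return list(self.table["spot_id"])

    def row(self, spot_id: str) -> pd.Series:
        hit = self.table[self.table["spot_id"] == spot_id]
        if hit.empty:
            raise KeyError(f"unknown spot {spot_id!r}")
        return hit.iloc[0]

    def glomerulus_spots(self) -> pd.DataFrame:
        g = self.table["glomerulus_id"]
        return self.table[g.notna() & (g != "")]

    def subset(self, mask: pd.Series) -> "SpotLattice":
        return SpotLattice(self.table[mask].reset_index(drop=True))


@dataclass
class SignatureMatrix:
    """Genes x cell-types mean expression profiles, counts-per-10k scale."""

    gene_ids: list[str]
    cell_type_names: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_type_names = [str(c) for c in self.cell_type_names]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_type_names, "cell type")
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.gene_ids), len(self.cell_type_names)):
            raise ValidationError("signature profile shape inconsistent with identifiers")
        if np.any(self.profiles < 0):
            raise ValidationError("negative values in signature profiles")
        zero = ~self.profiles.any(axis=0)
        if zero.any():
            bad = [c for c, z in zip(self.cell_type_names, zero) if z]
            raise ValidationError(f"all-zero signature column(s): {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=self.gene_ids, columns=self.cell_type_names)


@dataclass
class FractionMatrix:
    """Spots x cell-types estimated (or true) fractions; rows on the simplex.

    ``degenerate`` flags spots whose fractions could not be estimated
    (all-zero expression); their rows are NaN rather than silently uniform.
    """

    spot_ids: list[str]
    cell_type_names: list[str]
    fractions: np.ndarray
    degenerate: np.ndarray | None = None
    residual_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        _check_unique(self.spot_ids, "spot")
        _check_unique(self.cell_type_names, "cell type")
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.spot_ids), len(self.cell_type_names)):
            raise ValidationError("fraction matrix shape inconsistent with identifiers")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.spot_ids), dtype=bool)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        ok = ~self.degenerate
        vals = self.fractions[ok]
        if vals.size:
            if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
                raise ValidationError("fractions outside [0, 1]")
            sums = vals.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValidationError("non-degenerate fraction rows must sum to 1 within 1e-9")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.spot_ids, columns=self.cell_type_names)

    def column(self, cell_type: str) -> pd.Series:
        if cell_type not in self.cell_type_names:
            raise KeyError(
                f"unknown cell type {cell_type!r}; available: {self.cell_type_names}"
            )
        j = self.cell_type_names.index(cell_type)
        return pd.Series(self.fractions[:, j], index=self.spot_ids, name=cell_type)


@dataclass
class NormalizedMatrix:
    """Genes x spots normalized expression with provenance metadata."""

    gene_ids: list[str]
    spot_ids: list[str]
    values: np.ndarray
    cell_type: str | None = None
    min_fraction: float | None = None
    scale: float | None = None
    log: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.spot_ids, "spot")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValidationError("normalized matrix shape inconsistent with identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values in normalized matrix")
        if np.any(self.values < 0):
            raise ValidationError("negative values in normalized matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.spot_ids)

    def gene_values(self, gene_id: str) -> pd.Series:
        if gene_id not in self.gene_ids:
            raise KeyError(f"unknown gene {gene_id!r}")
        i = self.gene_ids.index(gene_id)
        return pd.Series(self.values[i], index=self.spot_ids, name=gene_id)


@dataclass
class ContingencyTable2x2:
    """2x2 contingency table with row/column labels, for Fisher's exact test."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValidationError("contingency table must be 2x2")
        if np.any(self.counts < 0):
            raise ValidationError("contingency table entries must be non-negative")
        if self.counts.sum() == 0:
            raise ValidationError("contingency table total must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


@dataclass
class PipelineConfig:
    """Tunable thresholds of the full pipeline, with study defaults.

    QC bounds follow the single-cell filters of the source study design
    (200-5,000 detected genes, <30,000 UMI, <40% mitochondrial); the
    remaining knobs parameterize spot selection and the heterogeneity screen.
    """

    min_genes: int = 200
    max_genes: int = 5000
    max_umi: int = 30000
    max_mito_frac: float = 0.40
    mito_prefix: str = "Mt-"
    min_fraction: float = 0.05
    min_mean: float = 0.01
    top_skew_frac: float = 0.05
    high_resp_frac: float = 0.25
    lognorm_scale: float = 10000.0
    alpha: float = 0.05
    target_cell_type: str = "JG"
    response_gene: str = "Ren"
    group_a_type: str = "TAL-1"
    group_b_type: str = "TAL-2"
    responder_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ConfigurationError("min_genes must satisfy 0 < min_genes < max_genes")
        if self.max_umi <= 0:
            raise ConfigurationError("max_umi must be positive")
        for name in ("max_mito_frac", "min_fraction", "top_skew_frac",
                     "high_resp_frac", "alpha", "responder_quantile"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must lie in (0, 1); got {v}")
        if self.min_mean < 0:
            raise ConfigurationError("min_mean must be non-negative")
        if self.lognorm_scale <= 0:
            raise ConfigurationError("lognorm_scale must be positive")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)
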