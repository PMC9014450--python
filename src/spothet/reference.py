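"""Single-cell reference QC, signature construction and marker ranking."""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compare import bh_adjust, wilcoxon_rank_sum
from .containers import CountMatrix, PipelineConfig, SignatureMatrix, ValidationError

log = logging.getLogger(__name__)


def mito_genes(gene_ids: Sequence[str], prefix: str = "Mt-") -> list[str]:
    """Mitochondrial genes by identifier prefix (rat convention ``Mt-``)."""
    return [g for g in gene_ids if g.startswith(prefix)]


def qc_filter_cells(
    counts: CountMatrix,
    mito_gene_set: Iterable[str] | None = None,
    config: PipelineConfig | None = None,
) -> CountMatrix:
    """Keep cells with 200-5,000 detected genes, <30,000 UMIs and <40% mito.

    Boundaries are inclusive on the detected-gene range and strict on the
    UMI and mitochondrial bounds, reading the study's "200-5,000 genes,
    under 30,000 UMI, fewer than 40% mitochondrial" literally. Idempotent;
    cell order is preserved. An empty result warns rather than raises.
    """
    cfg = config or PipelineConfig()
    if mito_gene_set is None:
        mito_gene_set = mito_genes(counts.gene_ids, cfg.mito_prefix)
    dense = counts.dense()
    detected = (dense > 0).sum(axis=0)
    total = dense.sum(axis=0)
    mito_idx = [i for i, g in enumerate(counts.gene_ids) if g in set(mito_gene_set)]
    mito_total = dense[mito_idx].sum(axis=0) if mito_idx else np.zeros_like(total)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    keep = (
        (detected >= cfg.min_genes)
        & (detected <= cfg.max_genes)
        & (total < cfg.max_umi)
        & (mito_frac < cfg.max_mito_frac)
    )
    kept = [s for s, k in zip(counts.sample_ids, keep) if k]
    if not kept:
        warnings.warn("QC filter removed every cell", stacklevel=2)
        return CountMatrix(list(counts.gene_ids), [], counts.counts[:, :0], counts.modality)
    return counts.subset_samples(kept)


def counts_per_10k(dense: np.ndarray) -> np.ndarray:
    """Scale each column to 10,000 total counts (columns with zero total stay zero)."""
    totals = dense.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(totals > 0, dense * (10000.0 / np.maximum(totals, 1e-300)), 0.0)
    return out


def build_signature(counts: CountMatrix, labels: Sequence[str]) -> SignatureMatrix:
    """Mean counts-per-10k profile per cell type.

    Each cell is library-size normalized to 10,000 before averaging, so the
    signature matches the linear mixing model of the deconvolution stage.
    """
    if len(labels) != counts.n_samples:
        missing = counts.n_samples - len(labels)
        raise ValidationError(
            f"labels ({len(labels)}) do not cover all {counts.n_samples} cells")
    dense = counts.dense()
    totals = dense.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"all-zero cell(s) cannot be normalized: {[counts.sample_ids[i] for i in zero[:5]]}")
    norm = counts_per_10k(dense)
    types = sorted(set(labels))
    labels_arr = np.asarray(labels)
    profiles = np.column_stack([norm[:, labels_arr == t].mean(axis=1) for t in types])
    return SignatureMatrix(list(counts.gene_ids), types, profiles)


def rank_markers(counts: CountMatrix, labels: Sequence[str]) -> pd.DataFrame:
    """One-vs-rest marker ranking per cell type.

    Wilcoxon rank-sum on counts-per-10k values, BH-adjusted within each
    type, log2 fold change of (mean + 1); sorted by fold change descending
    within type. Requires at least two types.
    """
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValidationError("marker ranking requires at least two cell types")
    if len(labels) != counts.n_samples:
        raise ValidationError("labels do not cover all cells")
    norm = counts_per_10k(counts.dense())
    labels_arr = np.asarray(labels)
    frames = []
    for t in types:
        in_t = labels_arr == t
        a, b = norm[:, in_t], norm[:, ~in_t]
        pvals = np.empty(counts.n_genes)
        stat = np.empty(counts.n_genes)
        for i in range(counts.n_genes):
            stat[i], pvals[i] = wilcoxon_rank_sum(a[i], b[i])
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        frame = pd.DataFrame({
            "cell_type": t,
            "gene_id": counts.gene_ids,
            "mean_in_type": mean_a,
            "mean_rest": mean_b,
            "log2_fc": np.log2((mean_a + 1.0) / (mean_b + 1.0)),
            "statistic": stat,
            "p": pvals,
            "adj_p": bh_adjust(pvals),
        })
        frames.append(frame.sort_values(
            ["log2_fc", "gene_id"], ascending=[False, True]))
    return pd.concat(frames, ignore_index=True)
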