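"""Group comparison statistics: rank-sum tests, BH adjustment, DE ranking,
and homolog-mapped cross-dataset correlation."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix, ValidationError

#: exact null enumeration is feasible and tie-free below this group size
EXACT_MAX_N = 8


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the smaller group has at most
    ``EXACT_MAX_N`` observations and there are no ties, and the normal
    approximation with tie and continuity corrections otherwise. Returns
    ``(U statistic of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def de_between_groups(
    norm: NormalizedMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> pd.DataFrame:
    """Per-gene differential expression between two disjoint spot groups.

    Wilcoxon rank-sum per gene, BH adjustment across genes, log2 fold
    change of (mean + 1) pseudocounted normalized means; rows sorted by
    fold change descending (the ranking used to report response genes).
    """
    a = list(dict.fromkeys(group_a))
    b = list(dict.fromkeys(group_b))
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    overlap = set(a) & set(b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    pos = {s: i for i, s in enumerate(norm.spot_ids)}
    missing = [s for s in a + b if s not in pos]
    if missing:
        raise ValidationError(f"spots not in normalized matrix: {missing[:5]}")
    ia = [pos[s] for s in a]
    ib = [pos[s] for s in b]
    va, vb = norm.values[:, ia], norm.values[:, ib]
    stat = np.empty(len(norm.gene_ids))
    p = np.empty(len(norm.gene_ids))
    for i in range(len(norm.gene_ids)):
        stat[i], p[i] = wilcoxon_rank_sum(va[i], vb[i])
    mean_a, mean_b = va.mean(axis=1), vb.mean(axis=1)
    out = pd.DataFrame({
        "gene_id": norm.gene_ids,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "log2_fc": np.log2((mean_a + 1.0) / (mean_b + 1.0)),
        "statistic": stat,
        "p": p,
        "adj_p": bh_adjust(p),
    })
    return out.sort_values(["log2_fc", "gene_id"],
                           ascending=[False, True]).reset_index(drop=True)


def filter_one_to_one(pairs: Iterable[tuple[str, str]]) -> dict[str, str]:
    """Drop source or target genes appearing in more than one pair."""
    pairs = list(pairs)
    src = pd.Series([s for s, _ in pairs])
    dst = pd.Series([t for _, t in pairs])
    src_ok = ~src.duplicated(keep=False)
    dst_ok = ~dst.duplicated(keep=False)
    return {s: t for (s, t), a, b in zip(pairs, src_ok, dst_ok) if a and b}


def homolog_correlation(
    expr_a: Mapping[str, float] | pd.Series,
    expr_b: Mapping[str, float] | pd.Series,
    homolog_map: Iterable[tuple[str, str]],
) -> tuple[float, int]:
    """Pearson correlation of log1p mean expression across homolog pairs.

    Ambiguous (one-to-many) mappings and genes absent from either profile
    are dropped; at least 10 shared mapped genes are required. Returns
    ``(r, n_genes_used)``.
    """
    a = pd.Series(expr_a, dtype=float)
    b = pd.Series(expr_b, dtype=float)
    mapping = filter_one_to_one(homolog_map)
    shared = [(s, t) for s, t in mapping.items() if s in a.index and t in b.index]
    if len(shared) < 10:
        raise ValidationError(
            f"only {len(shared)} one-to-one mapped genes shared; need >= 10")
    va = np.log1p(np.array([a[s] for s, _ in shared]))
    vb = np.log1p(np.array([b[t] for _, t in shared]))
    r = stats.pearsonr(va, vb).statistic
    return float(r), len(shared)
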