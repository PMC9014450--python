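"""Cell-fraction normalization of spot expression.

The central normalization attributes a spot's counts to a target cell
type by dividing each gene's count by that type's estimated fraction:

    NC_ij = C_ij / F_j

over the spots whose fraction passes a minimum threshold, followed
(optionally) by conventional total-count log normalization,
log(1 + scale * v / total), with natural log and scale 10,000.
"""

from __future__ import annotations

import numpy as np

from .containers import CountMatrix, FractionMatrix, NormalizedMatrix, ValidationError


def fraction_normalize(
    counts: CountMatrix,
    fractions: FractionMatrix,
    cell_type: str,
    min_fraction: float,
) -> NormalizedMatrix:
    """Divide spot counts by the target cell type's estimated fraction.

    Only spots with fraction >= ``min_fraction`` (and non-degenerate
    estimates) are retained; every retained spot has F_j > 0 by
    construction, so the division is well defined.
    """
    missing = [s for s in fractions.spot_ids if s not in set(counts.sample_ids)]
    if missing:
        raise ValidationError(
            f"fraction spots absent from count matrix: {missing[:5]}")
    col = fractions.column(cell_type)
    ok = ~np.asarray(fractions.degenerate)
    vals = np.nan_to_num(col.to_numpy(), nan=-1.0)
    keep = [s for s, k in zip(fractions.spot_ids, ok & (vals >= min_fraction)) if k]
    if min_fraction <= 0 and np.any(vals[ok & (vals >= min_fraction)] <= 0):
        raise ValidationError("cannot normalize by a zero fraction; raise min_fraction")
    sub = counts.subset_samples(keep)
    f = col.loc[keep].to_numpy()
    values = sub.dense() / f[None, :]
    return NormalizedMatrix(
        list(sub.gene_ids), keep, values,
        cell_type=cell_type, min_fraction=min_fraction, log=False)


def lognormalize_total(nc: NormalizedMatrix, scale: float = 10000.0) -> NormalizedMatrix:
    """Total-count normalize each spot to ``scale`` and apply log1p.

    value_ij -> log(1 + scale * value_ij / sum_i value_ij), natural log.
    Invariant to any per-spot rescaling of the input.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    totals = nc.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"zero-total spot(s) cannot be normalized: {[nc.spot_ids[i] for i in zero[:5]]}")
    values = np.log1p(scale * nc.values / totals[None, :])
    return NormalizedMatrix(
        list(nc.gene_ids), list(nc.spot_ids), values,
        cell_type=nc.cell_type, min_fraction=nc.min_fraction,
        scale=scale, log=True)
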