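"""Per-spot cell-type fraction estimation by non-negative least squares.

Each spot's transcriptome is modelled as a linear mixture of the reference
signature columns; counts-per-10k spot profiles are fitted with NNLS over
the shared gene set and the coefficients renormalized onto the simplex.
This is a transparent stand-in for SVR-based cell-fraction tools built on
the same linear mixing model; numerical agreement with them is not claimed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import CountMatrix, FractionMatrix, SignatureMatrix, ValidationError
from .reference import counts_per_10k


def estimate_fractions(
    spot_counts: CountMatrix, signature: SignatureMatrix
) -> FractionMatrix:
    """Estimate spots x types fractions from a signature matrix.

    Requires at least 50 shared genes (warns below 200). All-zero spots are
    flagged degenerate with NaN rows rather than being assigned fractions.
    Per-spot residual norms (of the fitted counts-per-10k profile) are
    attached for diagnostics. Fractions are scale-invariant in the spot's
    library size by construction.

    The initial unweighted NNLS fit is refined by two iteratively
    reweighted passes with inverse-variance weights 1 / sqrt(mu + theta *
    mu^2 + 1) computed from the fitted means (theta estimated per spot from
    the squared residuals by method of moments), matching the
    heteroscedastic noise of overdispersed counts. On noiseless mixtures
    the refinement leaves the exact solution untouched.
    """
    shared = [g for g in spot_counts.gene_ids if g in set(signature.gene_ids)]
    if len(shared) < 50:
        raise ValidationError(
            f"only {len(shared)} genes shared between spots and signature; need >= 50")
    if len(shared) < 200:
        warnings.warn(
            f"only {len(shared)} shared genes; fraction estimates may be unstable",
            stacklevel=2)
    sig = signature.to_frame().loc[shared].to_numpy()
    dense = spot_counts.subset_genes(shared).dense()
    totals = dense.sum(axis=0)
    norm = counts_per_10k(dense)

    n_spots = spot_counts.n_samples
    n_types = len(signature.cell_type_names)
    fractions = np.full((n_spots, n_types), np.nan)
    residual = np.full(n_spots, np.nan)
    degenerate = totals == 0
    for j in range(n_spots):
        if degenerate[j]:
            continue
        b = norm[:, j]
        coef, rnorm = nnls(sig, b)
        for _ in range(2):
            mu = sig @ coef
            resid2 = (b - mu) ** 2
            theta = max(0.0, float(np.median(
                (resid2 - mu) / np.maximum(mu, 1e-6) ** 2)))
            wt = 1.0 / np.sqrt(mu + theta * mu ** 2 + 1.0)
            coef, _ = nnls(sig * wt[:, None], b * wt)
        rnorm = float(np.linalg.norm(sig @ coef - b))
        s = coef.sum()
        if s <= 0:
            degenerate[j] = True
            continue
        fractions[j] = coef / s
        residual[j] = rnorm
    return FractionMatrix(
        list(spot_counts.sample_ids),
        list(signature.cell_type_names),
        fractions,
        degenerate=degenerate,
        residual_norm=residual,
    )


def select_spots_by_fraction(
    fractions: FractionMatrix, cell_type: str, min_fraction: float
) -> list[str]:
    """Spots whose estimated fraction of ``cell_type`` is >= ``min_fraction``.

    Degenerate spots are never selected; order follows the fraction matrix
    and is therefore deterministic.
    """
    col = fractions.column(cell_type)  # raises with available types listed
    ok = ~np.asarray(fractions.degenerate)
    vals = np.nan_to_num(col.to_numpy(), nan=-1.0)
    keep = ok & (vals >= min_fraction)
    return [s for s, k in zip(fractions.spot_ids, keep) if k]
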