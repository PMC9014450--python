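"""Heterogeneous drug-response screening on fraction-normalized expression.

The screen asks, per gene, whether expression across target-cell spots is
compatible with a homogeneous (Gaussian) response or shows the long right
tail expected when only a subset of structures responds: a one-sample
Kolmogorov-Smirnov test against a Gaussian with the sample's own mean and
standard deviation, plus moment skewness (g1) ranking with a minimum-mean
filter. Spots are then classified as responding or not, the responder-by-
condition contrast is tested with Fisher's exact test, and the top quartile
of responders per sample is flagged "high-responding".
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ContingencyTable2x2, NormalizedMatrix, ValidationError
from .spatial import fisher_exact


def gene_distribution_stats(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean, standard deviation (ddof=1) and moment skewness g1.

    g1 = m3 / m2^(3/2) with central moments m_k = (1/n) sum (x - mean)^k
    (no small-sample bias correction). A constant vector has undefined
    skewness and is rejected rather than returning NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError(f"need n >= 3 values for skewness; got {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValidationError("skewness undefined for a constant vector")
    return float(x.mean()), sd, float(stats.skew(x, bias=True))


def ks_gaussian_test(values: Sequence[float], lilliefors: bool = False) -> tuple[float, float]:
    """One-sample KS test against Normal(sample mean, sample sd).

    Returns ``(D, p)``. By default p comes from the asymptotic KS
    distribution, which ignores that the Gaussian parameters were estimated
    from the same sample (anti-conservative); ``lilliefors=True`` applies
    the Lilliefors correction instead.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValidationError(f"need n >= 5 values for the KS test; got {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValidationError("KS test undefined for a constant vector")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf
        d, p = _lf(x, dist="norm", pvalmethod="table")
        return float(d), float(p)
    res = stats.kstest(x, "norm", args=(x.mean(), sd), method="asymp")
    return float(res.statistic), float(res.pvalue)


def skewness_screen(
    norm: NormalizedMatrix,
    min_mean: float = 0.01,
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Rank genes by skewness, flagging the top tail.

    Genes whose mean normalized expression is strictly above ``min_mean``
    are retained; the ``ceil(top_frac * n_retained)`` highest-skewness
    genes among them are flagged ``top_skew`` (ties broken by gene id).
    Genes with undefined skewness (constant across spots) are retained in
    the table but flagged and never counted in the top set.
    """
    if not (0 < top_frac < 1):
        raise ValidationError("top_frac must lie in (0, 1)")
    rows = []
    for i, g in enumerate(norm.gene_ids):
        x = norm.values[i]
        mean = float(x.mean())
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        skew = float(stats.skew(x, bias=True)) if sd > 0 else np.nan
        rows.append({"gene_id": g, "n": x.size, "mean": mean, "sd": sd,
                     "skewness": skew, "passes_mean_filter": mean > min_mean})
    table = pd.DataFrame(rows)
    retained = table[table["passes_mean_filter"] & table["skewness"].notna()]
    if len(retained) < 20:
        warnings.warn(
            f"only {len(retained)} genes retained; skewness quantile is unstable",
            stacklevel=2)
    table["top_skew"] = False
    if len(retained):
        k = max(1, math.ceil(top_frac * len(retained)))
        top = retained.sort_values(
            ["skewness", "gene_id"], ascending=[False, True]).head(k)
        table.loc[top.index, "top_skew"] = True
        table["skew_threshold"] = float(top["skewness"].min())
    return table


def control_reference_threshold(
    control_values: Sequence[float], quantile: float = 0.95
) -> float:
    """Responder threshold as an upper quantile of the control distribution.

    A spot "responds" when its normalized response-gene expression exceeds
    what untreated tissue typically shows; the default reference point is
    the control 95th percentile.
    """
    x = np.asarray(control_values, dtype=float)
    if x.size == 0:
        raise ValidationError("control distribution is empty")
    if not (0 < quantile < 1):
        raise ValidationError("quantile must lie in (0, 1)")
    return float(np.quantile(x, quantile))


def classify_responders(
    values: Mapping[str, float] | pd.Series, threshold: float = 0.0
) -> pd.Series:
    """Label each spot ``"Responding"`` if value > threshold (strict)."""
    s = pd.Series(values, dtype=float)
    return pd.Series(
        np.where(s.to_numpy() > threshold, "Responding", "Non-responding"),
        index=s.index, name="responder")


def responder_condition_test(
    responder_table: pd.DataFrame,
) -> tuple[ContingencyTable2x2, float, float]:
    """Fisher's exact test of responder label by condition.

    ``responder_table`` needs ``condition`` (Ctrl/Losa) and ``responder``
    columns; both conditions must be present. Returns (table, p, odds ratio)
    with rows (Losa, Ctrl) and columns (Responding, Non-responding).
    """
    for c in ("condition", "responder"):
        if c not in responder_table.columns:
            raise ValidationError(f"responder table missing column {c!r}")
    conditions = set(responder_table["condition"])
    if not {"Ctrl", "Losa"} <= conditions:
        raise ValidationError(
            f"both conditions required; present: {sorted(conditions)}")
    counts = np.zeros((2, 2), dtype=int)
    for i, cond in enumerate(("Losa", "Ctrl")):
        sub = responder_table[responder_table["condition"] == cond]
        counts[i, 0] = int((sub["responder"] == "Responding").sum())
        counts[i, 1] = int((sub["responder"] == "Non-responding").sum())
    table = ContingencyTable2x2(
        counts, row_labels=("Losa", "Ctrl"),
        col_labels=("Responding", "Non-responding"))
    p, orr = fisher_exact(table)
    return table, p, orr


def select_high_responding(
    values_by_sample: Mapping[str, Mapping[str, float] | pd.Series],
    frac: float = 0.25,
) -> pd.DataFrame:
    """Top-``frac`` spots by normalized response-gene value, per sample.

    Within each sample the ``ceil(frac * n)`` highest-valued spots are
    selected (ties broken by spot id, ascending); samples are ranked
    independently and the union returned with per-sample provenance.
    Samples with no eligible spots are skipped with a warning.
    """
    if not (0 < frac <= 1):
        raise ValidationError("frac must lie in (0, 1]")
    frames = []
    for sample, vals in values_by_sample.items():
        s = pd.Series(vals, dtype=float)
        if s.empty:
            warnings.warn(f"sample {sample!r} has no eligible spots; skipped",
                          stacklevel=2)
            continue
        k = math.ceil(frac * len(s))
        order = s.reset_index()
        order.columns = ["spot_id", "value"]
        order = order.sort_values(["value", "spot_id"], ascending=[False, True])
        chosen = order.head(k).copy()
        chosen["sample_id"] = sample
        frames.append(chosen)
    if not frames:
        return pd.DataFrame(columns=["spot_id", "value", "sample_id"])
    return pd.concat(frames, ignore_index=True)
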