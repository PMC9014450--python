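"""End-to-end orchestration: QC -> signature -> deconvolution ->
fraction normalization -> spatial adjacency -> heterogeneity screen -> DE.

``run_pipeline`` is deterministic given its inputs and configuration; all
stage outputs are returned in memory and, when an output directory is
given, written as TSV reports whose header comment carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as spio
from .compare import de_between_groups, wilcoxon_rank_sum
from .containers import (
    ContingencyTable2x2,
    CountMatrix,
    FractionMatrix,
    NormalizedMatrix,
    PipelineConfig,
    SpotLattice,
    ValidationError,
)
from .deconvolve import estimate_fractions, select_spots_by_fraction
from .heterogeneity import (
    classify_responders,
    control_reference_threshold,
    ks_gaussian_test,
    responder_condition_test,
    select_high_responding,
    skewness_screen,
)
from .normalize import fraction_normalize, lognormalize_total
from .reference import build_signature, qc_filter_cells
from .spatial import adjacency_report, classify_dominant

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineInputs:
    """In-memory inputs of a pipeline run."""

    sc_counts: CountMatrix
    sc_labels: list[str]
    spot_counts: CountMatrix
    lattice: SpotLattice


@dataclass
class PipelineResult:
    config: PipelineConfig
    signature_frame: pd.DataFrame
    fractions: FractionMatrix
    nc: NormalizedMatrix
    lognorm: NormalizedMatrix
    adjacency: pd.DataFrame
    gene_stats: pd.DataFrame
    responders: pd.DataFrame
    responder_table: ContingencyTable2x2
    responder_p: float
    responder_odds: float
    responder_threshold: float
    ks_results: pd.DataFrame
    de_table: pd.DataFrame | None
    md_response: pd.DataFrame
    n_cells_qc: int


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - reraise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def eligible_response_spots(
    fractions: FractionMatrix, lattice: SpotLattice, config: PipelineConfig
) -> list[str]:
    """Glomerulus-overlapping spots with a relevant target-type fraction."""
    selected = set(select_spots_by_fraction(
        fractions, config.target_cell_type, config.min_fraction))
    glom = lattice.glomerulus_spots()["spot_id"]
    return [s for s in glom if s in selected]


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    chash = config_hash(config)

    # --- QC + signature ---------------------------------------------------
    try:
        qc = qc_filter_cells(inputs.sc_counts, config=config)
        kept = set(qc.sample_ids)
        labels = [l for s, l in zip(inputs.sc_counts.sample_ids, inputs.sc_labels)
                  if s in kept]
        if qc.n_samples == 0:
            raise ValidationError("QC removed every reference cell")
    except Exception as exc:
        raise StageError(f"stage 'qc' failed: {exc}") from exc
    try:
        signature = build_signature(qc, labels)
    except Exception as exc:
        raise StageError(f"stage 'signature' failed: {exc}") from exc

    # --- deconvolution ----------------------------------------------------
    try:
        fractions = estimate_fractions(inputs.spot_counts, signature)
    except Exception as exc:
        raise StageError(f"stage 'deconvolve' failed: {exc}") from exc

    # --- fraction normalization for the target cell type ------------------
    try:
        nc = fraction_normalize(
            inputs.spot_counts, fractions, config.target_cell_type, config.min_fraction)
        logn = lognormalize_total(nc, config.lognorm_scale)
    except Exception as exc:
        raise StageError(f"stage 'normalize' failed: {exc}") from exc

    # --- spatial adjacency (dominant-score TAL classification) ------------
    try:
        adjacency = _spatial_stage(fractions, inputs.lattice, config)
    except Exception as exc:
        raise StageError(f"stage 'spatial' failed: {exc}") from exc

    # --- heterogeneity screen ---------------------------------------------
    try:
        het = _heterogeneity_stage(nc, logn, fractions, inputs.lattice, config)
    except Exception as exc:
        raise StageError(f"stage 'heterogeneity' failed: {exc}") from exc
    (gene_stats, responders, resp_table, resp_p, resp_odds,
     threshold, ks_results) = het

    # --- macula densa response (group-B analog) ----------------------------
    try:
        md_response = md_response_test(
            inputs.spot_counts, fractions, inputs.lattice, config)
    except Exception as exc:
        raise StageError(f"stage 'md_response' failed: {exc}") from exc

    # --- DE: high-responding vs other eligible treated spots ---------------
    try:
        de_table = _de_stage(logn, responders)
    except Exception as exc:
        raise StageError(f"stage 'de' failed: {exc}") from exc

    result = PipelineResult(
        config=config,
        signature_frame=signature.to_frame(),
        fractions=fractions,
        nc=nc,
        lognorm=logn,
        adjacency=adjacency,
        gene_stats=gene_stats,
        responders=responders,
        responder_table=resp_table,
        responder_p=resp_p,
        responder_odds=resp_odds,
        responder_threshold=threshold,
        ks_results=ks_results,
        de_table=de_table,
        md_response=md_response,
        n_cells_qc=qc.n_samples,
    )
    if out_dir is not None:
        _write_reports(result, Path(out_dir), chash)
    return result


def _spatial_stage(
    fractions: FractionMatrix, lattice: SpotLattice, config: PipelineConfig
) -> pd.DataFrame:
    score_a = fractions.column(config.group_a_type)
    score_b = fractions.column(config.group_b_type)
    cortical = lattice.table[lattice.table["zone"] == "Cortex"]["spot_id"]
    labels = {}
    degenerate = dict(zip(fractions.spot_ids, np.asarray(fractions.degenerate)))
    for s in cortical:
        if s not in score_a.index or degenerate.get(s, False):
            continue
        labels[s] = classify_dominant(float(score_a[s]), float(score_b[s]))
    glom = list(lattice.glomerulus_spots()["spot_id"])
    report = adjacency_report(labels, glom, lattice)
    report["group"] = report["group"].map(
        {"GroupA": config.group_a_type, "GroupB": config.group_b_type})
    return report


def _heterogeneity_stage(
    nc: NormalizedMatrix,
    logn: NormalizedMatrix,
    fractions: FractionMatrix,
    lattice: SpotLattice,
    config: PipelineConfig,
):
    eligible = eligible_response_spots(fractions, lattice, config)
    if not eligible:
        raise ValidationError("no glomerulus spot passed the fraction threshold")
    meta = lattice.table.set_index("spot_id").loc[eligible]
    if config.response_gene not in logn.gene_ids:
        raise ValidationError(f"response gene {config.response_gene!r} not present")
    values = logn.gene_values(config.response_gene)[eligible]

    ctrl_spots = [s for s in eligible if meta.loc[s, "condition"] == "Ctrl"]
    if ctrl_spots:
        threshold = control_reference_threshold(
            values[ctrl_spots], config.responder_quantile)
    else:
        threshold = 0.0
    responder = classify_responders(values, threshold)

    # per-sample top quartile of normalized response-gene expression
    values_by_sample = {
        sample: values[[s for s in eligible if meta.loc[s, "sample_id"] == sample]]
        for sample in sorted(set(meta["sample_id"]))
    }
    high = select_high_responding(values_by_sample, config.high_resp_frac)
    high_set = set(high["spot_id"])

    responders = pd.DataFrame({
        "spot_id": eligible,
        "sample_id": meta["sample_id"].to_numpy(),
        "condition": meta["condition"].to_numpy(),
        "glomerulus_id": meta["glomerulus_id"].to_numpy(),
        "value": values.to_numpy(),
        "responder": responder.to_numpy(),
    })
    responders["high_responding"] = responders["spot_id"].isin(high_set)

    resp_table, resp_p, resp_odds = responder_condition_test(responders)

    # skewness screen on the log-normalized values, treated arm
    losa_spots = [s for s in eligible if meta.loc[s, "condition"] == "Losa"]
    screen_spots = losa_spots if len(losa_spots) >= 3 else eligible
    pos = {s: i for i, s in enumerate(logn.spot_ids)}
    idx = [pos[s] for s in screen_spots]
    logn_sub = NormalizedMatrix(
        list(logn.gene_ids), screen_spots, logn.values[:, idx],
        cell_type=logn.cell_type, min_fraction=logn.min_fraction,
        scale=logn.scale, log=True)
    gene_stats = skewness_screen(logn_sub, config.min_mean, config.top_skew_frac)

    # Gaussian-null KS per sample for the response gene (log-normalized)
    ks_rows = []
    for sample in sorted(set(meta["sample_id"])):
        spots = [s for s in eligible if meta.loc[s, "sample_id"] == sample]
        if len(spots) < 5:
            continue
        x = values[spots].to_numpy()
        if np.std(x, ddof=1) == 0:
            continue
        d, p = ks_gaussian_test(x)
        ks_rows.append({"gene_id": config.response_gene, "sample_id": sample,
                        "n": len(spots), "ks_D": d, "ks_p": p})
    ks_results = pd.DataFrame(ks_rows)
    return gene_stats, responders, resp_table, resp_p, resp_odds, threshold, ks_results


def _de_stage(logn: NormalizedMatrix, responders: pd.DataFrame) -> pd.DataFrame | None:
    treated = responders[responders["condition"] == "Losa"]
    group_a = list(treated[treated["high_responding"]]["spot_id"])
    group_b = list(treated[~treated["high_responding"]]["spot_id"])
    if not group_a or not group_b:
        return None
    return de_between_groups(logn, group_a, group_b)


def md_response_test(
    spot_counts: CountMatrix,
    fractions: FractionMatrix,
    lattice: SpotLattice,
    config: PipelineConfig,
    md_gene: str = "Ptgs2",
    md_type: str | None = None,
) -> pd.DataFrame:
    """Treated-vs-control response of the macula densa gene.

    Spots are selected by the macula densa (group-B) fraction, expression
    is fraction-normalized to that type and log-normalized, and conditions
    are compared by Wilcoxon rank-sum.
    """
    md_type = md_type or config.group_b_type
    nc = fraction_normalize(spot_counts, fractions, md_type, config.min_fraction)
    logn = lognormalize_total(nc, config.lognorm_scale)
    if md_gene not in logn.gene_ids:
        raise ValidationError(f"macula densa gene {md_gene!r} not present")
    vals = logn.gene_values(md_gene)
    cond = lattice.table.set_index("spot_id")["condition"]
    shared = [s for s in logn.spot_ids if s in cond.index]
    losa = [s for s in shared if cond[s] == "Losa"]
    ctrl = [s for s in shared if cond[s] == "Ctrl"]
    if not losa or not ctrl:
        raise ValidationError("both conditions required for the response test")
    stat, p = wilcoxon_rank_sum(vals[losa].to_numpy(), vals[ctrl].to_numpy())
    return pd.DataFrame([{
        "gene_id": md_gene, "cell_type": md_type,
        "n_losa": len(losa), "n_ctrl": len(ctrl),
        "mean_losa": float(vals[losa].mean()), "mean_ctrl": float(vals[ctrl].mean()),
        "statistic": stat, "p": p,
    }])


def _write_reports(result: PipelineResult, out_dir: Path, chash: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.write_table(
        result.signature_frame.reset_index(names="gene_id"),
        out_dir / "signature.tsv", chash)
    spio.write_fractions(result.fractions, out_dir / "fractions.tsv")
    spio.write_table(result.adjacency, out_dir / "adjacency.tsv", chash)
    spio.write_table(result.gene_stats, out_dir / "gene_stats.tsv", chash)
    spio.write_table(result.responders, out_dir / "responders.tsv", chash)
    spio.write_table(result.ks_results, out_dir / "ks_results.tsv", chash)
    spio.write_table(result.md_response, out_dir / "md_response.tsv", chash)
    if result.de_table is not None:
        spio.write_table(result.de_table, out_dir / "de.tsv", chash)
    summary = {
        "config_hash": chash,
        "config": dataclasses.asdict(result.config),
        "n_cells_qc": result.n_cells_qc,
        "responder_threshold": result.responder_threshold,
        "responder_fisher_p": result.responder_p,
        "responder_odds_ratio": result.responder_odds,
        "responder_table": result.responder_table.counts.tolist(),
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
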