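"""Synthetic Visium-like kidney tissues with planted ground truth.

The generator emulates the study design that the pipeline is built for:
hexagonally packed spot lattices banded into the four renal zones (Cortex,
OMOS, OMIS, IM), sparse single-spot glomeruli containing podocyte /
mesangial / juxtaglomerular (JG) fractions, one macula-densa-enriched spot
(TAL-2) planted adjacent to each glomerulus, and a two-arm drug study
(Ctrl vs Losa) in which treatment induces the macula-densa response gene
(*Ptgs2* analog) everywhere and the JG response gene (*Ren* analog) only in
a planted "high-responder" subset of glomeruli. Every planted feature is
recorded so downstream stages can be scored against the truth.

Counts follow a gamma-Poisson (negative binomial) model with a single
shared dispersion and log-normal per-cell/per-spot depth variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ZONES,
    ConfigurationError,
    CountMatrix,
    FractionMatrix,
    SpotLattice,
    ValidationError,
)
from .spatial import hex_offsets

RESPONSE_GENE = "Ren"          # JG response gene analog
MD_RESPONSE_GENE = "Ptgs2"     # macula densa response gene analog
HOUSEKEEPING_GENE = "Rplp0"    # homogeneous high-expression control
TAL_SHARED_MARKER = "Slc12a1"  # expressed by both TAL sub-populations
MD_MARKER = "Pappa2"           # macula densa (TAL-2) marker

#: zone-affinity weights of the default renal cell-type roster. Types with
#: an empty mapping occur only inside glomeruli.
DEFAULT_CELL_TYPES: dict[str, dict[str, float]] = {
    "Podocyte": {},
    "Mesangial": {},
    "JG": {},
    "PT": {"Cortex": 1.0, "OMOS": 0.7},
    "TAL-1": {"Cortex": 0.8, "OMOS": 1.0, "OMIS": 0.3},
    "TAL-2": {"Cortex": 0.08},
    "DTL": {"OMIS": 0.8, "IM": 1.0},
    "CD-PC": {"OMIS": 0.4, "IM": 0.8},
    "CD-IC": {"OMIS": 0.6, "IM": 0.3},
    "Endo": {"Cortex": 0.3, "OMOS": 0.3, "OMIS": 0.3, "IM": 0.2},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the reference study layout: three control and three
    treated tissue sections, 40 single-spot glomeruli per section with one
    macula densa neighbour each, ~5,000 UMIs per spot, a 5-fold *Ren*
    induction restricted to the planted top-25% high-responder glomeruli
    and a 3-fold *Ptgs2* induction in treated macula densa.
    """

    n_genes: int = 300
    cell_types: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CELL_TYPES.items()})
    n_cells_per_type: int = 200
    lattice_rows: int = 40
    lattice_cols: int = 30
    zone_layout: tuple[tuple[str, int], ...] | None = None
    n_glomeruli: int = 40
    glomerulus_types: dict[str, float] = field(
        default_factory=lambda: {"Podocyte": 0.5, "Mesangial": 0.3, "JG": 0.2})
    macula_densa_type: str = "TAL-2"
    macula_densa_fraction: float = 0.6
    depth_mean_umi: float = 5000.0
    depth_cv: float = 0.2
    nb_dispersion: float = 0.05
    conditions: dict[str, int] = field(default_factory=lambda: {"Ctrl": 3, "Losa": 3})
    effect_ptgs2_fold: float = 3.0
    effect_ren_fold: float = 5.0
    high_responder_frac: float = 0.25
    md_placement: str = "adjacent"
    dirichlet_conc: float = 1.0
    marker_share: float = 0.02
    marker_leak: float = 0.02
    n_markers_per_type: int = 5
    n_mito_genes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells_per_type", "lattice_rows", "lattice_cols",
                     "n_glomeruli", "n_markers_per_type"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive; got {getattr(self, name)}")
        if self.n_mito_genes < 0:
            raise ConfigurationError("n_mito_genes must be non-negative")
        for name in ("macula_densa_fraction", "high_responder_frac",
                     "marker_share", "marker_leak"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]; got {v}")
        for name in ("effect_ptgs2_fold", "effect_ren_fold"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1; got {getattr(self, name)}")
        for name in ("depth_mean_umi", "dirichlet_conc"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.nb_dispersion < 0 or self.depth_cv < 0:
            raise ConfigurationError("nb_dispersion and depth_cv must be non-negative")
        if self.md_placement not in ("adjacent", "random"):
            raise ConfigurationError("md_placement must be 'adjacent' or 'random'")
        if not self.cell_types:
            raise ConfigurationError("cell_types must be non-empty")
        for t, weights in self.cell_types.items():
            bad = set(weights) - set(ZONES)
            if bad:
                raise ConfigurationError(f"cell_types[{t!r}] has unknown zones {sorted(bad)}")
        for t in self.glomerulus_types:
            if t not in self.cell_types:
                raise ConfigurationError(f"glomerulus_types references unknown type {t!r}")
        gsum = sum(self.glomerulus_types.values())
        if not math.isclose(gsum, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"glomerulus_types fractions must sum to 1; got {gsum}")
        if self.macula_densa_type not in self.cell_types:
            raise ConfigurationError(
                f"macula_densa_type {self.macula_densa_type!r} not in cell_types")
        if not self.conditions:
            raise ConfigurationError("conditions must be non-empty")
        for cond, n in self.conditions.items():
            if cond not in ("Ctrl", "Losa"):
                raise ConfigurationError(f"conditions has unknown condition {cond!r}")
            if n < 0:
                raise ConfigurationError(f"conditions[{cond!r}] must be non-negative")
        layout = self.resolved_zone_layout()
        if sum(n for _, n in layout) != self.lattice_rows:
            raise ConfigurationError("zone_layout row counts must partition lattice_rows")
        for z, _ in layout:
            if z not in ZONES:
                raise ConfigurationError(f"zone_layout has unknown zone {z!r}")

    def resolved_zone_layout(self) -> tuple[tuple[str, int], ...]:
        """Zone bands as (zone, n_rows); default: four equal bands in order."""
        if self.zone_layout is not None:
            return tuple(self.zone_layout)
        base, extra = divmod(self.lattice_rows, len(ZONES))
        return tuple((z, base + (1 if i < extra else 0)) for i, z in enumerate(ZONES))

    @property
    def type_names(self) -> list[str]:
        return list(self.cell_types)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic tissue."""

    true_fractions: FractionMatrix
    planted_high_responders: dict[str, set[str]]
    macula_densa_spots: set[str]
    base_means: pd.DataFrame  # genes x types, expected counts per cell

    def __post_init__(self) -> None:
        known = set(self.true_fractions.spot_ids)
        frame = self.true_fractions.to_frame()
        sums = frame.sum(axis=1)
        if np.any(np.abs(sums.to_numpy() - 1.0) > 1e-9):
            raise ValidationError("true fraction rows must sum to 1")
        self._glom_spots: set[str] = set()

    def planted_glomerulus_ids(self) -> set[str]:
        out: set[str] = set()
        for s in self.planted_high_responders.values():
            out |= s
        return out


def _gene_names(config: SimConfig) -> tuple[list[str], dict[str, list[str]]]:
    """Assemble the gene list and the per-type marker assignment.

    Named analogs come first so reports read like the field's gene symbols;
    remaining slots are filled with neutral identifiers.
    """
    markers: dict[str, list[str]] = {t: [] for t in config.cell_types}
    names: list[str] = []

    def add(name: str) -> str:
        names.append(name)
        return name

    for t in config.cell_types:
        for i in range(config.n_markers_per_type):
            if t == "JG" and i == 0:
                g = RESPONSE_GENE
            elif t == "TAL-2" and i == 0:
                g = MD_RESPONSE_GENE
            elif t == "TAL-2" and i == 1:
                g = MD_MARKER
            else:
                g = f"{t}.mk{i + 1}"
            markers[t].append(add(g))
    if "TAL-1" in markers and "TAL-2" in markers:
        add(TAL_SHARED_MARKER)
        markers["TAL-1"].append(TAL_SHARED_MARKER)
        markers["TAL-2"].append(TAL_SHARED_MARKER)
    add(HOUSEKEEPING_GENE)
    mito = [add(f"Mt-{i + 1}") for i in range(config.n_mito_genes)]
    n_filler = config.n_genes - len(names)
    if n_filler < 0:
        raise ConfigurationError(
            f"n_genes={config.n_genes} too small for marker layout ({len(names)} named genes)")
    for i in range(n_filler):
        add(f"G{i + 1:04d}")
    return names, markers


def build_base_means(config: SimConfig) -> pd.DataFrame:
    """Per-type expected counts per cell (genes x types), deterministic in seed.

    Each marker gene takes ``marker_share`` of its type's transcriptome and
    leaks ``marker_leak`` of that into other types; the housekeeping analog
    takes 2% uniformly; remaining mass goes to baseline genes with
    log-normal gene- and type-level variation. Columns sum to
    ``depth_mean_umi``.
    """
    rng = np.random.default_rng([101, config.seed])
    names, markers = _gene_names(config)
    types = config.type_names
    shares = pd.DataFrame(0.0, index=names, columns=types)

    for t in types:
        for g in markers[t]:
            shares.loc[g, t] = config.marker_share
    # leak: off-type expression of marker genes
    marker_rows = sorted({g for ms in markers.values() for g in ms})
    for g in marker_rows:
        on = shares.loc[g] > 0
        shares.loc[g, ~on.to_numpy()] = config.marker_share * config.marker_leak
    shares.loc[HOUSEKEEPING_GENE, :] = 0.02
    for i in range(config.n_mito_genes):
        shares.loc[f"Mt-{i + 1}", :] = 0.004
    fixed = shares.sum(axis=0)

    baseline_rows = shares.index[(shares == 0).all(axis=1)]
    gene_prop = rng.lognormal(0.0, 0.4, size=len(baseline_rows))
    type_prop = rng.lognormal(0.0, 0.3, size=(len(baseline_rows), len(types)))
    raw = gene_prop[:, None] * type_prop
    raw = raw / raw.sum(axis=0, keepdims=True)
    for j, t in enumerate(types):
        shares.loc[baseline_rows, t] = raw[:, j] * (1.0 - fixed[t])
    return shares * config.depth_mean_umi


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw; dispersion 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, dispersion * mean)
    return rng.poisson(lam)


def _depth_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Log-normal depth multipliers with mean exactly 1."""
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)


def make_reference(config: SimConfig) -> tuple[CountMatrix, list[str]]:
    """Simulate a labelled single-cell reference dataset.

    Returns the genes x cells count matrix and the per-cell type labels.
    """
    rng = np.random.default_rng([1, config.seed])
    base = build_base_means(config)
    n_types = len(config.type_names)
    n_cells = n_types * config.n_cells_per_type
    counts = np.empty((len(base.index), n_cells), dtype=np.int64)
    labels: list[str] = []
    barcodes: list[str] = []
    col = 0
    for t in config.type_names:
        mu = base[t].to_numpy()
        depth = _depth_factors(rng, config.n_cells_per_type, config.depth_cv)
        for k in range(config.n_cells_per_type):
            counts[:, col] = _nb_draw(rng, mu * depth[k], config.nb_dispersion)
            barcodes.append(f"{t}.c{k + 1}")
            labels.append(t)
            col += 1
    matrix = CountMatrix(list(base.index), barcodes, counts, modality="single_cell")
    return matrix, labels


def _build_sample_lattice(
    config: SimConfig,
    sample_id: str,
    condition: str,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """One capture area: spot table, true fractions, macula densa spots."""
    layout = config.resolved_zone_layout()
    zone_of_row: list[str] = []
    for zone, n in layout:
        zone_of_row.extend([zone] * n)

    records = []
    coord_to_spot: dict[tuple[int, int], str] = {}
    for r in range(config.lattice_rows):
        for c in range(config.lattice_cols):
            col = 2 * c + (r % 2)
            sid = f"{sample_id}:r{r}c{col}"
            records.append(
                {"spot_id": sid, "array_row": r, "array_col": col,
                 "zone": zone_of_row[r], "glomerulus_id": None,
                 "sample_id": sample_id, "condition": condition})
            coord_to_spot[(r, col)] = sid
    table = pd.DataFrame(records)

    def neighbours(r: int, col: int) -> list[str]:
        out = []
        for dr, dc in hex_offsets():
            sid = coord_to_spot.get((r + dr, col + dc))
            if sid is not None:
                out.append(sid)
        return out

    cortex = table[table["zone"] == "Cortex"]
    spot_row = {row.spot_id: (row.array_row, row.array_col) for row in table.itertuples()}
    zone_by_spot = dict(zip(table["spot_id"], table["zone"]))

    glom_of_spot: dict[str, str] = {}
    md_spots: list[str] = []
    occupied: set[str] = set()
    candidates = list(cortex["spot_id"])
    rng.shuffle(candidates)
    g_idx = 0
    for sid in candidates:
        if g_idx >= config.n_glomeruli:
            break
        r, col = spot_row[sid]
        nbrs = neighbours(r, col)
        if sid in occupied or any(n in glom_of_spot for n in nbrs):
            continue
        free = [n for n in nbrs
                if n not in occupied and zone_by_spot[n] == "Cortex"]
        if config.md_placement == "adjacent" and not free:
            continue
        gid = f"{sample_id}:g{g_idx + 1}"
        glom_of_spot[sid] = gid
        occupied.add(sid)
        if config.md_placement == "adjacent":
            md = free[rng.integers(len(free))]
            md_spots.append(md)
            occupied.add(md)
        g_idx += 1
    if g_idx < config.n_glomeruli:
        raise ConfigurationError(
            f"n_glomeruli={config.n_glomeruli} cannot be placed: only {g_idx} cortical "
            f"spots with a free neighbour available in sample {sample_id}")
    if config.md_placement == "random":
        pool = [s for s in cortex["spot_id"] if s not in occupied]
        rng.shuffle(pool)
        md_spots = pool[: config.n_glomeruli]
        occupied.update(md_spots)

    table["glomerulus_id"] = table["spot_id"].map(glom_of_spot)

    # --- true fractions ---------------------------------------------------
    types = config.type_names
    fracs = pd.DataFrame(0.0, index=table["spot_id"].to_numpy(), columns=types)
    zone_pools: dict[str, tuple[list[str], np.ndarray]] = {}
    for zone in ZONES:
        names = [t for t in types if config.cell_types[t].get(zone, 0.0) > 0]
        alpha = np.array([config.cell_types[t][zone] for t in names]) * config.dirichlet_conc
        zone_pools[zone] = (names, alpha)

    md_set = set(md_spots)
    for row in table.itertuples():
        sid = row.spot_id
        if sid in glom_of_spot:
            for t, f in config.glomerulus_types.items():
                fracs.loc[sid, t] = f
        elif sid in md_set:
            names, alpha = zone_pools[row.zone]
            rest = [t for t in names if t != config.macula_densa_type]
            alpha_rest = np.array([config.cell_types[t][row.zone] for t in rest])
            w = rng.dirichlet(alpha_rest * config.dirichlet_conc)
            fracs.loc[sid, config.macula_densa_type] = config.macula_densa_fraction
            fracs.loc[sid, rest] = (1.0 - config.macula_densa_fraction) * w
        else:
            names, alpha = zone_pools[row.zone]
            fracs.loc[sid, names] = rng.dirichlet(alpha)
    return table, fracs, md_spots


def make_tissue(config: SimConfig) -> tuple[SpotLattice, SyntheticTruth]:
    """Simulate spot lattices for every sample, with planted ground truth."""
    rng = np.random.default_rng([2, config.seed])
    base = build_base_means(config)
    tables, frac_frames, md_all = [], [], []
    planted: dict[str, set[str]] = {}
    n_planted = math.ceil(config.high_responder_frac * config.n_glomeruli)
    for condition in ("Ctrl", "Losa"):
        for k in range(config.conditions.get(condition, 0)):
            sample_id = f"{condition}{k + 1}"
            table, fracs, md = _build_sample_lattice(config, sample_id, condition, rng)
            tables.append(table)
            frac_frames.append(fracs)
            md_all.extend(md)
            if condition == "Losa":
                gids = sorted(table["glomerulus_id"].dropna())
                chosen = rng.choice(len(gids), size=n_planted, replace=False)
                planted[sample_id] = {gids[i] for i in sorted(chosen)}
    lattice = SpotLattice(pd.concat(tables, ignore_index=True))
    fracs = pd.concat(frac_frames)
    truth = SyntheticTruth(
        true_fractions=FractionMatrix(
            list(fracs.index), list(fracs.columns), fracs.to_numpy()),
        planted_high_responders=planted,
        macula_densa_spots=set(md_all),
        base_means=base,
    )
    # invariant: every planted glomerulus id exists in the lattice
    known = set(lattice.table["glomerulus_id"].dropna())
    for sample, gids in planted.items():
        missing = gids - known
        if missing:
            raise ValidationError(f"planted high-responders not in lattice: {sorted(missing)}")
    return lattice, truth


def sample_counts_from_fractions(
    fractions: pd.DataFrame,
    base_means: pd.DataFrame,
    depth_mean_umi: float,
    nb_dispersion: float,
    depth_cv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw genes x spots NB counts from per-spot type mixtures.

    ``fractions`` is spots x types; expected profiles are the fraction-
    weighted type base means rescaled to the requested mean depth.
    """
    b = base_means[fractions.columns].to_numpy()
    expected = fractions.to_numpy() @ b.T  # spots x genes
    expected = expected * (depth_mean_umi / base_means.to_numpy().sum(axis=0).mean())
    depth = _depth_factors(rng, len(fractions), depth_cv)
    return _nb_draw(rng, (expected * depth[:, None]).T, nb_dispersion)


def make_spot_counts(
    lattice: SpotLattice, truth: SyntheticTruth, config: SimConfig
) -> CountMatrix:
    """Draw the spatial count matrix, applying the planted treatment effects.

    The *Ptgs2* analog is induced ``effect_ptgs2_fold``-fold in the macula
    densa component of every treated-sample spot; the *Ren* analog is
    induced ``effect_ren_fold``-fold in the JG component of planted
    high-responder glomerulus spots only.
    """
    rng = np.random.default_rng([3, config.seed])
    base = truth.base_means
    fracs = truth.true_fractions.to_frame()
    missing = [s for s in lattice.spot_ids if s not in fracs.index]
    if missing:
        raise ValidationError(f"spots missing from truth fractions: {missing[:5]}")
    fracs = fracs.loc[lattice.spot_ids]

    expected = fracs.to_numpy() @ base.to_numpy().T  # spots x genes
    gene_idx = {g: i for i, g in enumerate(base.index)}
    t_idx = {t: j for j, t in enumerate(fracs.columns)}

    treated = (lattice.table["condition"] == "Losa").to_numpy()
    md_type = config.macula_densa_type
    if MD_RESPONSE_GENE in gene_idx and md_type in t_idx:
        gi = gene_idx[MD_RESPONSE_GENE]
        boost = (fracs.to_numpy()[:, t_idx[md_type]]
                 * base.loc[MD_RESPONSE_GENE, md_type]
                 * (config.effect_ptgs2_fold - 1.0))
        expected[treated, gi] += boost[treated]
    planted_gids = truth.planted_glomerulus_ids()
    jg_types = [t for t in config.glomerulus_types
                if t in t_idx and RESPONSE_GENE in gene_idx]
    if RESPONSE_GENE in gene_idx and "JG" in t_idx and planted_gids:
        gi = gene_idx[RESPONSE_GENE]
        is_planted = lattice.table["glomerulus_id"].isin(planted_gids).to_numpy()
        boost = (fracs.to_numpy()[:, t_idx["JG"]]
                 * base.loc[RESPONSE_GENE, "JG"]
                 * (config.effect_ren_fold - 1.0))
        expected[is_planted, gi] += boost[is_planted]

    depth = _depth_factors(rng, expected.shape[0], config.depth_cv)
    counts = _nb_draw(rng, (expected * depth[:, None]).T, config.nb_dispersion)
    return CountMatrix(list(base.index), lattice.spot_ids, counts, modality="spatial")
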