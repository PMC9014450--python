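"""Hex-lattice adjacency and glomerulus-enrichment statistics.

A Visium spot's six neighbours sit at array offsets (0, +-2) and
(+-1, +-1); spots from different capture areas (samples) are never
neighbours. Spot groups classified by their dominant score are compared
for glomerulus adjacency with Fisher's exact test.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ContingencyTable2x2, SpotLattice, ValidationError

_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


def hex_offsets() -> tuple[tuple[int, int], ...]:
    """(row, col) offsets of the six hex neighbours (Visium convention)."""
    return _OFFSETS


def hex_neighbors(lattice: SpotLattice, spot_id: str) -> set[str]:
    """Existing neighbours of ``spot_id`` within the same sample (<= 6)."""
    row = lattice.row(spot_id)  # KeyError for unknown spot
    t = lattice.table
    same = t[t["sample_id"] == row["sample_id"]]
    coords = {(r, c): s for s, r, c in zip(
        same["spot_id"], same["array_row"], same["array_col"])}
    out = set()
    for dr, dc in _OFFSETS:
        hit = coords.get((row["array_row"] + dr, row["array_col"] + dc))
        if hit is not None:
            out.add(hit)
    return out


def neighbor_map(lattice: SpotLattice) -> dict[str, set[str]]:
    """All-spot adjacency in one pass (per-sample hex neighbourhoods)."""
    out: dict[str, set[str]] = {}
    for _, same in lattice.table.groupby("sample_id"):
        coords = {(r, c): s for s, r, c in zip(
            same["spot_id"], same["array_row"], same["array_col"])}
        for (r, c), s in coords.items():
            out[s] = {coords[(r + dr, c + dc)]
                      for dr, dc in _OFFSETS if (r + dr, c + dc) in coords}
    return out


def classify_dominant(score_a: float, score_b: float) -> str:
    """Dominant-score spot classification.

    A spot with both scores zero is ``"Unclassified"``; otherwise it joins
    ``"GroupA"`` only when its A score is strictly higher, ties going to
    ``"GroupB"`` (the strictly-greater rule of the reference design).
    """
    if score_a < 0 or score_b < 0:
        raise ValidationError(f"scores must be non-negative; got ({score_a}, {score_b})")
    if score_a == 0 and score_b == 0:
        return "Unclassified"
    return "GroupA" if score_a > score_b else "GroupB"


def adjacency_contingency(
    labels: Mapping[str, str],
    glomerulus_spots: Iterable[str],
    lattice: SpotLattice,
    group_labels: tuple[str, str] = ("GroupA", "GroupB"),
) -> ContingencyTable2x2:
    """Count classified spots by glomerulus adjacency.

    ``labels`` maps eligible spot ids to one of ``group_labels``
    (``"Unclassified"`` entries are ignored); glomerulus spots themselves
    are excluded from counting. Rows are the two groups, columns are
    (adjacent to >= 1 glomerulus spot, not adjacent).
    """
    glom = set(glomerulus_spots)
    nbrs = neighbor_map(lattice)
    counts = np.zeros((2, 2), dtype=int)
    n_eligible = 0
    for spot, grp in labels.items():
        if spot in glom or grp == "Unclassified":
            continue
        if grp not in group_labels:
            raise ValidationError(f"unknown group label {grp!r} for spot {spot!r}")
        n_eligible += 1
        i = group_labels.index(grp)
        adjacent = bool(nbrs.get(spot, set()) & glom)
        counts[i, 0 if adjacent else 1] += 1
    if n_eligible == 0:
        raise ValidationError("no eligible classified spots to tabulate")
    return ContingencyTable2x2(
        counts, row_labels=group_labels, col_labels=("adjacent", "not_adjacent"))


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(p, odds_ratio)``; the p-value sums hypergeometric
    probabilities of all tables (margins fixed) no more probable than the
    observed one. A zero margin makes every table equally probable, so
    p = 1 (flagged with a warning by callers that care).
    """
    c = table.counts
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        return 1.0, _sample_odds_ratio(c)
    res = stats.fisher_exact(c, alternative="two-sided")
    return float(res.pvalue), _sample_odds_ratio(c)


def _sample_odds_ratio(c: np.ndarray) -> float:
    a, b, cc, d = c[0, 0], c[0, 1], c[1, 0], c[1, 1]
    if b * cc == 0:
        return float("inf") if a * d > 0 else float("nan")
    return float((a * d) / (b * cc))


def adjacency_report(
    labels: Mapping[str, str],
    glomerulus_spots: Iterable[str],
    lattice: SpotLattice,
    group_labels: tuple[str, str] = ("GroupA", "GroupB"),
) -> pd.DataFrame:
    """Contingency counts plus odds ratio and Fisher p as a tidy table."""
    table = adjacency_contingency(labels, glomerulus_spots, lattice, group_labels)
    p, orr = fisher_exact(table)
    frame = table.to_frame().reset_index(names="group")
    frame["odds_ratio"] = orr
    frame["fisher_p"] = p
    return frame
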