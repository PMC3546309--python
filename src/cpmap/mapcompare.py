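"""Joining datasets of one parent and comparing maps across parents.

A parent mapped in two crosses (as female in one, male in the other)
yields two gamete matrices over overlapping marker sets.  Joining them
concatenates progeny columns after reconciling the arbitrary a/b code
polarity per marker, then reruns the full grouping/ordering pipeline on
the combined matrix — the joined map is the reference frame.

Across parents, maps are compared on shared markers: rank correlation of
positions (colinearity), per-LG length ratios after remapping on the
common marker set (recombination-rate differences, e.g. heterochiasmy),
and projection of markers mapped in only one parent into the reference
frame through a monotone piecewise-linear "tendency curve" through the
shared anchors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._util import CODE_MISSING, weighted_isotonic
from .ordering import GeneticMap
from .segcoding import GameteMatrix

__all__ = [
    "join_parent_datasets",
    "common_marker_remap",
    "colinearity_stats",
    "project_markers",
]


def _reconcile_codes(gam_a: GameteMatrix, gam_b: GameteMatrix) -> tuple[GameteMatrix, list[str]]:
    """Flip B's codes where its a/b polarity disagrees with A's.

    Polarity is anchored on the allele-of-code tables (the same parent has
    the same alleles in both crosses); markers whose allele tables are
    irreconcilable are dropped from B and reported.
    """
    flips: dict[str, bool] = {}
    dropped: list[str] = []
    for m in gam_b.markers:
        if m not in gam_a.markers:
            flips[m] = False
            continue
        ta = gam_a.allele_of_code.get(m)
        tb = gam_b.allele_of_code.get(m)
        if ta is None or tb is None or ta == tb:
            flips[m] = False
        elif ta == (tb[1], tb[0]):
            flips[m] = True
        else:
            dropped.append(m)
    keep = [m for m in gam_b.markers if m not in dropped]
    gb = gam_b.subset(keep)
    for r, m in enumerate(gb.markers):
        if flips.get(m):
            col = gb.codes[r]
            scored = col != CODE_MISSING
            col[scored] = 1 - col[scored]
            gb.allele_of_code[m] = (gb.allele_of_code[m][1], gb.allele_of_code[m][0])
    if dropped:
        warnings.warn(f"irreconcilable code polarity, markers dropped from second "
                      f"dataset: {dropped}")
    return gb, dropped


def join_parent_datasets(gam_a: GameteMatrix, gam_b: GameteMatrix,
                         label: str | None = None) -> GameteMatrix:
    """Combine two gamete matrices of the same parent (progeny concatenated).

    Markers present in a single dataset are kept (columns missing for the
    other cross's progeny).  The caller reruns the mapping pipeline on the
    result to obtain the joined reference map.
    """
    gb, _ = _reconcile_codes(gam_a, gam_b)
    markers = list(gam_a.markers) + [m for m in gb.markers if m not in gam_a.markers]
    na, nb = gam_a.n_progeny, gb.n_progeny
    codes = np.full((len(markers), na + nb), CODE_MISSING, dtype=np.int8)
    row = {m: i for i, m in enumerate(markers)}
    for i, m in enumerate(gam_a.markers):
        codes[row[m], :na] = gam_a.codes[i]
    for i, m in enumerate(gb.markers):
        codes[row[m], na:] = gb.codes[i]
    allele = dict(gb.allele_of_code)
    allele.update(gam_a.allele_of_code)
    individuals = [f"A.{x}" for x in gam_a.individuals] + [f"B.{x}" for x in gb.individuals]
    source = {m: ("both" if (m in gam_a.markers and m in gb.markers)
                  else ("A" if m in gam_a.markers else "B")) for m in markers}
    out = GameteMatrix(label or gam_a.parent, markers, individuals, codes, allele)
    out.source = source  # type: ignore[attr-defined]
    return out


def common_marker_remap(
    gams: dict[str, GameteMatrix],
    shared_markers: list[str],
    anchor_table: dict[str, str] | None = None,
    **map_kwargs,
):
    """Rebuild each parent's map restricted to a shared marker set.

    Returns ``(maps, lengths)`` where ``maps`` maps dataset label to the
    remapped result and ``lengths`` is a per-LG length table across
    datasets (LGs with fewer than two shared markers excluded).
    """
    from .pipeline import build_parent_map

    if not shared_markers:
        raise ValueError("empty shared marker list")
    maps = {}
    for label, gam in gams.items():
        sub = gam.subset([m for m in shared_markers if m in gam.markers])
        maps[label] = build_parent_map(sub, anchor_table=anchor_table, **map_kwargs)
    rows = []
    for label, res in maps.items():
        for lg in res.genetic_map.linkage_groups:
            if lg.n_markers >= 2:
                rows.append({"dataset": label, "lg": lg.lg_id,
                             "n_markers": lg.n_markers, "size_cM": lg.length})
    lengths = pd.DataFrame(rows).pivot(index="lg", columns="dataset", values="size_cM")
    return maps, lengths


def _shared_positions(lg1, map2: GeneticMap):
    """Positions of lg1's markers that are also mapped in map2 (same LG id)."""
    try:
        lg2 = map2.lg(lg1.lg_id)
    except KeyError:
        return [], np.empty(0), np.empty(0)
    shared = [m for m in lg1.markers if m in lg2.markers]
    x = np.array([lg1.position_of(m) for m in shared])
    y = np.array([lg2.position_of(m) for m in shared])
    return shared, x, y


def colinearity_stats(map1: GeneticMap, map2: GeneticMap) -> pd.DataFrame:
    """Rank correlation of shared-marker positions per LG, plus inversions.

    Orientation is auto-resolved: a negative correlation means the two maps
    run in opposite directions, so map2's positions are reflected before the
    statistics are computed (a reversed map is perfectly colinear).
    Adjacent-pair order flips surviving orientation resolution are listed as
    candidate local inversions (reported, never corrected).
    """
    rows = []
    for lg1 in map1.linkage_groups:
        shared, x, y = _shared_positions(lg1, map2)
        if len(shared) < 3:
            continue
        rho = spearmanr(x, y).statistic
        flipped = False
        if rho < 0:
            y = y.max() - y
            rho = spearmanr(x, y).statistic
            flipped = True
        order = np.argsort(x)
        inversions = []
        ys = y[order]
        for a, b in zip(range(len(ys) - 1), range(1, len(ys))):
            if ys[b] < ys[a]:
                inversions.append((shared[order[a]], shared[order[b]]))
        rows.append({"lg": lg1.lg_id, "n_shared": len(shared), "rho": float(rho),
                     "orientation_flipped": flipped, "n_inversions": len(inversions),
                     "inversions": inversions})
    return pd.DataFrame(rows).set_index("lg") if rows else pd.DataFrame(
        columns=["n_shared", "rho", "orientation_flipped", "n_inversions", "inversions"])


def project_markers(source_map: GeneticMap, ref_map: GeneticMap) -> pd.DataFrame:
    """Estimate reference-frame positions for markers mapped only in source.

    Per LG, a monotone piecewise-linear curve is fitted through the shared
    anchor positions (source x, reference y); source-only markers are
    interpolated, with linear extrapolation beyond the terminal anchors.
    Non-monotone anchors (local inversions) are regularized by isotonic
    regression first and flagged.
    """
    rows = []
    for lg_s in source_map.linkage_groups:
        shared, x, y = _shared_positions(lg_s, ref_map)
        if len(shared) < 2:
            continue
        rho = spearmanr(x, y).statistic if len(shared) >= 3 else (
            1.0 if (x[1] - x[0]) * (y[1] - y[0]) >= 0 else -1.0)
        if rho < 0:
            y = y.max() - y
        order = np.argsort(x)
        xa, ya = x[order], y[order]
        monotone = bool(np.all(np.diff(ya) >= 0))
        if not monotone:
            ya = weighted_isotonic(ya)
        # strictly increasing x for interpolation
        keep = np.concatenate([[True], np.diff(xa) > 1e-12])
        xa, ya = xa[keep], ya[keep]
        slope_lo = (ya[1] - ya[0]) / (xa[1] - xa[0]) if len(xa) > 1 and xa[1] > xa[0] else 1.0
        slope_hi = (ya[-1] - ya[-2]) / (xa[-1] - xa[-2]) if len(xa) > 1 and xa[-1] > xa[-2] else 1.0
        shared_set = set(shared)
        for m in lg_s.markers:
            px = lg_s.position_of(m)
            if m in shared_set:
                method = "anchor"
                est = float(np.interp(px, xa, ya))
            elif px < xa[0]:
                method = "extrapolated"
                est = float(ya[0] + slope_lo * (px - xa[0]))
            elif px > xa[-1]:
                method = "extrapolated"
                est = float(ya[-1] + slope_hi * (px - xa[-1]))
            else:
                method = "interpolated"
                est = float(np.interp(px, xa, ya))
            rows.append({"marker": m, "lg": lg_s.lg_id, "source_pos": px,
                         "est_ref_pos": est, "method": method,
                         "anchors_nonmonotone": not monotone,
                         "estimated": m not in shared_set})
    return pd.DataFrame(rows)
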