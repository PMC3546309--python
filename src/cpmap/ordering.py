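"""Marker ordering and map-distance assignment within linkage groups.

The ordering procedure is a regression-mapping scheme in the JoinMap
tradition: markers enter one at a time in decreasing informativeness, each
insertion slot is scored by a weighted least-squares fit of map positions to
the pairwise Kosambi distances (weights = independence LOD), a sliding
three-marker "ripple" permutation pass refines the order after every
insertion, and a marker whose best insertion degrades the normalized fit by
more than a jump threshold is set aside rather than forced into the map.

Positions are expressed in centiMorgans from 0 at the proximal end of the
group.  The Kosambi map function, which allows for moderate crossover
interference, converts recombination fractions to additive distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from ._util import CODE_MISSING, weighted_isotonic

__all__ = [
    "LinkageGroup",
    "GeneticMap",
    "SingletonReport",
    "kosambi",
    "kosambi_inverse",
    "order_markers_regression",
    "detect_singletons",
    "clean_and_remap",
    "summarize_map",
]


def kosambi(r) -> float | np.ndarray:
    """Map distance in cM for recombination fraction ``r``: 25*ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d) -> float | np.ndarray:
    """Recombination fraction for a Kosambi distance ``d`` in cM: tanh(2d/100)/2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


@dataclass
class LinkageGroup:
    """Ordered markers with cM positions on one linkage group."""

    lg_id: str
    markers: list[str]
    positions: np.ndarray
    unplaced: list[tuple[str, str]] = field(default_factory=list)  # (marker, reason)
    source: dict[str, str] = field(default_factory=dict)  # marker -> dataset flag

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.markers) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def position_of(self, marker: str) -> float:
        return float(self.positions[self.markers.index(marker)])

    def reversed(self) -> "LinkageGroup":
        pos = self.length - self.positions[::-1]
        return LinkageGroup(self.lg_id, list(self.markers[::-1]), pos,
                            list(self.unplaced), dict(self.source))


@dataclass
class GeneticMap:
    """A set of linkage groups mapped for one parent (or joined dataset)."""

    parent: str
    linkage_groups: list[LinkageGroup]

    @property
    def total_markers(self) -> int:
        return sum(lg.n_markers for lg in self.linkage_groups)

    @property
    def total_length(self) -> float:
        return float(sum(lg.length for lg in self.linkage_groups))

    def lg(self, lg_id: str) -> LinkageGroup:
        for g in self.linkage_groups:
            if g.lg_id == lg_id:
                return g
        raise KeyError(lg_id)


@dataclass
class SingletonReport:
    """Cells whose phase disagrees with both nearest non-missing flanks."""

    cells: list[tuple[str, str]]  # (marker, individual)
    per_lg: dict[str, int]

    @property
    def n_flagged(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# weighted least-squares position fitting


class _PairFit:
    """WLS position fit machinery for a fixed active marker set.

    Residuals are p_later - p_earlier - d for every usable pair; the normal
    matrix is a weighted graph Laplacian that does not depend on the order,
    so it is Cholesky-factorised once and each candidate order costs only a
    right-hand-side rebuild and a triangular solve.
    """

    def __init__(self, active: list[int], pairs: dict[tuple[int, int], tuple[float, float]]):
        self.active = list(active)
        self.local = {m: i for i, m in enumerate(self.active)}
        u, v, w, d = [], [], [], []
        for (a, b), (wt, dist) in pairs.items():
            if a in self.local and b in self.local:
                u.append(self.local[a])
                v.append(self.local[b])
                w.append(wt)
                d.append(dist)
        self.u = np.asarray(u, dtype=int)
        self.v = np.asarray(v, dtype=int)
        self.w = np.asarray(w, dtype=float)
        self.d = np.asarray(d, dtype=float)
        self.sum_w = float(self.w.sum())
        self.sum_wd2 = float((self.w * self.d**2).sum())
        k = len(self.active)
        lap = np.zeros((k, k))
        np.add.at(lap, (self.u, self.u), self.w)
        np.add.at(lap, (self.v, self.v), self.w)
        np.add.at(lap, (self.u, self.v), -self.w)
        np.add.at(lap, (self.v, self.u), -self.w)
        self._cho = cho_factor(lap[1:, 1:]) if k > 1 else None

    def fit(self, order: list[int]) -> tuple[np.ndarray, float]:
        """Optimal positions (reference marker at 0) and objective for ``order``."""
        k = len(self.active)
        if k == 1:
            return np.zeros(1), 0.0
        rank = np.empty(k, dtype=int)
        for r, m in enumerate(order):
            rank[self.local[m]] = r
        sign = np.where(rank[self.v] > rank[self.u], 1.0, -1.0)
        b = np.zeros(k)
        np.add.at(b, self.v, sign * self.w * self.d)
        np.add.at(b, self.u, -sign * self.w * self.d)
        p = np.zeros(k)
        p[1:] = cho_solve(self._cho, b[1:])
        obj = max(self.sum_wd2 - float(b @ p), 0.0)
        return p, obj

    def norm_obj(self, obj: float) -> float:
        return float(np.sqrt(obj / self.sum_w)) if self.sum_w > 0 else 0.0

    def positions_for(self, order: list[int]) -> np.ndarray:
        """Monotone cM positions along ``order``, starting at 0."""
        p, _ = self.fit(order)
        along = np.array([p[self.local[m]] for m in order])
        along = weighted_isotonic(along)
        return along - along[0]


def _usable_pairs(
    pairs: pd.DataFrame,
    index_of: dict[str, int],
    min_pair_lod: float,
    max_pair_rf: float,
    rf_cap: float = 0.4999,
) -> dict[tuple[int, int], tuple[float, float]]:
    out: dict[tuple[int, int], tuple[float, float]] = {}
    sub = pairs[
        pairs["marker_i"].isin(index_of)
        & pairs["marker_j"].isin(index_of)
        & (pairs["ind_lod"] >= min_pair_lod)
        & (pairs["rf"] <= max_pair_rf)
    ]
    for mi, mj, rf, w in zip(sub["marker_i"], sub["marker_j"], sub["rf"], sub["ind_lod"]):
        a, b = index_of[mi], index_of[mj]
        if a > b:
            a, b = b, a
        out[(a, b)] = (float(w), float(kosambi(min(rf, rf_cap))))
    return out


def _position_fitter(placed, pairs, index_of, min_pair_lod, position_max_rf,
                     max_pair_rf, full_pairs) -> "_PairFit":
    """Short-range pair fit for final positions, relaxing the RF cap until
    the ordered markers form one connected pair graph."""
    import networkx as nx

    cap = position_max_rf
    while cap < max_pair_rf:
        pd_pos = _usable_pairs(pairs, index_of, min_pair_lod, cap)
        g = nx.Graph()
        g.add_nodes_from(placed)
        g.add_edges_from((a, b) for a, b in pd_pos if a in set(placed) and b in set(placed))
        if nx.is_connected(g):
            return _PairFit(placed, pd_pos)
        cap += 0.05
    return _PairFit(placed, full_pairs)


def order_markers_regression(
    markers: list[str],
    codes: np.ndarray,
    pairs: pd.DataFrame,
    *,
    lg_id: str = "LG",
    jump_threshold: float = 5.0,
    min_pair_lod: float = 1.0,
    max_pair_rf: float = 0.35,
    position_max_rf: float = 0.30,
    ripple_window: int = 3,
) -> LinkageGroup:
    """Order one linkage group and fit cM positions.

    Parameters
    ----------
    markers, codes
        Group marker names and their gamete-code rows (int8, -1 missing).
    pairs
        Two-point table from :func:`cpmap.linkage.pairwise_table` (may cover
        a superset of the group).
    jump_threshold
        Maximal tolerated increase of the normalized objective (RMS residual
        in cM) when inserting a marker; worse markers are set aside.
    position_max_rf
        Final cM positions are refitted using only pairs up to this
        recombination fraction: two-point distances beyond ~30 cM are noisy
        and biased by the ``max_pair_rf`` truncation, so they steer the
        order search but not the distance scale.  The cap is relaxed
        automatically when the short-range pair graph does not connect the
        ordered markers.

    Markers without any usable pair (``ind_lod >= min_pair_lod`` and
    ``rf <= max_pair_rf``) to the placed set are reported unplaced.
    """
    k = len(markers)
    if k == 0:
        return LinkageGroup(lg_id, [], np.empty(0))
    if k == 1:
        return LinkageGroup(lg_id, list(markers), np.zeros(1))
    codes = np.asarray(codes, dtype=np.int8)
    index_of = {m: i for i, m in enumerate(markers)}
    pair_d = _usable_pairs(pairs, index_of, min_pair_lod, max_pair_rf)
    neighbors: dict[int, set[int]] = {i: set() for i in range(k)}
    for a, b in pair_d:
        neighbors[a].add(b)
        neighbors[b].add(a)

    n_inf = (codes != CODE_MISSING).sum(axis=1)

    # start from the strongest pair; then always insert the remaining marker
    # most strongly linked to the placed set (informativeness breaks ties) —
    # the growing map stays locally dense and each insertion well determined
    if not pair_d:
        return LinkageGroup(
            lg_id, [min(markers)], np.zeros(1),
            unplaced=sorted((m, "no_linkage") for m in markers if m != min(markers)),
        )
    (a0, b0) = max(pair_d, key=lambda ab: (pair_d[ab][0], -ab[0], -ab[1]))
    placed: list[int] = [a0, b0]
    remaining = [i for i in range(k) if i not in placed]
    unplaced: list[tuple[str, str]] = []

    def link_strength(x: int) -> float:
        best = 0.0
        for p in neighbors[x] & set(placed):
            key = (x, p) if x < p else (p, x)
            best = max(best, pair_d[key][0])
        return best

    norm_prev = 0.0
    from itertools import permutations

    while remaining:
        scored = [(link_strength(x), int(n_inf[x]), markers[x], x) for x in remaining]
        scored = [s for s in scored if s[0] > 0.0]
        if not scored:
            break
        _, _, _, x = max(scored, key=lambda s: (s[0], s[1], [-ord(c) for c in s[2]]))
        remaining.remove(x)
        fitter = _PairFit(placed + [x], pair_d)
        best = None
        for slot in range(len(placed) + 1):
            cand = placed[:slot] + [x] + placed[slot:]
            _, obj = fitter.fit(cand)
            if best is None or obj < best[0] - 1e-12:
                best = (obj, cand)
        obj_new, cand = best
        norm_new = fitter.norm_obj(obj_new)
        if norm_new - norm_prev > jump_threshold:
            unplaced.append((markers[x], "jump"))
            continue
        placed = cand
        obj_cur = obj_new
        # ripple: permute every sliding window, greedy accept improvements
        if len(placed) >= ripple_window:
            for start in range(len(placed) - ripple_window + 1):
                window = placed[start : start + ripple_window]
                for perm in permutations(window):
                    if list(perm) == placed[start : start + ripple_window]:
                        continue
                    cand2 = placed[:start] + list(perm) + placed[start + ripple_window :]
                    _, obj2 = fitter.fit(cand2)
                    if obj2 < obj_cur - 1e-12:
                        placed, obj_cur = cand2, obj2
        norm_prev = fitter.norm_obj(obj_cur)
    for x in remaining:
        unplaced.append((markers[x], "no_linkage"))

    # final polish: alternate ripple and single-marker relocation passes
    # until the objective stops improving (terminal placements are only
    # one-sidedly constrained during greedy insertion)
    fitter = _PairFit(placed, pair_d)
    _, obj_cur = fitter.fit(placed)
    from itertools import permutations

    for _ in range(20):
        improved = False
        if len(placed) >= ripple_window:
            for start in range(len(placed) - ripple_window + 1):
                window = placed[start : start + ripple_window]
                for perm in permutations(window):
                    cand = placed[:start] + list(perm) + placed[start + ripple_window :]
                    _, obj2 = fitter.fit(cand)
                    if obj2 < obj_cur - 1e-12:
                        placed, obj_cur = cand, obj2
                        improved = True
        for idx in range(len(placed)):
            x = placed[idx]
            rest = placed[:idx] + placed[idx + 1 :]
            for slot in range(len(rest) + 1):
                if slot == idx:
                    continue
                cand = rest[:slot] + [x] + rest[slot:]
                _, obj2 = fitter.fit(cand)
                if obj2 < obj_cur - 1e-12:
                    placed, obj_cur = cand, obj2
                    improved = True
        # segment reversals (2-opt): untangle folds the smaller moves miss
        for i in range(len(placed) - 1):
            for j in range(i + 1, len(placed)):
                cand = placed[:i] + placed[i : j + 1][::-1] + placed[j + 1 :]
                _, obj2 = fitter.fit(cand)
                if obj2 < obj_cur - 1e-12:
                    placed, obj_cur = cand, obj2
                    improved = True
        if not improved:
            break

    pos_fitter = _position_fitter(placed, pairs, index_of, min_pair_lod,
                                  position_max_rf, max_pair_rf, pair_d)
    positions = pos_fitter.positions_for(placed)
    names = [markers[i] for i in placed]
    lg = LinkageGroup(lg_id, names, positions, unplaced=sorted(unplaced))
    # orientation convention: smallest marker name in the proximal half
    anchor = min(names)
    if lg.length > 0 and lg.position_of(anchor) > lg.length / 2.0:
        lg = lg.reversed()
        lg.unplaced = sorted(unplaced)
    return lg


# ---------------------------------------------------------------------------
# singleton detection and cleaning


def detect_singletons(
    lg: LinkageGroup, markers: list[str], codes: np.ndarray, individuals: list[str]
) -> SingletonReport:
    """Flag cells whose phase-aligned code differs from both nearest flanks.

    ``codes`` must be phase-aligned (one consistent haplotype labelled "a"
    along the group); rows follow ``markers``.  A cell is a singleton iff its
    code differs from the nearest non-missing code on *each* side along the
    map order — the signature of a genotyping error on a dense map, since a
    real crossover changes phase for all downstream markers.
    """
    row_of = {m: i for i, m in enumerate(markers)}
    order_rows = [row_of[m] for m in lg.markers if m in row_of]
    order_names = [m for m in lg.markers if m in row_of]
    sub = np.asarray(codes, dtype=np.int8)[order_rows]
    cells: list[tuple[str, str]] = []
    for j, ind in enumerate(individuals):
        col = sub[:, j]
        nz = np.flatnonzero(col != CODE_MISSING)
        if nz.size < 3:
            continue
        vals = col[nz]
        mid = vals[1:-1]
        bad = (mid != vals[:-2]) & (mid != vals[2:])
        for t in np.flatnonzero(bad):
            cells.append((order_names[nz[t + 1]], ind))
    return SingletonReport(cells=cells, per_lg={lg.lg_id: len(cells)})


def clean_and_remap(
    markers: list[str],
    codes: np.ndarray,
    individuals: list[str],
    lg: LinkageGroup,
    report: SingletonReport,
    **order_kwargs,
) -> tuple[np.ndarray, LinkageGroup]:
    """Blank singleton cells and recompute the group order and positions.

    One cleaning round only: flagged cells become missing, markers left with
    no data are dropped with a warning, and the ordering is rerun on the
    cleaned codes.
    """
    from .linkage import pairwise_table

    codes = np.asarray(codes, dtype=np.int8).copy()
    row_of = {m: i for i, m in enumerate(markers)}
    col_of = {ind: j for j, ind in enumerate(individuals)}
    for m, ind in report.cells:
        codes[row_of[m], col_of[ind]] = CODE_MISSING
    keep = (codes != CODE_MISSING).any(axis=1)
    if not keep.all():
        dropped = [m for m, k in zip(markers, keep) if not k]
        warnings.warn(f"markers with no remaining data dropped after cleaning: {dropped}")
    kept_markers = [m for m, k in zip(markers, keep) if k]
    kept_codes = codes[keep]
    pairs = pairwise_table(kept_codes, kept_markers)
    order_kwargs.setdefault("lg_id", lg.lg_id)
    new_lg = order_markers_regression(kept_markers, kept_codes, pairs, **order_kwargs)
    return codes, new_lg


def summarize_map(
    gmap: GeneticMap, distortion_p: dict[str, float] | pd.Series | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-LG table of marker count (M), distorted count (D), size, and gap census.

    Gaps are inter-marker intervals in (5, 10] cM and > 10 cM.  ``distortion_p``
    maps marker -> segregation-test p-value; markers absent from it count as
    undistorted.
    """
    if distortion_p is None:
        distortion_p = {}
    if isinstance(distortion_p, pd.Series):
        distortion_p = distortion_p.to_dict()
    rows = []
    for lg in gmap.linkage_groups:
        gaps = np.diff(lg.positions) if lg.n_markers > 1 else np.empty(0)
        rows.append(
            {
                "lg": lg.lg_id,
                "n_markers": lg.n_markers,
                "n_distorted": sum(
                    1 for m in lg.markers if distortion_p.get(m, 1.0) < alpha
                ),
                "size_cM": round(lg.length, 2),
                "gaps_5_10": int(np.count_nonzero((gaps > 5.0) & (gaps <= 10.0))),
                "gaps_gt_10": int(np.count_nonzero(gaps > 10.0)),
            }
        )
    out = pd.DataFrame(rows)
    total = {
        "lg": "total",
        "n_markers": int(out["n_markers"].sum()) if len(out) else 0,
        "n_distorted": int(out["n_distorted"].sum()) if len(out) else 0,
        "size_cM": round(float(out["size_cM"].sum()), 2) if len(out) else 0.0,
        "gaps_5_10": int(out["gaps_5_10"].sum()) if len(out) else 0,
        "gaps_gt_10": int(out["gaps_gt_10"].sum()) if len(out) else 0,
    }
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)
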