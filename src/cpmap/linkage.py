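"""Two-point linkage statistics for pseudo-testcross gamete data.

Each parent of an outbred F1 cross is mapped from its own gamete codes
(``a``/``b`` per informative marker and progeny).  For a marker pair the
recombination fraction is estimated from the discordance count over jointly
scored progeny; linkage is scored with a testcross LOD, while marker
*grouping* uses the likelihood-ratio test of independence of the 2x2 joint
code table (the "independence LOD"), which is robust to segregation
distortion because it conditions on the observed marginal counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import xlogy

from ._util import CODE_MISSING

LN10 = np.log(10.0)

__all__ = [
    "PairwiseLinkage",
    "MarkerGroupSet",
    "estimate_rf",
    "independence_lod",
    "pairwise_table",
    "group_markers",
    "group_stability_scan",
]


@dataclass(frozen=True)
class PairwiseLinkage:
    """Two-point summary for one ordered marker pair."""

    marker_i: str
    marker_j: str
    rf: float
    lod: float
    ind_lod: float
    phase: str | None  # "coupling" | "repulsion"; None when undefined
    n_informative: int


@dataclass
class MarkerGroupSet:
    """Partition of markers into linkage groups at one LOD threshold."""

    threshold: float
    groups: list[list[str]]
    ungrouped: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _joint(col_i: np.ndarray, col_j: np.ndarray):
    col_i = np.asarray(col_i, dtype=np.int8)
    col_j = np.asarray(col_j, dtype=np.int8)
    mask = (col_i != CODE_MISSING) & (col_j != CODE_MISSING)
    return col_i[mask], col_j[mask]


def estimate_rf(col_i, col_j, marker_i: str = "i", marker_j: str = "j") -> PairwiseLinkage | None:
    """Estimate the recombination fraction for one pair of gamete-code columns.

    Over the jointly non-missing progeny, with ``m`` discordant codes out of
    ``n``, the maximum-likelihood testcross estimate is ``min(m, n-m)/n``
    (the complementary count is used when the pair is in repulsion, i.e. the
    arbitrary a/b labels of the two markers belong to opposite haplotypes).
    The LOD is the log10 likelihood ratio of linkage at ``rf`` versus free
    recombination (r = 1/2).

    Returns ``None`` when fewer than two jointly scored progeny exist (the
    pair is then excluded from grouping).
    """
    a, b = _joint(col_i, col_j)
    n = a.size
    if n < 2:
        return None
    m = int(np.count_nonzero(a != b))
    mp = min(m, n - m)
    rf = mp / n
    phase = "coupling" if m <= n - m else "repulsion"
    if mp == 0:
        lod = n * np.log10(2.0)
    else:
        lod = mp * np.log10(2.0 * rf) + (n - mp) * np.log10(2.0 * (1.0 - rf))
    return PairwiseLinkage(
        marker_i=marker_i,
        marker_j=marker_j,
        rf=float(rf),
        lod=float(max(lod, 0.0)),
        ind_lod=float(independence_lod(col_i, col_j)),
        phase=phase,
        n_informative=n,
    )


def _g2_from_counts(n11, n12, n21, n22):
    """Likelihood-ratio G^2 of independence for 2x2 counts (vectorised)."""
    n11 = np.asarray(n11, dtype=float)
    obs = np.stack([n11, np.asarray(n12, float), np.asarray(n21, float), np.asarray(n22, float)])
    n = obs.sum(axis=0)
    r1 = obs[0] + obs[1]
    r2 = obs[2] + obs[3]
    c1 = obs[0] + obs[2]
    c2 = obs[1] + obs[3]
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack([r1 * c1, r1 * c2, r2 * c1, r2 * c2]) / np.where(n > 0, n, 1.0)
        terms = 2.0 * (xlogy(obs, obs) - xlogy(obs, np.where(exp > 0, exp, 1.0)))
    g2 = terms.sum(axis=0)
    # degenerate margins (monomorphic column) contribute nothing
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    return np.where(degenerate, 0.0, np.maximum(g2, 0.0))


def independence_lod(col_i, col_j) -> float:
    """Independence LOD = G^2 / (2 ln 10) for the joint a/b x a/b table."""
    a, b = _joint(col_i, col_j)
    if a.size == 0:
        return 0.0
    n11 = np.count_nonzero((a == 0) & (b == 0))
    n12 = np.count_nonzero((a == 0) & (b == 1))
    n21 = np.count_nonzero((a == 1) & (b == 0))
    n22 = np.count_nonzero((a == 1) & (b == 1))
    g2 = _g2_from_counts(n11, n12, n21, n22)
    return float(g2 / (2.0 * LN10))


def pairwise_table(codes: np.ndarray, markers: list[str]) -> pd.DataFrame:
    """All-pairs two-point statistics, vectorised with matrix products.

    Parameters
    ----------
    codes
        int8 array, markers x progeny, values {0, 1, -1(missing)}.
    markers
        Marker names, one per row of ``codes``.

    Returns a DataFrame with one row per unordered pair (i < j by row
    index) and columns ``marker_i, marker_j, rf, lod, ind_lod, phase, n``.
    Pairs with fewer than two joint observations are omitted.
    """
    codes = np.asarray(codes, dtype=np.int8)
    k = codes.shape[0]
    A = (codes == 0).astype(np.float64)
    B = (codes == 1).astype(np.float64)
    n11 = A @ A.T
    n12 = A @ B.T
    n21 = B @ A.T
    n22 = B @ B.T
    n = n11 + n12 + n21 + n22
    m = n12 + n21  # discordant
    iu, ju = np.triu_indices(k, 1)
    nn = n[iu, ju]
    keep = nn >= 2
    iu, ju, nn = iu[keep], ju[keep], nn[keep]
    mm = m[iu, ju]
    mp = np.minimum(mm, nn - mm)
    rf = mp / nn
    with np.errstate(divide="ignore"):
        lod = np.where(
            mp == 0,
            nn * np.log10(2.0),
            mp * np.log10(np.maximum(2.0 * rf, 1e-300))
            + (nn - mp) * np.log10(2.0 * (1.0 - rf)),
        )
    g2 = _g2_from_counts(n11[iu, ju], n12[iu, ju], n21[iu, ju], n22[iu, ju])
    ind = g2 / (2.0 * LN10)
    names = np.asarray(markers)
    return pd.DataFrame(
        {
            "marker_i": names[iu],
            "marker_j": names[ju],
            "rf": rf,
            "lod": np.maximum(lod, 0.0),
            "ind_lod": ind,
            "phase": np.where(mm <= nn - mm, "coupling", "repulsion"),
            "n": nn.astype(int),
        }
    )


def group_markers(pairs: pd.DataFrame, markers: list[str], threshold: float = 4.0,
                  bridge_guard: bool = True) -> MarkerGroupSet:
    """Partition markers into connected components of the ind-LOD graph.

    Edges are pairs with ``ind_lod >= threshold``; single-marker components
    are reported as ungrouped.  With ``bridge_guard`` (default), one lone
    supra-threshold pair is never allowed to fuse two multi-marker groups:
    genuinely linked regions always produce several significant pairs,
    whereas with tens of thousands of inter-group tests a single spurious
    edge at the threshold is expected by chance.  The result is
    deterministic and invariant to the input marker order (groups sorted by
    size then by smallest name).
    """
    g = nx.Graph()
    g.add_nodes_from(markers)
    sel = pairs[pairs["ind_lod"] >= threshold]
    g.add_edges_from(zip(sel["marker_i"], sel["marker_j"]))
    if bridge_guard:
        # credibility test for a junction held together by one edge or one
        # marker: a genuine junction (e.g. across a marker desert) includes
        # at least one reasonably close pair (rf <= 0.30, a ~5-sigma event
        # for unlinked loci at n ~ 150), whereas chance associations between
        # chromosomes — which replicate over whole correlated marker blocks
        # and so cannot be filtered by counting edges — sit near the
        # detection limit with rf ~ 1/3
        support = pairs[(pairs["ind_lod"] >= 0.75 * threshold)
                        & (pairs["rf"] <= 0.30)]
        sup_i = support["marker_i"].to_numpy()
        sup_j = support["marker_j"].to_numpy()

        def corroborated(side_a: set, side_b: set, skip_pairs=(), skip_nodes=()) -> bool:
            for x, y in zip(sup_i, sup_j):
                if (x, y) in skip_pairs or (y, x) in skip_pairs:
                    continue
                if x in skip_nodes or y in skip_nodes:
                    continue
                if (x in side_a and y in side_b) or (x in side_b and y in side_a):
                    return True
            return False

        for _ in range(5):
            changed = False
            # a lone uncorroborated edge never fuses two multi-marker groups
            for u, v in sorted(nx.bridges(g)):
                if not g.has_edge(u, v):
                    continue
                g.remove_edge(u, v)
                cu = nx.node_connected_component(g, u)
                cv = nx.node_connected_component(g, v)
                if len(cu) < 3 or len(cv) < 3 or corroborated(cu, cv):
                    g.add_edge(u, v)
                else:
                    changed = True
            # nor does a lone marker: an uncorroborated cut vertex joining
            # multi-marker parts stays with the part it is most connected to
            for a in sorted(nx.articulation_points(g)):
                nbrs = sorted(g.neighbors(a))
                h = g.copy()
                h.remove_node(a)
                parts: list[set] = []
                seen: set = set()
                for nb in nbrs:
                    if nb in seen:
                        continue
                    comp = nx.node_connected_component(h, nb)
                    seen |= comp
                    parts.append(comp)
                big = [p for p in parts if len(p) >= 3]
                if len(big) < 2:
                    continue
                home = max(big, key=lambda p: (sum(1 for nb in nbrs if nb in p),
                                               len(p), -ord(min(p)[0])))
                for p in big:
                    if p is home or corroborated(home | {a}, p):
                        continue
                    for nb in nbrs:
                        if nb in p and g.has_edge(a, nb):
                            g.remove_edge(a, nb)
                            changed = True
            if not changed:
                break
    groups, ungrouped = [], []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) == 1:
            ungrouped.append(members[0])
        else:
            groups.append(members)
    groups.sort(key=lambda ms: (-len(ms), ms[0]))
    return MarkerGroupSet(threshold=float(threshold), groups=groups, ungrouped=sorted(ungrouped))


def group_stability_scan(
    pairs: pd.DataFrame, markers: list[str], thresholds=range(4, 11)
) -> pd.DataFrame:
    """Rerun grouping over a LOD ladder and report when each base group splits.

    The base partition is taken at the lowest threshold.  For each base group
    the report gives the first threshold at which its markers no longer fall
    in a single group (NaN if intact through the ladder).
    """
    thresholds = sorted(thresholds)
    if not markers:
        return pd.DataFrame(columns=["group", "n_markers", "first_split_lod"])
    base = group_markers(pairs, markers, thresholds[0])
    rows = []
    for gi, members in enumerate(base.groups):
        member_set = set(members)
        split_at = np.nan
        for t in thresholds[1:]:
            part = group_markers(pairs, members, t)
            intact = any(set(g) == member_set for g in part.groups)
            if not intact:
                split_at = t
                break
        rows.append({"group": gi, "n_markers": len(members), "first_split_lod": split_at})
    return pd.DataFrame(rows)
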