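"""Kosambi mapping function, regression ordering, singletons and summaries."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpmap._util import CODE_MISSING
from cpmap.linkage import pairwise_table
from cpmap.ordering import (
    GeneticMap,
    LinkageGroup,
    SingletonReport,
    clean_and_remap,
    detect_singletons,
    kosambi,
    kosambi_inverse,
    order_markers_regression,
    summarize_map,
)
from cpmap.segcoding import code_markers, derive_gamete_matrix

from conftest import simulate_testcross


class TestKosambi:
    def test_zero(self):
        assert kosambi(0.0) == 0.0

    def test_quarter(self):
        assert kosambi(0.25) == pytest.approx(25 * np.log(3), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=0.01, max_value=0.49))
    def test_mutual_inverses(self, r):
        assert kosambi_inverse(kosambi(r)) == pytest.approx(r, abs=1e-12)


def _codes_for_rfs(rfs, n=200, seed=0):
    """Deterministic gamete codes realising exact adjacent discordances."""
    rng = np.random.default_rng(seed)
    cols = [rng.integers(0, 2, n).astype(np.int8)]
    for r in rfs:
        k = int(round(r * n))
        flip = np.zeros(n, bool)
        flip[rng.choice(n, k, replace=False)] = True
        nxt = cols[-1].copy()
        nxt[flip] = 1 - nxt[flip]
        cols.append(nxt)
    return np.array(cols)


def exhaustive_best_order(markers, codes, pairs, **kwargs):
    """Oracle: evaluate the ordering objective for every permutation."""
    from cpmap.ordering import _PairFit, _usable_pairs

    idx = {m: i for i, m in enumerate(markers)}
    pd_ = _usable_pairs(pairs, idx, kwargs.get("min_pair_lod", 1.0),
                        kwargs.get("max_pair_rf", 0.35))
    fitter = _PairFit(list(range(len(markers))), pd_)
    best = None
    for perm in permutations(range(len(markers))):
        if perm[0] > perm[-1]:
            continue  # skip reflections
        _, obj = fitter.fit(list(perm))
        if best is None or obj < best[0] - 1e-12:
            best = (obj, list(perm))
    return [markers[i] for i in best[1]]


class TestOrdering:
    def test_three_markers_match_exhaustive_search(self):
        codes = _codes_for_rfs([0.10, 0.10], n=200)
        markers = ["a", "b", "c"]
        pairs = pairwise_table(codes, markers)
        lg = order_markers_regression(markers, codes, pairs, lg_id="t")
        oracle = exhaustive_best_order(markers, codes, pairs)
        assert lg.markers in (oracle, oracle[::-1])
        # positions close to the chained Kosambi distances
        d1 = kosambi(pairs.set_index(["marker_i", "marker_j"]).loc[("a", "b"), "rf"])
        assert lg.positions[1] == pytest.approx(d1, abs=2.0)

    def test_five_markers_match_exhaustive_search(self):
        codes = _codes_for_rfs([0.08, 0.12, 0.10, 0.09], n=300, seed=5)
        markers = list("abcde")
        pairs = pairwise_table(codes, markers)
        lg = order_markers_regression(markers, codes, pairs, lg_id="t")
        oracle = exhaustive_best_order(markers, codes, pairs)
        assert lg.markers in (oracle, oracle[::-1])

    def test_two_markers_length_is_kosambi_of_rf(self):
        codes = _codes_for_rfs([0.10], n=200)
        markers = ["a", "b"]
        pairs = pairwise_table(codes, markers)
        lg = order_markers_regression(markers, codes, pairs, lg_id="t")
        rf = pairs["rf"].iloc[0]
        assert lg.length == pytest.approx(kosambi(rf), abs=1e-9)

    def test_single_marker_group(self):
        lg = order_markers_regression(["a"], np.zeros((1, 10), np.int8),
                                      pd.DataFrame(columns=["marker_i", "marker_j",
                                                            "rf", "ind_lod"]))
        assert lg.markers == ["a"] and lg.length == 0.0

    def test_length_invariant_under_code_relabel(self):
        codes = _codes_for_rfs([0.1, 0.15, 0.08], n=250, seed=2)
        markers = list("abcd")
        pairs = pairwise_table(codes, markers)
        lg1 = order_markers_regression(markers, codes, pairs, lg_id="t")
        flipped = codes.copy()
        flipped[1] = 1 - flipped[1]  # relabel a<->b for one marker
        pairs2 = pairwise_table(flipped, markers)
        lg2 = order_markers_regression(markers, flipped, pairs2, lg_id="t")
        assert lg1.length == pytest.approx(lg2.length, abs=1e-9)

    def test_positions_monotone_and_start_at_zero(self):
        tm, gm, truth = simulate_testcross(21, n=150, markers_per_lg=15,
                                           lg_sizes=[120.0])
        gam = derive_gamete_matrix(gm, code_markers(gm), 1)
        pairs = pairwise_table(gam.codes, gam.markers)
        lg = order_markers_regression(gam.markers, gam.codes, pairs, lg_id="LG1")
        assert lg.positions[0] == 0.0
        assert np.all(np.diff(lg.positions) >= 0)

    def test_error_free_order_recovery(self):
        tm, gm, truth = simulate_testcross(22, n=150, markers_per_lg=15,
                                           lg_sizes=[110.0, 95.0])
        gam = derive_gamete_matrix(gm, code_markers(gm), 1)
        pairs = pairwise_table(gam.codes, gam.markers)
        for tlg in tm.lgs:
            members = [m for m in gam.markers if m in tlg.markers]
            rows = [gam.markers.index(m) for m in members]
            lg = order_markers_regression(members, gam.codes[rows], pairs,
                                          lg_id=tlg.lg_id)
            want = [m for m in tlg.markers if m in lg.markers]
            assert lg.markers in (want, want[::-1])


class TestSingletons:
    def _lg(self, k):
        return LinkageGroup("LG1", [f"m{i}" for i in range(k)],
                            np.arange(k, dtype=float) * 5.0)

    def _report(self, pattern):
        codes = np.array([pattern], dtype=np.int8).T  # one individual
        markers = [f"m{i}" for i in range(len(pattern))]
        return detect_singletons(self._lg(len(pattern)), markers, codes, ["i1"])

    def test_isolated_discordance_flagged(self):
        rep = self._report([0, 0, 1, 0, 0])
        assert rep.cells == [("m2", "i1")]

    def test_true_crossover_not_flagged(self):
        rep = self._report([0, 0, 1, 1, 1])
        assert rep.cells == []

    def test_nearest_nonmissing_flank_rule(self):
        rep = self._report([0, CODE_MISSING, 1, 0])
        assert rep.cells == [("m2", "i1")]

    def test_terminal_cells_never_flagged(self):
        rep = self._report([1, 0, 0, 0, 1])
        assert rep.cells == []

    def test_clean_idempotent_without_singletons(self):
        codes = _codes_for_rfs([0.1, 0.1, 0.1], n=150, seed=9)
        markers = list("abcd")
        pairs = pairwise_table(codes, markers)
        lg = order_markers_regression(markers, codes, pairs, lg_id="t")
        rep = SingletonReport([], {})
        cleaned, lg2 = clean_and_remap(markers, codes, [f"i{j}" for j in range(150)],
                                       lg, rep)
        assert (cleaned == codes).all()
        assert lg2.markers == lg.markers
        assert np.allclose(lg2.positions, lg.positions)

    def test_all_missing_marker_dropped_with_warning(self):
        codes = _codes_for_rfs([0.1, 0.1], n=100, seed=4)
        markers = list("abc")
        pairs = pairwise_table(codes, markers)
        lg = order_markers_regression(markers, codes, pairs, lg_id="t")
        rep = SingletonReport([("b", f"i{j}") for j in range(100)], {})
        with pytest.warns(UserWarning, match="dropped"):
            _, lg2 = clean_and_remap(markers, codes, [f"i{j}" for j in range(100)],
                                     lg, rep)
        assert "b" not in lg2.markers


class TestSummarize:
    def test_uniform_spacing_has_no_gaps(self):
        lg = LinkageGroup("LG1", [f"m{i}" for i in range(21)],
                          np.arange(21, dtype=float))
        out = summarize_map(GeneticMap("p", [lg]))
        assert out.loc[0, "gaps_5_10"] == 0 and out.loc[0, "gaps_gt_10"] == 0
        assert out.loc[0, "n_markers"] == 21

    def test_gap_census_classes(self):
        lg = LinkageGroup("LG1", list("abcd"), np.array([0.0, 7.0, 14.0, 30.0]))
        out = summarize_map(GeneticMap("p", [lg]))
        assert out.loc[0, "gaps_5_10"] == 2
        assert out.loc[0, "gaps_gt_10"] == 1

    def test_distorted_count_matches_pvalues(self):
        lg = LinkageGroup("LG1", list("abc"), np.array([0.0, 5.0, 10.0]))
        out = summarize_map(GeneticMap("p", [lg]),
                            {"a": 0.01, "b": 0.2, "c": 0.04})
        assert out.loc[0, "n_distorted"] == 2
        assert out.iloc[-1]["n_distorted"] == 2  # totals row
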