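"""Meiosis simulator: crossover process, selection, genotyping, study dataset."""

import numpy as np
import pandas as pd
import pytest

from cpmap.ordering import kosambi_inverse
from cpmap.segcoding import MISSING_CALL
from cpmap.simdata import (
    ConfigurationError,
    GameteBatch,
    SelectedLocus,
    SelectionModel,
    SimConfig,
    TrueLG,
    TrueMap,
    apply_gametic_selection,
    gamete_with_layout,
    genotype_progeny,
    make_study_like_dataset,
    simulate_crossovers,
    simulate_gamete,
    simulate_gametes,
    simulate_progeny,
)

from conftest import make_testcross_map


class TestCrossoverProcess:
    def test_zero_length_lg_never_recombines(self):
        xs = simulate_crossovers(0.0, 50, model="gamma", rng=1)
        assert all(len(x) == 0 for x in xs)
        alleles, xov, org = simulate_gamete(["A"], ["B"], [0.0], 0.0, rng=1)
        assert len(xov) == 0 and len(set(org)) == 1

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_crossovers(100.0, 1, model="chi-square", rng=0)
        with pytest.raises(ConfigurationError):
            SimConfig(interference_model="bogus")

    def test_poisson_mean_crossovers(self):
        rng = np.random.default_rng(2)
        xs = simulate_crossovers(100.0, 30000, model="poisson", rng=rng)
        counts = np.array([len(v) for v in xs])
        se = 1.0 / np.sqrt(len(counts))  # Poisson(1) sd = 1
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_gamma_rf_matches_inverse_kosambi(self):
        # two loci 10 cM apart: recombinant fraction ~ 0.5 tanh(0.2)
        rng = np.random.default_rng(3)
        n = 60000
        xs = simulate_crossovers(12.0, n, model="gamma", nu=2.63, rng=rng)
        rec = np.fromiter(
            ((np.searchsorted(v, 11.0) - np.searchsorted(v, 1.0)) % 2 for v in xs),
            dtype=int, count=n)
        target = kosambi_inverse(10.0)
        se = np.sqrt(target * (1 - target) / n)
        assert abs(rec.mean() - target) < 3 * se

    def test_crossover_density_one_per_morgan(self):
        rng = np.random.default_rng(4)
        xs = simulate_crossovers(150.0, 20000, model="gamma", rng=rng)
        mean = np.mean([len(v) for v in xs])
        assert mean == pytest.approx(1.5, abs=3 * np.sqrt(1.5 / 20000) * 2)


class TestGameticSelection:
    def _one_locus_map(self):
        return TrueMap(
            [TrueLG("LG1", ["m1", "m2"], np.array([0.0, 10.0]))],
            pd.DataFrame(
                {"lg": ["LG1"] * 2, "pos": [0.0, 10.0], "marker_class": ["snp"] * 2,
                 "p1_h1": ["A", "A"], "p1_h2": ["B", "B"],
                 "p2_h1": ["A", "A"], "p2_h2": ["A", "A"]},
                index=["m1", "m2"]),
        )

    def test_no_selection_keeps_half_frequency(self):
        tm = self._one_locus_map()
        rng = np.random.default_rng(5)
        batch = simulate_gametes(tm, 40000, rng=rng)
        sel = SelectionModel([SelectedLocus("LG1", 0.0, "female", 0, 0.0)])
        mask = apply_gametic_selection(batch, sel, "female", rng)
        freq = (batch.origins["LG1"][mask, 0] == 0).mean()
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / mask.sum())

    def test_selected_frequency_converges_to_closed_form(self):
        # retention 1 vs 1-s  =>  favored frequency 1/(2-s) = 0.625 at s = 0.4
        tm = self._one_locus_map()
        rng = np.random.default_rng(6)
        batch = simulate_gametes(tm, 60000, rng=rng)
        sel = SelectionModel([SelectedLocus("LG1", 0.0, "female", 0, 0.4)])
        mask = apply_gametic_selection(batch, sel, "female", rng)
        freq = (batch.origins["LG1"][mask, 0] == 0).mean()
        expected = 1.0 / 1.6
        assert abs(freq - expected) < 3 * np.sqrt(expected * (1 - expected) / mask.sum())

    def test_linked_marker_frequency_two_point_algebra(self):
        # marker at true rf r from the selected locus:
        # favored-origin freq = q(1-r) + (1-q) r with q = 1/(2-s)
        tm = self._one_locus_map()
        rng = np.random.default_rng(7)
        batch = simulate_gametes(tm, 60000, rng=rng)
        sel = SelectionModel([SelectedLocus("LG1", 0.0, "female", 0, 0.4)])
        mask = apply_gametic_selection(batch, sel, "female", rng)
        q = 1.0 / 1.6
        r = kosambi_inverse(10.0)
        expected = q * (1 - r) + (1 - q) * r
        freq = (batch.origins["LG1"][mask, 1] == 0).mean()
        assert abs(freq - expected) < 3 * np.sqrt(expected * (1 - expected) / mask.sum())

    def test_exhausted_pool_raises(self):
        from cpmap.simdata import SimulationError, sample_parent_gametes

        tm = self._one_locus_map()
        # contradictory full-strength selection: no gamete can satisfy both
        sel = SelectionModel([SelectedLocus("LG1", 0.0, "female", 0, 1.0),
                              SelectedLocus("LG1", 0.0, "female", 1, 1.0)])
        with pytest.raises(SimulationError, match="exhausts"):
            sample_parent_gametes(tm, 200, "female", sel, SimConfig(),
                                  np.random.default_rng(0), max_rounds=3)


class TestGenotyping:
    def test_null_allele_reporting(self):
        tm = TrueMap(
            [TrueLG("LG1", ["m1", "m2"], np.array([0.0, 5.0]))],
            pd.DataFrame(
                {"lg": ["LG1"] * 2, "pos": [0.0, 5.0], "marker_class": ["snp"] * 2,
                 "p1_h1": ["A", "0"], "p1_h2": ["A", "0"],
                 "p2_h1": ["0", "0"], "p2_h2": ["0", "0"]},
                index=["m1", "m2"]),
        )
        fem = np.array([["A", "A"], ["0", "0"]])
        mal = np.array([["0", "0"], ["0", "0"]])
        gm = genotype_progeny(fem, mal, tm)
        assert (gm.calls.loc["m1"] == "AA").all()      # A/0 reported homozygous
        assert (gm.calls.loc["m2"] == MISSING_CALL).all()  # 0/0 does not amplify

    def test_deterministic_at_zero_rates(self):
        tm = make_testcross_map(np.random.default_rng(0), 5, [40.0])
        fem = np.array([["A", "B"]] * 5)
        mal = np.array([["A", "A"]] * 5)
        g1 = genotype_progeny(fem, mal, tm, rng=np.random.default_rng(1))
        g2 = genotype_progeny(fem, mal, tm, rng=np.random.default_rng(99))
        assert g1.calls.equals(g2.calls)

    def test_missing_rate_applied(self):
        tm = make_testcross_map(np.random.default_rng(0), 10, [50.0])
        rng = np.random.default_rng(8)
        gm, truth = simulate_progeny(tm, None, SimConfig(n_progeny=200,
                                                         missing_rate=0.2), rng)
        frac = (gm.calls == MISSING_CALL).to_numpy().mean()
        assert 0.15 < frac < 0.25


class TestLayouts:
    def test_prescribed_crossover_counts(self):
        tm = make_testcross_map(np.random.default_rng(1), 10)
        layout = {"LG1": 1, "LG3": 2, "LG4": 2, "LG5": 2, "LG7": 1, "LG9": 1}
        g = gamete_with_layout(tm, layout, rng=np.random.default_rng(2))
        counts = {lg: len(g.crossovers[lg][0]) for lg in g.lg_ids}
        for lg in g.lg_ids:
            assert counts[lg] == layout.get(lg, 0)
        assert g.crossover_count() == 9

    def test_layout_margins_and_separation(self):
        tm = make_testcross_map(np.random.default_rng(1), 10)
        g = gamete_with_layout(tm, {"LG3": 2}, rng=np.random.default_rng(3))
        pts = g.crossovers["LG3"][0]
        L = tm.lg("LG3").length
        assert pts.min() >= 10.0 and pts.max() <= L - 10.0
        assert np.diff(pts).min() >= 20.0


@pytest.fixture(scope="module")
def study_ds():
    return make_study_like_dataset(5, scale=0.1)


class TestStudyDataset:
    @pytest.fixture()
    def ds(self, study_ds):
        return study_ds

    def test_progeny_sizes(self, ds):
        assert [b.genotypes.calls.shape[1] for b in ds.bundles] == [156, 140, 147]

    def test_nine_linkage_groups(self, ds):
        assert len(ds.truemap.lgs) == 9

    def test_donor_gamete_has_nine_crossovers(self, ds):
        assert ds.donor_crossover_count == 9
        assert {k: len(v) for k, v in ds.donor_crossovers.items()} == {
            "LG1": 1, "LG2": 0, "LG3": 2, "LG4": 2, "LG5": 2, "LG6": 0,
            "LG7": 1, "LG8": 0, "LG9": 1}

    def test_haploid_gamete_has_eight_crossovers(self, ds):
        assert ds.haploid_crossover_count == 8

    def test_same_seed_reproduces_byte_identical(self, ds):
        ds2 = make_study_like_dataset(5, scale=0.1)
        for b1, b2 in zip(ds.bundles, ds2.bundles):
            assert b1.genotypes.calls.equals(b2.genotypes.calls)
        assert ds.haploid_calls.equals(ds2.haploid_calls)

    def test_central_parent_shared_across_crosses(self, ds):
        # the central parent is male in cross 1 and female in cross 2: its
        # true genotypes must agree marker by marker
        b1, b2 = ds.bundle("CPxNC"), ds.bundle("NCxPP")
        for m in ds.truemap.markers[:50]:
            assert (b1.truth.truemap.parent_genotype(2, m)
                    == b2.truth.truemap.parent_genotype(1, m))

    def test_testcross_majority_matches_design(self, ds):
        from cpmap.segcoding import census_segregation_types, code_markers

        cen1 = census_segregation_types(code_markers(ds.bundle("CPxNC").genotypes))
        cen2 = census_segregation_types(code_markers(ds.bundle("NCxPP").genotypes))
        # central parent heterozygous: nnxnp dominates when it is male,
        # lmxll when it is female
        assert cen1.seg_counts["nnxnp"] > cen1.seg_counts["lmxll"]
        assert cen2.seg_counts["lmxll"] > cen2.seg_counts["nnxnp"]
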