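"""Cross-validation harness: fold construction, masking, the Pearson-R
accuracy statistic against a textbook oracle, summaries and profiles."""

import numpy as np
import pandas as pd
import pytest

import ldpanel as lp
from ldpanel.core import MISSING, GenotypeMatrix
from ldpanel.evaluation import MaskingScheme
from ldpanel.panels import PanelDefinition
from conftest import make_map, make_matrix, pearson_oracle


class TestMaskingScheme:
    def test_partition_of_272_into_10_folds(self):
        ids = [f"i{k}" for k in range(272)]
        schemes = lp.make_masking_scheme(ids, 10, 0.1, seed=4)
        sizes = sorted(len(s.validation) for s in schemes)
        assert set(sizes) == {27, 28}
        all_val = [i for s in schemes for i in s.validation]
        assert sorted(all_val) == sorted(ids)       # partition: disjoint + cover

    def test_one_individual_per_fold(self):
        schemes = lp.make_masking_scheme([f"i{k}" for k in range(10)], 10, 0.1, 0)
        assert all(len(s.validation) == 1 for s in schemes)

    def test_deterministic_and_seed_sensitive(self):
        ids = [f"i{k}" for k in range(40)]
        a = lp.make_masking_scheme(ids, 4, 0.25, seed=7)
        b = lp.make_masking_scheme(ids, 4, 0.25, seed=7)
        c = lp.make_masking_scheme(ids, 4, 0.25, seed=8)
        assert [s.validation for s in a] == [s.validation for s in b]
        assert [s.validation for s in a] != [s.validation for s in c]

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            lp.make_masking_scheme(["a", "b"], 5, 0.2, 0)

    def test_inconsistent_fraction_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            lp.make_masking_scheme([f"i{k}" for k in range(40)], 10, 0.5, 0)


class TestMaskGenotypes:
    def _small(self):
        rng = np.random.default_rng(5)
        return make_matrix(rng.integers(0, 3, size=(6, 10)).astype(np.int8))

    def test_full_panel_is_identity(self):
        g = self._small()
        scheme = MaskingScheme(1, ["i0", "i1"], list(g.markers))
        assert lp.mask_genotypes(g, scheme).equals(g)

    def test_empty_panel_blanks_validation_rows(self):
        g = self._small()
        scheme = MaskingScheme(1, ["i2"], [])
        out = lp.mask_genotypes(g, scheme)
        assert np.all(out.dosages[2] == MISSING)
        assert np.array_equal(np.delete(out.dosages, 2, axis=0),
                              np.delete(g.dosages, 2, axis=0))

    def test_masked_entry_count(self):
        g = self._small()
        panel = list(g.markers[:3])
        scheme = MaskingScheme(1, ["i0", "i4"], panel)
        out = lp.mask_genotypes(g, scheme)
        for row in (0, 4):
            assert (out.dosages[row] == MISSING).sum() >= g.n_markers - 3
        assert not g.equals(out)  # original untouched, copy modified


class TestAccuracyStatistic:
    def test_perfect_and_anticorrelated(self):
        truth = make_matrix([[0, 2], [1, 1], [2, 0], [0, 1]])
        r = lp.accuracy_per_snp(truth.dosages.astype(float), truth, list(truth.markers))
        assert np.allclose(r, 1.0)
        r_neg = lp.accuracy_per_snp(2.0 - truth.dosages, truth, list(truth.markers))
        assert np.allclose(r_neg, -1.0)

    def test_matches_textbook_pearson_on_random_pairs(self):
        rng = np.random.default_rng(12)
        truth_d = rng.integers(0, 3, size=(60, 50)).astype(np.int8)
        imputed = rng.random((60, 50)) * 2
        truth = make_matrix(truth_d)
        r = lp.accuracy_per_snp(imputed, truth, list(truth.markers))
        for j in range(50):
            assert r.iloc[j] == pytest.approx(
                pearson_oracle(imputed[:, j], truth_d[:, j]), abs=1e-12)
        r_ind = lp.accuracy_per_individual(imputed, truth, list(truth.markers))
        for i in range(60):
            assert r_ind.iloc[i] == pytest.approx(
                pearson_oracle(imputed[i], truth_d[i]), abs=1e-12)

    def test_zero_variance_reported_missing(self):
        truth = make_matrix([[0], [1], [2]])
        const = np.ones((3, 1))
        r = lp.accuracy_per_snp(const, truth, ["m0"])
        assert np.isnan(r.iloc[0])

    def test_missing_truth_excluded_from_pairs(self):
        truth = make_matrix([[0], [1], [2], [MISSING]])
        imputed = np.array([[0.0], [1.0], [2.0], [99.0]])
        r = lp.accuracy_per_snp(imputed, truth, ["m0"])
        assert r.iloc[0] == pytest.approx(1.0)


class TestSummaries:
    def test_constant_perfect(self):
        s = lp.summarize_accuracy([1, 1, 1, 1])
        assert (s["mean"], s["sd"], s["pct_gt_threshold"]) == (1.0, 0.0, 100.0)

    def test_strict_threshold(self):
        assert lp.summarize_accuracy([0.9, 0.7])["pct_gt_threshold"] == 50.0
        assert lp.summarize_accuracy([0.8, 0.8])["pct_gt_threshold"] == 0.0

    def test_arithmetic(self):
        s = lp.summarize_accuracy([0.5, 0.7, 0.9])
        assert s["mean"] == pytest.approx(0.7)
        assert (s["min"], s["max"]) == (0.5, 0.9)
        assert s["pct_gt_threshold"] == pytest.approx(100 / 3)

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            lp.summarize_accuracy([np.nan, np.nan])


class TestMafBins:
    def test_boundary_goes_to_upper_bin(self):
        r = pd.Series([0.5], index=["m"])
        maf = pd.Series([0.05], index=["m"])
        out = lp.accuracy_by_maf_bin(r, maf)
        hit = out[out["n"] > 0]
        assert len(hit) == 1
        assert hit.iloc[0]["maf_lo"] == 0.05

    def test_single_bin_mean_is_global_mean(self):
        r = pd.Series([0.2, 0.4, 0.9], index=list("abc"))
        maf = pd.Series([0.32, 0.35, 0.38], index=list("abc"))
        out = lp.accuracy_by_maf_bin(r, maf)
        hit = out[out["n"] > 0]
        assert len(hit) == 1
        assert hit.iloc[0]["mean_r"] == pytest.approx(r.mean())

    def test_monotone_fixture_gives_increasing_bin_means(self):
        rng = np.random.default_rng(3)
        maf = pd.Series(rng.uniform(0.011, 0.499, 300))
        maf.index = [f"m{k}" for k in range(300)]
        r = maf.rank() / 300.0   # accuracy = MAF rank
        out = lp.accuracy_by_maf_bin(r, maf)
        means = out.loc[out["n"] > 0, "mean_r"].to_numpy()
        assert np.all(np.diff(means) > 0)


class TestChromosomeEnds:
    def test_selection_count_and_short_chromosome_flag(self):
        mmap = make_map(300, n_chrom=2)      # 150 markers per chromosome
        r = pd.Series(0.9, index=list(mmap.markers))
        tab, selected = lp.chromosome_end_accuracy(r, mmap, n_end=50)
        assert len(selected) == 200 and not tab["overlap"].any()
        tab2, selected2 = lp.chromosome_end_accuracy(r, mmap, n_end=100)
        assert tab2["overlap"].all() and len(selected2) == 300

    def test_end_sets_are_outermost_markers(self):
        mmap = make_map(100)
        r = pd.Series(np.linspace(0, 1, 100), index=list(mmap.markers))
        tab, selected = lp.chromosome_end_accuracy(r, mmap, n_end=10)
        assert set(selected) == set(list(mmap.markers[:10]) + list(mmap.markers[-10:]))
        row = tab.iloc[0]
        assert row["interior_mean"] == pytest.approx(r.iloc[10:-10].mean())


class TestRunCv:
    def _setup(self, small_qc, small_study):
        g, mmap = small_qc
        return g, small_study.bundle.pedigree, mmap

    def test_full_panel_gives_perfect_accuracy(self, small_qc, small_study):
        g, ped, mmap = self._setup(small_qc, small_study)
        full = PanelDefinition("full", None, list(g.markers))
        reports, _ = lp.run_cv_experiment(g, ped, mmap, [full], n_replicates=2,
                                          validation_fraction=0.5, seed=3,
                                          with_baseline=False)
        r = reports["full"].per_snp.dropna()
        assert np.allclose(r, 1.0)

    def test_nested_tiers_monotone_and_deterministic(self, small_qc, small_study):
        g, ped, mmap = self._setup(small_qc, small_study)
        dense = PanelDefinition("dense", None, list(g.markers[::2]))
        sparse = PanelDefinition("sparse", None, list(g.markers[::8]))
        kw = dict(n_replicates=2, validation_fraction=0.5, seed=3,
                  with_baseline=False)
        reports, comparison = lp.run_cv_experiment(g, ped, mmap, [dense, sparse], **kw)
        m = comparison.set_index("tier")["snp_mean"]
        se = reports["sparse"].summary_snp["sd"] / np.sqrt(reports["sparse"].summary_snp["n"])
        assert m["dense"] >= m["sparse"] - se
        reports2, comparison2 = lp.run_cv_experiment(g, ped, mmap, [dense, sparse], **kw)
        pd.testing.assert_frame_equal(comparison, comparison2)
        pd.testing.assert_series_equal(reports["dense"].per_snp, reports2["dense"].per_snp)

    def test_no_leakage_of_masked_truth(self, small_qc, small_study):
        """Poisoning the masked truth entries must not change any imputed
        value: the imputer can never see them."""
        g, ped, mmap = self._setup(small_qc, small_study)
        panel = PanelDefinition("p", None, list(g.markers[::4]))
        kw = dict(n_replicates=2, validation_fraction=0.5, seed=9,
                  with_baseline=False)
        reports, _ = lp.run_cv_experiment(g, ped, mmap, [panel], **kw)

        # poison one fold; only that fold's entries are hidden while it is
        # validated (its genotypes legitimately serve as reference in the
        # other replicate), so its own imputed rows must be unchanged
        poisoned = g.copy()
        schemes = lp.make_masking_scheme(g.individuals, 2, 0.5, seed=9)
        fold = schemes[0].validation
        panel_cols = set(g.marker_positions(panel.markers).tolist())
        masked_cols = [j for j in range(g.n_markers) if j not in panel_cols]
        rows = g.individual_positions(fold)
        block = poisoned.dosages[np.ix_(rows, masked_cols)]
        poisoned.dosages[np.ix_(rows, masked_cols)] = np.where(
            block == MISSING, MISSING, 2 - block)
        reports_p, _ = lp.run_cv_experiment(poisoned, ped, mmap, [panel], **kw)
        assert np.array_equal(
            reports["p"].extras["imputed_pooled"][rows],
            reports_p["p"].extras["imputed_pooled"][rows])
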