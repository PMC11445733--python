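"""Population analytics: MAF spectrum, heterozygosity, IBS/MDS, the
admixture EM and Evanno Delta-K."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binom

import ldpanel as lp
from ldpanel.core import MISSING
from conftest import make_matrix


class TestMafSpectrum:
    def test_all_top_bin(self):
        g = make_matrix(np.tile([0, 1, 1, 2], (4, 1)).T)
        out = lp.maf_spectrum(g)
        top = out.iloc[-1]
        assert top["count"] == g.n_markers and top["fraction"] == 1.0

    def test_empty_matrix_rejected(self):
        g = make_matrix(np.zeros((3, 0), dtype=np.int8))
        with pytest.raises(ValueError):
            lp.maf_spectrum(g)

    def test_uniform_maf_fills_bins_evenly(self):
        rng = np.random.default_rng(8)
        n_ind, n_mark = 4000, 1000
        maf = rng.uniform(0.0, 0.5, n_mark)
        d = rng.binomial(2, maf, size=(n_ind, n_mark)).astype(np.int8)
        out = lp.maf_spectrum(make_matrix(d))
        se = np.sqrt(0.1 * 0.9 / n_mark)
        assert np.all(np.abs(out["fraction"] - 0.1) < 4 * se)


class TestHeterozygosity:
    def test_extremes(self):
        assert lp.individual_heterozygosity(make_matrix([[1, 1, 1]])).iloc[0] == 1.0
        assert lp.individual_heterozygosity(make_matrix([[0, 2, 0]])).iloc[0] == 0.0

    def test_missing_excluded(self):
        h = lp.individual_heterozygosity(make_matrix([[1, MISSING, 0, 1]]))
        assert h.iloc[0] == pytest.approx(2 / 3)

    def test_hwe_expectation_at_half(self):
        rng = np.random.default_rng(10)
        d = rng.binomial(2, 0.5, size=(300, 400)).astype(np.int8)
        h = lp.individual_heterozygosity(make_matrix(d))
        se = np.sqrt(0.25 / (300 * 400))
        assert abs(h.mean() - 0.5) < 3 * se


class TestIbs:
    def test_identical_and_opposite_rows(self):
        g = make_matrix([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        ibs = lp.ibs_matrix(g)
        assert ibs.similarity[0, 1] == pytest.approx(1.0)
        assert ibs.distance[0, 1] == pytest.approx(0.0)
        g2 = make_matrix([[0, 0], [2, 2]])
        assert lp.ibs_matrix(g2).similarity[0, 1] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        g = make_matrix([[0, 1, 2], [1, 1, 0]])
        # per-marker sharing: (2-1)/2, (2-0)/2, (2-2)/2 -> mean = 0.5
        assert lp.ibs_matrix(g).similarity[0, 1] == pytest.approx(0.5)

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = MISSING
        ibs = lp.ibs_matrix(make_matrix(d))
        assert np.allclose(ibs.similarity, ibs.similarity.T)
        assert np.allclose(np.diag(ibs.similarity), 1.0)
        assert ibs.similarity.min() >= 0.0 and ibs.similarity.max() <= 1.0

    def test_disjoint_missing_patterns_rejected(self):
        g = make_matrix([[0, MISSING], [MISSING, 1]])
        with pytest.raises(ValueError, match="share no genotyped marker"):
            lp.ibs_matrix(g)


def _procrustes_residual(a, b):
    """Least-squares residual after optimally rotating/reflecting b onto a."""
    a = a - a.mean(0)
    b = b - b.mean(0)
    u, _, vt = np.linalg.svd(b.T @ a)
    rot = u @ vt
    return np.linalg.norm(a - b @ rot)


class TestClassicalMds:
    def test_zero_distances_collapse_to_origin(self):
        coords = lp.classical_mds(np.zeros((5, 5)), k=2)
        assert np.allclose(coords, 0.0)

    def test_recovers_planted_euclidean_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 2.0], [2.2, 1.5]])
        D = squareform(pdist(pts))
        coords = lp.classical_mds(D, k=2)
        assert _procrustes_residual(pts, coords) < 1e-8

    def test_agrees_with_reference_pcoa(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(15, 4))
        D = squareform(pdist(pts))
        ours = lp.classical_mds(D, k=2)
        theirs = skbio.stats.ordination.pcoa(D, number_of_dimensions=2).samples.to_numpy()
        # same embedding up to per-axis sign
        for ax in range(2):
            assert (np.allclose(ours[:, ax], theirs[:, ax], atol=1e-8)
                    or np.allclose(ours[:, ax], -theirs[:, ax], atol=1e-8))

    def test_axis_orientation_fixed(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 2.0], [2.2, 1.5]])
        D = squareform(pdist(pts))
        coords = lp.classical_mds(D, k=2)
        for ax in range(2):
            col = coords[:, ax]
            assert col[np.argmax(np.abs(col))] > 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            lp.classical_mds(np.array([[0, 1.0], [2.0, 0]]))
        with pytest.raises(ValueError, match="dimensions"):
            lp.classical_mds(squareform(pdist([[0.0], [1.0]])), k=2)

    def test_two_regions_separate_on_axis_one(self):
        cfg = lp.SimConfig(n_chromosomes=2, markers_per_chromosome=150,
                           fst=0.1, seed=6)
        study = lp.simulate_study(cfg, "two_regions")
        g, _ = lp.apply_qc(study.bundle.genotypes, None, lp.QcThresholds())
        coords = lp.classical_mds(lp.ibs_matrix(g).distance, k=2)
        lab = study.labels.loc[g.individuals].to_numpy()
        ax1 = coords[:, 0]
        between = abs(ax1[lab == "north"].mean() - ax1[lab == "southeast"].mean())
        within = (ax1[lab == "north"].std() + ax1[lab == "southeast"].std()) / 2
        assert between > 3 * within


class TestAdmixtureEm:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
        g = make_matrix(d)
        fit = lp.admixture_em(g, 1)
        assert np.allclose(fit.Q, 1.0)
        freq = g.allele_frequencies()
        assert np.allclose(fit.P[0], np.clip(freq, 1e-3, 1 - 1e-3))
        ll = binom.logpmf(d, 2, np.clip(freq, 1e-12, 1 - 1e-12)[None, :]).sum()
        assert fit.log_likelihood == pytest.approx(ll, rel=1e-9)

    def test_loglik_monotone_nondecreasing(self):
        cfg = lp.SimConfig(n_chromosomes=1, markers_per_chromosome=120,
                           fst=0.2, seed=3)
        study = lp.simulate_study(cfg, "two_regions")
        fit = lp.admixture_em(study.bundle.genotypes, 2, seed=11, max_iter=120)
        assert np.all(np.diff(fit.log_likelihood_path) >= -1e-8)

    def test_q_rows_normalized_and_p_bounded(self):
        rng = np.random.default_rng(5)
        g = make_matrix(rng.integers(0, 3, size=(25, 60)).astype(np.int8))
        fit = lp.admixture_em(g, 3, seed=2, max_iter=60)
        assert np.allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)
        assert fit.P.min() >= 0.0 and fit.P.max() <= 1.0

    def test_two_population_label_recovery(self):
        cfg = lp.SimConfig(n_chromosomes=2, markers_per_chromosome=150,
                           fst=0.15, seed=7)
        study = lp.simulate_study(cfg, "two_regions")
        g, _ = lp.apply_qc(study.bundle.genotypes, None, lp.QcThresholds())
        fit = lp.admixture_em(g, 2, seed=1)
        assert lp.label_recovery(fit, study.labels.loc[g.individuals]) >= 0.95

    def test_no_spurious_structure_in_homogeneous_population(self):
        # one panmictic population analyzed at K=2: unregularized ML
        # admixture absorbs some sampling noise into Q (null runs sit near
        # mean |q - 0.5| ~ 0.25), but memberships must stay far from the
        # full polarization (0.5) that a genuinely structured sample shows
        rng = np.random.default_rng(20)
        p = rng.uniform(0.1, 0.9, 300)
        d = rng.binomial(2, p, size=(100, 300)).astype(np.int8)
        fit = lp.admixture_em(make_matrix(d), 2, seed=4, max_iter=150)
        assert np.abs(fit.Q[:, 0] - 0.5).mean() < 0.35

    def test_k_bounds_rejected(self):
        g = make_matrix(np.zeros((3, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            lp.admixture_em(g, 0)
        with pytest.raises(ValueError):
            lp.admixture_em(g, 4)


class TestEvannoDeltaK:
    def test_flat_likelihood_gives_zero(self):
        tab = pd.DataFrame({1: [-10.0, -12.0], 2: [-10.0, -12.0], 3: [-10.0, -12.0]})
        out = lp.evanno_delta_k(tab)
        assert out["delta_k"].iloc[0] == 0.0

    def test_formula_against_direct_evaluation(self):
        tab = pd.DataFrame({1: [-100.0, -102.0], 2: [-50.0, -52.0], 3: [-49.0, -51.0]})
        out = lp.evanno_delta_k(tab)
        second = [abs(-100 - 2 * -50 + -49), abs(-102 - 2 * -52 + -51)]
        expected = np.mean(second) / np.std([-50, -52], ddof=1)
        assert out["delta_k"].iloc[0] == pytest.approx(expected)
        assert out.attrs["optimal_k"] == 2

    def test_zero_sd_flagged_infinite(self):
        tab = pd.DataFrame({1: [-10.0, -11.0], 2: [-5.0, -5.0], 3: [-4.0, -4.5]})
        out = lp.evanno_delta_k(tab)
        assert np.isinf(out["delta_k"].iloc[0]) and out["zero_sd"].iloc[0]

    def test_grid_requirements(self):
        with pytest.raises(ValueError, match="three"):
            lp.evanno_delta_k(pd.DataFrame({1: [0.0, 1], 2: [0.0, 1]}))
        with pytest.raises(ValueError, match="contiguous"):
            lp.evanno_delta_k(pd.DataFrame({1: [0.0, 1], 3: [0.0, 1], 5: [0.0, 1]}))
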