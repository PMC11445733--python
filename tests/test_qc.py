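"""QC filters: MAF, call rate, the HWE exact test against an enumeration
oracle, Mendelian-error scanning, and the composed filter pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ldpanel as lp
from ldpanel.core import MISSING
from ldpanel.qc import hwe_exact_test, hwe_pvalues
from conftest import hwe_enumeration_oracle, make_matrix


class TestMinorAlleleFrequency:
    @pytest.mark.parametrize("dosages, expected", [
        ([[0], [0], [0], [0]], 0.0),
        ([[1], [1], [1], [1]], 0.5),
        ([[2], [1], [0], [MISSING]], 0.5),   # 3 of 6 counted alleles
        ([[2], [2], [1], [0]], min(5 / 8, 3 / 8)),
    ])
    def test_hand_counts(self, dosages, expected):
        g = make_matrix(dosages)
        assert lp.minor_allele_frequency(g, "m0") == pytest.approx(expected)

    def test_all_missing_marker_is_nan(self):
        g = make_matrix([[MISSING], [MISSING]])
        assert np.isnan(lp.minor_allele_frequency(g))[0]


class TestCallRate:
    def test_complete_matrix(self):
        g = make_matrix([[0, 1], [2, 1]])
        assert np.all(lp.call_rate(g, "marker") == 1.0)
        assert np.all(lp.call_rate(g, "sample") == 1.0)

    def test_single_missing_entry(self):
        d = np.ones((10, 1), dtype=np.int8)
        d[3, 0] = MISSING
        assert lp.call_rate(make_matrix(d), "marker")[0] == pytest.approx(0.9)

    def test_noise_rate_recovered(self, small_study):
        cfg = lp.SimConfig(n_chromosomes=4, markers_per_chromosome=120,
                           missing_rate=0.05, error_rate=0.0, seed=31)
        noisy = lp.apply_genotyping_noise(small_study.clean_genotypes, cfg)
        cr = lp.call_rate(noisy, "marker")
        se = np.sqrt(0.05 * 0.95 / noisy.dosages.size)
        assert abs(cr.mean() - 0.95) < 3 * se


class TestHweExactTest:
    def test_monomorphic_is_certain(self):
        assert hwe_exact_test(17, 0, 0) == 1.0

    @pytest.mark.parametrize("table", [(50, 0, 50), (25, 50, 25), (3, 5, 2),
                                       (0, 1, 0), (10, 1, 10), (2, 9, 30)])
    def test_matches_enumeration_oracle(self, table):
        assert hwe_exact_test(*table) == pytest.approx(
            hwe_enumeration_oracle(*table), abs=1e-12)

    def test_modal_table_has_large_p(self):
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_rejects_empty_table(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_oracle_equivalence_property(self, a, h, b):
        if a + h + b == 0:
            return
        p = hwe_exact_test(a, h, b)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_enumeration_oracle(a, h, b), abs=1e-12)


class TestMendelScan:
    def _geno(self, sire, dam, off):
        g = make_matrix([[sire], [dam], [off]], individuals=["s", "d", "o"])
        ped = lp.Pedigree.from_records([
            ("s", None, None, None), ("d", None, None, None), ("o", "s", "d", "f")])
        return g, ped

    @pytest.mark.parametrize("sire,dam,off,is_err", [
        (0, 0, 2, True), (0, 0, 1, True), (0, 0, 0, False),
        (2, 2, 2, False), (2, 2, 1, True),
        (0, 2, 1, False), (0, 2, 0, True), (0, 2, 2, True),
        (1, 1, 0, False), (1, 1, 1, False), (1, 1, 2, False),
        (0, 1, 2, True), (0, 1, 1, False),
    ])
    def test_trio_transmission_table(self, sire, dam, off, is_err):
        g, ped = self._geno(sire, dam, off)
        scan = lp.mendel_error_scan(g, ped)
        assert scan.per_trio["errors"].iloc[0] == int(is_err)

    @pytest.mark.parametrize("parent,off,is_err", [
        (0, 2, True), (2, 0, True), (0, 1, False), (1, 2, False)])
    def test_duo_rule_with_missing_parent(self, parent, off, is_err):
        g, ped = self._geno(parent, MISSING, off)
        scan = lp.mendel_error_scan(g, ped)
        assert scan.per_trio["errors"].iloc[0] == int(is_err)

    def test_planted_error_rate_recovered(self, small_study):
        g = small_study.clean_genotypes.copy()
        ped = small_study.bundle.pedigree
        rng = np.random.default_rng(55)
        offspring = [i for i in ped.individuals if ped.parents_of(i)[0] is not None]
        rows = g.individual_positions(offspring)
        plant = rng.random((len(rows), g.n_markers)) < 0.05
        # force a guaranteed-detectable error: flip the offspring genotype to
        # the opposite homozygote of a homozygous parent
        for r, row in enumerate(rows):
            sire = g.row(ped.parents_of(offspring[r])[0])
            targets = np.flatnonzero(plant[r] & (sire != 1) & (sire != MISSING))
            g.dosages[row, targets] = 2 - sire[targets]
        scan = lp.mendel_error_scan(g, ped)
        planted_frac = np.mean([
            (plant[r] & (g.row(ped.parents_of(offspring[r])[0]) != 1)).mean()
            for r in range(len(rows))])
        rate = scan.per_trio["rate"].mean()
        se = np.sqrt(planted_frac * (1 - planted_frac) / g.n_markers)
        assert abs(rate - planted_frac) < 3 * se


class TestApplyQc:
    def test_disabled_thresholds_are_identity(self, small_study):
        g = small_study.bundle.genotypes
        thr = lp.QcThresholds(maf_min=None, marker_call_rate_min=None,
                              hwe_alpha=None, mendel_trio_max=None,
                              mendel_marker_max=None)
        out, rep = lp.apply_qc(g, small_study.bundle.pedigree, thr)
        assert out.equals(g)
        assert rep.to_frame()["markers_removed"].sum() == 0

    def test_low_maf_marker_removed(self):
        d = np.zeros((50, 2), dtype=np.int8)
        d[:2, 0] = 1          # MAF 0.02
        d[:20, 1] = 1         # MAF 0.2
        g = make_matrix(d)
        out, rep = lp.apply_qc(g, None, lp.QcThresholds(
            maf_min=0.05, marker_call_rate_min=None, hwe_alpha=None), order=("maf",))
        assert list(out.markers) == ["m1"]

    def test_call_rate_removal_counted_in_its_step(self):
        d = np.ones((20, 2), dtype=np.int8)
        d[:3, 0] = MISSING    # 85% call rate
        g = make_matrix(d)
        out, rep = lp.apply_qc(g, None, lp.QcThresholds(
            maf_min=None, hwe_alpha=None, marker_call_rate_min=0.9))
        steps = rep.to_frame().set_index("step")
        assert steps.loc["call_rate", "markers_removed"] == 1
        assert list(out.markers) == ["m1"]

    def test_filters_compose_and_report_balances(self, small_study):
        g = small_study.bundle.genotypes
        out, rep = lp.apply_qc(g, small_study.bundle.pedigree, lp.QcThresholds())
        tab = rep.to_frame()
        assert (tab["markers_after"] == tab["markers_before"] - tab["markers_removed"]).all()
        assert tab["markers_before"].iloc[1:].tolist() == tab["markers_after"].iloc[:-1].tolist()
        assert out.n_markers == tab["markers_after"].iloc[-1]

    def test_idempotence(self, small_study):
        g = small_study.bundle.genotypes
        thr = lp.QcThresholds()
        once, _ = lp.apply_qc(g, small_study.bundle.pedigree, thr)
        twice, rep2 = lp.apply_qc(once, small_study.bundle.pedigree, thr)
        assert twice.equals(once)

    def test_mendel_step_drops_bad_offspring(self, small_study):
        g = small_study.clean_genotypes.copy()
        ped = small_study.bundle.pedigree
        bad = "O001"
        row = g.individual_positions([bad])[0]
        sire = g.row(ped.parents_of(bad)[0])
        targets = np.flatnonzero((sire != 1) & (sire != MISSING))[:g.n_markers // 5]
        g.dosages[row, targets] = 2 - sire[targets]
        out, rep = lp.apply_qc(g, ped, lp.QcThresholds(
            maf_min=None, marker_call_rate_min=None, hwe_alpha=None,
            mendel_trio_max=0.05, mendel_marker_max=1.0), order=("mendel",))
        assert bad not in set(out.individuals)


def test_null_hwe_rejection_rate_conservative():
    # random-mating null: dosage ~ Binomial(2, p); the exact test should
    # reject at most alpha (+ Monte-Carlo slack) of markers
    rng = np.random.default_rng(17)
    n_ind, n_mark, alpha = 200, 1500, 0.05
    p = rng.uniform(0.1, 0.9, size=n_mark)
    d = rng.binomial(2, p, size=(n_ind, n_mark)).astype(np.int8)
    g = make_matrix(d)
    pvals = hwe_pvalues(g)
    rate = (pvals < alpha).mean()
    se = np.sqrt(alpha * (1 - alpha) / n_mark)
    assert rate <= alpha + 3 * se
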