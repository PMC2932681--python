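"""Score-clone association, Bonferroni logic, cis/trans classification."""

import numpy as np
import pytest

from lfcna import (
    CGHProfile,
    classify_cis_trans,
    correlate_scores_with_clones,
    select_cna_factors,
    signature_clone_association,
)
from lfcna.association import AssociationResult
from lfcna.ler import GenomeGrid, LERNullCalibration, LERProfile
from lfcna.projection import ProjectedScores


def _make_cgh(values, chrom="chr1", length=1e8):
    m, n = values.shape
    return CGHProfile(
        clone_ids=[f"c{i}" for i in range(m)],
        clone_chrom=np.array([chrom] * m, dtype=object),
        clone_pos=np.linspace(1e6, length - 1e6, m),
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
    )


def _scores(values):
    k, n = values.shape
    return ProjectedScores(scores=values,
                           factor_ids=[f"factor{j+1}" for j in range(k)],
                           sample_ids=[f"s{i}" for i in range(n)])


class TestCorrelation:
    def test_identical_clone_perfect_correlation(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(1, 30))
        cgh = _make_cgh(np.vstack([s, rng.normal(size=(4, 30))]))
        res = correlate_scores_with_clones(_scores(s), cgh, alpha=0.05,
                                           min_complete_pairs=3)
        assert res.r[0, 0] == pytest.approx(1.0)
        assert res.significant[0, 0]

    def test_bonferroni_threshold_arithmetic(self):
        # alpha=.05 over a 2150-clone panel: per-test level ~2.326e-5
        rng = np.random.default_rng(1)
        s = rng.normal(size=(1, 20))
        cgh = _make_cgh(rng.normal(size=(5, 20)))
        res = correlate_scores_with_clones(_scores(s), cgh, alpha=0.05,
                                           n_tests_override=2150,
                                           min_complete_pairs=3)
        assert 0.05 / res.n_tests == pytest.approx(2.3255813953e-5)

    def test_significance_mask_is_exact_bonferroni(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(3, 40))
        cgh = _make_cgh(rng.normal(size=(20, 40)))
        res = correlate_scores_with_clones(_scores(s), cgh, alpha=0.3,
                                           min_complete_pairs=3)
        np.testing.assert_array_equal(
            res.significant, res.p < res.bonferroni_alpha / res.n_tests)

    def test_symmetry_scores_vs_clones(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(4, 25))
        C = rng.normal(size=(6, 25))
        res1 = correlate_scores_with_clones(_scores(S), _make_cgh(C),
                                            min_complete_pairs=3)
        res2 = correlate_scores_with_clones(_scores(C), _make_cgh(S),
                                            min_complete_pairs=3)
        np.testing.assert_allclose(res1.r, res2.r.T, atol=1e-12)

    def test_zero_variance_clone_flagged_degenerate(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=(1, 15))
        C = rng.normal(size=(3, 15))
        C[1] = 5.0
        res = correlate_scores_with_clones(_scores(s), _make_cgh(C),
                                           min_complete_pairs=3)
        assert res.degenerate[0, 1]
        assert res.p[0, 1] == 1.0

    def test_missing_heavy_clones_dropped(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=(1, 20))
        C = rng.normal(size=(4, 20))
        C[2, :10] = np.nan  # 50% missing
        res = correlate_scores_with_clones(_scores(s), _make_cgh(C),
                                           min_complete_pairs=3)
        assert res.r.shape[1] == 3
        assert "c2" not in res.clone_ids

    def test_pairwise_complete_handling(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=(1, 30))
        C = np.vstack([s + 0.01 * rng.normal(size=30)])
        C[0, :3] = np.nan
        res = correlate_scores_with_clones(_scores(s), _make_cgh(C),
                                           min_complete_pairs=3)
        assert res.r[0, 0] > 0.99

    def test_too_few_samples_rejected(self):
        s = np.zeros((1, 2))
        with pytest.raises(ValueError):
            correlate_scores_with_clones(_scores(s), _make_cgh(np.zeros((2, 2))))


class TestSignatureAssociation:
    def test_signature_equal_to_clone_is_significant(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=30)
        C = np.vstack([v, rng.normal(size=(9, 30))])
        res = signature_clone_association(v, _make_cgh(C), alpha=0.05)
        assert res.significant[0, 0]
        assert not res.significant[0, 1:].any()

    def test_all_zero_signature_degenerate(self):
        rng = np.random.default_rng(8)
        C = rng.normal(size=(5, 20))
        res = signature_clone_association(np.zeros(20), _make_cgh(C))
        assert res.degenerate.all()
        assert (res.p == 1.0).all()


def _ler_stub(max_val, chrom="chr1", pos=5e7, null_samples=None, frac=0.05):
    grid = GenomeGrid(points={chrom: np.array([pos - 1e6, pos, pos + 1e6])})
    prof = LERProfile(grid=grid, values=np.array([1.0, max_val, 1.0]),
                      kernel_fraction=frac, factor_id="factor1")
    if null_samples is None:
        null_samples = np.full(200, 1.0)
    calib = LERNullCalibration(kernel_fraction=frac, n_permutations=len(null_samples),
                               null_max_samples=np.asarray(null_samples))
    return prof, calib


class TestCisTrans:
    def _assoc(self, p_val, chrom="chr1", pos=5e7):
        return AssociationResult(
            r=np.array([[0.9]]), p=np.array([[p_val]]),
            factor_ids=["factor1"], clone_ids=["c0"],
            clone_chrom=np.array([chrom], dtype=object),
            clone_pos=np.array([pos]),
            bonferroni_alpha=0.01, n_tests=1)

    def test_colocalized_significant_peak_is_cis(self):
        prof, calib = _ler_stub(8.0)
        call = classify_cis_trans("factor1", self._assoc(1e-10), prof, calib,
                                  alpha_ler=0.01, colocalization_window=5e6)
        assert call.call == "cis"
        assert call.ler_peak[0] == "chr1"

    def test_significant_clone_without_ler_is_trans(self):
        prof, calib = _ler_stub(1.0, null_samples=np.full(200, 2.0))
        call = classify_cis_trans("factor1", self._assoc(1e-10), prof, calib,
                                  alpha_ler=0.01, colocalization_window=5e6)
        assert call.call == "trans"

    def test_distant_ler_peak_is_trans(self):
        prof, calib = _ler_stub(8.0, pos=9e7)
        call = classify_cis_trans("factor1", self._assoc(1e-10, pos=1e6),
                                  prof, calib, alpha_ler=0.01,
                                  colocalization_window=5e6)
        assert call.call == "trans"

    def test_no_significant_clone_is_none(self):
        prof, calib = _ler_stub(8.0)
        call = classify_cis_trans("factor1", self._assoc(0.5), prof, calib,
                                  alpha_ler=0.01, colocalization_window=5e6)
        assert call.call == "none"


class TestSelection:
    def _assoc_with(self, p_min, n_clones=10):
        p = np.full((1, n_clones), 0.5)
        p[0, 0] = p_min
        return AssociationResult(
            r=np.zeros((1, n_clones)), p=p,
            factor_ids=["factor1"], clone_ids=[f"c{i}" for i in range(n_clones)],
            clone_chrom=np.array(["chr1"] * n_clones, dtype=object),
            clone_pos=np.linspace(0, 9e7, n_clones),
            bonferroni_alpha=0.01, n_tests=n_clones)

    def test_requires_significance_in_both_cohorts(self):
        strong, weak = self._assoc_with(1e-12), self._assoc_with(0.5)
        both = select_cna_factors(strong, strong, alpha=0.01)
        assert bool(both.loc["factor1", "selected"])
        one = select_cna_factors(strong, weak, alpha=0.01)
        assert not bool(one.loc["factor1", "selected"])

    def test_mismatched_factor_sets_rejected(self):
        a = self._assoc_with(1e-12)
        b = self._assoc_with(1e-12)
        b.factor_ids = ["other"]
        with pytest.raises(ValueError):
            select_cna_factors(a, b)
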