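"""Generators: determinism, planted-truth bookkeeping, geometric invariants."""

import numpy as np
import pytest
from scipy import stats

from lfcna import (
    HUMAN_CHROM_LENGTHS,
    FactorSpec,
    default_clone_positions,
    simulate_annotation,
    simulate_designed_experiment,
    simulate_factor_cohort,
    simulate_paired_cohorts,
)


class TestAnnotation:
    def test_positions_within_chromosomes(self):
        ann = simulate_annotation(10, [1e6], clustering=0.0, seed=0)
        assert ann.n_genes == 10
        assert (ann.start >= 0).all() and (ann.start < 1e6).all()

    def test_deterministic_given_seed(self):
        a = simulate_annotation(50, HUMAN_CHROM_LENGTHS, clustering=0.5, seed=3)
        b = simulate_annotation(50, HUMAN_CHROM_LENGTHS, clustering=0.5, seed=3)
        assert a.gene_ids == b.gene_ids
        assert (a.chromosome == b.chromosome).all()
        np.testing.assert_array_equal(a.start, b.start)

    def test_chromosome_counts_match_length_proportions(self):
        # binomial 99% bounds per chromosome for length-proportional placement
        n = 3000
        ann = simulate_annotation(n, HUMAN_CHROM_LENGTHS, clustering=0.0, seed=11)
        total = sum(HUMAN_CHROM_LENGTHS.values())
        for c, L in HUMAN_CHROM_LENGTHS.items():
            count = int((ann.chromosome == c).sum())
            lo, hi = stats.binom.interval(0.99, n, L / total)
            assert lo <= count <= hi, f"{c}: {count} outside [{lo}, {hi}]"

    def test_empty_chromosome_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotation(10, [], seed=0)

    def test_clustering_concentrates_positions(self):
        flat = simulate_annotation(2000, [1e8], clustering=0.0, seed=5)
        clus = simulate_annotation(2000, [1e8], clustering=1.0, seed=5)
        # nearest-neighbour distances shrink when genes form islands
        def med_nn(a):
            s = np.sort(a.start)
            return np.median(np.diff(s))
        assert med_nn(clus) < med_nn(flat) / 2


class TestDesignedExperiment:
    def test_null_effect_still_records_affected_sets(self):
        expr, design, truth = simulate_designed_experiment(
            100, [10, 10], affected_fraction=0.1, effect_size=0.0,
            noise_sd=0.3, seed=1)
        assert all(len(v) == 10 for v in truth.affected_genes.values())
        assert abs(expr.values.mean()) < 0.1  # pure noise

    def test_noise_free_limit_recovers_exact_shift(self):
        expr, design, truth = simulate_designed_experiment(
            50, [5, 5], affected_fraction=0.2, effect_size=3.0,
            noise_sd=0.0, seed=2)
        # without noise the group means differ exactly by the planted shift
        g2 = design.values[0].astype(bool)
        diff = expr.values[:, g2].mean(axis=1) - expr.values[:, ~g2].mean(axis=1)
        planted = truth.loadings_true[:, 0]
        np.testing.assert_allclose(diff, planted, atol=1e-12)

    def test_affected_gene_count_is_exact(self):
        _, design, truth = simulate_designed_experiment(
            200, [20, 20], affected_fraction=0.1, effect_size=2.0,
            noise_sd=0.5, seed=3)
        assert len(truth.affected_genes[design.vector_names[0]]) == 20

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_designed_experiment(100, [10], 0.1, 1.0, 0.5, seed=0)
        with pytest.raises(ValueError):
            simulate_designed_experiment(100, [10, 10], 0.1, 1.0, -1.0, seed=0)


@pytest.fixture(scope="module")
def cohort_setup():
    ann = simulate_annotation(
        400, HUMAN_CHROM_LENGTHS, clustering=1.0, seed=9,
        extra_peaks=[("chr8", 7e6), ("chr8", 7e6)])
    # the sparse genome-wide panel plus guaranteed in-segment clones
    clones = default_clone_positions(ann.chrom_lengths, 60) \
        + [("chr8", 7e6), ("chr12", 70e6)]
    specs = [
        FactorSpec(None, 1.0, "cis", ("chr8", 2e6, 12e6)),
        FactorSpec(15, 1.0, "trans", ("chr12", 65e6, 75e6)),
        FactorSpec(15, 1.0, "neutral"),
    ]
    return ann, clones, specs


class TestFactorCohort:
    def test_noise_free_identity(self, cohort_setup):
        ann, clones, specs = cohort_setup
        expr, cgh, truth = simulate_factor_cohort(
            ann, 30, specs, noise_sd=0.0, clone_positions=clones,
            clone_noise_sd=0.0, seed=4, score_noise_sd=0.0)
        np.testing.assert_allclose(
            expr.values, truth.loadings_true @ truth.scores_true, atol=1e-12)
        inside = truth.clone_segment >= 0
        np.testing.assert_allclose(
            cgh.values[inside],
            truth.copy_number_latent[truth.clone_segment[inside]], atol=1e-12)
        np.testing.assert_allclose(cgh.values[~inside], 0.0, atol=1e-12)

    def test_cis_members_inside_segment(self, cohort_setup):
        ann, clones, specs = cohort_setup
        _, _, truth = simulate_factor_cohort(
            ann, 40, specs, 0.5, clones, 0.2, seed=5)
        j, c, s, e, mode = truth.segment_map[0]
        assert mode == "cis"
        loaded = np.where(truth.loadings_true[:, j] != 0)[0]
        inside = ((ann.chromosome[loaded] == c)
                  & (ann.start[loaded] >= s) & (ann.start[loaded] < e))
        assert inside.mean() >= 0.8

    def test_in_segment_clone_tracks_factor_score(self, cohort_setup):
        ann, clones, specs = cohort_setup
        _, cgh, truth = simulate_factor_cohort(
            ann, 200, specs, 0.5, clones, clone_noise_sd=0.2, seed=6,
            score_noise_sd=0.2)
        cis_j = truth.segment_map[0][0]
        in_seg = np.where(truth.clone_segment == 0)[0]
        assert len(in_seg) >= 1
        r = np.corrcoef(truth.scores_true[cis_j], cgh.values[in_seg[0]])[0, 1]
        assert r > 0.9

    def test_neutral_factor_uncorrelated_with_clones(self, cohort_setup):
        # fixed seed sequence; a neutral factor should stay below the
        # Bonferroni bar in nearly every replicate
        ann, clones, specs = cohort_setup
        n, m = 60, 60
        thr_r = None
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            _, cgh, truth = simulate_factor_cohort(
                ann, n, specs, 0.5, clones, 0.2, seed=100 + seed)
            neutral_j = 2
            s = truth.scores_true[neutral_j]
            r = np.abs(np.corrcoef(np.vstack([s, cgh.values]))[0, 1:])
            if thr_r is None:
                t_crit = stats.t.isf(0.05 / m / 2, n - 2)
                thr_r = np.sqrt(t_crit**2 / (t_crit**2 + n - 2))
            hits += (r.max() >= thr_r)
        assert hits / n_seeds <= 0.05

    def test_segment_outside_chromosome_rejected(self, cohort_setup):
        ann, clones, _ = cohort_setup
        bad = [FactorSpec(5, 1.0, "cis", ("chr21", 0, 9e9))]
        with pytest.raises(ValueError):
            simulate_factor_cohort(ann, 10, bad, 0.5, clones, 0.2, seed=0)


class TestPairedCohorts:
    def test_gene_variances_agree_at_large_n(self, cohort_setup):
        ann, clones, specs = cohort_setup
        expr_a, _, truth = simulate_factor_cohort(
            ann, 600, specs, 0.5, clones, 0.2, seed=8)
        expr_b, _, _ = simulate_paired_cohorts(truth, ann, clones, 600, seed=9)
        va = expr_a.values.var(axis=1)
        vb = expr_b.values.var(axis=1)
        # shared loadings + shared noise model => same per-gene variances
        assert np.median(np.abs(va - vb) / (va + vb)) < 0.12

    def test_noise_free_rank_one_rows_proportional(self):
        ann = simulate_annotation(30, [1e6], seed=10)
        specs = [FactorSpec(30, 1.0, "neutral")]
        expr_a, _, truth = simulate_factor_cohort(
            ann, 20, specs, 0.0, [("chr1", 5e5)], 0.0, seed=11)
        expr_b, _, _ = simulate_paired_cohorts(truth, ann, [("chr1", 5e5)], 15, seed=12)
        a = truth.loadings_true[:, 0]
        for X in (expr_a.values, expr_b.values):
            live = a != 0
            ratios = X[live] / a[live, None]
            np.testing.assert_allclose(
                ratios, np.broadcast_to(ratios[0], ratios.shape), atol=1e-9)

    def test_same_seed_reproduces_cohort_b(self, cohort_setup):
        ann, clones, specs = cohort_setup
        _, _, truth = simulate_factor_cohort(ann, 30, specs, 0.5, clones, 0.2, seed=13)
        b1, c1, _ = simulate_paired_cohorts(truth, ann, clones, 25, seed=14)
        b2, c2, _ = simulate_paired_cohorts(truth, ann, clones, 25, seed=14)
        np.testing.assert_array_equal(b1.values, b2.values)
        np.testing.assert_array_equal(c1.values, c2.values)

    def test_score_shift_moves_cohort_mean(self, cohort_setup):
        ann, clones, specs = cohort_setup
        _, _, truth = simulate_factor_cohort(ann, 30, specs, 0.5, clones, 0.2, seed=15)
        b_shift, _, tb = simulate_paired_cohorts(
            truth, ann, clones, 200, score_distribution_shift=2.0, seed=16)
        assert tb.scores_true.mean() > 1.0
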