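from itertools import combinations

import numpy as np
import pytest
from scipy.stats import pearsonr

from forkswitch.io import ExpressionMatrix
from forkswitch.search import (
    Bicluster,
    DegenerateScoreError,
    SeedSpec,
    build_seed_geneset,
    cluster_runs_silhouette,
    correlation_score,
    find_seed,
    refine_gene_set,
    run_ensemble,
    split_gene_groups,
)
from forkswitch.extension import CorrelationVector

from conftest import small_planted


def brute_force_score(matrix, genes, samples):
    """Textbook oracle: average the pairwise |r| one gene pair at a time."""
    X = matrix.submatrix(list(genes), list(samples))
    vals = [
        abs(pearsonr(X[i], X[j]).statistic)
        for i, j in combinations(range(X.shape[0]), 2)
    ]
    return float(np.mean(vals))


class TestCorrelationScore:
    def test_exact_affine_copy_scores_one(self, tiny_matrix):
        assert correlation_score(tiny_matrix, ["g1", "g2"], tiny_matrix.sample_ids) == pytest.approx(1.0)

    def test_negated_gene_scores_one_via_absolute_value(self, tiny_matrix):
        assert correlation_score(tiny_matrix, ["g1", "g3"], tiny_matrix.sample_ids) == pytest.approx(1.0)

    def test_matches_pairwise_oracle(self, rng):
        values = rng.normal(size=(5, 8))
        matrix = ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"s{j}" for j in range(8)], values
        )
        got = correlation_score(matrix, matrix.gene_ids, matrix.sample_ids)
        assert got == pytest.approx(
            brute_force_score(matrix, matrix.gene_ids, matrix.sample_ids), abs=1e-12
        )

    def test_permutation_invariance(self, rng):
        values = rng.normal(size=(6, 10))
        matrix = ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"s{j}" for j in range(10)], values
        )
        base = correlation_score(matrix, matrix.gene_ids, matrix.sample_ids)
        for _ in range(5):
            gperm = list(rng.permutation(matrix.gene_ids))
            sperm = list(rng.permutation(matrix.sample_ids))
            assert correlation_score(matrix, gperm, sperm) == pytest.approx(base, abs=1e-12)

    def test_zero_variance_gene_errors_naming_gene(self):
        matrix = ExpressionMatrix(
            ["flat", "g2"], ["s1", "s2", "s3"], np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        )
        with pytest.raises(DegenerateScoreError, match="flat"):
            correlation_score(matrix, ["flat", "g2"], matrix.sample_ids)

    @pytest.mark.parametrize(
        "genes,samples", [(["g1"], ["s1", "s2", "s3"]), (["g1", "g2"], ["s1", "s2"])]
    )
    def test_minimum_sizes_enforced(self, tiny_matrix, genes, samples):
        with pytest.raises(ValueError):
            correlation_score(tiny_matrix, genes, samples)


class TestSeedGenesets:
    def test_anchor_perfect_copy_ranks_first(self, tiny_matrix):
        spec = SeedSpec(mode="anchor_correlated", size=2, anchor="g1")
        assert set(build_seed_geneset(tiny_matrix, spec)) == {"g1", "g2"}

    def test_random_mode_is_deterministic(self, planted_small):
        matrix, _ = planted_small
        a = build_seed_geneset(matrix, SeedSpec(mode="random", size=30, rng_seed=5))
        b = build_seed_geneset(matrix, SeedSpec(mode="random", size=30, rng_seed=5))
        assert a == b
        c = build_seed_geneset(matrix, SeedSpec(mode="random", size=30, rng_seed=6))
        assert a != c

    def test_anchor_matches_brute_force_ranking(self, rng):
        values = rng.normal(size=(20, 15))
        matrix = ExpressionMatrix(
            [f"g{i:02d}" for i in range(20)], [f"s{j}" for j in range(15)], values
        )
        anchor = "g07"
        got = build_seed_geneset(
            matrix, SeedSpec(mode="anchor_correlated", size=5, anchor=anchor)
        )
        arow = matrix.submatrix([anchor])[0]
        corrs = {
            g: pearsonr(matrix.submatrix([g])[0], arow).statistic
            for g in matrix.gene_ids
        }
        expected = sorted(matrix.gene_ids, key=lambda g: -corrs[g])[:5]
        assert set(got) == set(expected)

    def test_explicit_mode_intersects_with_matrix(self, tiny_matrix):
        spec = SeedSpec(mode="explicit", genes=["g1", "gX", "g3"])
        assert build_seed_geneset(tiny_matrix, spec) == ["g1", "g3"]

    def test_anchor_absent_errors(self, tiny_matrix):
        with pytest.raises(ValueError, match="gX"):
            build_seed_geneset(
                tiny_matrix, SeedSpec(mode="anchor_correlated", size=2, anchor="gX")
            )

    def test_size_exceeding_gene_count_errors(self, tiny_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            build_seed_geneset(tiny_matrix, SeedSpec(mode="random", size=99))


class TestFindSeed:
    def test_m_equal_to_sample_count_returns_all_samples(self, planted_small):
        matrix, _ = planted_small
        genes = matrix.gene_ids[:20]
        run = find_seed(matrix, genes, m=matrix.n_samples, iterations=10, rng_seed=0)
        assert sorted(run.sample_seed) == sorted(matrix.sample_ids)
        assert len(run.trajectory) == 1  # nothing beyond the initial score

    def test_trajectory_non_decreasing_and_final_at_least_initial(self, planted_small):
        matrix, _ = planted_small
        run = find_seed(matrix, matrix.gene_ids[:40], m=8, iterations=200, rng_seed=1)
        traj = np.array(run.trajectory)
        assert np.all(np.diff(traj) > 0)
        assert run.score >= traj[0]
        assert run.score == pytest.approx(traj[-1])

    def test_reproducible_from_rng_seed(self, planted_small):
        matrix, _ = planted_small
        a = find_seed(matrix, matrix.gene_ids[:40], m=8, iterations=100, rng_seed=9)
        b = find_seed(matrix, matrix.gene_ids[:40], m=8, iterations=100, rng_seed=9)
        assert a.sample_seed == b.sample_seed
        assert a.trajectory == b.trajectory

    def test_final_score_beats_random_subset_mean(self, planted_small):
        matrix, _ = planted_small
        genes = matrix.gene_ids[:40]
        run = find_seed(matrix, genes, m=8, iterations=300, rng_seed=2)
        rng = np.random.default_rng(0)
        rand_scores = []
        for _ in range(20):
            subset = list(rng.choice(matrix.sample_ids, size=8, replace=False))
            rand_scores.append(correlation_score(matrix, genes, subset))
        assert run.score > np.mean(rand_scores)

    def test_greedy_restarts_attain_exhaustive_maximum_small(self):
        # 8 samples, planted 4-sample module: enumerate all C(8,4) subsets
        matrix, truth = small_planted(
            rng_seed=7, n_genes=10, n_samples=8, genes_per_group=3,
            samples_per_fork=2, effect=3.0,
        )
        genes = matrix.gene_ids
        best = max(
            correlation_score(matrix, genes, list(subset))
            for subset in combinations(matrix.sample_ids, 4)
        )
        greedy = max(
            find_seed(matrix, genes, m=4, iterations=150, rng_seed=s).score
            for s in range(20)
        )
        assert greedy == pytest.approx(best, abs=1e-12)

    def test_m_larger_than_cohort_errors(self, tiny_matrix):
        with pytest.raises(ValueError):
            find_seed(tiny_matrix, ["g1", "g2"], m=10, iterations=5, rng_seed=0)


class TestEnsemble:
    def test_same_base_seed_gives_identical_runs(self, planted_small):
        matrix, _ = planted_small
        specs = [SeedSpec(mode="random", size=30, rng_seed=1)]
        a = run_ensemble(matrix, specs, m=6, iterations=50, n_runs=3, base_rng_seed=4)
        b = run_ensemble(matrix, specs, m=6, iterations=50, n_runs=3, base_rng_seed=4)
        assert [r.sample_seed for r in a] == [r.sample_seed for r in b]
        assert [r.rng_seed for r in a] == [4, 5, 6]

    def test_single_run_reduces_to_find_seed(self, planted_small):
        matrix, _ = planted_small
        spec = SeedSpec(mode="random", size=30, rng_seed=1)
        genes = build_seed_geneset(matrix, spec)
        ens = run_ensemble(matrix, [spec], m=6, iterations=50, n_runs=1, base_rng_seed=11)
        direct = find_seed(matrix, genes, m=6, iterations=50, rng_seed=11)
        assert ens[0].sample_seed == direct.sample_seed
        assert ens[0].score == pytest.approx(direct.score)

    def test_most_runs_score_high_on_planted_data(self):
        matrix, truth = small_planted(rng_seed=5, n_samples=80, samples_per_fork=20)
        mod = truth.design.modules[0]
        spec = SeedSpec(mode="explicit", genes=mod.genes)
        runs = run_ensemble(matrix, [spec], m=8, iterations=300, n_runs=10, base_rng_seed=0)
        frac_high = np.mean([r.score > 0.5 for r in runs])
        assert frac_high >= 0.8


class TestSplitAndRefine:
    def test_split_copies_and_negations_exactly(self, rng):
        base = rng.normal(size=12)
        values = np.vstack([base, base + 1, -base, 2 - base])
        matrix = ExpressionMatrix(
            ["p1", "p2", "n1", "n2"], [f"s{j}" for j in range(12)], values
        )
        pos, neg = split_gene_groups(matrix, matrix.gene_ids, matrix.sample_ids)
        assert {tuple(sorted(pos)), tuple(sorted(neg))} == {("p1", "p2"), ("n1", "n2")}

    def test_split_on_planted_groups_matches_labels(self):
        matrix, truth = small_planted(rng_seed=11, n_samples=80, samples_per_fork=25)
        mod = truth.design.modules[0]
        pos, neg = split_gene_groups(matrix, mod.genes, mod.samples)
        match = max(
            len(set(pos) & set(mod.pos_genes)) + len(set(neg) & set(mod.neg_genes)),
            len(set(pos) & set(mod.neg_genes)) + len(set(neg) & set(mod.pos_genes)),
        ) / len(mod.genes)
        assert match >= 0.95

    def test_all_identical_genes_degenerate_warning(self, rng, caplog):
        base = rng.normal(size=10)
        values = np.vstack([base, base * 2 + 1, base * 0.5])
        matrix = ExpressionMatrix(["a", "b", "c"], [f"s{j}" for j in range(10)], values)
        with caplog.at_level("WARNING", logger="forkswitch"):
            pos, neg = split_gene_groups(matrix, matrix.gene_ids, matrix.sample_ids)
        assert neg == []
        assert sorted(pos) == ["a", "b", "c"]
        assert "degenerate" in caplog.text

    def test_refine_drops_least_coherent_fraction(self, planted_small):
        matrix, truth = planted_small
        mod = truth.design.modules[0]
        genes = mod.genes + matrix.gene_ids[-10:]  # coherent module + noise
        kept = refine_gene_set(matrix, genes, mod.samples, drop_fraction=0.25)
        assert len(kept) == len(genes) - 10
        dropped = set(genes) - set(kept)
        assert len(dropped & set(matrix.gene_ids[-10:])) >= 8


def _flat_cv(matrix, values):
    return CorrelationVector("", list(matrix.gene_ids), values, [matrix.gene_ids[0]])


class TestSilhouetteConsolidation:
    def test_identical_cvs_collapse_to_single_cluster(self, planted_small):
        matrix, truth = planted_small
        mod = truth.design.modules[0]
        runs = run_ensemble(
            matrix, [SeedSpec(mode="explicit", genes=mod.genes)],
            m=6, iterations=100, n_runs=3, base_rng_seed=0,
        )
        rng = np.random.default_rng(0)
        cv = np.clip(rng.normal(size=matrix.n_genes), -1, 1)
        cvs = [_flat_cv(matrix, cv.copy()) for _ in runs]
        bics = cluster_runs_silhouette(matrix, runs, cvs, k_max=3, min_sil=0.25)
        assert len(bics) == 1
        assert bics[0].score == pytest.approx(max(r.score for r in runs))

    def test_sign_flipped_cv_counts_as_same_bicluster(self, planted_small):
        matrix, truth = planted_small
        mod = truth.design.modules[0]
        runs = run_ensemble(
            matrix, [SeedSpec(mode="explicit", genes=mod.genes)],
            m=6, iterations=100, n_runs=2, base_rng_seed=0,
        )
        rng = np.random.default_rng(1)
        cv = np.clip(rng.normal(size=matrix.n_genes), -1, 1)
        cvs = [_flat_cv(matrix, cv.copy()), _flat_cv(matrix, -cv)]
        bics = cluster_runs_silhouette(matrix, runs, cvs, k_max=3, min_sil=0.25)
        assert len(bics) == 1

    def test_two_orthogonal_modules_recovered_as_two_clusters(self):
        from forkswitch.simulate import generate_planted_data, two_module_design

        design = two_module_design(
            shared_lf=False, rng_seed=2, n_genes=300, n_samples=80,
            genes_per_group=20, samples_per_fork=15,
        )
        matrix, truth = generate_planted_data(design)
        runs, cvs = [], []
        rng = np.random.default_rng(0)
        for mi, mod in enumerate(design.modules):
            for ri in range(10):
                run = find_seed(
                    matrix, mod.genes, m=8, iterations=150, rng_seed=mi * 100 + ri,
                    run_id=f"m{mi}r{ri}",
                )
                runs.append(run)
                signal = np.zeros(matrix.n_genes)
                signal[matrix.gene_rows(mod.pos_genes)] = 0.9
                signal[matrix.gene_rows(mod.neg_genes)] = -0.9
                noise = rng.normal(scale=0.05, size=matrix.n_genes)
                cvs.append(_flat_cv(matrix, np.clip(signal + noise, -1, 1)))
        bics = cluster_runs_silhouette(matrix, runs, cvs, k_max=6, min_sil=0.25)
        assert len(bics) == 2
        found_gene_sets = [set(b.gene_set) for b in bics]
        for mod in design.modules:
            overlaps = [len(set(mod.genes) & fs) / len(fs) for fs in found_gene_sets]
            assert max(overlaps) > 0.85

    def test_k_max_below_two_errors(self, planted_small):
        matrix, truth = planted_small
        with pytest.raises(ValueError):
            cluster_runs_silhouette(matrix, [], [], k_max=1)

    def test_mismatched_gene_universe_errors(self, planted_small):
        matrix, truth = planted_small
        mod = truth.design.modules[0]
        runs = run_ensemble(
            matrix, [SeedSpec(mode="explicit", genes=mod.genes)],
            m=6, iterations=20, n_runs=2, base_rng_seed=0,
        )
        good = _flat_cv(matrix, np.zeros(matrix.n_genes))
        bad = CorrelationVector("", ["x", "y"], np.zeros(2), ["x"])
        with pytest.raises(ValueError, match="universe"):
            cluster_runs_silhouette(matrix, runs, [good, bad], k_max=3)
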