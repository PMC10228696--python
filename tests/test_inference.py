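"""Clone-deconvolution engine: frequency regression, pruning, ancestral and
hybrid searches, and full-pipeline recovery on noise-free and simulated
data."""

import numpy as np
import pytest

from cloneboot import (GenotypeMatrix, ReadCountTable, RunConfig, VAFMatrix,
                       decompose_hybrids, eq1_residual, estimate_frequencies,
                       finalize, genotype_error, infer_ancestral_clones,
                       pool_and_filter, prune_low_frequency,
                       deconvolve_clones, simulate_reads, simulate_truth)
from cloneboot.inference import qc_snv_mask
from cloneboot.trees import build_tree


def geno(rows, ids=None, snvs=None):
    ids = ids or [f"c{i}" for i in range(len(rows))]
    snvs = snvs or [f"s{j}" for j in range(len(rows[0]))]
    return GenotypeMatrix(ids, snvs, [[int(ch) for ch in r] for r in rows])


def vaf(values, snvs=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    snvs = snvs or [f"s{j}" for j in range(values.shape[1])]
    return VAFMatrix([f"S{i}" for i in range(values.shape[0])], snvs, values)


class TestEstimateFrequencies:
    def test_two_clone_hand_solution(self):
        # (1/2)(f1 [1,0] + f2 [1,1]) = [0.5, 0.3]  =>  f2 = 0.6, f1 = 0.4
        f = estimate_frequencies(geno(["10", "11"]), vaf([0.5, 0.3]))
        assert np.allclose(f.values, [[0.4, 0.6]], atol=1e-8)

    def test_zero_vafs_give_zero_frequencies(self):
        f = estimate_frequencies(geno(["10", "11"]), vaf([0.0, 0.0]))
        assert np.allclose(f.values, 0.0)

    def test_exact_recovery_of_forward_simulated_frequencies(self, rng):
        # V constructed exactly as (1/2) f M with full-row-rank M
        M = geno(["1000", "1100", "1110", "1111"])
        f_true = np.array([[0.4, 0.3, 0.2, 0.1], [0.1, 0.2, 0.3, 0.4]])
        V = vaf(0.5 * f_true @ M.state)
        f = estimate_frequencies(M, V)
        assert np.allclose(f.values, f_true, atol=1e-6)

    def test_constraints_always_hold(self, rng):
        for _ in range(20):
            state = rng.integers(0, 2, size=(4, 6))
            state[state.sum(axis=1) == 0, 0] = 1
            M = GenotypeMatrix([f"c{i}" for i in range(4)],
                               [f"s{j}" for j in range(6)], state)
            M = M.dedup()
            V = vaf(rng.uniform(0, 1, size=(3, 6)))
            f = estimate_frequencies(M, V)
            assert (f.values >= 0).all()
            assert (f.values.sum(axis=1) <= 1 + 1e-6).all()

    def test_adding_clones_never_raises_residual(self, rng):
        M1 = geno(["1000", "1100"])
        M2 = geno(["1000", "1100", "1110"])
        V = vaf(rng.uniform(0, 0.5, size=(2, 4)))
        r1 = eq1_residual(M1, estimate_frequencies(M1, V), V)
        r2 = eq1_residual(M2, estimate_frequencies(M2, V), V)
        assert r2 <= r1 + 1e-9


class TestPruneLowFrequency:
    def setup_method(self):
        self.M = geno(["10", "11"])
        self.V = vaf([[0.5, 0.002]])

    def test_clone_below_threshold_removed(self):
        f = estimate_frequencies(self.M, self.V)
        M2, f2 = prune_low_frequency(self.M, f, self.V, 0.01)
        assert M2.clone_ids == ["c0"]

    def test_all_above_threshold_unchanged(self):
        M = geno(["10", "11"])
        V = vaf([[0.5, 0.2]])
        f = estimate_frequencies(M, V)
        M2, _ = prune_low_frequency(M, f, V, 0.01)
        assert M2.clone_ids == M.clone_ids

    def test_exactly_at_threshold_retained(self):
        # the rule is strictly "lower than": a 1% clone at threshold 1% stays
        from cloneboot import FrequencyMatrix
        M = geno(["10", "01"])
        f = FrequencyMatrix(["S0"], M.clone_ids, [[0.5, 0.01]])
        V = vaf([[0.25, 0.005]])
        M2, _ = prune_low_frequency(M, f, V, 0.01)
        assert M2.n_clones == 2


class TestPoolAndFilter:
    def make_counts(self):
        # s1 passes QC everywhere; s2 fails (ref max 49)
        return ReadCountTable(["S1", "S2"], ["s1", "s2"],
                              ref=[[60, 49], [70, 30]],
                              alt=[[10, 5], [12, 6]])

    def test_duplicates_removed(self):
        counts = self.make_counts()
        cands = [geno(["11"], ids=["a"], snvs=["s1", "s2"]),
                 geno(["11"], ids=["b"], snvs=["s1", "s2"])]
        pooled = pool_and_filter(cands, counts, RunConfig())
        assert pooled.n_clones == 1

    def test_qc_mask_respects_read_thresholds(self):
        counts = self.make_counts()
        mask = qc_snv_mask(counts, 50, 2)
        assert mask.tolist() == [True, False]

    def test_single_candidate_returned_unchanged(self):
        counts = self.make_counts()
        pooled = pool_and_filter([geno(["10"], snvs=["s1", "s2"])],
                                 counts, RunConfig())
        assert pooled.row_tuples() == [(1, 0)]

    def test_candidate_without_unique_qc_snv_dropped(self):
        # the stray candidate carries only a shared SNV (s2) and one that
        # fails QC (s3); it is no subset of another candidate -> spurious
        counts = ReadCountTable(["S1"], ["s1", "s2", "s3"],
                                ref=[[60, 70, 40]], alt=[[10, 12, 5]])
        cands = [geno(["110"], ids=["a"], snvs=counts.snv_ids),
                 geno(["011"], ids=["stray"], snvs=counts.snv_ids)]
        pooled = pool_and_filter(cands, counts, RunConfig())
        assert (0, 1, 1) not in pooled.row_tuples()
        assert (1, 1, 0) in pooled.row_tuples()


class TestAncestralClones:
    def test_missing_intermediate_proposed(self):
        M = geno(["110", "101"])
        tree = build_tree(M)
        M2 = infer_ancestral_clones(tree, M)
        assert (1, 0, 0) in M2.row_tuples()

    def test_no_additions_when_ancestor_observed(self):
        M = geno(["100", "110", "101"])
        tree = build_tree(M)
        M2 = infer_ancestral_clones(tree, M)
        assert M2.row_tuples() == M.row_tuples()


class TestDecomposeHybrids:
    def test_exact_model_fit_is_fixpoint(self):
        M = geno(["1111"])
        f_true = np.array([[0.5], [0.5]])
        V = vaf(0.5 * f_true @ M.state)
        f = estimate_frequencies(M, V)
        assert decompose_hybrids(M, V, f, 0.01).row_tuples() == M.row_tuples()

    def test_merged_clones_recovered_by_split(self):
        # truth: clones {s1,s2} and {s3,s4} with opposite frequencies in
        # two samples, but the candidate set merged them into one genotype
        M_true = geno(["1100", "0011"])
        f_true = np.array([[0.8, 0.2], [0.2, 0.8]])
        V = vaf(0.5 * f_true @ M_true.state)
        M = geno(["1111"])
        f = estimate_frequencies(M, V)
        M2 = decompose_hybrids(M, V, f, 0.01)
        assert (1, 1, 0, 0) in M2.row_tuples()
        assert (0, 0, 1, 1) in M2.row_tuples()


class TestFinalize:
    def test_no_unassigned_snvs_leaves_genotypes_unchanged(self):
        M = geno(["10", "11"])
        V = vaf([[0.5, 0.3]])
        f = estimate_frequencies(M, V)
        pred = finalize(M, f, V)
        assert sorted(pred.genotypes.row_tuples()) == sorted(M.row_tuples())

    def test_exact_profile_match_assigned_to_that_clone(self):
        M = geno(["100", "010"])
        from cloneboot import FrequencyMatrix
        f = FrequencyMatrix(["S0", "S1"], M.clone_ids,
                            [[0.6, 0.2], [0.2, 0.6]])
        # s3's observed VAFs equal clone c1's expected profile exactly
        V = vaf([[0.3, 0.1, 0.1], [0.1, 0.3, 0.3]])
        pred = finalize(M, f, V)
        rows = {tuple(r) for r in pred.genotypes.state}
        assert (0, 1, 1) in rows

    def test_tie_broken_toward_higher_mean_frequency(self):
        M = geno(["100", "010"])
        from cloneboot import FrequencyMatrix
        f = FrequencyMatrix(["S0", "S1"], M.clone_ids,
                            [[0.7, 0.2], [0.2, 0.5]])
        exp1 = 0.5 * f.values[:, 0]
        exp2 = 0.5 * f.values[:, 1]
        mid = (exp1 + exp2) / 2  # exactly equidistant profiles
        V = vaf(np.column_stack([exp1, exp2, mid]))
        pred = finalize(M, f, V)
        rows = {tuple(r) for r in pred.genotypes.state}
        assert (1, 0, 1) in rows  # c0 has the higher mean frequency


class TestFullEngine:
    def test_noise_free_identifiable_instance_recovered_exactly(self):
        # exhaustively checkable scale: 4 clones, 8 SNVs, distinct profiles
        M_true = geno(["10000000", "11100000", "11111000", "11111111"])
        f_true = np.array([[0.40, 0.30, 0.20, 0.10],
                           [0.05, 0.15, 0.30, 0.50],
                           [0.70, 0.10, 0.10, 0.10]])
        V = vaf(0.5 * f_true @ M_true.state)
        depth = 100_000
        counts = ReadCountTable(
            V.sample_ids, V.snv_ids,
            ref=np.round(depth * (1 - V.values)).astype(int),
            alt=np.round(depth * V.values).astype(int))
        pred = deconvolve_clones(counts, RunConfig(qc_min_ref=1))
        assert sorted(pred.genotypes.row_tuples()) == sorted(M_true.row_tuples())

    def test_single_clone_dataset(self):
        counts = ReadCountTable(["S1"], ["s1", "s2"],
                                ref=[[60, 55]], alt=[[40, 45]])
        pred = deconvolve_clones(counts, RunConfig(qc_min_ref=10))
        assert pred.genotypes.row_tuples() == [(1, 1)]
        mean_vaf = counts.vaf().values.mean()
        assert pred.frequencies.values[0, 0] == pytest.approx(2 * mean_vaf,
                                                              abs=0.02)

    def test_high_depth_simulation_recovered(self):
        truth = simulate_truth(3, 9, 2, "monoclonal", seed=0)
        # the exact-recovery guarantee holds for clearly separated clones
        assert (truth.frequencies.values.max(axis=0) > 0.15).all()
        counts = simulate_reads(truth, seed=100, depth_range=(1000, 1000))
        pred = deconvolve_clones(counts, RunConfig(rng_seed=1))
        report = genotype_error(truth.genotypes, pred.genotypes)
        assert report.dataset_ge == 0.0

    def test_engine_deterministic(self):
        truth = simulate_truth(5, 20, 3, "monoclonal", seed=3)
        counts = simulate_reads(truth, seed=4)
        p1 = deconvolve_clones(counts, RunConfig(rng_seed=1))
        p2 = deconvolve_clones(counts, RunConfig(rng_seed=1))
        assert p1.genotypes.row_tuples() == p2.genotypes.row_tuples()
        assert np.allclose(p1.frequencies.values, p2.frequencies.values)

    @pytest.mark.parametrize("n_clones,n_snvs,n_samples,seeding", [
        (6, 9, 5, "monoclonal"),
        (12, 40, 5, "polyclonal"),
        (16, 60, 8, "monoclonal"),
        (26, 99, 8, "polyclonal"),
    ])
    def test_simulation_grid_completes(self, n_clones, n_snvs, n_samples,
                                       seeding):
        truth = simulate_truth(n_clones, n_snvs, n_samples, seeding, seed=11)
        counts = simulate_reads(truth, seed=12)
        pred = deconvolve_clones(counts, RunConfig(rng_seed=2))
        assert pred.genotypes.n_clones >= 1
        assert (pred.frequencies.values.sum(axis=1) <= 1 + 1e-6).all()
        # every SNV assigned somewhere after finalisation
        assert (pred.genotypes.state == 1).any(axis=0).all()
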