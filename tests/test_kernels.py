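import itertools

import numpy as np
import pytest

from morphgreml.datatypes import RelatednessMatrix
from morphgreml.kernels import (GenotypePCA, NotPositiveDefiniteError,
                                bend_to_pd, core_product, genotype_pcs,
                                offdiag_correlation,
                                prune_by_relatedness,
                                relatedness_from_matrix, standardize_columns)
from morphgreml.simulate import SimulationConfig, simulate_genotypes

from conftest import random_pd_matrix


class TestStandardize:
    def test_three_point_column(self):
        Z = standardize_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z.ravel(), [-1.22474487, 0.0, 1.22474487],
                                   atol=1e-8)

    def test_constant_column_dropped_with_warning(self):
        M = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, kept = standardize_columns(M, return_kept=True)
        assert Z.shape == (3, 1)
        assert kept.tolist() == [1]

    def test_population_moments(self, rng):
        Z = standardize_columns(rng.normal(3, 5, size=(50, 10)))
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)


class TestRelatednessFromMatrix:
    def test_two_subject_outer_product(self):
        rm = relatedness_from_matrix(np.array([[-1.0], [1.0]]), "GRM")
        np.testing.assert_allclose(rm.values, [[1, -1], [-1, 1]])

    def test_identical_rows_share_diagonal_value(self, rng):
        row = rng.standard_normal(20)
        M = np.vstack([row, row, rng.standard_normal(20)])
        rm = relatedness_from_matrix(M, "BRM")
        assert rm.values[0, 1] == pytest.approx(rm.values[0, 0])

    def test_matches_double_loop_oracle_and_unit_trace(self, rng):
        Z = standardize_columns(rng.standard_normal((30, 200)))
        rm = relatedness_from_matrix(Z, "GRM")
        oracle = np.empty((30, 30))
        for i in range(30):
            for j in range(30):
                oracle[i, j] = np.dot(Z[i], Z[j]) / 200
        np.testing.assert_allclose(rm.values, oracle, atol=1e-10)
        assert np.trace(rm.values) / 30 == pytest.approx(1.0, abs=1e-8)

    def test_invariant_to_marker_order(self, rng):
        Z = standardize_columns(rng.standard_normal((15, 40)))
        perm = rng.permutation(40)
        np.testing.assert_allclose(relatedness_from_matrix(Z, "GRM").values,
                                   relatedness_from_matrix(Z[:, perm], "GRM").values,
                                   atol=1e-12)


class TestPruning:
    @staticmethod
    def _rm(values):
        n = values.shape[0]
        return RelatednessMatrix(np.array([f"s{i}" for i in range(1, n + 1)]),
                                 values, "GRM")

    def test_single_related_pair_drops_later_subject(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.6
        kept = prune_by_relatedness(self._rm(vals), 0.05)
        assert kept.tolist() == ["s1", "s3"]

    def test_unrelated_sample_untouched(self, rng):
        vals = np.eye(6) + 0.01 * random_pd_matrix(rng, 6, jitter=0)
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        assert prune_by_relatedness(self._rm(vals), 0.05).size == 6

    def test_planted_cliques_match_exhaustive_maximum(self, rng):
        """Greedy pruning retains a maximum unrelated set on clique-structured
        relatedness, checked against brute force over all 2^8 subsets."""
        for trial in range(10):
            n = 8
            vals = 0.02 * rng.uniform(-1, 1, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 1.0)
            sizes = [2, 3]
            members = rng.permutation(n)[:sum(sizes)]
            start = 0
            for size in sizes:
                clique = members[start:start + size]
                for a, b in itertools.combinations(clique, 2):
                    vals[a, b] = vals[b, a] = rng.uniform(0.1, 0.5)
                start += size
            rm = self._rm(vals)
            kept = prune_by_relatedness(rm, 0.05)
            idx = {s: i for i, s in enumerate(rm.subject_ids)}
            kept_idx = [idx[s] for s in kept]
            adj = vals >= 0.05
            np.fill_diagonal(adj, False)
            assert not adj[np.ix_(kept_idx, kept_idx)].any()
            best = 0
            for mask in itertools.product([0, 1], repeat=n):
                sel = [i for i in range(n) if mask[i]]
                if not adj[np.ix_(sel, sel)].any():
                    best = max(best, len(sel))
            assert len(kept) == best


class TestBending:
    def test_identity_unchanged(self):
        rm = RelatednessMatrix(np.array(["a", "b"]), np.eye(2), "GRM")
        assert bend_to_pd(rm) is rm

    def test_negative_eigenvalue_lifted_to_floor(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        eig = np.array([-0.1, 0.2, 0.5, 1.0, 1.5, 2.0])
        vals = (Q * eig) @ Q.T
        vals = (vals + vals.T) / 2
        rm = RelatednessMatrix(np.array([f"s{i}" for i in range(6)]), vals, "GRM")
        bent = bend_to_pd(rm)
        floor = 1e-6 * eig.mean()
        out_eig = np.linalg.eigvalsh(bent.values)
        assert out_eig.min() >= floor * 0.99
        # eigenvalue clipping perturbs by at most the lifted amount
        spectral = np.linalg.norm(bent.values - vals, 2)
        assert spectral <= abs(eig.min()) + floor + 1e-10

    def test_idempotent(self, rng):
        A = rng.standard_normal((8, 8))
        vals = (A + A.T) / 2
        rm = RelatednessMatrix(np.array([f"s{i}" for i in range(8)]), vals, "GRM")
        bent = bend_to_pd(rm)
        again = bend_to_pd(bent)
        np.testing.assert_allclose(again.values, bent.values, atol=1e-12)


class TestCore:
    @staticmethod
    def _rm(values, kind="GRM"):
        n = values.shape[0]
        return RelatednessMatrix(np.array([f"s{i}" for i in range(n)]), values, kind)

    def test_identity_inputs_give_twice_identity(self):
        core = core_product(self._rm(np.eye(4)), self._rm(np.eye(4), "BRM"))
        np.testing.assert_array_equal(core.values, 2 * np.eye(4))
        assert core.kind == "CORE"

    def test_equal_inputs_give_twice_input(self, rng):
        A = random_pd_matrix(rng, 5)
        core = core_product(self._rm(A), self._rm(A, "BRM"))
        np.testing.assert_allclose(core.values, 2 * A, rtol=1e-12, atol=1e-12)

    def test_matches_explicit_triangular_factors(self, rng):
        A, B = random_pd_matrix(rng, 6), random_pd_matrix(rng, 6)
        core = core_product(self._rm(A), self._rm(B, "BRM"))
        L_a, L_b = np.linalg.cholesky(A), np.linalg.cholesky(B)
        np.testing.assert_allclose(core.values, L_a @ L_b.T + L_b @ L_a.T,
                                   atol=1e-10)
        # exactly symmetric: model fitting needs no re-symmetrization
        np.testing.assert_array_equal(core.values, core.values.T)

    def test_indefinite_input_instructs_bending(self, rng):
        A = random_pd_matrix(rng, 4)
        bad = A - 2 * np.linalg.eigvalsh(A).max() * np.eye(4)
        with pytest.raises(NotPositiveDefiniteError, match="bend"):
            core_product(self._rm(bad), self._rm(A, "BRM"))


class TestOffdiagCorrelation:
    @staticmethod
    def _rm(values, kind="GRM"):
        n = values.shape[0]
        return RelatednessMatrix(np.array([f"s{i}" for i in range(n)]), values, kind)

    def test_self_correlation_is_one(self, rng):
        A = random_pd_matrix(rng, 10)
        res = offdiag_correlation(self._rm(A), self._rm(A, "BRM"))
        assert res.r == pytest.approx(1.0)
        assert res.n_pairs == 45

    def test_matches_vectorised_oracle(self, rng):
        A, B = random_pd_matrix(rng, 50), random_pd_matrix(rng, 50)
        res = offdiag_correlation(self._rm(A), self._rm(B, "BRM"))
        i, j = np.tril_indices(50, k=-1)
        oracle = np.corrcoef(A[i, j], B[i, j])[0, 1]
        assert res.r == pytest.approx(oracle, abs=1e-12)
        assert res.ci_low < res.r < res.ci_high

    def test_constant_offdiagonals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            offdiag_correlation(self._rm(np.eye(4)), self._rm(np.eye(4), "BRM"))


class TestGenotypePCA:
    def test_scores_orthogonal_and_match_svd_oracle(self, rng):
        geno = simulate_genotypes(SimulationConfig(
            n_subjects=60, n_snps=150, seed=5))
        scores = genotype_pcs(geno, k=4)
        cross = scores.T @ scores
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-8
        Z = standardize_columns(geno.imputed())
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        oracle = U[:, :4] * s[:4]
        for k in range(4):
            sign = np.sign(oracle[:, k] @ scores[:, k])
            np.testing.assert_allclose(scores[:, k], sign * oracle[:, k],
                                       atol=1e-8)
        # variances decrease with component order
        v = scores.var(axis=0)
        assert np.all(np.diff(v) <= 1e-12)

    def test_rank_deficit_returns_available_components_with_warning(self, rng):
        geno = simulate_genotypes(SimulationConfig(n_subjects=5, n_snps=30, seed=1))
        with pytest.warns(UserWarning, match="rank"):
            scores = genotype_pcs(geno, k=10)
        assert scores.shape[1] <= 5

    def test_first_axis_separates_planted_subpopulations(self, rng):
        """Two subpopulations with drifted allele frequencies split on PC1."""
        n, m = 120, 400
        p1 = rng.uniform(0.1, 0.5, size=m)
        drift = np.clip(p1 + rng.choice([-0.2, 0.2], size=m), 0.05, 0.95)
        counts = np.vstack([
            rng.binomial(2, p1, size=(n // 2, m)),
            rng.binomial(2, drift, size=(n // 2, m)),
        ]).astype(np.int8)
        from morphgreml.datatypes import GenotypeMatrix
        geno = GenotypeMatrix(np.array([f"s{i}" for i in range(n)]),
                              np.array([f"rs{j}" for j in range(m)]), counts)
        pc1 = genotype_pcs(geno, k=2)[:, 0]
        a, b = pc1[: n // 2], pc1[n // 2:]
        pooled_sd = np.sqrt((a.var() + b.var()) / 2)
        assert abs(a.mean() - b.mean()) > 3 * pooled_sd

    def test_transform_reproduces_fit_scores(self, rng):
        geno = simulate_genotypes(SimulationConfig(n_subjects=40, n_snps=100, seed=2))
        pca = GenotypePCA(n_components=3).fit(geno)
        np.testing.assert_allclose(pca.transform(geno), pca.scores_, atol=1e-8)


def test_grm_trace_normalisation(small_cohort):
    grm = small_cohort.grm
    assert np.trace(grm.values) / grm.n_subjects == pytest.approx(1.0, abs=1e-8)
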