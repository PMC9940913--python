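"""In-silico perturbation couplings, aggregation, structural estimator."""

import numpy as np
import pytest
from scipy import stats as sps

from crbm import connectivity as C, model as M
from crbm.io import MorphologySet, RegionAnnotation
from crbm.model import CRBMParams

from conftest import quadratic_params, random_params


def brute_force_local_coupling(v, i, j, params):
    """Independent oracle: the four conditionals from the raw marginal."""

    def logf(vi, vj):
        w = v.copy().astype(float)
        w[i], w[j] = vi, vj
        return M.marginal_log_unnormalized(w, params)

    return (logf(1, 1) - logf(0, 1)) - (logf(1, 0) - logf(0, 0))


class TestLocalCoupling:
    def test_independent_model_gives_zero(self):
        p = CRBMParams(weights=np.zeros((5, 2)), g=np.random.default_rng(0).normal(size=5),
                       gamma_plus=[1, 1], gamma_minus=[1, 1],
                       theta_plus=[0, 0], theta_minus=[0, 0])
        v = np.array([1, 0, 1, 1, 0], dtype=float)
        for i in range(5):
            for j in range(i + 1, 5):
                assert C.local_coupling(v, i, j, p) == pytest.approx(0.0)

    def test_quadratic_model_couplings_are_constant_hopfield(self):
        p = quadratic_params(6, 2, seed=3)
        J_ref = (p.weights / p.gamma_plus) @ p.weights.T
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = (rng.random(6) < 0.5).astype(float)
            assert C.local_coupling(v, 0, 3, p) == pytest.approx(J_ref[0, 3],
                                                                 rel=1e-9)

    def test_matches_bruteforce_conditionals(self):
        p = random_params(8, 3, seed=5)
        rng = np.random.default_rng(1)
        for _ in range(5):
            v = (rng.random(8) < 0.4).astype(float)
            i, j = rng.choice(8, size=2, replace=False)
            got = C.local_coupling(v, int(i), int(j), p)
            ref = brute_force_local_coupling(v, int(i), int(j), p)
            assert got == pytest.approx(float(ref), rel=1e-9, abs=1e-11)

    def test_symmetry_in_i_and_j(self):
        p = random_params(6, 2, seed=6)
        v = np.array([1, 1, 0, 0, 1, 0], dtype=float)
        assert C.local_coupling(v, 1, 4, p) == pytest.approx(
            C.local_coupling(v, 4, 1, p)
        )

    def test_self_coupling_rejected(self, small_params):
        with pytest.raises(ValueError):
            C.local_coupling(np.zeros(8), 2, 2, small_params)


class TestCouplingMatrices:
    def test_zero_weights_give_zero_matrices(self, rng):
        p = CRBMParams(weights=np.zeros((6, 2)), g=np.zeros(6),
                       gamma_plus=[1, 1], gamma_minus=[1, 1],
                       theta_plus=[0, 0], theta_minus=[0, 0])
        v = (rng.random((6, 50)) < 0.3).astype(int)
        assert np.all(C.coupling_matrix_exact(v, p).values == 0)
        assert np.all(C.coupling_matrix_fast(v, p).values == 0)

    def test_fast_single_unit_arithmetic(self):
        # M=1, w_i=1, w_j=2, quadratic gamma=2: Gamma'' = 1/2 constant
        p = CRBMParams(weights=np.array([[1.0], [2.0]]), g=np.zeros(2),
                       gamma_plus=[2.0], gamma_minus=[2.0],
                       theta_plus=[0.0], theta_minus=[0.0])
        v = np.array([[0, 1], [1, 0]], dtype=int)
        J = C.coupling_matrix_fast(v, p)
        assert J.values[0, 1] == pytest.approx(1.0)

    def test_exact_equals_fast_on_quadratic_models(self, rng):
        p = quadratic_params(10, 3, seed=4)
        v = (rng.random((10, 100)) < 0.3).astype(int)
        Je = C.coupling_matrix_exact(v, p)
        Jf = C.coupling_matrix_fast(v, p)
        assert np.max(np.abs(Je.values - Jf.values)) < 1e-8

    def test_exact_matches_framewise_bruteforce(self, rng):
        p = random_params(6, 2, seed=7)
        v = (rng.random((6, 20)) < 0.4).astype(int)
        J = C.coupling_matrix_exact(v, p)
        for i, j in [(0, 3), (2, 5)]:
            ref = np.mean([
                brute_force_local_coupling(v[:, t].astype(float), i, j, p)
                for t in range(v.shape[1])
            ])
            assert J.values[i, j] == pytest.approx(float(ref), rel=1e-9)

    def test_fast_correlates_with_exact_on_generic_models(self, rng):
        p = random_params(10, 3, seed=9, weight_scale=0.6)
        v = (rng.random((10, 150)) < 0.3).astype(int)
        Je = C.coupling_matrix_exact(v, p).values
        Jf = C.coupling_matrix_fast(v, p).values
        iu = np.triu_indices(10, k=1)
        r = np.corrcoef(Je[iu], Jf[iu])[0, 1]
        assert r > 0.95

    def test_budget_guard(self, rng):
        p = random_params(10, 3, seed=9)
        v = (rng.random((10, 50)) < 0.3).astype(int)
        with pytest.raises(ValueError, match="budget"):
            C.coupling_matrix_exact(v, p, budget=10)


class TestRegionAggregate:
    def _matrix(self, values):
        labels = [str(i) for i in range(values.shape[0])]
        return C.ConnectivityMatrix(values=values, level="neuron",
                                    labels=labels, provenance="crbm_fast")

    def test_single_region_mean_abs_offdiagonal(self, rng):
        J = rng.normal(size=(6, 6))
        J = J + J.T
        np.fill_diagonal(J, 0.0)
        ann = RegionAnnotation(membership=np.ones((1, 6), dtype=int),
                               region_names=["all"])
        out = C.region_aggregate(self._matrix(J), ann, min_neurons=1)
        iu = np.triu_indices(6, k=1)
        assert out.values[0, 0] == pytest.approx(np.abs(J[iu]).mean())

    def test_block_constant_between_regions(self):
        J = np.zeros((10, 10))
        J[:5, 5:] = 0.3
        J[5:, :5] = 0.3
        ann = RegionAnnotation(
            membership=np.vstack([np.r_[np.ones(5), np.zeros(5)],
                                  np.r_[np.zeros(5), np.ones(5)]]).astype(int),
            region_names=["A", "B"])
        out = C.region_aggregate(self._matrix(J), ann)
        assert out.values[0, 1] == pytest.approx(0.3)
        assert out.values[0, 0] == pytest.approx(0.0)

    def test_matches_double_loop(self, rng):
        J = rng.normal(size=(9, 9))
        J = J + J.T
        np.fill_diagonal(J, 0.0)
        mem = np.zeros((2, 9), dtype=int)
        mem[0, :5] = 1
        mem[1, 5:] = 1
        ann = RegionAnnotation(membership=mem, region_names=["A", "B"])
        out = C.region_aggregate(self._matrix(J), ann, min_neurons=2)
        ref = np.mean([abs(J[i, j]) for i in range(5) for j in range(5, 9)])
        assert out.values[0, 1] == pytest.approx(ref)

    def test_small_regions_dropped(self, rng):
        J = rng.normal(size=(8, 8))
        J = J + J.T
        np.fill_diagonal(J, 0.0)
        mem = np.zeros((2, 8), dtype=int)
        mem[0, :6] = 1
        mem[1, 6:] = 1  # only 2 neurons
        ann = RegionAnnotation(membership=mem, region_names=["big", "small"])
        out = C.region_aggregate(self._matrix(J), ann, min_neurons=5)
        assert out.labels == ["big"]


class TestSpecimenAverage:
    def _region(self, values, labels):
        return C.ConnectivityMatrix(values=values, level="region",
                                    labels=labels, provenance="crbm_fast")

    def test_single_specimen_identity(self):
        m = self._region(np.array([[0.0, 1.0], [1.0, 0.0]]), ["A", "B"])
        out = C.specimen_average([m], [100], [{"A": 5, "B": 7}])
        np.testing.assert_allclose(out.values, m.values)

    def test_equal_weights_plain_mean(self):
        m1 = self._region(np.array([[0.0, 1.0], [1.0, 0.0]]), ["A", "B"])
        m2 = self._region(np.array([[0.0, 3.0], [3.0, 0.0]]), ["A", "B"])
        out = C.specimen_average([m1, m2], [100, 100],
                                 [{"A": 5, "B": 5}, {"A": 5, "B": 5}])
        assert out.values[0, 1] == pytest.approx(2.0)

    def test_hand_computed_weighted_mean(self):
        # specimen 1: T=100, N_A=10, N_B=20 -> weight 100*(30)/2 = 1500
        # specimen 2: T=200, N_A=5,  N_B=5  -> weight 200*(10)/2 = 1000
        m1 = self._region(np.array([[0.0, 2.0], [2.0, 0.0]]), ["A", "B"])
        m2 = self._region(np.array([[0.0, 7.0], [7.0, 0.0]]), ["A", "B"])
        out = C.specimen_average([m1, m2], [100, 200],
                                 [{"A": 10, "B": 20}, {"A": 5, "B": 5}])
        expected = (1500 * 2.0 + 1000 * 7.0) / 2500
        assert out.values[0, 1] == pytest.approx(expected)

    def test_all_masked_pair_stays_masked(self):
        m1 = self._region(np.array([[0.0, np.nan], [np.nan, 0.0]]), ["A", "B"])
        out = C.specimen_average([m1], [50], [{"A": 5, "B": 5}])
        assert np.isnan(out.values[0, 1])


class TestBaselines:
    def test_duplicated_neurons_fully_correlated(self, rng):
        base = (rng.random(500) < 0.4).astype(int)
        other = (rng.random(500) < 0.4).astype(int)
        v = np.stack([base, base, other])
        _, corr = C.baseline_matrices(v)
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        v = (rng.random((6, 30_000)) < 0.3).astype(int)
        cov, corr = C.baseline_matrices(v)
        iu = np.triu_indices(6, k=1)
        assert np.all(np.abs(corr.values[iu]) < 0.05)

    def test_matches_hand_computation(self):
        v = np.array([[1, 0, 1, 0], [1, 1, 0, 0]])
        cov, corr = C.baseline_matrices(v)
        x, y = v.astype(float)
        ref_cov = np.mean((x - x.mean()) * (y - y.mean())) * 4 / 3  # ddof=1
        assert cov.values[0, 1] == pytest.approx(ref_cov)
        ref_corr = ref_cov / (x.std(ddof=1) * y.std(ddof=1))
        assert corr.values[0, 1] == pytest.approx(ref_corr)

    def test_zero_variance_neuron_zeroed(self):
        v = np.vstack([np.zeros(10, dtype=int),
                       (np.arange(10) % 2)])
        _, corr = C.baseline_matrices(v)
        assert corr.values[0, 1] == 0.0


class TestStructural:
    def test_no_neurites_gives_zero(self):
        morph = MorphologySet(soma_region=[0, 1], neurite_length=np.zeros((2, 2)),
                              volumes=[1.0, 1.0], region_names=["A", "B"])
        for variant in ("direct", "legacy"):
            out = C.structural_estimator(morph, variant)
            assert np.nansum(out.values) == 0.0

    def test_two_region_hand_example(self):
        # neuron 0: soma A, 2 units of neurite in B; neuron 1: soma B, 4 in A
        morph = MorphologySet(soma_region=[0, 1],
                              neurite_length=np.array([[0.0, 2.0], [4.0, 0.0]]),
                              volumes=[1.0, 1.0], region_names=["A", "B"])
        out = C.structural_estimator(morph, "direct")
        assert out.values[0, 1] == pytest.approx(3.0)  # mean of 2 and 4

    def test_volume_doubling_halves_entries(self):
        rng = np.random.default_rng(0)
        morph = MorphologySet(soma_region=[0, 1, 0],
                              neurite_length=rng.random((3, 2)) * 5,
                              volumes=[1.0, 2.0], region_names=["A", "B"])
        base = C.structural_estimator(morph, "direct").values
        doubled = MorphologySet(soma_region=morph.soma_region,
                                neurite_length=morph.neurite_length,
                                volumes=morph.volumes * 2,
                                region_names=morph.region_names)
        out = C.structural_estimator(doubled, "direct").values
        np.testing.assert_allclose(out, base / 2)

    def test_length_scaling_is_linear(self):
        rng = np.random.default_rng(1)
        morph = MorphologySet(soma_region=[0, 1, 1],
                              neurite_length=rng.random((3, 2)) * 3,
                              volumes=[1.0, 1.5], region_names=["A", "B"])
        base = C.structural_estimator(morph, "direct").values
        scaled = MorphologySet(soma_region=morph.soma_region,
                               neurite_length=morph.neurite_length * 7,
                               volumes=morph.volumes,
                               region_names=morph.region_names)
        out = C.structural_estimator(scaled, "direct").values
        np.testing.assert_allclose(out, base * 7)

    def test_indirect_passthrough_neuron_counts_only_in_legacy(self):
        # one neuron with soma in C, neurites in A and B: no direct A-B link
        morph = MorphologySet(
            soma_region=[2, 0, 1],
            neurite_length=np.array([[3.0, 5.0, 0.0],
                                     [0.0, 0.0, 0.0],
                                     [0.0, 0.0, 0.0]]),
            volumes=[1.0, 1.0, 1.0],
            region_names=["A", "B", "C"])
        direct = C.structural_estimator(morph, "direct")
        legacy = C.structural_estimator(morph, "legacy")
        assert direct.values[0, 1] == pytest.approx(0.0)
        assert legacy.values[0, 1] > 0.0

    def test_somata_free_region_uses_defined_direction(self):
        morph = MorphologySet(soma_region=[0, 0],
                              neurite_length=np.array([[0.0, 2.0], [0.0, 4.0]]),
                              volumes=[1.0, 1.0], region_names=["A", "B"])
        out = C.structural_estimator(morph, "direct")
        # B hosts no somata: only the A->B direction exists, mean length 3
        assert out.values[0, 1] == pytest.approx(3.0)


class TestRegionalOccupancy:
    def _annotation(self, n_regions, assignment):
        mem = np.zeros((n_regions, len(assignment)), dtype=int)
        mem[assignment, np.arange(len(assignment))] = 1
        return RegionAnnotation(membership=mem,
                                region_names=[f"r{k}" for k in range(n_regions)])

    def test_single_region_assembly(self):
        w = np.zeros((10, 1))
        w[:5, 0] = 0.5
        p = CRBMParams(weights=w, g=np.zeros(10), gamma_plus=[1],
                       gamma_minus=[1], theta_plus=[0], theta_minus=[0])
        ann = self._annotation(4, [0] * 5 + [1, 1, 2, 2, 3])
        occ, table = C.regional_occupancy(p, ann)
        assert table.loc[0, "effective_regions"] == pytest.approx(1.0)
        assert table.loc[0, "regions_overlapped"] == 1

    def test_equal_spread_over_k_regions(self):
        w = np.zeros((12, 1))
        w[:, 0] = 0.5
        p = CRBMParams(weights=w, g=np.zeros(12), gamma_plus=[1],
                       gamma_minus=[1], theta_plus=[0], theta_minus=[0])
        ann = self._annotation(3, [0, 1, 2] * 4)
        occ, table = C.regional_occupancy(p, ann)
        assert table.loc[0, "effective_regions"] == pytest.approx(3.0)

    def test_disconnected_unit_flagged(self):
        p = CRBMParams(weights=np.zeros((4, 1)), g=np.zeros(4),
                       gamma_plus=[1], gamma_minus=[1],
                       theta_plus=[0], theta_minus=[0])
        ann = self._annotation(2, [0, 0, 1, 1])
        _, table = C.regional_occupancy(p, ann)
        assert bool(table.loc[0, "disconnected"])


class TestCompareMatrices:
    def _region(self, values, labels):
        return C.ConnectivityMatrix(values=values, level="region",
                                    labels=labels, provenance="structural")

    def test_self_comparison_is_one(self, rng):
        vals = rng.random((5, 5))
        vals = vals + vals.T
        m = self._region(vals, list("abcde"))
        r, _ = C.compare_matrices(m, m, "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_transform_spearman_one(self, rng):
        vals = rng.random((5, 5))
        vals = vals + vals.T
        a = self._region(vals, list("abcde"))
        b = self._region(np.exp(vals), list("abcde"))
        rs, _ = C.compare_matrices(a, b, "spearman")
        rp, _ = C.compare_matrices(a, b, "pearson")
        assert rs == pytest.approx(1.0)
        assert rp <= 1.0

    def test_matches_textbook_rank_correlation(self):
        va = np.zeros((4, 4))
        vb = np.zeros((4, 4))
        iu = np.triu_indices(4, k=1)
        a_vals = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        b_vals = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 9.0])
        va[iu] = a_vals
        vb[iu] = b_vals
        va += va.T
        vb += vb.T
        a = self._region(va, list("wxyz"))
        b = self._region(vb, list("wxyz"))
        r, p = C.compare_matrices(a, b, "spearman")
        ref_r, ref_p = sps.spearmanr(a_vals, b_vals)
        assert r == pytest.approx(ref_r)
        assert p == pytest.approx(ref_p)

    def test_zero_structural_entries_excluded(self, rng):
        va = rng.random((5, 5))
        va += va.T
        vb = va.copy()
        vb[0, 1] = vb[1, 0] = 0.0  # absent structural connection
        a = self._region(va, list("abcde"))
        b = self._region(vb, list("abcde"))
        r, _ = C.compare_matrices(a, b, "spearman", exclude_zeros_in_b=True)
        assert r == pytest.approx(1.0)
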