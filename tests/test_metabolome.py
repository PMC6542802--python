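"""Metabolome pipeline: filtering, transforms, imputation, PCA, Z separation."""

import math

import numpy as np
import pytest

import deathcue as dc
from deathcue.errors import (
    DegenerateDataError,
    DomainError,
    EmptyMatrixError,
    InsufficientDataError,
    ParameterError,
    PipelineOrderError,
)
from tests.conftest import make_matrix


class TestFilterMissingness:
    def test_boundary_five_of_32_kept_six_dropped(self):
        values = np.ones((32, 3))
        values[:6, 0] = np.nan   # 6 of 32 missing -> dropped
        values[:5, 1] = np.nan   # 5 of 32 missing -> retained
        m = make_matrix(values, names=["drop", "keep", "full"])
        out = dc.filter_missingness(m)
        assert out.metabolite_names == ["keep", "full"]

    def test_identity_when_complete(self):
        m = make_matrix(np.arange(12.0).reshape(4, 3) + 1)
        out = dc.filter_missingness(m)
        assert out.metabolite_names == m.metabolite_names
        assert np.array_equal(out.data.to_numpy(), m.data.to_numpy())
        assert out.stage == "filtered"

    def test_fully_missing_metabolite_dropped(self):
        values = np.ones((8, 2))
        values[:, 0] = np.nan
        out = dc.filter_missingness(make_matrix(values, names=["gone", "ok"]))
        assert out.metabolite_names == ["ok"]

    def test_all_dropped_raises(self):
        values = np.full((8, 2), np.nan)
        with pytest.raises(EmptyMatrixError):
            dc.filter_missingness(make_matrix(values))

    def test_order_preserved(self):
        values = np.ones((32, 4))
        values[:7, 1] = np.nan
        names = ["c", "x", "a", "b"]
        out = dc.filter_missingness(make_matrix(values, names=names))
        assert out.metabolite_names == ["c", "a", "b"]


class TestLogTransform:
    def test_values(self):
        m = dc.filter_missingness(make_matrix([[math.e, 1.0], [math.e**2, 4.0]]))
        out = dc.log_transform(m)
        assert out.data.iloc[0, 0] == pytest.approx(1.0)
        assert out.data.iloc[0, 1] == pytest.approx(0.0)
        assert out.scale == "log"

    def test_mask_preserved(self):
        m = dc.filter_missingness(make_matrix(
            [[1.0, np.nan], [2.0, 3.0], [4.0, 5.0]]), max_missing_fraction=0.4)
        out = dc.log_transform(m)
        assert out.missing_mask.iloc[0, 1]
        assert not out.missing_mask.iloc[1, 1]

    def test_refuses_second_log(self):
        m = dc.filter_missingness(make_matrix([[1.0, 2.0], [3.0, 4.0]]))
        out = dc.log_transform(m)
        out2 = dc.MetaboliteMatrix(out.data, out.sample_factors, scale="log",
                                   stage="filtered")
        with pytest.raises(DomainError, match="log"):
            dc.log_transform(out2)

    def test_nonpositive_names_cell(self):
        m = dc.filter_missingness(make_matrix([[1.0, -2.0], [3.0, 4.0]],
                                              names=["a", "bad"]))
        with pytest.raises(DomainError, match="bad"):
            dc.log_transform(m)

    def test_requires_filtered_stage(self):
        with pytest.raises(PipelineOrderError):
            dc.log_transform(make_matrix([[1.0, 2.0]]))


def to_logged(values, names=None):
    """Wrap an already-log-scale array at the 'logged' stage."""
    m = make_matrix(values, names=names, stage="logged", scale="log")
    return m


class TestKnnImpute:
    def test_identity_when_complete(self):
        m = to_logged([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = dc.knn_impute(m, k=1)
        assert np.array_equal(out.data.to_numpy(), m.data.to_numpy())
        assert out.stage == "imputed"

    def test_constant_neighbourhood(self):
        values = np.array([
            [1.0, 1.01, 7.0, np.nan],
            [2.0, 2.01, 8.0, 2.0],
            [3.0, 3.01, 9.0, 3.0],
            [4.0, 4.01, 10.0, 4.0],
        ])
        # nearest two metabolites to the last one are the first two; in sample 1
        # they hold 1.0 and 1.01
        out = dc.knn_impute(to_logged(values), k=2)
        assert out.data.iloc[0, 3] == pytest.approx((1.0 + 1.01) / 2)

    def test_hand_computed_four_by_three(self):
        # distances to the missing metabolite over jointly observed samples:
        # d(C,A) = sqrt(0.03) ~ 0.173, d(C,B) = sqrt(3.63) ~ 1.905
        values = np.array([
            [1.0, 1.0, 1.1],
            [2.0, 2.0, 2.1],
            [3.0, 5.0, 3.1],
            [4.0, 8.0, np.nan],
        ])
        out = dc.knn_impute(to_logged(values, names=["A", "B", "C"]), k=2)
        # k=2 uses both available neighbours: mean(4.0, 8.0) = 6.0
        assert out.data.iloc[3, 2] == pytest.approx(6.0)
        out1 = dc.knn_impute(to_logged(values, names=["A", "B", "C"]), k=1)
        # the single nearest metabolite is A -> value 4.0
        assert out1.data.iloc[3, 2] == pytest.approx(4.0)

    def test_neighbour_selection_hand_computed(self):
        # T missing in sample 5; distances over samples 1-4:
        # d(T,A)=0.2, d(T,B)=0.5, d(T,C)=20 -> k=2 picks A,B -> (20+30)/2
        values = np.array([
            [10.1, 10.0, 0.0, 10.0],
            [11.1, 11.0, 1.0, 11.0],
            [12.1, 12.0, 2.0, 12.0],
            [13.1, 13.5, 3.0, 13.0],
            [20.0, 30.0, 40.0, np.nan],
        ])
        out = dc.knn_impute(to_logged(values, names=["A", "B", "C", "T"]), k=2)
        assert out.data.iloc[4, 3] == pytest.approx(25.0)

    def test_too_few_neighbours_warns(self):
        values = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
        with pytest.warns(UserWarning, match="neighbours"):
            out = dc.knn_impute(to_logged(values), k=10)
        assert out.data.iloc[1, 1] == pytest.approx(3.0)

    def test_requires_logged_stage(self):
        with pytest.raises(PipelineOrderError):
            dc.knn_impute(make_matrix([[1.0, 2.0]]))


class TestStandardize:
    def test_columns_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        m = to_logged(rng.normal(5, 2, (20, 6)))
        m = dc.knn_impute(m)
        out = dc.standardize(m)
        X = out.data.to_numpy()
        assert np.abs(X.mean(axis=0)).max() < 1e-10
        assert np.abs(X.var(axis=0, ddof=1) - 1).max() < 1e-10

    def test_standardized_input_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        m = dc.knn_impute(to_logged(X))
        out = dc.standardize(m)
        assert np.abs(out.data.to_numpy() - X).max() < 1e-10

    def test_constant_column_raises_with_name(self):
        values = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        m = dc.knn_impute(to_logged(values, names=["flat", "ok"]))
        with pytest.raises(DegenerateDataError, match="flat"):
            dc.standardize(m)


class TestRunPCA:
    @staticmethod
    def processed(X):
        return dc.standardize(dc.knn_impute(to_logged(np.asarray(X, float))))

    def test_two_metabolite_perfect_correlation(self):
        m = self.processed([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        dec = dc.run_pca(m)
        assert np.allclose(np.abs(dec.loadings["PC1"]), 1 / math.sqrt(2))
        assert dec.loadings["PC1"].iloc[0] > 0  # sign convention
        assert dec.explained_variance[0] == pytest.approx(2.0)
        assert dec.explained_variance[1] == pytest.approx(0.0, abs=1e-12)

    def test_loadings_orthonormal_and_variance_conserved(self):
        rng = np.random.default_rng(3)
        m = self.processed(rng.normal(size=(12, 7)))
        dec = dc.run_pca(m)
        L = dec.loadings.to_numpy()
        assert np.abs(L.T @ L - np.eye(L.shape[1])).max() < 1e-8
        assert dec.explained_variance.sum() == pytest.approx(7.0, rel=1e-6)
        assert np.all(np.diff(dec.explained_variance) <= 1e-12)

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        m = self.processed(rng.normal(size=(10, 5)))
        dec = dc.run_pca(m)
        for col in dec.loadings:
            v = dec.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_too_few_samples(self):
        m = self.processed(np.array([[1.0, 2.0], [3.0, 1.0]]))
        with pytest.raises(InsufficientDataError):
            dc.run_pca(m)


class TestZSeparation:
    def test_hand_computed_toy(self):
        z = dc.z_separation([0, 1, 2, 3], ["a", "a", "b", "b"])
        assert z.z_observed == pytest.approx(4.0)
        assert z.group_means == {"a": 0.5, "b": 2.5}

    def test_zero_when_group_means_equal(self):
        z = dc.z_separation([0, 1, 1, 0], ["a", "a", "b", "b"])
        assert z.z_observed == pytest.approx(0.0)

    def test_label_permutation_symmetry(self):
        x = [0.3, 1.2, -0.5, 2.0, 0.1, 0.9]
        z1 = dc.z_separation(x, ["a", "a", "a", "b", "b", "b"])
        z2 = dc.z_separation(x, ["b", "b", "b", "a", "a", "a"])
        assert z1.z_observed == pytest.approx(z2.z_observed)

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (-1.5, 3.0), (0.1, -7.0)])
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.2, -0.5, 2.0, 0.1, 0.9])
        labels = ["a", "a", "a", "b", "b", "b"]
        z1 = dc.z_separation(x, labels)
        z2 = dc.z_separation(a * x + b, labels)
        assert z2.z_observed == pytest.approx(z1.z_observed)

    def test_mean_square_variant_scales_by_constant(self):
        x = [0, 1, 2, 3, 1, 4]
        labels = ["a", "a", "a", "b", "b", "b"]
        ss = dc.z_separation(x, labels, within="ss")
        msq = dc.z_separation(x, labels, within="mean_square")
        assert msq.z_observed == pytest.approx(ss.z_observed * (6 - 2))

    def test_degenerate_within_raises(self):
        with pytest.raises(DegenerateDataError):
            dc.z_separation([1, 1, 2, 2], ["a", "a", "b", "b"])

    def test_small_groups_raise(self):
        with pytest.raises(InsufficientDataError):
            dc.z_separation([1, 2, 3], ["a", "a", "b"])


class TestPermutationPCTest:
    def test_smoothing_lower_bound(self, default_metabolome):
        proc = dc.process_matrix(default_metabolome)
        res = dc.permutation_pc_test(proc, n_permutations=10, seed=0)
        assert all(z.p_value >= 1 / 11 for z in res)

    def test_seeded_reproducibility(self, default_metabolome):
        proc = dc.process_matrix(default_metabolome)
        r1 = dc.permutation_pc_test(proc, n_permutations=99, seed=5)
        r2 = dc.permutation_pc_test(proc, n_permutations=99, seed=5)
        assert [z.p_value for z in r1] == [z.p_value for z in r2]

    def test_unknown_factor_raises(self, default_metabolome):
        proc = dc.process_matrix(default_metabolome)
        with pytest.raises(ParameterError):
            dc.permutation_pc_test(proc, grouping_factor="diet")

    def test_planted_component_found_and_attributed(self, default_metabolome):
        proc = dc.process_matrix(default_metabolome)
        dec = dc.run_pca(proc)
        res = dc.permutation_pc_test(proc, n_permutations=499, seed=1,
                                     decomposition=dec)
        L = dec.loadings.to_numpy()
        v = default_metabolome.truth.direction
        corrs = np.abs([np.corrcoef(L[:, j], v)[0, 1] for j in range(L.shape[1])])
        best = int(np.argmax(corrs))
        assert corrs[best] > 0.9
        assert res[best].p_value < 0.05
        strat = dc.stratified_pc_test(proc, "exposure", "genotype",
                                      n_permutations=499, seed=2,
                                      decomposition=dec)
        assert strat[best] < 0.05


class TestRankLoadings:
    @staticmethod
    def decomposition(loadings, names):
        import pandas as pd

        L = np.asarray(loadings, dtype=float)
        cols = [f"PC{i + 1}" for i in range(L.shape[1])]
        return dc.PCDecomposition(
            loadings=pd.DataFrame(L, index=names, columns=cols),
            projections=pd.DataFrame(np.zeros((3, L.shape[1])), columns=cols),
            explained_variance=np.ones(L.shape[1]),
        )

    def test_absolute_value_ordering(self):
        d = self.decomposition([[0.9], [-0.95], [0.1]], ["a", "b", "c"])
        assert dc.rank_loadings(d, 1, top_n=2) == ["b", "a"]

    def test_ties_lexicographic(self):
        d = self.decomposition([[0.5], [-0.5], [0.2]], ["zeta", "alpha", "mid"])
        assert dc.rank_loadings(d, 1, top_n=2) == ["alpha", "zeta"]

    def test_top_n_truncated_with_warning(self):
        d = self.decomposition([[0.5], [0.1]], ["a", "b"])
        with pytest.warns(UserWarning, match="truncat"):
            out = dc.rank_loadings(d, 1, top_n=5)
        assert out == ["a", "b"]

    def test_invalid_component(self):
        d = self.decomposition([[0.5], [0.1]], ["a", "b"])
        with pytest.raises(ParameterError):
            dc.rank_loadings(d, 3)


class TestScreenCandidates:
    @staticmethod
    def build(shift_control=0.0, shift_mutant=0.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        genotype = ["control"] * (2 * n) + ["mutant"] * (2 * n)
        exposure = (["exposed"] * n + ["unexposed"] * n) * 2
        X = rng.normal(size=(4 * n, 3))
        X[:n, 0] += shift_control
        X[2 * n:3 * n, 0] += shift_mutant
        m = make_matrix(X, genotype=genotype, exposure=exposure,
                        names=["cand", "x1", "x2"], stage="standardized",
                        scale="log")
        return m

    def test_control_only_shift_flagged(self):
        out = dc.screen_candidates(self.build(shift_control=2.5), ["cand"])
        assert out[0].flagged
        assert out[0].p_control < 0.05 <= out[0].p_mutant

    def test_shift_in_both_genotypes_not_flagged(self):
        out = dc.screen_candidates(
            self.build(shift_control=2.5, shift_mutant=2.5), ["cand"])
        assert not out[0].flagged
        assert out[0].p_mutant < 0.05

    def test_direction_follows_control_effect_sign(self):
        out = dc.screen_candidates(self.build(shift_control=-2.5), ["cand"])
        assert out[0].direction == "less"
        assert out[0].flagged

    def test_null_rarely_flagged(self):
        flags = 0
        for seed in range(200):
            out = dc.screen_candidates(self.build(seed=seed), ["cand"])
            flags += out[0].flagged
        # criterion (i) alone holds with probability alpha under the null
        assert flags / 200 <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 200)

    def test_small_cell_raises(self):
        m = self.build(n=1)
        with pytest.raises(InsufficientDataError):
            dc.screen_candidates(m, ["cand"])

    def test_unknown_candidate_raises(self):
        with pytest.raises(ParameterError):
            dc.screen_candidates(self.build(), ["nope"])


class TestPipelineOrder:
    def test_full_chain_stages(self, default_metabolome):
        m = default_metabolome
        assert m.stage == "raw"
        proc = dc.process_matrix(m)
        assert proc.stage == "standardized"
        X = proc.data.to_numpy()
        assert np.abs(X.mean(0)).max() < 1e-10
        assert np.abs(X.var(0, ddof=1) - 1).max() < 1e-10

    def test_out_of_order_calls_raise(self, default_metabolome):
        m = default_metabolome
        with pytest.raises(PipelineOrderError):
            dc.standardize(m)
        with pytest.raises(PipelineOrderError):
            dc.run_pca(m)
        filtered = dc.filter_missingness(m)
        with pytest.raises(PipelineOrderError):
            dc.filter_missingness(filtered)
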