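"""Transform, PCA/pPCA, broken-stick retention and sign handling."""

import numpy as np
import pandas as pd
import pytest

from pacelife.ordination import (
    OrdinationResult,
    TransformedMatrix,
    TransformError,
    broken_stick,
    canonicalize_signs,
    pca,
    phylo_pca,
    relative_importance,
    retain_components,
    transform,
)
from pacelife.phylo import read_newick, vcv_matrix


def make_Z(X, columns=None, labels=None):
    X = np.asarray(X, dtype=float)
    return TransformedMatrix(
        values=X,
        row_labels=labels or [f"r{i}" for i in range(X.shape[0])],
        columns=columns or [f"t{j}" for j in range(X.shape[1])],
        dropped=[],
        zero_filled=[],
        meta={},
    )


class TestTransform:
    def test_fecundity_plus_one_z_scores(self):
        raw = pd.DataFrame({"fecundity": [0.0, 1.0], "afr": [1.0, 2.0]})
        Z = transform(raw, fecundity_plus_one=True)
        col = Z.frame()["fecundity"].to_numpy()
        np.testing.assert_allclose(col, [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)
        assert Z.meta["fecundity"]["plus_one"]

    def test_constant_column_dropped(self):
        raw = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        Z = transform(raw)
        assert Z.dropped == ["b"]
        assert Z.columns == ["a"]

    def test_columns_standardized(self, rng):
        raw = pd.DataFrame(np.exp(rng.normal(size=(30, 4))),
                           columns=["afr", "adult_lifespan",
                                    "breeding_frequency", "fecundity"])
        Z = transform(raw)
        np.testing.assert_allclose(Z.values.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(Z.values.std(axis=0, ddof=1), 1, atol=1e-8)

    def test_nonpositive_value_named(self):
        raw = pd.DataFrame({"afr": [1.0, 0.0]}, index=["x", "y"])
        with pytest.raises(TransformError, match=r"afr.*'y'"):
            transform(raw)

    def test_zero_fecundity_ok_with_plus_one(self):
        raw = pd.DataFrame({"fecundity": [0.0, 0.5, 2.0]})
        Z = transform(raw, fecundity_plus_one=True)
        assert np.isfinite(Z.values).all()

    def test_constant_column_zero_filled_on_request(self):
        raw = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        Z = transform(raw, on_constant="zero")
        assert Z.zero_filled == ["b"]
        np.testing.assert_allclose(Z.frame()["b"], 0)


class TestPca:
    def test_rank_one_gives_full_first_component(self):
        x = np.linspace(-1, 1, 10)
        res = pca(make_Z(np.column_stack([x, 2 * x])))
        assert res.proportions[0] == pytest.approx(1.0)

    def test_uncorrelated_equal_variance_limit(self, rng):
        X = rng.normal(size=(4000, 4))
        res = pca(make_Z(X))
        np.testing.assert_allclose(res.proportions, 0.25, atol=0.05)

    def test_total_variance_conserved(self, rng):
        X = rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4))
        res = pca(make_Z(X))
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(np.cov(X, rowvar=False, ddof=1))
        )
        assert res.scores.var(axis=0, ddof=1).sum() == pytest.approx(
            X.var(axis=0, ddof=1).sum()
        )

    def test_orthonormal_loadings(self, rng):
        res = pca(make_Z(rng.normal(size=(20, 4))))
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(4), atol=1e-10
        )

    def test_single_trait_rejected(self):
        with pytest.raises(ValueError, match="2 varying traits"):
            pca(make_Z(np.linspace(0, 1, 5)[:, None]))


class TestPhyloPca:
    def test_star_phylogeny_equals_plain_pca(self, rng):
        """With C = identity the pPCA must reduce to the plain PCA."""
        for _ in range(10):
            X = rng.normal(size=(8, 4))
            Z = make_Z(X)
            plain = pca(Z)
            phylo = phylo_pca(Z, np.eye(8))
            np.testing.assert_allclose(
                phylo.eigenvalues, plain.eigenvalues, atol=1e-10
            )
            np.testing.assert_allclose(
                np.abs(phylo.loadings), np.abs(plain.loadings), atol=1e-8
            )

    def test_collinear_traits_any_tree(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        C = vcv_matrix(t, ["A", "B", "C"])
        x = np.array([1.0, 2.0, 4.0])
        res = phylo_pca(make_Z(np.column_stack([x, 3 * x])), C)
        assert res.proportions[0] == pytest.approx(1.0)

    def test_three_species_micro_oracle(self):
        """Frozen values from an independent GLS + eigen computation."""
        t = read_newick("((A:1,B:1):1,C:2);")
        C = vcv_matrix(t, ["A", "B", "C"])
        Z = make_Z([[1, 2], [2, 1], [3, 3]], columns=["u", "v"],
                   labels=["A", "B", "C"])
        res = phylo_pca(Z, C)
        np.testing.assert_allclose(
            res.eigenvalues, [0.642857142857, 0.5], atol=1e-9
        )
        np.testing.assert_allclose(
            np.abs(res.loadings), np.full((2, 2), np.sqrt(0.5)), atol=1e-9
        )
        np.testing.assert_allclose(
            np.abs(res.scores[:, 0]),
            [0.909137290097, 0.909137290097, 1.212183053463],
            atol=1e-9,
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            phylo_pca(make_Z(np.zeros((4, 2))), np.eye(3))


class TestBrokenStick:
    def test_four_components(self):
        np.testing.assert_allclose(
            broken_stick(4),
            [0.520833333, 0.270833333, 0.145833333, 0.0625],
            atol=1e-9,
        )

    def test_k1_and_k2(self):
        np.testing.assert_allclose(broken_stick(1), [1.0])
        np.testing.assert_allclose(broken_stick(2), [0.75, 0.25])

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 7, 20])
    def test_sums_to_one_and_decreasing(self, k):
        b = broken_stick(k)
        assert b.sum() == pytest.approx(1.0)
        assert np.all(np.diff(b) < 0) or k == 1

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            broken_stick(0)


def result_with_proportions(p):
    p = np.asarray(p, dtype=float)
    k = len(p)
    return OrdinationResult(
        eigenvalues=p.copy(),
        loadings=np.eye(k),
        scores=np.zeros((2, k)),
        proportions=p,
        columns=[f"t{i}" for i in range(k)],
        row_labels=["a", "b"],
        mode="plain",
    )


class TestRetention:
    def test_only_pc1(self):
        res = result_with_proportions([0.77, 0.13, 0.07, 0.03])
        np.testing.assert_array_equal(
            retain_components(res), [True, False, False, False]
        )

    def test_none_retained(self):
        res = result_with_proportions([0.40, 0.30, 0.20, 0.10])
        assert not retain_components(res).any()

    def test_boundary_strict(self):
        res = result_with_proportions(broken_stick(4))
        assert not retain_components(res).any()

    def test_sequential_stop(self):
        # PC2 above its stick but PC1 below: nothing retained
        res = result_with_proportions([0.50, 0.30, 0.15, 0.05])
        assert not retain_components(res).any()


class TestRelativeImportance:
    def test_rows_sum_to_one(self, rng):
        V = rng.normal(size=(4, 4))
        np.testing.assert_allclose(relative_importance(V).sum(axis=1), 1.0)

    def test_hand_cases(self):
        np.testing.assert_allclose(
            relative_importance(np.array([[0.5, 0.5, 0.0, 0.0]])),
            [[0.5, 0.5, 0.0, 0.0]],
        )
        np.testing.assert_allclose(
            relative_importance(np.array([[-0.8, 0.2]])), [[0.8, 0.2]]
        )
        np.testing.assert_allclose(relative_importance(np.array([[1.0]])), [[1.0]])

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            relative_importance(np.array([[0.0, 0.0], [1.0, 0.0]]))


class TestCanonicalize:
    def make(self, anchor_loading):
        V = np.array([[0.6, 0.8], [anchor_loading, -0.6 * np.sign(anchor_loading)]])
        return OrdinationResult(
            eigenvalues=np.array([2.0, 1.0]),
            loadings=V.copy(),
            scores=np.array([[1.0, 2.0], [-1.0, -2.0]]),
            proportions=np.array([2 / 3, 1 / 3]),
            columns=["afr", "adult_lifespan"],
            row_labels=["a", "b"],
            mode="plain",
        )

    def test_positive_anchor_flipped(self):
        res = canonicalize_signs(self.make(0.6))
        assert res.loadings[1, 0] == pytest.approx(-0.6)
        assert 1 in res.sign_flips

    def test_negative_anchor_unchanged(self):
        res = self.make(-0.6)
        before = res.loadings.copy()
        canonicalize_signs(res)
        np.testing.assert_allclose(res.loadings[:, 0], before[:, 0])

    def test_idempotent(self):
        res = canonicalize_signs(self.make(0.6))
        after_once = res.loadings.copy()
        canonicalize_signs(res)
        np.testing.assert_allclose(res.loadings, after_once)

    def test_scores_flip_with_loadings(self):
        res = self.make(0.6)
        s0 = res.scores[:, 0].copy()
        canonicalize_signs(res)
        np.testing.assert_allclose(res.scores[:, 0], -s0)

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            canonicalize_signs(self.make(0.5), anchor_trait="fecundity")
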