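"""AHP eigenvector weighting, consistency ratios and hierarchy composition."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riceval import PairwiseMatrix, compose, consistency, paper_hierarchy, principal_weights
from riceval.ahp import RANDOM_INDEX_SAATY, Hierarchy
from riceval.errors import ValidationError

SAATY_VALUES = [Fraction(1, k) for k in range(9, 1, -1)] + [Fraction(k) for k in range(1, 10)]


def random_reciprocal(rng, n):
    a = np.ones((n, n))
    vals = [float(v) for v in SAATY_VALUES]
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = rng.choice(vals)
            a[j, i] = 1.0 / a[i, j]
    return PairwiseMatrix(tuple(f"c{k}" for k in range(n)), a)


def dense_eig_weights(a):
    """Independent oracle: dominant eigenpair from a dense solver."""
    vals, vecs = np.linalg.eig(a)
    i = np.argmax(vals.real)
    w = np.abs(vecs[:, i].real)
    return w / w.sum(), float(vals.real[i])


class TestPrincipalWeights:
    def test_two_by_two_closed_form(self):
        m = PairwiseMatrix(("x", "y"), np.array([[1.0, 7.0], [1 / 7, 1.0]]))
        w, lam = principal_weights(m)
        assert w["x"] == pytest.approx(0.875, abs=1e-12)
        assert w["y"] == pytest.approx(0.125, abs=1e-12)
        assert lam == pytest.approx(2.0, abs=1e-10)

    def test_rank_one_consistent_matrix(self):
        m = PairwiseMatrix(("a", "b", "c"),
                           np.array([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1.0]]))
        w, lam = principal_weights(m)
        assert [w["a"], w["b"], w["c"]] == pytest.approx([4 / 7, 2 / 7, 1 / 7])
        assert lam == pytest.approx(3.0, abs=1e-10)

    def test_criterion_matrix_weights(self):
        h = paper_hierarchy()
        w, lam = principal_weights(h.criterion_matrix)
        assert list(w.values()) == pytest.approx(
            [0.5650, 0.2622, 0.1175, 0.0553], abs=2e-4)
        assert lam > 4

    @pytest.mark.parametrize("n,seed", [(3, 0), (4, 1), (5, 2), (6, 3), (7, 4)])
    def test_agrees_with_dense_solver(self, n, seed):
        rng = np.random.default_rng(seed)
        m = random_reciprocal(rng, n)
        w, lam = principal_weights(m)
        w_oracle, lam_oracle = dense_eig_weights(m.a)
        assert np.array(list(w.values())) == pytest.approx(w_oracle, abs=1e-9)
        assert lam == pytest.approx(lam_oracle, abs=1e-9)

    def test_non_reciprocal_rejected(self):
        a = np.array([[1.0, 2.0], [0.6, 1.0]])
        with pytest.raises(ValidationError, match="reciprocal"):
            PairwiseMatrix(("x", "y"), a)

    @given(seed=st.integers(0, 10_000), n=st.integers(3, 7))
    @settings(max_examples=40, deadline=None)
    def test_lambda_max_at_least_order(self, seed, n):
        m = random_reciprocal(np.random.default_rng(seed), n)
        _, lam = principal_weights(m)
        assert lam >= n - 1e-9


class TestConsistency:
    def test_criterion_matrix_cr(self):
        rep = consistency(paper_hierarchy().criterion_matrix)
        assert rep.CR == pytest.approx(0.0438, abs=5e-4)
        assert rep.acceptable

    def test_saaty_variant(self):
        rep = consistency(paper_hierarchy().criterion_matrix,
                          random_index=RANDOM_INDEX_SAATY)
        assert rep.CR == pytest.approx(0.0434, abs=5e-4)

    def test_two_by_two_always_consistent(self):
        m = PairwiseMatrix(("x", "y"), np.array([[1.0, 7.0], [1 / 7, 1.0]]))
        assert consistency(m).CR == 0.0

    def test_rank_one_matrix_has_zero_ci(self):
        m = PairwiseMatrix(("a", "b", "c"),
                           np.array([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1.0]]))
        rep = consistency(m)
        assert rep.CI == pytest.approx(0.0, abs=1e-9)
        assert rep.CR == pytest.approx(0.0, abs=1e-9)


class TestCompose:
    def test_published_global_weights(self):
        composed = compose(paper_hierarchy())
        expected = {"palatability": 0.5650, "adhesiveness": 0.2294,
                    "resilience": 0.0328, "b_value": 0.1175,
                    "iodine_color_value": 0.0553}
        for leaf, w in expected.items():
            assert composed.weights[leaf] == pytest.approx(w, abs=2e-4)

    def test_weights_sum_to_one(self):
        composed = compose(paper_hierarchy())
        assert sum(composed.weights.values()) == pytest.approx(1.0, abs=1e-10)

    def test_total_ordering_cr_reported(self):
        composed = compose(paper_hierarchy())
        assert composed.total_ordering_CR == pytest.approx(0.0438, abs=5e-4)
        assert composed.reports["B2"].CR == 0.0

    def test_single_criterion_single_leaf(self):
        m = PairwiseMatrix(("only",), np.array([[1.0]]))
        h = Hierarchy(criterion_matrix=m, children={"only": ["leaf"]},
                      sub_matrices={})
        assert compose(h).weights == {"leaf": pytest.approx(1.0)}

    def test_scale_invariance_of_consistent_matrix(self):
        # weights of a rank-one matrix equal the generating ratio vector
        v = np.array([4.0, 2.0, 1.0])
        a = np.outer(v, 1 / v)
        m = PairwiseMatrix(("a", "b", "c"), a)
        w, _ = principal_weights(m)
        assert np.array(list(w.values())) == pytest.approx(v / v.sum(), abs=1e-12)
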