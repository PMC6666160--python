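"""Principal-component factor extraction, varimax rotation, assignment."""

import numpy as np
import pandas as pd
import pytest

from riceval import assign_to_factors, extract_factors, rotate_varimax
from riceval.correlation import CorrelationMatrix
from riceval.errors import ValidationError
from riceval.factors import FactorModel
from riceval import fixtures


def cm_from(r, names=None):
    r = np.asarray(r, dtype=float)
    names = tuple(names or [f"v{i}" for i in range(len(r))])
    return CorrelationMatrix(names, r, 100)


class TestExtraction:
    def test_two_by_two_closed_form(self):
        model = extract_factors(cm_from([[1, 0.8], [0.8, 1]]))
        assert model.eigenvalues == pytest.approx([1.8, 0.2])
        assert model.retained_k == 1
        assert model.contribution[0] == pytest.approx(90.0)

    def test_panel_retains_five_factors(self, panel_correlation):
        cm, _ = panel_correlation
        model = extract_factors(cm)
        assert model.retained_k == 5
        assert model.eigenvalues.sum() == pytest.approx(17.0, abs=1e-6)

    def test_cumulative_equals_eigensum_oracle(self, panel_correlation):
        cm, _ = panel_correlation
        model = extract_factors(cm)
        w = np.sort(np.linalg.eigvalsh((cm.r + cm.r.T) / 2))[::-1]  # oracle
        assert model.cumulative[-1] == pytest.approx(w[:5].sum() / 17 * 100, abs=1e-9)

    def test_loadings_reconstruct_eigvecs(self):
        r = [[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]]
        model = extract_factors(cm_from(r), k=3)
        # full-rank loadings satisfy L L' = R for a PSD correlation matrix
        assert model.loadings @ model.loadings.T == pytest.approx(np.array(r), abs=1e-10)

    def test_no_retainable_factor_errors(self):
        with pytest.raises(ValidationError, match="explicit k"):
            extract_factors(cm_from(np.eye(3)))

    def test_asymmetric_input_rejected(self):
        r = np.eye(3)
        r[0, 1] = 0.5  # not mirrored
        df = pd.DataFrame(r, index=list("abc"), columns=list("abc"))
        with pytest.raises(ValidationError, match="symmetric"):
            extract_factors(df)


class TestVarimax:
    @pytest.fixture()
    def block_model(self):
        # two independent 3-index blocks with within-block r = 0.7
        r = np.eye(6)
        for i in range(3):
            for j in range(3):
                if i != j:
                    r[i, j] = r[i + 3, j + 3] = 0.7
        return extract_factors(cm_from(r))

    def test_communalities_preserved(self, block_model):
        rotated = rotate_varimax(block_model)
        assert rotated.communalities == pytest.approx(
            block_model.communalities, abs=1e-10)

    def test_cumulative_contribution_invariant(self, panel_correlation):
        cm, _ = panel_correlation
        model = extract_factors(cm)
        rotated = rotate_varimax(model)
        assert rotated.cumulative[-1] == pytest.approx(model.cumulative[-1], abs=1e-9)

    def test_blocks_separate_onto_factors(self, block_model):
        assign = assign_to_factors(rotate_varimax(block_model))
        groups = {assign[f"v{i}"] for i in range(3)}, {assign[f"v{i}"] for i in range(3, 6)}
        assert all(len(g) == 1 for g in groups)
        assert groups[0] != groups[1]

    def test_rotation_idempotent_up_to_sign_and_order(self, panel_correlation):
        cm, _ = panel_correlation
        once = rotate_varimax(extract_factors(cm))
        twice = rotate_varimax(once)
        # compare column sets up to sign via absolute cross-products
        gram = np.abs(once.loadings.T @ twice.loadings)
        col_norms = np.linalg.norm(once.loadings, axis=0)
        # each rotated column should align (|cos| ~ 1) with exactly one original
        aligned = (gram / np.outer(col_norms, col_norms)).max(axis=1)
        assert aligned == pytest.approx(np.ones(5), abs=1e-6)

    def test_single_factor_rotation_is_identity(self):
        model = extract_factors(cm_from([[1, 0.8], [0.8, 1]]))
        rotated = rotate_varimax(model)
        assert np.array_equal(rotated.loadings, model.loadings)
        assert rotated.rotated


@pytest.fixture(scope="module")
def published_model():
    loadings = fixtures.load_fixture("table4")
    k = loadings.shape[1]
    ssl = (loadings**2).sum(axis=0).values
    return FactorModel(
        names=tuple(loadings.index), eigenvalues=np.sort(ssl)[::-1],
        retained_k=k, loadings=loadings.values,
        contribution=ssl / 17 * 100, cumulative=np.cumsum(ssl / 17 * 100),
        rotated=True,
    )


class TestAssignment:
    def test_sensory_block_and_transmittance_on_first_factor(self, published_model):
        assign = assign_to_factors(published_model)
        for name in ("palatability", "taste", "sensory_comprehensive_evaluation",
                     "appearance", "smell", "light_transmittance"):
            assert assign[name] == 1

    def test_resilience_cohesiveness_fourth_factor(self, published_model):
        assign = assign_to_factors(published_model)
        assert assign["resilience"] == 4
        assert assign["cohesiveness"] == 4

    def test_tie_breaks_to_lower_factor(self):
        model = FactorModel(
            names=("a",), eigenvalues=np.array([1.0, 1.0]), retained_k=2,
            loadings=np.array([[0.5, -0.5]]),
            contribution=np.array([50.0, 50.0]),
            cumulative=np.array([50.0, 100.0]), rotated=True,
        )
        assert assign_to_factors(model)["a"] == 1
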