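"""Trait models, projection and attributions (selection recall/null studies
live in the acceptance suite; these tests cover the contracts)."""

import numpy as np
import pandas as pd
import pytest

from rootclines.errors import ConfigError, SchemaError
from rootclines.envmodels import (
    boruta_select,
    fit_trait_model,
    project,
    shap_attribute,
)


@pytest.fixture(scope="module")
def linear_world():
    rng = np.random.default_rng(42)
    n = 120
    X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"d{j}" for j in range(6)])
    y = 2.0 * X["d0"].to_numpy() - 1.0 * X["d1"].to_numpy() + 0.3 * rng.normal(size=n)
    return X, y


class TestSelection:
    def test_duplicated_descriptor_same_decision(self, linear_world):
        X, y = linear_world
        X2 = X.copy()
        X2["d0_copy"] = X2["d0"]
        sel = boruta_select(y, X2, trait="dup", n_trees=200, max_runs=40, seed=0)
        dec = {}
        for f in ("d0", "d0_copy"):
            dec[f] = ("confirmed" if f in sel.confirmed else
                      "rejected" if f in sel.rejected else "tentative")
        assert dec["d0"] == dec["d0_copy"] == "confirmed"

    def test_column_order_invariance(self, linear_world):
        X, y = linear_world
        s1 = boruta_select(y, X, trait="t", n_trees=200, max_runs=30, seed=3)
        s2 = boruta_select(y, X[list(reversed(X.columns))], trait="t",
                           n_trees=200, max_runs=30, seed=3)
        assert s1.confirmed == s2.confirmed
        assert s1.rejected == s2.rejected

    def test_too_few_accessions_rejected(self):
        X = pd.DataFrame(np.zeros((10, 3)), columns=list("abc"))
        with pytest.raises(ConfigError):
            boruta_select(np.zeros(10), X)


class TestTraitModel:
    def test_self_predicting_sanity(self, linear_world):
        X, y = linear_world
        X2 = X.copy()
        X2["self"] = y
        m = fit_trait_model(y, X2, ["self"], trait="t", n_trees=300, seed=0)
        assert m.oob_r2 > 0.9

    def test_null_oob_r2_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(300, 5)),
                             columns=[f"d{j}" for j in range(5)])
            y = rng.normal(size=300)
            m = fit_trait_model(y, X, list(X.columns), trait="null",
                                n_trees=200, seed=seed)
            vals.append(m.oob_r2)
        # OOB percent variance explained is slightly negatively biased
        # under the null; it must never look predictive
        assert abs(np.mean(vals)) < 0.1
        assert np.mean(vals) <= 0.05

    def test_determinism(self, linear_world):
        X, y = linear_world
        m1 = fit_trait_model(y, X, ["d0", "d1"], trait="t", n_trees=200, seed=5)
        m2 = fit_trait_model(y, X, ["d0", "d1"], trait="t", n_trees=200, seed=5)
        np.testing.assert_array_equal(m1.estimator.predict(X[["d0", "d1"]]),
                                      m2.estimator.predict(X[["d0", "d1"]]))

    def test_split_candidates_floor_p_over_3(self, linear_world):
        X, y = linear_world
        m = fit_trait_model(y, X, list(X.columns), trait="t", n_trees=50, seed=0)
        assert m.split_candidates == 2
        m1 = fit_trait_model(y, X, ["d0", "d1"], trait="t", n_trees=50, seed=0)
        assert m1.split_candidates == 1  # floor(2/3) -> minimum 1

    def test_empty_confirmed_set_is_not_modeled(self, linear_world):
        X, y = linear_world
        with pytest.raises(ConfigError, match="not modeled"):
            fit_trait_model(y, X, [], trait="t")

    def test_more_trees_changes_oob_little(self, linear_world):
        X, y = linear_world
        feats = list(X.columns)
        m_small = fit_trait_model(y, X, feats, trait="t", n_trees=500, seed=1)
        m_big = fit_trait_model(y, X, feats, trait="t", n_trees=5000, seed=1)
        assert abs(m_small.oob_r2 - m_big.oob_r2) < 0.1


class TestProjection:
    def test_identity_on_training_table(self, linear_world):
        X, y = linear_world
        m = fit_trait_model(y, X, ["d0", "d1"], trait="t", n_trees=200, seed=0)
        proj = project([m], X.assign(accession=[f"a{i}" for i in range(len(X))]))
        np.testing.assert_allclose(proj.values["t"].to_numpy(),
                                   m.estimator.predict(X[["d0", "d1"]]))
        assert not proj.extrapolation.any().any()

    def test_constant_rows_give_constant_projection(self, linear_world):
        X, y = linear_world
        m = fit_trait_model(y, X, ["d0", "d1"], trait="t", n_trees=200, seed=0)
        tgt = pd.DataFrame({"accession": ["p", "q"], "d0": [0.1, 0.1],
                            "d1": [-0.2, -0.2]})
        proj = project([m], tgt)
        assert proj.values["t"].nunique() == 1

    def test_extrapolation_flagged_not_dropped(self, linear_world):
        X, y = linear_world
        m = fit_trait_model(y, X, ["d0", "d1"], trait="t", n_trees=100, seed=0)
        tgt = pd.DataFrame({"accession": ["far"], "d0": [50.0], "d1": [0.0]})
        proj = project([m], tgt)
        assert len(proj.values) == 1
        assert proj.extrapolation.loc["far", "d0"]

    def test_missing_descriptor_named(self, linear_world):
        X, y = linear_world
        m = fit_trait_model(y, X, ["d0", "d1"], trait="t", n_trees=50, seed=0)
        with pytest.raises(SchemaError, match="d1"):
            project([m], pd.DataFrame({"accession": ["p"], "d0": [0.0]}))


class TestModelArchive:
    def test_round_trip_preserves_predictions(self, linear_world, tmp_path):
        from rootclines.envmodels import load_models, save_models
        X, y = linear_world
        m = fit_trait_model(y, X, ["d0", "d1"], trait="t", n_trees=100, seed=0)
        save_models([m], tmp_path / "models.joblib")
        back = load_models(tmp_path / "models.joblib")[0]
        np.testing.assert_array_equal(back.estimator.predict(X[["d0", "d1"]]),
                                      m.estimator.predict(X[["d0", "d1"]]))
        assert back.trait == "t" and back.seed == 0


class TestShap:
    def test_single_descriptor_contribution_is_exact(self, linear_world):
        X, y = linear_world
        m = fit_trait_model(y, X, ["d0"], trait="t", n_trees=100, seed=0)
        rows = X.head(4)
        att = shap_attribute(m, rows, method="exact_tree")
        pred = m.estimator.predict(rows[["d0"]].to_numpy())
        np.testing.assert_allclose(
            att.base_value + att.contributions["d0"].to_numpy(), pred, atol=1e-9)

    def test_duplicated_descriptor_splits_symmetrically(self, linear_world):
        X, y = linear_world
        X2 = X[["d0"]].copy()
        X2["d0b"] = X2["d0"]
        m = fit_trait_model(y, X2, ["d0", "d0b"], trait="t", n_trees=500, seed=0)
        att = shap_attribute(m, X2.head(6), method="exact_tree")
        a = att.contributions["d0"].to_numpy()
        b = att.contributions["d0b"].to_numpy()
        # the fitted forest splits the duplicated signal across the two
        # columns; over many trees the split is balanced, so the exact
        # attributions agree up to the forest's column-choice noise
        assert np.abs(a - b).mean() < 0.15 * np.abs(a + b).mean()

    def test_exact_and_sampling_agree(self, linear_world):
        X, y = linear_world
        m = fit_trait_model(y, X, ["d0", "d1", "d2"], trait="t",
                            n_trees=100, seed=0)
        rows = X.head(5)
        exact = shap_attribute(m, rows, method="exact_tree", seed=1)
        samp = shap_attribute(m, rows, method="sampling", n_samples=300, seed=1)
        pred = m.estimator.predict(rows[["d0", "d1", "d2"]].to_numpy())
        np.testing.assert_allclose(exact.predictions(), pred, atol=1e-8)
        np.testing.assert_allclose(samp.predictions(), pred, atol=1e-8)
        spread = pred.std() + 1e-12
        mad = np.abs(exact.contributions.to_numpy()
                     - samp.contributions.to_numpy()).mean()
        assert mad < 0.05 * spread

    def test_unknown_method(self, linear_world):
        X, y = linear_world
        m = fit_trait_model(y, X, ["d0"], trait="t", n_trees=20, seed=0)
        with pytest.raises(ConfigError):
            shap_attribute(m, X.head(1), method="kernel")
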