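import numpy as np
import pandas as pd
import pytest

import dustgeorisk as dg
from dustgeorisk.synthetic_data import SyntheticSpec


@pytest.fixture(scope="module")
def separated():
    """Six widely separated groups (centroid gap >= 4 within-group SDs,
    n = 20 per group) for the parameter-recovery checks."""
    params = {}
    groups = [(f"G{i + 1}", 20) for i in range(6)]
    for i in range(6):
        for j, el in enumerate(dg.ELEMENTS):
            base = 100.0 * (j + 1)
            boost = 3.0 if i == j else 1.0  # group i enriched in element i
            params[(f"G{i + 1}", el)] = (base * boost, base * boost * 0.05)
    spec = SyntheticSpec(groups=groups, element_params=params, seed=13)
    table = dg.generate(spec)
    X, _ = dg.preprocess(table)
    return X, table.groups


class TestPreprocess:
    def test_columns_are_zero_mean_unit_sd(self, table):
        X, _ = dg.preprocess(table)
        assert np.allclose(X.mean(), 0, atol=1e-12)
        assert np.allclose(X.std(ddof=1), 1, atol=1e-12)

    def test_stored_parameters_reproduce_training_geometry(self, table):
        X, prep = dg.preprocess(table)
        again = prep.transform(table.data)
        pd.testing.assert_frame_equal(X, again)

    def test_nonpositive_values_rejected(self, table):
        data = table.data.copy()
        data.iloc[0, 0] = 0.0
        t = dg.ConcentrationTable(data, table.groups)
        with pytest.raises(ValueError, match="positive"):
            dg.preprocess(t)

    def test_constant_column_becomes_zero_with_warning(self, table):
        data = table.data.copy()
        data["Zn"] = 7.0
        t = dg.ConcentrationTable(data, table.groups)
        with pytest.warns(UserWarning, match="Zn"):
            X, _ = dg.preprocess(t)
        assert (X["Zn"] == 0).all()


class TestMlr:
    def test_fixture_fit_reproduces_group_separability(self, table, X_logz):
        """Every group except the drilling zone is perfectly recovered; any
        residual confusion is the drilling -> crushing overlap."""
        run = dg.fit_mlr(X_logz, table.groups)
        cm = run.confusion
        assert run.accuracy >= 100 * 23 / 24
        for g in ("A2", "A3", "B1", "B2", "C"):
            assert cm.loc[g, g] == 4
        off = cm.to_numpy().sum() - np.trace(cm.to_numpy())
        assert off in (0, 1)
        if off == 1:
            assert cm.loc["A1", "A2"] == 1

    def test_posteriors_sum_to_one(self, table, X_logz):
        run = dg.fit_mlr(X_logz, table.groups)
        assert np.allclose(run.probabilities.sum(axis=1), 1.0)

    def test_information_criteria_consistent(self, table, X_logz):
        run = dg.fit_mlr(X_logz, table.groups)
        m2ll, aic, bic = (run.extras[k] for k in ("minus2ll", "aic", "bic"))
        k_params = 5 * 8  # (classes - 1) * (predictors + intercept)
        assert aic == pytest.approx(m2ll + 2 * k_params)
        assert bic == pytest.approx(m2ll + k_params * np.log(24))
        lr = run.extras["lr_test"]
        assert lr["df"] == 35
        assert lr["chi2"] == pytest.approx(2 * 24 * np.log(6) - m2ll, abs=1e-6)

    def test_reference_class_coefficients(self, table, X_logz):
        run = dg.fit_mlr(X_logz, table.groups, reference_class="A2")
        assert "A2" not in run.extras["coefficients"]
        assert set(run.extras["coefficients"]) == {"A1", "A3", "B1", "B2", "C"}

    def test_single_class_rejected(self, table, X_logz):
        with pytest.raises(ValueError):
            dg.fit_mlr(X_logz, pd.Series("G", index=X_logz.index))

    def test_well_separated_groups_fully_classified(self, separated):
        X, groups = separated
        assert dg.fit_mlr(X, groups, reference_class="G1").accuracy == 100.0


class TestDtc:
    def test_training_accuracy_and_confused_drilling_zone(self, table, X_logz):
        run = dg.fit_dtc(X_logz, table.groups)
        assert run.accuracy == pytest.approx(100 * 20 / 24)
        cm = run.confusion
        assert cm.loc["A1", "A1"] == 0  # drilling zone fully misassigned
        assert cm.loc["A1", ["A2", "C"]].sum() == 4
        for g in ("A2", "A3", "B1", "B2", "C"):
            assert cm.loc[g, g] == 4

    def test_copper_and_lead_dominate_importance(self, table, X_logz):
        run = dg.fit_dtc(X_logz, table.groups)
        rvi = run.extras["relative_importance"]
        assert set(rvi.index[:2]) == {"Cu", "Pb"}
        assert rvi.max() == 100.0

    def test_pure_leaves_have_zero_gini(self, separated):
        X, groups = separated
        run = dg.fit_dtc(X, groups)
        tree = run.extras["tree"].tree_
        leaves = tree.children_left == -1
        assert np.allclose(tree.impurity[leaves], 0.0)

    def test_pruned_tree_never_larger(self, table, X_logz):
        run = dg.fit_dtc(X_logz, table.groups)
        pruning = run.extras["pruning"]
        assert pruning["pruned_n_leaves"] <= run.extras["tree"].get_n_leaves()
        assert pruning["pruned_accuracy"] <= run.accuracy + 1e-9

    def test_auc_per_class_bounded(self, table, X_logz):
        auc = dg.fit_dtc(X_logz, table.groups).extras["auc_one_vs_rest"]
        assert set(auc) == set(table.group_codes)
        assert all(0.5 <= v <= 1.0 for v in auc.values())

    def test_too_few_samples_rejected(self, table, X_logz):
        with pytest.raises(ValueError):
            dg.fit_dtc(X_logz.iloc[:6], table.groups.iloc[:6], min_leaf=4)

    def test_well_separated_groups_fully_classified(self, separated):
        X, groups = separated
        assert dg.fit_dtc(X, groups).accuracy >= 95.0


class TestSvm:
    def test_linearly_separable_toy_is_perfect(self):
        rng = np.random.default_rng(4)
        a = rng.normal((2, 2), 0.2, size=(10, 2))
        b = rng.normal((-2, -2), 0.2, size=(10, 2))
        X = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
        groups = pd.Series(["A"] * 10 + ["B"] * 10)
        run = dg.fit_svm(X, groups)
        assert run.accuracy == 100.0

    def test_representative_protocol_trains_on_one_per_group(self, table, X_logz):
        run = dg.fit_svm(X_logz, table.groups, protocol="representative")
        train = run.extras["train_samples"]
        assert len(train) == 6
        assert len({table.groups[s] for s in train}) == 6
        assert run.extras["decision_function"].shape == (24, 6)
        assert 0 < run.accuracy <= 100

    def test_probabilities_sum_to_one(self, table, X_logz):
        run = dg.fit_svm(X_logz, table.groups)
        assert np.allclose(run.probabilities.sum(axis=1), 1.0)

    def test_missing_class_rejected(self, table, X_logz):
        groups = table.groups.copy()
        with pytest.raises(ValueError):
            dg.fit_svm(X_logz.iloc[:8], groups.iloc[:8].replace("A2", "A1"),
                       protocol="representative")

    def test_well_separated_groups_fully_classified(self, separated):
        X, groups = separated
        assert dg.fit_svm(X, groups).accuracy >= 95.0


class TestPlsda:
    def test_two_component_fit_diagnostics(self, table, X_rawz):
        run = dg.fit_plsda(X_rawz, table.groups, n_components=2)
        ex = run.extras
        assert ex["n_components"] == 2
        assert 0 < ex["x_variance_cum_pct"] < 100
        assert len(ex["x_variance_pct"]) == 2
        assert ex["leverage"].between(0, 1).all()
        assert (ex["hotelling_t2"] >= 0).all()

    def test_loo_selects_two_components_on_fixture(self, table, X_rawz):
        run = dg.fit_plsda(X_rawz, table.groups)
        assert run.extras["n_components"] == 2

    def test_vip_normalization_identity(self, table, X_rawz, X_logz):
        """Mean of squared VIP scores is exactly 1 for any fit."""
        for X, nc in ((X_rawz, 2), (X_logz, 3)):
            run = dg.fit_plsda(X, table.groups, n_components=nc)
            assert (run.extras["vip"] ** 2).mean() == pytest.approx(1.0, rel=1e-9)

    def test_relevant_predictor_set(self, table, X_rawz):
        run = dg.fit_plsda(X_rawz, table.groups, n_components=2)
        assert run.extras["vip_selected"] == ["Cr", "Cu", "Fe", "Mn", "Zn"]
        vip = run.extras["vip"]
        assert vip.idxmax() == "Fe" and vip.idxmin() == "Ni"

    def test_full_rank_model_reproduces_least_squares(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = X @ [1.0, -2.0, 0.5, 3.0] + rng.normal(0, 0.1, 30)
        groups = pd.Series(np.where(y > y.median(), "High", "Low"))
        codes = np.where(groups == "High", 2.0, 1.0)
        run = dg.fit_plsda(X, groups, n_components=4, class_order=["Low", "High"])
        Xc = X - X.mean()
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(30), Xc]), codes, rcond=None)
        ols_pred = np.column_stack([np.ones(30), Xc]) @ beta
        assert np.allclose(run.extras["predicted_codes"], ols_pred, atol=1e-8)

    def test_excess_components_rejected(self, table, X_rawz):
        with pytest.raises(ValueError, match="rank"):
            dg.fit_plsda(X_rawz, table.groups, n_components=10)

    def test_onehot_probabilities_sum_to_one(self, table, X_rawz):
        run = dg.fit_plsda(X_rawz, table.groups, n_components=2, coding="onehot")
        assert np.allclose(run.probabilities.sum(axis=1), 1.0)

    def test_well_separated_groups_fully_classified(self, separated):
        X, groups = separated
        order = sorted(set(groups))
        run = dg.fit_plsda(X, groups, n_components=5, class_order=order)
        assert run.accuracy >= 95.0


class TestConfusionIdentities:
    def test_row_sums_and_accuracy_identity(self, table, X_logz, X_rawz):
        runs = [
            dg.fit_mlr(X_logz, table.groups),
            dg.fit_dtc(X_logz, table.groups),
            dg.fit_svm(X_logz, table.groups),
            dg.fit_plsda(X_rawz, table.groups, n_components=2),
        ]
        for run in runs:
            cm = run.confusion.to_numpy()
            assert (run.confusion.sum(axis=1) == 4).all()
            assert run.accuracy == pytest.approx(100 * np.trace(cm) / cm.sum())
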