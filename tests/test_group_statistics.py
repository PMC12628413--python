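import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dustgeorisk as dg


def make_table(arrays: dict[str, np.ndarray]) -> dg.ConcentrationTable:
    """Balanced table with one informative element (Pb); the rest constant 1."""
    n = sum(len(a) for a in arrays.values())
    data = pd.DataFrame(1.0, index=[f"S{i}" for i in range(n)],
                        columns=list(dg.ELEMENTS))
    groups, values = [], []
    for g, arr in arrays.items():
        groups.extend([g] * len(arr))
        values.extend(arr)
    data["Pb"] = values
    return dg.ConcentrationTable(data, pd.Series(groups, index=data.index))


class TestDescriptives:
    def test_cv_uses_sample_sd(self, table):
        d = dg.descriptives(table)
        assert d.loc["Cu", "Coefficient of variation"] == pytest.approx(142.60, abs=0.005)
        assert d.loc["Pb", "Standard deviation"] == pytest.approx(21.70, abs=0.005)

    def test_constant_column_has_zero_cv(self):
        t = make_table({"G1": np.ones(3), "G2": np.ones(3)})
        assert dg.descriptives(t).loc["Pb", "Coefficient of variation"] == 0


class TestRouting:
    def test_heteroscedastic_element_routes_to_welch(self, table):
        res = dg.route_group_comparison(table, "Pb")
        lev = res.details["levene"]
        assert lev["statistic"] == pytest.approx(4.207, abs=0.005)
        assert lev["p"] == pytest.approx(0.0104, abs=0.0005)
        assert res.test == "Welch's ANOVA"
        assert res.statistic == pytest.approx(105.09, abs=0.01)
        assert res.df == (5, 8.2)
        assert res.p_display == "< 0.0001"

    def test_homoscedastic_element_routes_to_classic_anova(self, table):
        res = dg.route_group_comparison(table, "Cu")
        assert res.details["levene"]["p"] == pytest.approx(0.1317, abs=0.0005)
        assert res.test == "one-way ANOVA"
        assert res.statistic == pytest.approx(68.11, abs=0.01)
        assert res.df == (5, 18)

    def test_identical_groups_give_null_f(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        t = make_table({g: base for g in ("G1", "G2", "G3")})
        res = dg.route_group_comparison(t, "Pb")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_group_is_degenerate_and_welch_routed(self):
        t = make_table({"G1": np.ones(4), "G2": np.array([1.0, 2, 3, 4])})
        res = dg.route_group_comparison(t, "Pb")
        assert "zero variance" in res.routing_note
        assert res.test == "Welch's ANOVA"

    def test_shapiro_reported_per_group_with_low_power_flag(self, table):
        res = dg.route_group_comparison(table, "Zn")
        sh = res.details["shapiro"]
        assert set(sh) == set(table.group_codes)
        assert all("low power" in v["note"] for v in sh.values())
        # matches the published premise: all groups pass normality at 0.05
        assert all(v["p"] > 0.05 for v in sh.values())

    def test_f_statistic_agrees_with_regression_identity(self, table):
        """One-way F computed from mean squares equals the regression-R2
        form F = (R2/(k-1)) / ((1-R2)/(n-k)) to 1e-9 relative."""
        for el in ("Cu", "Zn", "Mn"):
            res = dg.route_group_comparison(table, el)
            y = table.data[el].to_numpy()
            fitted = table.data.groupby(table.groups)[el].transform("mean").to_numpy()
            r2 = 1 - ((y - fitted) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            k, n = 6, len(y)
            f_reg = (r2 / (k - 1)) / ((1 - r2) / (n - k))
            assert res.statistic == pytest.approx(f_reg, rel=1e-9)

    def test_welch_approaches_classic_for_equal_variances_and_sizes(self):
        """With identical group variances and sizes, Welch's F equals the
        classic one-way F up to its finite-sample denominator correction
        1 + 2(k-2)/(k^2-1) * sum((1 - w_j/W)^2/(n_j - 1)), which tends to 1
        as n grows.  Checked exactly at small n and to 1% at n = 200."""
        import pingouin as pg
        for n, rel in ((4, None), (200, 0.01)):
            dev = np.linspace(-1.5, 1.5, n)
            t = make_table({"G1": 10 + dev, "G2": 14 + dev, "G3": 19 + dev})
            groups = [t.data.loc[t.groups == g, "Pb"].to_numpy()
                      for g in t.group_codes]
            f_classic, _ = stats.f_oneway(*groups)
            frame = pd.DataFrame({"y": t.data["Pb"], "g": t.groups})
            welch_f = float(pg.welch_anova(dv="y", between="g", data=frame)["F"][0])
            k = 3
            correction = 1 + 2 * (k - 2) / (k ** 2 - 1) * 3 * (1 - 1 / k) ** 2 / (n - 1)
            assert welch_f * correction == pytest.approx(f_classic, rel=1e-9)
            if rel is not None:
                assert welch_f == pytest.approx(f_classic, rel=rel)


class TestCorrelation:
    def test_published_pairs_and_labels(self, table):
        r, labels = dg.pearson_matrix(table)
        assert r.loc["Ni", "Cr"] == pytest.approx(0.86, abs=0.005)
        assert labels.loc["Ni", "Cr"] == "strong"
        assert r.loc["Mn", "Cr"] == pytest.approx(-0.35, abs=0.005)
        assert labels.loc["Mn", "Cr"] == "weak"
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)

    def test_constant_column_reported_missing(self):
        t = make_table({"G1": np.array([1.0, 2, 3]), "G2": np.array([2.0, 4, 5])})
        r, _ = dg.pearson_matrix(t)
        assert np.isnan(r.loc["Cu", "Pb"])  # Cu column is constant
        assert not np.isnan(r.loc["Pb", "Pb"])


class TestBartlett:
    def test_published_chi2(self, table):
        res = dg.bartlett_sphericity(table)
        assert res.statistic == pytest.approx(176.88, abs=0.01)
        assert res.df == (21,)
        assert res.p_value < 1e-4

    def test_identity_correlation_gives_zero(self):
        rng = np.random.default_rng(0)
        # two exactly uncorrelated columns via Gram-Schmidt
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        b -= np.polyfit(a, b, 1)[0] * a
        frame = pd.DataFrame({"x": a, "y": b})
        res = dg.bartlett_sphericity(frame)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_two_column_closed_form(self):
        """For p = 2, chi2 = -(n - 1 - 9/6) ln(1 - r^2): hand-evaluated oracle."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        frame = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        expected = -(30 - 1 - 9 / 6) * np.log(1 - r ** 2)
        res = dg.bartlett_sphericity(frame)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.df == (1,)
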