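"""Cohort statistics: descriptives, t, chi-square, ANCOVA, reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinavasc.stats import (
    ancova,
    chi_square,
    describe,
    percent_excess,
    report_tables,
    subject_means,
    t_test,
)


def two_group_frame(a, b, rng=None):
    rows = []
    rng = rng or np.random.default_rng(0)
    for g, vals in (("HLC", a), ("LLC", b)):
        for i, v in enumerate(vals):
            rows.append(
                {
                    "subject_id": f"{g}-{i}",
                    "group": g,
                    "y": float(v),
                    "age": float(rng.normal(8.4, 0.5)),
                    "sex": "male" if rng.random() < 0.5 else "female",
                    "axl_mm": float(rng.normal(23.0, 1.0)),
                }
            )
    return pd.DataFrame(rows)


class TestDescribe:
    def test_hand_case(self):
        df = two_group_frame([1, 2, 3], [4, 4, 4])
        d = describe(df, "y")
        hlc = d[d["group"] == "HLC"].iloc[0]
        llc = d[d["group"] == "LLC"].iloc[0]
        assert hlc["mean"] == 2.0 and hlc["sd"] == 1.0
        assert llc["sd"] == 0.0

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.normal(5, 2, 40)
        df = two_group_frame(vals[:20], vals[20:])
        d = describe(df, "y")
        a = vals[:20]
        mean = sum(a) / len(a)
        sd = (sum((x - mean) ** 2 for x in a) / (len(a) - 1)) ** 0.5
        row = d[d["group"] == "HLC"].iloc[0]
        assert row["mean"] == pytest.approx(mean, rel=1e-12)
        assert row["sd"] == pytest.approx(sd, rel=1e-12)


class TestTTest:
    def test_identical_groups(self):
        df = two_group_frame([1, 2, 3], [1, 2, 3])
        t, p = t_test(df, "y")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_pooled_formula_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        df = two_group_frame(a, b)
        t, p = t_test(df, "y")
        # textbook pooled-variance formula by hand
        ma, mb = np.mean(a), np.mean(b)
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_hand = (ma - mb) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand, rel=1e-12)

    def test_p_matches_permutation_null(self, rng):
        a = [2.1, 3.4, 1.9, 4.0, 2.8, 3.1]
        b = [3.9, 4.4, 5.1, 3.2, 4.8, 4.1]
        df = two_group_frame(a, b)
        t_obs, p = t_test(df, "y")
        pool = np.array(a + b)
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, 12)), axis=1)
        perm = pool[idx]
        da = perm[:, :6]
        db = perm[:, 6:]
        sp2 = (da.var(axis=1, ddof=1) + db.var(axis=1, ddof=1)) / 2
        t_perm = (da.mean(axis=1) - db.mean(axis=1)) / np.sqrt(sp2 * (2 / 6))
        p_perm = np.mean(np.abs(t_perm) >= abs(t_obs))
        mc_err = 3 * np.sqrt(max(p_perm, 1e-6) / n_perm)
        assert abs(p - p_perm) < max(0.01, 10 * mc_err)

    def test_zero_pooled_variance_raises(self):
        df = two_group_frame([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            t_test(df, "y")


class TestChiSquare:
    def test_equal_proportions_zero(self):
        df = pd.DataFrame(
            {"group": ["A"] * 20 + ["B"] * 20, "sex": (["male"] * 10 + ["female"] * 10) * 2}
        )
        chi2, p = chi_square(df, "sex")
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_contingency(self):
        # [[10, 20], [20, 10]]: all expected counts are 15 -> chi2 = 4*25/15 = 20/3
        rows = (
            [("A", "x")] * 10 + [("A", "y")] * 20 + [("B", "x")] * 20 + [("B", "y")] * 10
        )
        df = pd.DataFrame(rows, columns=["group", "cat"])
        chi2, _ = chi_square(df, "cat")
        assert chi2 == pytest.approx(20.0 / 3.0, rel=1e-12)

    @given(st.integers(2, 40), st.integers(2, 40), st.integers(2, 40), st.integers(2, 40))
    @settings(max_examples=30, deadline=None)
    def test_equals_squared_two_proportion_z(self, a, b, c, d):
        rows = (
            [("A", "x")] * a + [("A", "y")] * b + [("B", "x")] * c + [("B", "y")] * d
        )
        df = pd.DataFrame(rows, columns=["group", "cat"])
        chi2, _ = chi_square(df, "cat")
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        p_pool = (a + c) / (n1 + n2)
        if p_pool in (0.0, 1.0):
            return
        z = (p1 - p2) / np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        assert chi2 == pytest.approx(z**2, rel=1e-9)


class TestAncova:
    @staticmethod
    def fixture_frame(seed=0, n=6, effect=2.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("HLC", "LLC"):
            for i in range(n):
                age = rng.normal(8.4, 0.5)
                axl = rng.normal(23.0, 1.0)
                sex = "male" if rng.random() < 0.5 else "female"
                y = 10 + (effect if g == "HLC" else 0) + 0.5 * age - 0.3 * axl + rng.normal(0, 1)
                rows.append(
                    {"subject_id": f"{g}{i}", "group": g, "age": age, "sex": sex,
                     "axl_mm": axl, "y": y}
                )
        return pd.DataFrame(rows)

    def test_coefficients_match_normal_equations(self):
        df = self.fixture_frame()
        res = ancova(df, "y")
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df["group"] == "HLC").to_numpy(float),
                df["age"].to_numpy(float),
                (df["sex"] == "male").to_numpy(float),
                df["axl_mm"].to_numpy(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy(float))
        got = [
            res.coefficients["intercept"],
            res.coefficients["group[HLC]"],
            res.coefficients["age"],
            res.coefficients["sex[male]"],
            res.coefficients["axl_mm"],
        ]
        np.testing.assert_allclose(got, beta, rtol=1e-8)

    def test_balanced_centered_covariates_collapse_to_t_test(self):
        # mirrored covariates across groups: adjustment changes nothing
        rng = np.random.default_rng(5)
        rows = []
        covs = [(rng.normal(8.4, 0.5), rng.normal(23.0, 1.0), s) for s in ("male", "female") for _ in range(5)]
        for g, off in (("HLC", 1.0), ("LLC", 0.0)):
            for j, (age, axl, sex) in enumerate(covs):
                rows.append(
                    {"subject_id": f"{g}{j}", "group": g, "age": age, "sex": sex,
                     "axl_mm": axl, "y": off + float(rng.normal(0, 1))}
                )
        df = pd.DataFrame(rows)
        res = ancova(df, "y")
        raw_diff = df[df.group == "HLC"]["y"].mean() - df[df.group == "LLC"]["y"].mean()
        t, p_t = t_test(df, "y")
        # the adjusted contrast collapses exactly to the raw contrast; the
        # F/t^2 agreement is up to the residual degrees of freedom the
        # covariates consume
        assert res.adjusted_difference == pytest.approx(raw_diff, abs=1e-9)
        assert res.F == pytest.approx(t**2, rel=0.25)
        assert res.p == pytest.approx(p_t, abs=0.02)

    def test_no_group_effect_gives_null_difference(self):
        df = self.fixture_frame(seed=9, n=60, effect=0.0)
        res = ancova(df, "y")
        assert abs(res.adjusted_difference) < 1.0
        assert res.p > 0.001

    def test_rank_deficiency_names_column(self):
        df = self.fixture_frame()
        df["axl_mm"] = df["age"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            ancova(df, "y")

    def test_adjusted_means_at_grand_covariate_means(self):
        df = self.fixture_frame()
        res = ancova(df, "y")
        base = (
            res.coefficients["intercept"]
            + res.coefficients["age"] * df["age"].mean()
            + res.coefficients["sex[male]"] * (df["sex"] == "male").mean()
            + res.coefficients["axl_mm"] * df["axl_mm"].mean()
        )
        assert res.adjusted_means["LLC"] == pytest.approx(base, rel=1e-9)
        assert res.adjusted_means["HLC"] == pytest.approx(
            base + res.coefficients["group[HLC]"], rel=1e-9
        )


class TestReports:
    def test_empty_cohort_gives_header_only(self):
        reports = report_tables(pd.DataFrame())
        for df in reports.values():
            assert df.empty
            assert "parameter" in df.columns and "p" in df.columns

    def test_report_layout_and_labels(self):
        rng = np.random.default_rng(0)
        rows = []
        scopes = ["Global", "0.5–1.0 PD", "1.0–1.5 PD", "1.5–2.0 PD", "2.0–2.5 PD",
                  "Superior", "Nasal", "Inferior", "Temporal"]
        for g in ("HLC", "LLC"):
            for i in range(4):
                for scope in scopes:
                    rows.append(
                        {"subject_id": f"{g}{i}", "eye": "OD", "group": g, "scope": scope,
                         "age": rng.normal(8.4, 0.5), "sex": "male", "axl_mm": rng.normal(23, 1),
                         "VDf": rng.normal(1.4, 0.1), "VC": rng.normal(80, 5),
                         "VT": rng.normal(0.02, 0.003), "VD": rng.uniform(0.02, 0.1),
                         "VBA": rng.normal(60, 5), "AVR": rng.uniform(0.6, 0.9),
                         "disc_area": rng.normal(2.4, 0.2), "cup_area": rng.normal(0.5, 0.1),
                         "CDR": rng.uniform(0.1, 0.3)}
                    )
        reports = report_tables(pd.DataFrame(rows))
        assert list(reports["annulus"]["scope"].unique()) == scopes[1:5]
        assert list(reports["quadrant"]["scope"].unique()) == scopes[5:]
        assert set(reports["global"]["parameter"]) == {
            "VDf", "VT", "VD", "VBA", "VC", "AVR", "cup_area", "disc_area", "CDR"
        }

    def test_missing_scope_marked_absent(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "eye": ["OD"] * 4,
                "group": ["HLC", "HLC", "LLC", "LLC"],
                "scope": ["Global"] * 4,
                "age": [8.1, 8.2, 8.3, 8.4],
                "sex": ["male", "female", "male", "female"],
                "axl_mm": [22.9, 23.1, 23.0, 23.2],
                "VC": [80.0, 81.0, 83.0, 84.0],
            }
        )
        reports = report_tables(df)
        ann = reports["annulus"]
        assert ann["HLC_mean"].isna().all()  # no annulus rows in the input


def test_subject_means_preserves_group_and_averages_eyes():
    df = pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2", "s2"],
            "eye": ["OD", "OS", "OD", "OS"],
            "group": ["HLC", "HLC", "LLC", "LLC"],
            "age": [8.0, 8.0, 9.0, 9.0],
            "sex": ["male", "male", "female", "female"],
            "axl_mm": [23.0, 23.0, 22.5, 22.5],
            "VC": [80.0, 84.0, 90.0, 94.0],
        }
    )
    out = subject_means(df, ["VC"])
    assert len(out) == 2
    assert out.loc[out.subject_id == "s1", "VC"].iloc[0] == 82.0


def test_percent_excess_arithmetic():
    assert percent_excess(0.098, 0.077) == pytest.approx(27.27, abs=0.01)
    with pytest.raises(ZeroDivisionError):
        percent_excess(1.0, 0.0)
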