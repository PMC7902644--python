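"""Mixed ANOVA, sphericity machinery and post-hoc comparisons.

The ANOVA is checked against an independent projection-based
least-squares oracle (sequential sums of squares from explicit dummy
design matrices) and against reference implementations of the
assumption tests (scipy's Levene, pingouin's Mauchly/epsilon).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fmtengraft.inference import (
    bonferroni,
    box_m,
    check_assumptions,
    gg_epsilon,
    levene,
    mauchly,
    mixed_anova,
    pairwise_comparisons,
    simple_main_effects,
)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [
            (9.81e-04, 7, 6.867e-03),
            (1.37e-01, 7, 9.590e-01),
            (0.5, 7, 1.0),
        ],
    )
    def test_adjustment(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected, rel=1e-3)

    def test_vectorized(self):
        out = bonferroni(np.array([0.01, 0.3]), 5)
        assert np.allclose(out, [0.05, 1.0])


class TestGGEpsilon:
    def test_two_levels_is_exactly_one(self):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert gg_epsilon(cov) == 1.0

    def test_compound_symmetry_is_one(self):
        cov = 0.3 * np.ones((3, 3)) + 0.7 * np.eye(3)
        assert gg_epsilon(cov) == pytest.approx(1.0, abs=1e-10)

    def test_crafted_covariance_matches_formula(self):
        """Direct evaluation of the trace formula on a 3x3 covariance."""
        cov = np.array([[4.0, 1.0, 0.5], [1.0, 2.0, 0.3], [0.5, 0.3, 1.0]])
        k = 3
        h = np.eye(k) - np.ones((k, k)) / k
        s = h @ cov @ h
        expected = np.trace(s) ** 2 / ((k - 1) * np.trace(s @ s))
        assert gg_epsilon(cov) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        data = rng.normal(size=(15, 4)) @ rng.normal(size=(4, 4))
        eps_ref = pg.epsilon(pd.DataFrame(data), correction="gg")
        assert gg_epsilon(np.cov(data, rowvar=False)) == pytest.approx(
            eps_ref, abs=1e-10
        )

    def test_lower_bound_clamp(self):
        # rank-1 within-covariance drives epsilon to its floor 1/(k-1)
        v = np.array([1.0, 2.0, 3.0])
        cov = np.outer(v, v)
        assert gg_epsilon(cov) == pytest.approx(0.5, abs=1e-10)


class TestMauchly:
    def test_two_levels_trivial(self):
        data = np.random.default_rng(0).normal(size=(10, 2))
        assert mauchly(data) == (1.0, 1.0)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        data = rng.normal(size=(12, 4)) @ rng.normal(size=(4, 4))
        w, p = mauchly(data)
        ref = pg.sphericity(pd.DataFrame(data))
        assert w == pytest.approx(ref.W, abs=1e-10)
        # pingouin's second-order term has a small formula variant
        assert p == pytest.approx(ref.pval, rel=0.05)


class TestLevene:
    def test_identical_groups_statistic_zero(self):
        v = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        g = np.repeat([0, 1], 4)
        w, p = levene(v, g)
        assert w == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_brown_forsythe(self):
        rng = np.random.default_rng(11)
        g = np.repeat([0, 1, 2], 8)
        v = rng.normal(size=24) * np.array([1.0, 2.0, 0.5])[g]
        w, p = levene(v, g)
        ref = stats.levene(v[g == 0], v[g == 1], v[g == 2], center="median")
        assert w == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            levene(np.arange(4.0), np.zeros(4))


class TestBoxM:
    def test_equal_covariances_small_statistic(self):
        rng = np.random.default_rng(2)
        mats = [rng.normal(size=(20, 3)) for _ in range(3)]
        chi2, p = box_m(mats)
        assert p > 0.05

    def test_textbook_formula_on_two_cells(self):
        """Direct evaluation of Box's M with the chi-square scaling."""
        rng = np.random.default_rng(4)
        a = rng.normal(size=(10, 2))
        b = rng.normal(size=(12, 2)) * 2.0
        chi2, p = box_m([a, b])
        k, ns = 2, np.array([10, 12])
        n_tot, g = 22, 2
        covs = [np.cov(a, rowvar=False), np.cov(b, rowvar=False)]
        pooled = sum((n - 1) * c for n, c in zip(ns, covs)) / (n_tot - g)
        m = (n_tot - g) * np.log(np.linalg.det(pooled)) - sum(
            (n - 1) * np.log(np.linalg.det(c)) for n, c in zip(ns, covs)
        )
        c1 = (np.sum(1.0 / (ns - 1)) - 1.0 / (n_tot - g)) * (
            2 * k**2 + 3 * k - 1
        ) / (6.0 * (k + 1) * (g - 1))
        assert chi2 == pytest.approx(m * (1 - c1), abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(m * (1 - c1), 3), abs=1e-12)

    def test_detects_unequal_covariances(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(40, 2))
        b = rng.normal(size=(40, 2)) * 4.0
        _, p = box_m([a, b])
        assert p < 0.001


def projection_ss(resp: pd.DataFrame) -> dict[str, float]:
    """Independent oracle: sequential SS by least-squares projections.

    Builds explicit dummy design matrices and measures the increase in
    fitted sum of squares as each effect's span is added; in a balanced
    design this reproduces the classical ANOVA decomposition.
    """
    y = resp["engraftment"].to_numpy(dtype=float)

    def dummies(*cols):
        key = resp[list(cols)].astype(str).agg("|".join, axis=1)
        return pd.get_dummies(key).to_numpy(dtype=float)

    def fitted(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fit = x @ beta
        return float(fit @ fit)

    one = np.ones((len(resp), 1))
    spans = {
        "0": one,
        "A": np.hstack([one, dummies("diluent")]),
        "AB_": np.hstack([one, dummies("diluent"), dummies("week")]),
        "cells": dummies("diluent", "week"),
        "S": dummies("mouse_id"),
    }
    ss = {}
    ss["Diluents"] = fitted(spans["A"]) - fitted(spans["0"])
    ss["Week"] = fitted(spans["AB_"]) - fitted(spans["A"])
    ss["Diluents:Week"] = fitted(spans["cells"]) - fitted(spans["AB_"])
    ss["err_between"] = fitted(spans["S"]) - fitted(spans["cells"])
    sc = np.hstack([spans["S"], dummies("day")])
    ss["Day"] = fitted(sc) - fitted(spans["S"])
    sac = np.hstack([sc, dummies("diluent", "day")])
    ss["Diluents:Day"] = fitted(sac) - fitted(sc)
    sbc = np.hstack([sac, dummies("week", "day")])
    ss["Week:Day"] = fitted(sbc) - fitted(sac)
    sabc = np.hstack([sbc, dummies("diluent", "week", "day")])
    ss["Diluents:Week:Day"] = fitted(sabc) - fitted(sbc)
    ss["err_within"] = float(y @ y) - fitted(sabc)
    return ss


class TestMixedAnova:
    def test_matches_projection_oracle(self, balanced_response):
        eff = mixed_anova(balanced_response).set_index("effect")
        ss = projection_ss(balanced_response)
        ms_b = ss["err_between"] / (6 * 3)  # ab(n-1) = 3*2*3
        ms_w = ss["err_within"] / (6 * 3 * 2)
        expected_f = {
            "Diluents": (ss["Diluents"] / 2) / ms_b,
            "Week": (ss["Week"] / 1) / ms_b,
            "Day": (ss["Day"] / 2) / ms_w,
            "Diluents:Week": (ss["Diluents:Week"] / 2) / ms_b,
            "Diluents:Day": (ss["Diluents:Day"] / 4) / ms_w,
            "Week:Day": (ss["Week:Day"] / 2) / ms_w,
            "Diluents:Week:Day": (ss["Diluents:Week:Day"] / 4) / ms_w,
        }
        for name, f in expected_f.items():
            assert eff.loc[name, "F"] == pytest.approx(f, abs=1e-8), name

    def test_frozen_split_plot_reference(self, balanced_response):
        """F statistics previously verified against R's aov with
        Error(subject/day) on this exact fixture."""
        eff = mixed_anova(balanced_response).set_index("effect")
        frozen = {
            "Diluents": 0.352684,
            "Week": 0.123472,
            "Day": 0.727346,
            "Diluents:Week": 0.867561,
            "Diluents:Day": 5.444874,
            "Week:Day": 0.313341,
            "Diluents:Week:Day": 0.559338,
        }
        for name, f in frozen.items():
            assert eff.loc[name, "F"] == pytest.approx(f, abs=1e-5), name

    def test_ss_decomposition_identity(self, balanced_response):
        """Corrected total SS equals the sum of all effect and error SS."""
        eff = mixed_anova(balanced_response)
        y = balanced_response["engraftment"].to_numpy()
        ss_total = float(((y - y.mean()) ** 2).sum())
        ss = projection_ss(balanced_response)
        assert sum(ss.values()) == pytest.approx(ss_total, rel=1e-10)
        assert eff.attrs["ss_total"] == pytest.approx(ss_total, rel=1e-10)

    def test_translation_invariance(self, balanced_response):
        shifted = balanced_response.copy()
        shifted["engraftment"] = shifted["engraftment"] + 10.0
        f1 = mixed_anova(balanced_response)["F"].to_numpy()
        f2 = mixed_anova(shifted)["F"].to_numpy()
        assert np.allclose(f1, f2, atol=1e-8)

    def test_gg_correction_never_decreases_p_when_f_exceeds_one(
        self, balanced_response
    ):
        """Shrinking both degrees of freedom makes any F >= 1 less
        significant (for F < 1 neither p is ever significant)."""
        # force the correction path by evaluating with alpha = 1
        eff = mixed_anova(balanced_response, sphericity_alpha=1.0)
        within = eff[eff["sphericity_corrected"]]
        assert len(within) == 4
        assert (within["epsilon"] <= 1.0).all()
        relevant = within[within["F"] >= 1.0]
        assert (relevant["p"] >= relevant["p_uncorrected"] - 1e-15).all()

    def test_ges_bounded_and_olejnik_algina(self, balanced_response):
        eff = mixed_anova(balanced_response).set_index("effect")
        ss = projection_ss(balanced_response)
        err = ss["err_between"] + ss["err_within"]
        for name in ("Diluents", "Day", "Diluents:Week:Day"):
            expected = ss[name] / (ss[name] + err)
            assert eff.loc[name, "ges"] == pytest.approx(expected, abs=1e-10)
        assert eff["ges"].between(0, 1).all()

    def test_unbalanced_design_rejected(self, balanced_response):
        broken = balanced_response.iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            mixed_anova(broken)

    def test_bonferroni_family_of_seven(self, balanced_response):
        eff = mixed_anova(balanced_response)
        assert np.allclose(
            eff["p_adj"], np.minimum(1.0, eff["p"] * 7), atol=1e-15
        )


class TestAssumptionReport:
    def test_report_shapes(self, balanced_response):
        rep = check_assumptions(balanced_response)
        assert len(rep.levene) == 3
        assert rep.levene["p"].between(0, 1).all()
        assert 0 <= rep.mauchly[1] <= 1


class TestSimpleMainEffects:
    def test_strata_families(self, balanced_response):
        out = simple_main_effects(balanced_response)
        assert len(out) == 6  # 3 days x 2 weeks
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_single_stratum_no_adjustment(self, balanced_response):
        sub = balanced_response.query("day == 'D2' and week == 'W1'")
        out = simple_main_effects(sub, strata=("day",))
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(9)
        rows = []
        for a in ("MD", "TR", "NaCl"):
            for i in range(4):
                shift = {"MD": 1.0, "TR": 0.5, "NaCl": 0.0}[a]
                rows.append(
                    {
                        "diluent": a,
                        "week": "W1",
                        "day": "D2",
                        "mouse_id": f"{a}{i}",
                        "engraftment": shift + 0.1 * rng.normal(),
                    }
                )
        out = simple_main_effects(pd.DataFrame(rows))
        assert (out["p_adj"] < 0.05).all()

    def test_null_p_uniform(self):
        """With iid noise and no group effect, stratum p-values are
        uniform (KS over replicates)."""
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(200):
            rows = []
            for a in ("MD", "TR", "NaCl"):
                for i in range(4):
                    rows.append(
                        {
                            "diluent": a,
                            "week": "W1",
                            "day": "D2",
                            "mouse_id": f"{a}{i}",
                            "engraftment": rng.normal(),
                        }
                    )
            ps.append(simple_main_effects(pd.DataFrame(rows))["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPairwiseComparisons:
    def test_three_levels_give_three_comparisons_per_stratum(
        self, balanced_response
    ):
        out = pairwise_comparisons(balanced_response)
        assert (out.groupby(["day", "week"]).size() == 3).all()

    def test_t_statistic_hand_formula(self, balanced_response):
        out = pairwise_comparisons(balanced_response)
        row = out.iloc[0]
        sub = balanced_response.query(
            "day == @row.day and week == @row.week"
        )
        x = sub.loc[sub["diluent"] == row["level_1"], "engraftment"].to_numpy()
        y = sub.loc[sub["diluent"] == row["level_2"], "engraftment"].to_numpy()
        sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / 6
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * 0.5)
        assert row["t"] == pytest.approx(t, abs=1e-10)

    def test_zero_pooled_variance_flagged(self):
        rows = []
        for a in ("MD", "TR"):
            for i in range(3):
                rows.append(
                    {
                        "diluent": a,
                        "week": "W1",
                        "day": "D2",
                        "mouse_id": f"{a}{i}",
                        "engraftment": 0.5,
                    }
                )
        with pytest.raises(ValueError, match="pooled"):
            pairwise_comparisons(pd.DataFrame(rows))
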