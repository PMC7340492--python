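"""Factorial ANOVA, yield correlations and forward stepwise regression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

from phenotrial.trial_stats import (
    factorial_anova,
    significance_stars,
    stepwise_yield_model,
    yield_correlations,
)


def balanced_table(rng, n_per_cell=4, effects=(0.0, 0.0, 0.0), sd=1.0):
    rows = []
    ta, tb, tab = effects
    for tillage in ("CA", "CP"):
        for density in ("LD", "HD"):
            mu = (
                ta * (tillage == "CA")
                + tb * (density == "HD")
                + tab * ((tillage == "CA") and (density == "HD"))
            )
            for _ in range(n_per_cell):
                rows.append((tillage, density, mu + rng.normal(0, sd)))
    return pd.DataFrame(rows, columns=["tillage", "density", "y"])


class TestFactorialAnova:
    def test_matches_statsmodels_type2(self, rng):
        """Independent oracle: statsmodels anova_lm Type-II on unbalanced data."""
        df = balanced_table(rng, n_per_cell=6, effects=(0.8, 0.3, 0.2))
        df = df.drop(index=[0, 5, 9]).reset_index(drop=True)  # make it unbalanced
        res = factorial_anova(df, "y")
        fit = ols("y ~ C(tillage) * C(density)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        for mine, theirs in [("tillage", "C(tillage)"), ("density", "C(density)"),
                             ("tillage:density", "C(tillage):C(density)")]:
            assert res.effects.loc[mine, "F"] == pytest.approx(ref.loc[theirs, "F"], rel=1e-8)
            assert res.effects.loc[mine, "p"] == pytest.approx(ref.loc[theirs, "PR(>F)"], rel=1e-8)

    def test_hand_computed_2x2x2(self):
        """Closed-form sums of squares on a balanced 2x2 table with 2 reps."""
        df = pd.DataFrame(
            {
                "tillage": ["CA"] * 4 + ["CP"] * 4,
                "density": ["LD", "LD", "HD", "HD"] * 2,
                "y": [3.0, 5.0, 6.0, 8.0, 1.0, 3.0, 2.0, 4.0],
            }
        )
        # cell means: CA*LD 4, CA*HD 7, CP*LD 2, CP*HD 3; grand mean 4
        # balanced: SS_tillage = 8*(1.5^2)=18? No: arm means 5.5 and 2.5 -> 4*(1.5^2+1.5^2)=18
        # SS_density: LD 2.5? LD mean=(4+2)/2=3, HD=5 -> 4*(1^2+1^2)=8
        # SS_int: cells (4,7,2,3): interaction = cell - arm effects: 4*((4-5.5-3+4)^2...)
        res = factorial_anova(df, "y")
        mse = res.residual_ms
        assert res.residual_df == 4
        assert mse == pytest.approx(2.0)  # each cell has variance 2 with 1 df
        assert res.effects.loc["tillage", "ss"] == pytest.approx(18.0)
        assert res.effects.loc["density", "ss"] == pytest.approx(8.0)
        assert res.effects.loc["tillage:density", "ss"] == pytest.approx(2.0)
        assert res.effects.loc["tillage", "F"] == pytest.approx(9.0)

    def test_cell_means_layout(self, rng):
        df = balanced_table(rng)
        res = factorial_anova(df, "y")
        arms = res.cell_means[res.cell_means.effect == "tillage"]
        assert set(arms.level) == {"CA", "CP"}
        assert (res.cell_means.n >= 2).all()

    def test_empty_cell_named_in_error(self, rng):
        df = balanced_table(rng)
        df = df[~((df.tillage == "CP") & (df.density == "HD"))]
        with pytest.raises(ValueError, match="CP.*HD"):
            factorial_anova(df, "y")

    def test_single_rep_cell_rejected(self, rng):
        df = balanced_table(rng, n_per_cell=1)
        with pytest.raises(ValueError, match="replicate"):
            factorial_anova(df, "y")


class TestCorrelations:
    def make_table(self, rng, n=24):
        gy = rng.normal(2.5, 0.5, n)
        return pd.DataFrame(
            {
                "tillage": ["CA", "CP"] * (n // 2),
                "density": ["LD"] * (n // 2) + ["HD"] * (n // 2),
                "grain_yield": gy,
                "linear": 2 * gy + 1,
                "noise": rng.normal(size=n),
                "constant": 1.0,
            }
        )

    def test_perfect_linear_trait(self, rng):
        tab = self.make_table(rng)
        out = yield_correlations(tab, ["linear"])
        row = out[(out.subset == "all") & (out.trait == "linear")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.stars == "***"

    def test_affine_invariance_and_symmetry(self, rng):
        tab = self.make_table(rng)
        tab["scaled"] = -3.0 * tab["noise"] + 7.0
        out = yield_correlations(tab, ["noise", "scaled"])
        sub = out[out.subset == "all"].set_index("trait")
        assert sub.loc["scaled", "r"] == pytest.approx(-sub.loc["noise", "r"])
        # symmetry: swapping trait and response roles leaves r unchanged
        tab2 = tab.rename(columns={"grain_yield": "noise", "noise": "grain_yield"})
        out2 = yield_correlations(tab2, ["noise"])
        assert out2[out2.subset == "all"].iloc[0].r == pytest.approx(sub.loc["noise", "r"])

    def test_constant_trait_missing(self, rng):
        out = yield_correlations(self.make_table(rng), ["constant"])
        assert out.r.isna().all()

    def test_subset_structure(self, rng):
        out = yield_correlations(self.make_table(rng), ["linear"])
        assert set(out.subset) == {"all", "CA", "CP", "LD", "HD", "CA*LD", "CA*HD", "CP*LD", "CP*HD"}

    def test_null_trait_significance_rate(self, rng):
        """|r| exceeds the critical value 0.404 (alpha=0.05, n=24) about 5% of the time."""
        n, m = 24, 1000
        gy = rng.normal(size=n)
        noise = {f"t{i}": rng.normal(size=n) for i in range(m)}
        tab = pd.DataFrame({"tillage": ["CA"] * n, "density": ["LD"] * n, "grain_yield": gy, **noise})
        out = yield_correlations(tab, list(noise), subsets={"all": pd.Series(True, index=tab.index)})
        rate = (out.r.abs() > 0.404).mean()
        assert 0.035 <= rate <= 0.065

    def test_bh_adjustment_monotone(self, rng):
        out = yield_correlations(self.make_table(rng), ["linear", "noise"], bh_adjust=True)
        ok = out.dropna(subset=["p"])
        assert (ok.p_bh >= ok.p - 1e-12).all()


class TestStepwise:
    def test_single_perfect_predictor(self, rng):
        n = 40
        x = rng.normal(size=n)
        tab = pd.DataFrame({"grain_yield": 2 + 3 * x, "good": x,
                            "junk1": rng.normal(size=n), "junk2": rng.normal(size=n)})
        res = stepwise_yield_model(tab, ["junk1", "good", "junk2"])
        assert res.selected_predictors == ["good"]
        assert res.r_squared == pytest.approx(1.0)
        assert res.coefficients["good"] == pytest.approx(3.0)

    def test_no_informative_candidates(self, rng):
        n = 30
        tab = pd.DataFrame({"grain_yield": rng.normal(size=n),
                            "a": rng.normal(size=n) * 0 + rng.normal(size=n)})
        # force an impossible entry threshold so nothing can enter
        res = stepwise_yield_model(tab, ["a"], alpha_enter=1e-12)
        assert res.selected_predictors == []
        assert math.isnan(res.r_squared)

    def test_portions_sum_to_r_squared(self, rng):
        n = 60
        x1, x2, x3 = rng.normal(size=(3, n))
        tab = pd.DataFrame({"grain_yield": 1 + x1 + 0.5 * x2 + rng.normal(0, 0.5, n),
                            "x1": x1, "x2": x2, "x3": x3})
        res = stepwise_yield_model(tab, ["x1", "x2", "x3"])
        assert sum(res.variance_portions.values()) == pytest.approx(res.r_squared, abs=1e-9)
        assert res.selected_predictors[0] == "x1"  # largest RSS drop enters first

    def test_collinear_candidate_skipped(self, rng):
        n = 50
        x = rng.normal(size=n)
        tab = pd.DataFrame({"grain_yield": 2 * x + rng.normal(0, 0.3, n),
                            "x": x, "x_copy": x * 2.0 + 1.0})
        res = stepwise_yield_model(tab, ["x", "x_copy"])
        assert len(res.selected_predictors) == 1

    def test_max_predictors_cap(self, rng):
        n = 80
        xs = rng.normal(size=(6, n))
        y = xs.sum(axis=0) + rng.normal(0, 0.1, n)
        tab = pd.DataFrame({"grain_yield": y, **{f"x{i}": xs[i] for i in range(6)}})
        res = stepwise_yield_model(tab, [f"x{i}" for i in range(6)])
        assert len(res.selected_predictors) == 4

    def test_coefficients_match_statsmodels(self, rng):
        """Fitted coefficients on the selected set agree with an OLS oracle."""
        n = 50
        x1, x2 = rng.normal(size=(2, n))
        tab = pd.DataFrame({"grain_yield": 1 + 2 * x1 - x2 + rng.normal(0, 0.4, n), "x1": x1, "x2": x2})
        res = stepwise_yield_model(tab, ["x1", "x2"])
        X = sm.add_constant(tab[res.selected_predictors])
        fit = sm.OLS(tab["grain_yield"], X).fit()
        assert res.coefficients["intercept"] == pytest.approx(fit.params["const"], rel=1e-8)
        for p in res.selected_predictors:
            assert res.coefficients[p] == pytest.approx(fit.params[p], rel=1e-8)
        assert res.r_squared == pytest.approx(fit.rsquared, rel=1e-10)
        assert res.rse == pytest.approx(np.sqrt(fit.mse_resid), rel=1e-10)

    def test_forward_never_beats_best_subset(self, rng):
        """Exhaustive best-subset search bounds the forward-selection R^2."""
        for trial in range(10):
            n = 40
            xs = rng.normal(size=(5, n))
            y = 0.8 * xs[0] + 0.6 * xs[1] + rng.normal(0, 0.8, n)
            tab = pd.DataFrame({"grain_yield": y, **{f"x{i}": xs[i] for i in range(5)}})
            res = stepwise_yield_model(tab, [f"x{i}" for i in range(5)])
            k = max(len(res.selected_predictors), 1)
            best = 0.0
            for size in range(1, k + 1):
                for combo in itertools.combinations([f"x{i}" for i in range(5)], size):
                    X = np.column_stack([np.ones(n)] + [tab[c] for c in combo])
                    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                    rss = ((y - X @ beta) ** 2).sum()
                    best = max(best, 1 - rss / ((y - y.mean()) ** 2).sum())
            assert (math.isnan(res.r_squared) or res.r_squared <= best + 1e-9)


def test_significance_stars():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
    assert significance_stars(float("nan")) == ""
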