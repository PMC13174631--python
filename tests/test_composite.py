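"""Composite-depletion model, LOO framework, winner statistics, G-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from heteroscreen import composite_dependency as cd


class TestCompositeBeta:
    def test_single_subpopulation_is_its_effect(self):
        for T in (1.0, 8.0, 60.0):
            assert cd.composite_beta([1.0], [-1.0], T) == pytest.approx(-1.0)

    def test_equal_effects_collapse(self):
        assert cd.composite_beta([0.5, 0.5], [-2.0, -2.0], 8) == pytest.approx(-2.0)

    def test_hand_evaluated_mixture(self):
        # (1/8) * log2(0.9 * 2**-16 + 0.1)
        assert cd.composite_beta([0.9, 0.1], [-2.0, 0.0], 8) == pytest.approx(-0.4152, abs=1e-4)

    def test_converges_to_max_effect(self):
        # exact convergence law: beta(T) - max(s) -> log2(f_limiting) / T
        b60 = cd.composite_beta([0.99, 0.01], [-3.0, 0.0], 60)
        assert b60 - 0.0 == pytest.approx(np.log2(0.01) / 60, abs=1e-9)
        b150 = cd.composite_beta([0.99, 0.01], [-3.0, 0.0], 150)
        assert abs(b150 - 0.0) < 0.05

    def test_extreme_exponents_do_not_overflow(self):
        b = cd.composite_beta([0.5, 0.5], [-500.0, -1.0], 10)
        assert np.isfinite(b) and b == pytest.approx(-1.1, abs=0.1)

    @pytest.mark.parametrize("f", [[0.0, 1.0], [-0.1, 1.1], [0.5, 0.4]])
    def test_invalid_fractions(self, f):
        with pytest.raises(ValueError):
            cd.composite_beta(f, [-1.0, 0.0], 8)

    @given(
        st.integers(2, 6),
        st.integers(0, 2**31 - 1),
        st.floats(0.5, 30.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_by_extreme_effects(self, k, seed, T):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(k))
        f = f / f.sum()
        if np.any(f <= 0):
            return
        s = rng.uniform(-3, 1, size=k)
        b = cd.composite_beta(f, s, T)
        assert s.min() - 1e-9 <= b <= s.max() + 1e-9

    def test_monotone_in_T_toward_resistant_pole(self):
        f, s = [0.7, 0.3], [-2.0, -0.2]
        values = [cd.composite_beta(f, s, T) for T in np.linspace(1, 60, 30)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(max(s), abs=0.05)


class TestLimitingSubpop:
    def test_resistant_pole_and_index(self):
        top, idx = cd.limiting_subpop([0.5, 0.5], [-2.0, 0.0])
        assert top == 0.0 and idx == [1]

    def test_tie_returns_all_indices(self):
        top, idx = cd.limiting_subpop([0.5, 0.5], [-1.0, -1.0])
        assert top == -1.0 and idx == [0, 1]


def _affine_beta_table(n_org=6, slope=-2.0, intercept=5.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    betas = np.linspace(-1.5, -0.2, n_org)
    orgs = [f"O{i}" for i in range(n_org)]
    beta = pd.DataFrame({"gene": "g", "organoid": orgs, "beta": betas, "n_guides": 4})
    expr = intercept + slope * betas + rng.normal(0, noise, n_org)
    bulk = pd.DataFrame([expr], index=["g"], columns=orgs)
    return beta, bulk


class TestLooFit:
    def test_perfect_affine_relation_zero_residuals(self):
        beta, bulk = _affine_beta_table()
        res = cd.loo_fit(beta, bulk, "g")
        np.testing.assert_allclose(res["res_bulk"], 0.0, atol=1e-10)

    def test_constant_beta_flags_degenerate(self):
        beta, bulk = _affine_beta_table()
        beta["beta"] = -1.0
        res = cd.loo_fit(beta, bulk, "g")
        assert res.attrs["degenerate"] and res.empty

    def test_too_few_organoids_rejected(self):
        beta, bulk = _affine_beta_table(n_org=4)
        with pytest.raises(ValueError):
            cd.loo_fit(beta, bulk, "g", min_train=4)

    def test_noise_residuals_match_half_normal_mean(self):
        # mean |residual| of a LOO prediction under N(0, sigma) noise is
        # sigma_pred * sqrt(2/pi) with sigma_pred^2 = sigma^2 * (1 + 1/n + lev)
        sigma, n_org, n_rep = 0.5, 10, 60
        resids = []
        for rep in range(n_rep):
            beta, bulk = _affine_beta_table(n_org=n_org, noise=sigma, seed=rep)
            resids.extend(cd.loo_fit(beta, bulk, "g")["res_bulk"])
        observed = np.mean(resids)
        expected = sigma * np.sqrt(2 / np.pi)
        # prediction error slightly exceeds sigma; allow the inflation band
        assert expected * 0.95 < observed < expected * 1.35


class TestSubpopResiduals:
    def _loo_row(self, x_hat=4.0, x_bulk=5.0):
        return pd.DataFrame(
            {
                "gene": ["g"],
                "organoid": ["O1"],
                "beta": [-1.0],
                "x_bulk": [x_bulk],
                "x_hat": [x_hat],
                "res_bulk": [abs(x_bulk - x_hat)],
                "n_train": [5],
            }
        )

    def _subpop(self, means, fractions):
        return pd.DataFrame(
            {
                "gene": "g",
                "organoid": "O1",
                "subpopulation": [f"s{i}" for i in range(len(means))],
                "mean_expr": means,
                "cell_fraction": fractions,
            }
        )

    def test_all_subpops_at_bulk_mean_improvement_zero(self):
        loo = cd.subpop_residuals(self._loo_row(), self._subpop([5.0, 5.0], [0.5, 0.5]))
        row = loo.summary.iloc[0]
        assert row["res_winner"] == pytest.approx(row["res_bulk"])
        assert row["improvement"] == pytest.approx(0.0)

    def test_exact_match_gives_improvement_one(self):
        loo = cd.subpop_residuals(self._loo_row(x_hat=4.0), self._subpop([4.0, 7.0], [0.4, 0.6]))
        row = loo.summary.iloc[0]
        assert row["winner"] == "s0"
        assert row["improvement"] == pytest.approx(1.0)

    def test_tie_broken_by_cell_fraction_then_label(self):
        loo = cd.subpop_residuals(self._loo_row(x_hat=4.0), self._subpop([3.0, 5.0], [0.2, 0.8]))
        assert loo.summary.iloc[0]["winner"] == "s1"  # equal residual, larger fraction
        loo2 = cd.subpop_residuals(self._loo_row(x_hat=4.0), self._subpop([3.0, 5.0], [0.5, 0.5]))
        assert loo2.summary.iloc[0]["winner"] == "s0"  # full tie -> lexicographic

    def test_single_subpopulation_still_scored(self):
        loo = cd.subpop_residuals(self._loo_row(x_hat=4.0), self._subpop([4.5], [1.0]))
        row = loo.summary.iloc[0]
        assert row["winner"] == "s0"
        assert row["improvement"] == pytest.approx((1.0 - 0.5) / 1.0)

    def test_label_permutation_permutes_winners(self, limiting_cohort, cohort_beta):
        co = limiting_cohort
        preds = cd.loo_fit_all(cohort_beta, co.bulk_expression)
        loo = cd.subpop_residuals(preds, co.subpop_expression)
        swapped = co.subpop_expression.copy()
        swapped["subpopulation"] = swapped["subpopulation"].map({"subA": "subB", "subB": "subA"})
        loo_sw = cd.subpop_residuals(preds, swapped)
        mapping = {"subA": "subB", "subB": "subA"}
        assert (loo_sw.summary["winner"] == loo.summary["winner"].map(mapping)).all()


class TestR2Compare:
    def test_perfect_relation_gives_unit_r2(self):
        beta, bulk = _affine_beta_table()
        preds = cd.loo_fit_all(beta, bulk)
        sub = pd.DataFrame(
            {
                "gene": "g",
                "organoid": preds["organoid"],
                "subpopulation": "s0",
                "mean_expr": preds["x_bulk"].to_numpy(),
                "cell_fraction": 1.0,
            }
        )
        loo = cd.subpop_residuals(preds, sub)
        r2 = cd.r2_compare(loo)
        assert r2.loc[0, "r2_bulk"] == pytest.approx(1.0)
        assert r2.loc[0, "r2_sub"] == pytest.approx(1.0)

    def test_winner_equal_bulk_makes_r2_equal(self):
        beta, bulk = _affine_beta_table(noise=0.3, seed=3)
        preds = cd.loo_fit_all(beta, bulk)
        sub = pd.DataFrame(
            {
                "gene": "g",
                "organoid": preds["organoid"],
                "subpopulation": "s0",
                "mean_expr": preds["x_bulk"].to_numpy(),
                "cell_fraction": 1.0,
            }
        )
        loo = cd.subpop_residuals(preds, sub)
        r2 = cd.r2_compare(loo)
        assert r2.loc[0, "r2_sub"] == pytest.approx(r2.loc[0, "r2_bulk"])


class TestWinnerFrequency:
    def _loo_with_winners(self, winners):
        summary = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(winners))],
                "organoid": "O1",
                "beta": -1.0,
                "x_hat": 0.0,
                "x_bulk": 0.0,
                "res_bulk": 1.0,
                "winner": winners,
                "res_winner": 0.5,
                "improvement": 0.5,
                "n_train": 5,
                "n_subpops": 2,
            }
        )
        return cd.LOOResult(summary=summary, residuals=pd.DataFrame())

    def test_fractions(self):
        freq = cd.winner_frequency(self._loo_with_winners(["A"] * 6 + ["B"] * 4), "O1")
        assert freq["A"] == pytest.approx(0.6)
        assert freq.sum() == pytest.approx(1.0)

    def test_single_gene(self):
        freq = cd.winner_frequency(self._loo_with_winners(["A"]), "O1")
        assert freq.to_dict() == {"A": 1.0}


class TestGTest:
    def test_uniform_table_gives_zero(self):
        g, df, p = cd.gtest_independence([[10, 10], [10, 10]])
        assert g == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_hand_evaluated_association(self):
        g, df, _ = cd.gtest_independence([[20, 5], [5, 20]])
        assert g == pytest.approx(19.2745, abs=1e-3)
        assert df == 1

    def test_agrees_with_brute_force_on_random_tables(self, rng):
        for _ in range(100):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            obs = rng.integers(1, 60, size=shape).astype(float)
            g, df, p = cd.gtest_independence(obs)
            # independent brute-force evaluation of 2 * sum O * ln(O/E)
            total = obs.sum()
            g_ref = 0.0
            for i in range(shape[0]):
                for j in range(shape[1]):
                    e = obs[i].sum() * obs[:, j].sum() / total
                    if obs[i, j] > 0:
                        g_ref += 2.0 * obs[i, j] * np.log(obs[i, j] / e)
            assert g == pytest.approx(g_ref, abs=1e-10)
            assert df == (shape[0] - 1) * (shape[1] - 1)

    def test_agrees_with_scipy_log_likelihood_ratio(self, rng):
        obs = rng.integers(1, 40, size=(3, 4))
        g, df, p = cd.gtest_independence(obs)
        ref = stats.chi2_contingency(obs, correction=False, lambda_="log-likelihood")
        assert g == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            g, df, _ = cd.gtest_independence([[10, 0, 5], [8, 0, 7]])
        assert df == 1

    def test_pvalues_roughly_uniform_under_independence(self, rng):
        pvals = []
        for _ in range(200):
            row = rng.dirichlet([5, 5])
            col = rng.dirichlet([5, 5])
            obs = rng.multinomial(500, np.outer(row, col).ravel()).reshape(2, 2)
            if (obs.sum(axis=0) > 0).all() and (obs.sum(axis=1) > 0).all():
                pvals.append(cd.gtest_independence(obs)[2])
        ks = stats.ks_1samp(pvals, stats.uniform.cdf)
        assert ks.pvalue > 0.001


class TestWinnerLowexprAssociation:
    def test_perfect_association(self):
        n = 50
        summary = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "organoid": "O1",
                "beta": -1.0,
                "x_hat": 0.0,
                "x_bulk": 0.0,
                "res_bulk": 1.0,
                "winner": ["A" if i % 2 else "B" for i in range(n)],
                "res_winner": 0.5,
                "improvement": 0.5,
                "n_train": 5,
                "n_subpops": 2,
            }
        )
        sub = pd.DataFrame(
            {
                "gene": np.repeat([f"g{i}" for i in range(n)], 2),
                "organoid": "O1",
                "subpopulation": ["A", "B"] * n,
                # the winner is always the lowest expressor
                "mean_expr": [
                    (1.0 if summary.loc[i // 2, "winner"] == lab else 5.0)
                    for i, lab in enumerate(["A", "B"] * n)
                ],
                "cell_fraction": 0.5,
            }
        )
        res = cd.winner_lowexpr_association(
            cd.LOOResult(summary=summary, residuals=pd.DataFrame()), sub
        )
        row = res.per_organoid.iloc[0]
        assert row["match_rate"] == 1.0
        assert row["binom_p"] == pytest.approx(0.5**n, rel=1e-6)
        assert row["g_p"] < 1e-6

    def test_exchangeable_null_near_chance(self, rng):
        n = 400
        winners = rng.choice(["A", "B"], size=n)
        lows = rng.choice(["A", "B"], size=n)
        summary = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "organoid": "O1",
                "beta": -1.0,
                "x_hat": 0.0,
                "x_bulk": 0.0,
                "res_bulk": 1.0,
                "winner": winners,
                "res_winner": 0.5,
                "improvement": 0.5,
                "n_train": 5,
                "n_subpops": 2,
            }
        )
        sub = pd.DataFrame(
            {
                "gene": np.repeat([f"g{i}" for i in range(n)], 2),
                "organoid": "O1",
                "subpopulation": ["A", "B"] * n,
                "mean_expr": [
                    (1.0 if lows[i // 2] == lab else 5.0) for i, lab in enumerate(["A", "B"] * n)
                ],
                "cell_fraction": 0.5,
            }
        )
        res = cd.winner_lowexpr_association(
            cd.LOOResult(summary=summary, residuals=pd.DataFrame()), sub
        )
        rate = res.per_organoid.iloc[0]["match_rate"]
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n)
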