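"""Statistics layer: chi-square, Fisher's exact test, IRLS logistic GLM.

Independent oracles: a direct-loop chi-square, brute-force enumeration of
all margin-consistent tables for Fisher, closed-form log-odds contrasts for
the saturated GLM, and scipy/statsmodels as third-party cross-checks.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.stats import contingency as sp_contingency

import seafood_audit as sa
from seafood_audit.classify import ContingencyTable, DegenerateTableError
from seafood_audit.stats import compare_models, fit_logistic, logistic_design


def table(a, b, c, d):
    return ContingencyTable(((a, b), (c, d)))


# -- oracles ----------------------------------------------------------------


def chi_square_loop(counts):
    """Textbook X^2 = sum (O-E)^2/E computed cell by cell."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = counts[i].sum() * counts[:, j].sum() / n
            stat += (counts[i, j] - e) ** 2 / e
    return stat


def fisher_enumerate(counts, alternative):
    """Brute force: every 2x2 table with the observed margins."""
    counts = np.asarray(counts, int)
    r, c, n = counts[0].sum(), counts[:, 0].sum(), counts.sum()
    x_obs = counts[0, 0]

    def prob(x):
        return (
            math.comb(r, x) * math.comb(n - r, c - x) / math.comb(n, c)
        )

    support = [x for x in range(n + 1)
               if 0 <= r - x and 0 <= c - x and 0 <= n - r - c + x]
    p_obs = prob(x_obs)
    if alternative == "greater":
        return sum(prob(x) for x in support if x >= x_obs)
    if alternative == "less":
        return sum(prob(x) for x in support if x <= x_obs)
    return sum(p for p in map(prob, support) if p <= p_obs * (1 + 1e-7))


def random_tables(n_tables, max_total, seed):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_tables:
        cells = rng.multinomial(
            rng.integers(4, max_total + 1), rng.dirichlet(np.ones(4))
        )
        t = cells.reshape(2, 2)
        if t.sum(axis=0).min() > 0 and t.sum(axis=1).min() > 0:
            out.append(t)
    return out


# -- chi-square -------------------------------------------------------------


class TestChiSquare:
    @pytest.mark.parametrize(
        "counts, expected_stat, expected_p",
        [
            # ambiguity by cohort; total mislabeling; conservative mislabeling
            ([[89, 18], [176, 169]], 33.5, 7.06e-9),
            ([[37, 72], [112, 235]], 0.04, 0.8),
            ([[22, 87], [74, 273]], 0.01, 0.9),
        ],
    )
    def test_survey_values_with_continuity_correction(
        self, counts, expected_stat, expected_p
    ):
        res = sa.chi_square_2x2(table(*np.ravel(counts)))
        ndigits = max(len(str(expected_stat).split(".")[1]), 1)
        assert round(res.statistic, ndigits) == expected_stat
        assert res.p_value == pytest.approx(expected_p, rel=0.08)
        assert res.df == 1

    def test_independent_table_gives_zero_uncorrected(self):
        res = sa.chi_square_2x2(table(10, 20, 30, 60),
                                continuity_correction=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_uncorrected_matches_loop_oracle_and_scipy(self):
        for t in random_tables(100, 200, seed=11):
            res = sa.chi_square_2x2(ContingencyTable(tuple(map(tuple, t))),
                                    continuity_correction=False)
            assert res.statistic == pytest.approx(chi_square_loop(t))
            sp = scipy.stats.chi2_contingency(t, correction=False)
            assert res.statistic == pytest.approx(sp.statistic)
            assert res.p_value == pytest.approx(sp.pvalue)

    def test_corrected_matches_scipy(self):
        for t in random_tables(50, 200, seed=12):
            res = sa.chi_square_2x2(ContingencyTable(tuple(map(tuple, t))))
            sp = scipy.stats.chi2_contingency(t, correction=True)
            assert res.statistic == pytest.approx(sp.statistic)

    def test_degenerate_margin_advises_fisher(self):
        with pytest.raises((DegenerateTableError, ValueError)):
            sa.chi_square_2x2(table(0, 0, 5, 5))


# -- Fisher -----------------------------------------------------------------


class TestFisherExact:
    def test_substitution_by_concern_example(self):
        """[[2,0],[6,19]]: one-sided p = C(8,2)/C(27,2) = 0.0798; the
        two-sided inversion CI reaches infinity with a lower bound near 0.5."""
        t = table(2, 0, 6, 19)
        res = sa.fisher_exact(t, alternative="greater")
        assert res.p_value == pytest.approx(
            math.comb(8, 2) / math.comb(27, 2)
        )
        assert res.ci[1] == math.inf
        res2 = sa.fisher_exact(t, alternative="two_sided")
        assert res2.p_value == pytest.approx(0.0798, abs=5e-4)
        assert res2.odds_ratio == math.inf  # zero cell: conditional MLE diverges
        assert res2.ci[0] == pytest.approx(0.47, abs=0.05)
        assert res2.ci[1] == math.inf

    def test_balanced_table(self):
        res = sa.fisher_exact(table(1, 1, 1, 1))
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("alternative",
                             ["two_sided", "greater", "less"])
    def test_matches_enumeration_oracle(self, alternative):
        for t in random_tables(60, 40, seed=21):
            res = sa.fisher_exact(ContingencyTable(tuple(map(tuple, t))),
                                  alternative=alternative)
            assert res.p_value == pytest.approx(
                fisher_enumerate(t, alternative), abs=1e-10
            ), t.tolist()

    def test_two_sided_at_least_one_sided(self):
        for t in random_tables(40, 40, seed=22):
            two = sa.fisher_exact(ContingencyTable(tuple(map(tuple, t)))).p_value
            one = min(
                sa.fisher_exact(ContingencyTable(tuple(map(tuple, t))),
                                alternative=alt).p_value
                for alt in ("greater", "less")
            )
            assert two >= one - 1e-12

    def test_matches_scipy_p_and_conditional_mle(self):
        for t in random_tables(30, 60, seed=23):
            res = sa.fisher_exact(ContingencyTable(tuple(map(tuple, t))))
            assert res.p_value == pytest.approx(
                scipy.stats.fisher_exact(t)[1], abs=1e-9
            )
            sp_or = sp_contingency.odds_ratio(t)  # conditional MLE
            if np.isfinite(sp_or.statistic) and sp_or.statistic > 0:
                assert res.odds_ratio == pytest.approx(
                    sp_or.statistic, rel=1e-4
                )
                lo, hi = sp_or.confidence_interval(0.95)
                assert res.ci[0] == pytest.approx(lo, rel=1e-3, abs=1e-9)
                if math.isfinite(hi):
                    assert res.ci[1] == pytest.approx(hi, rel=1e-3)


# -- logistic regression ----------------------------------------------------


def simulate_cells(beta, n, seed):
    """Draw (precision, accuracy, concern) data from 2x2x2 cell log-odds."""
    rng = np.random.default_rng(seed)
    precision = rng.integers(0, 2, n)
    accuracy = rng.integers(0, 2, n)
    X, names = logistic_design(precision, accuracy)
    p = 1.0 / (1.0 + np.exp(-(X @ np.asarray(beta))))
    y = (rng.random(n) < p).astype(float)
    return X, names, y


class TestLogistic:
    def test_null_data_gives_null_effects(self):
        rng = np.random.default_rng(3)
        n = 4000
        precision = rng.integers(0, 2, n)
        accuracy = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.4).astype(float)
        X, names = logistic_design(precision, accuracy)
        fit = fit_logistic(X, y, names)
        assert np.all(np.abs(fit.coefficients[1:]) < 0.25)
        assert fit.mcfadden_r2 < 0.01

    def test_saturated_model_reproduces_cell_frequencies(self):
        X, names, y = simulate_cells([-2.11, 3.39, 3.21, -3.39], 2000, seed=5)
        fit = fit_logistic(X, y, names)
        for p_val, a_val in itertools.product((0, 1), repeat=2):
            mask = (X[:, 1] == p_val) & (X[:, 2] == a_val)
            assert fit.fitted[mask].mean() == pytest.approx(
                y[mask].mean(), abs=1e-10
            )
        # closed-form log-odds contrasts of the four cells
        lo = {}
        for p_val, a_val in itertools.product((0, 1), repeat=2):
            mask = (X[:, 1] == p_val) & (X[:, 2] == a_val)
            m = y[mask].mean()
            lo[(p_val, a_val)] = math.log(m / (1 - m))
        expected = [
            lo[(0, 0)],
            lo[(1, 0)] - lo[(0, 0)],
            lo[(0, 1)] - lo[(0, 0)],
            lo[(1, 1)] - lo[(1, 0)] - lo[(0, 1)] + lo[(0, 0)],
        ]
        assert np.allclose(fit.coefficients, expected, atol=1e-8)

    def test_matches_statsmodels(self):
        X, names, y = simulate_cells([-1.0, 1.2, 0.5, -0.7], 1500, seed=6)
        fit = fit_logistic(X, y, names)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.coefficients, ref.params, atol=1e-8)
        assert np.allclose(fit.standard_errors, ref.bse, atol=1e-8)
        assert fit.log_likelihood == pytest.approx(ref.llf)
        assert fit.aic == pytest.approx(ref.aic)
        assert fit.mcfadden_r2 == pytest.approx(ref.prsquared)

    def test_recovers_survey_model_coefficients(self):
        """Simulating n=10,000 from the fitted finfish model's log-odds
        (-2.11, +3.39, +3.21, -3.39) recovers each coefficient within 3 SE."""
        beta = np.array([-2.11, 3.39, 3.21, -3.39])
        X, names, y = simulate_cells(beta, 10_000, seed=7)
        fit = fit_logistic(X, y, names)
        assert np.all(np.abs(fit.coefficients - beta)
                      <= 3 * fit.standard_errors)
        assert fit.converged and not fit.separation
        assert max(fit.vif.values()) < 5.0 or "precision:accuracy" in fit.vif

    def test_importance_is_abs_z_and_or_is_exp_beta(self):
        X, names, y = simulate_cells([-1.0, 1.0, 0.5, 0.0], 1000, seed=8)
        fit = fit_logistic(X, y, names)
        for i, name in enumerate(names):
            assert fit.importance[name] == abs(float(fit.z_values[i]))
        assert np.allclose(fit.odds_ratios, np.exp(fit.coefficients))
        assert np.all(fit.odds_ratio_ci[:, 0] <= fit.odds_ratios + 1e-12)
        assert np.all(fit.odds_ratios <= fit.odds_ratio_ci[:, 1] + 1e-12)

    def test_mcfadden_zero_for_intercept_only_and_weakly_increasing(self):
        X, names, y = simulate_cells([-0.5, 0.8, 0.4, 0.2], 1200, seed=9)
        only = fit_logistic(X[:, :1], y, ("intercept",))
        mains = fit_logistic(X[:, :3], y, ("intercept", "precision",
                                           "accuracy"))
        full = fit_logistic(X, y, tuple(names))
        assert only.mcfadden_r2 == pytest.approx(0.0, abs=1e-10)
        assert only.mcfadden_r2 <= mains.mcfadden_r2 + 1e-12
        assert mains.mcfadden_r2 <= full.mcfadden_r2 + 1e-12

    def test_separation_is_flagged(self):
        x = np.array([0, 0, 0, 1, 1, 1], float)
        X = np.column_stack([np.ones_like(x), x])
        y = x.copy()  # perfect separation
        fit = fit_logistic(X, y, ("intercept", "x"))
        assert fit.separation

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10), np.arange(10)])
        y = (np.arange(10) > 4).astype(float)
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(X, y)

    def test_single_response_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((5, 1)), np.zeros(5))

    @given(st_.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_irls_loglikelihood_and_gradient(self, seed):
        """At convergence the score (gradient of the log-likelihood) is
        numerically zero."""
        X, names, y = simulate_cells([-1.0, 1.5, 0.8, -1.0], 400,
                                     seed=seed % (2**31))
        fit = fit_logistic(X, y, names)
        grad = X.T @ (y - fit.fitted)
        assert np.abs(grad).max() < 1e-6


class TestCompareModels:
    def test_interaction_model_wins_on_interaction_data(self):
        X, names, y = simulate_cells([-2.0, 3.0, 3.0, -3.2], 10_000, seed=10)
        full = fit_logistic(X, y, names)
        mains = fit_logistic(X[:, :3], y, names[:3])
        ranked = compare_models([mains, full])
        assert ranked[0][0] is full
        assert ranked[0][1] == 0.0 and ranked[1][1] > 0

    def test_identical_models_tie_and_single_fit_trivial(self):
        X, names, y = simulate_cells([-1.0, 0.5, 0.5, 0.0], 500, seed=11)
        fit = fit_logistic(X, y, names)
        ranked = compare_models([fit, fit])
        assert ranked[0][1] == 0.0 and ranked[1][1] == 0.0
        assert compare_models([fit])[0][0] is fit

    def test_mismatched_responses_rejected(self):
        X1, n1, y1 = simulate_cells([-1.0, 0.5, 0.5, 0.0], 500, seed=12)
        X2, n2, y2 = simulate_cells([-1.0, 0.5, 0.5, 0.0], 400, seed=13)
        with pytest.raises(ValueError):
            compare_models([fit_logistic(X1, y1, n1),
                            fit_logistic(X2, y2, n2)])
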