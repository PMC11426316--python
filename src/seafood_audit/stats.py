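"""Categorical statistics for the audit: chi-square, Fisher's exact test and
logistic regression, implemented from first principles.

The 2x2 chi-square uses the Yates continuity correction by default (the
convention the audit's printed test statistics follow).  Fisher's exact test
enumerates the hypergeometric distribution over all tables with the observed
margins; its odds ratio is the conditional maximum-likelihood estimate under
the noncentral hypergeometric likelihood and the confidence interval inverts
the exact test.  The logistic regression is fit by iteratively reweighted
least squares (IRLS) with Wald inference, AIC/AICc model comparison,
McFadden's pseudo-R-squared, variance-inflation screening and |z| variable
importance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy import stats as sps

from .classify import ContingencyTable, DegenerateTableError

__all__ = [
    "TestResult",
    "GlmFit",
    "SeparationWarning",
    "chi_square_2x2",
    "fisher_exact",
    "fit_logistic",
    "logistic_design",
    "compare_models",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one association test on a 2x2 table."""

    method: str
    p_value: float
    statistic: float | None = None
    df: int | None = None
    odds_ratio: float | None = None
    ci: tuple[float, float] | None = None
    alternative: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def chi_square_2x2(
    table: ContingencyTable, continuity_correction: bool = True
) -> TestResult:
    """Pearson chi-square test on a 2x2 table, Yates-corrected by default.

    X^2 = sum (|O - E| - c)^2 / E with c = 1/2 when corrected; the
    correction is capped at |O - E| so a cell can never overshoot.  One
    degree of freedom; the p-value is the upper chi-square tail.
    """
    table.require_nondegenerate()
    obs = table.array
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected == 0).any():
        raise DegenerateTableError(
            "an expected cell count is zero; use Fisher's exact test"
        )
    diff = np.abs(obs - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    a, b, c, d = obs.ravel()
    odds = _sample_odds_ratio(a, b, c, d)
    return TestResult(
        method="chi_square_yates" if continuity_correction else "chi_square",
        statistic=stat,
        df=1,
        p_value=p,
        odds_ratio=odds,
    )


def _sample_odds_ratio(a: float, b: float, c: float, d: float) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


# -- Fisher's exact test ----------------------------------------------------
#
# Condition on both margins.  With table [[x, r - x], [c - x, n - r - c + x]]
# (r = first row total, c = first column total, n = grand total) the count x
# ranges over max(0, r + c - n) .. min(r, c) and, under odds ratio psi, has
# the noncentral (Fisher) hypergeometric distribution
#     P(x) ~ C(r, x) C(n - r, c - x) psi^x.


def _support(r: int, c: int, n: int) -> np.ndarray:
    return np.arange(max(0, r + c - n), min(r, c) + 1)


def _log_weights(xs: np.ndarray, r: int, c: int, n: int) -> np.ndarray:
    return (
        special.gammaln(r + 1)
        - special.gammaln(xs + 1)
        - special.gammaln(r - xs + 1)
        + special.gammaln(n - r + 1)
        - special.gammaln(c - xs + 1)
        - special.gammaln(n - r - c + xs + 1)
    )


def _pmf(psi: float, xs: np.ndarray, logw: np.ndarray) -> np.ndarray:
    if psi <= 0:
        out = np.zeros_like(logw)
        out[np.argmin(xs)] = 1.0
        return out
    logp = logw + xs * math.log(psi)
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def _cmle_odds_ratio(x: int, xs: np.ndarray, logw: np.ndarray) -> float:
    """Conditional MLE: psi with E_psi[X] equal to the observed count."""
    if x == xs.min():
        return 0.0
    if x == xs.max():
        return math.inf

    def mean_shift(log_psi: float) -> float:
        p = _pmf(math.exp(log_psi), xs, logw)
        return float((p * xs).sum()) - x

    lo, hi = -1.0, 1.0
    while mean_shift(lo) > 0:
        lo *= 2
    while mean_shift(hi) < 0:
        hi *= 2
    return math.exp(optimize.brentq(mean_shift, lo, hi, xtol=1e-12))


def _tail(psi: float, x: int, xs: np.ndarray, logw: np.ndarray, upper: bool) -> float:
    p = _pmf(psi, xs, logw)
    return float(p[xs >= x].sum()) if upper else float(p[xs <= x].sum())


def _invert_tail(
    x: int, xs: np.ndarray, logw: np.ndarray, alpha: float, upper: bool
) -> float:
    """psi at which the chosen tail probability of x equals alpha."""

    def f(log_psi: float) -> float:
        return _tail(math.exp(log_psi), x, xs, logw, upper) - alpha

    # The upper tail P(X >= x) increases with psi, the lower tail decreases.
    lo, hi = -1.0, 1.0
    for _ in range(200):
        if f(lo) * f(hi) <= 0:
            break
        lo *= 2
        hi *= 2
    else:  # pragma: no cover - tails are monotone, a bracket always exists
        raise RuntimeError("failed to bracket the confidence bound")
    return math.exp(optimize.brentq(f, lo, hi, xtol=1e-12))


def fisher_exact(
    table: ContingencyTable,
    alternative: str = "two_sided",
    confidence: float = 0.95,
) -> TestResult:
    """Fisher's exact test by full hypergeometric enumeration.

    ``two_sided`` sums the probabilities of every margin-consistent table no
    more probable than the observed one; one-sided alternatives sum the
    corresponding tail.  The odds ratio is the conditional MLE and the
    confidence interval inverts the exact test (one-sided alternatives give
    half-open intervals reaching 0 or infinity).
    """
    if alternative not in {"two_sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    obs = table.array.astype(int)
    x = int(obs[0, 0])
    r, c, n = int(obs[0].sum()), int(obs[:, 0].sum()), int(obs.sum())
    xs = _support(r, c, n)
    logw = _log_weights(xs, r, c, n)
    null = _pmf(1.0, xs, logw)
    p_obs = float(null[xs == x][0])

    if alternative == "greater":
        p = float(null[xs >= x].sum())
    elif alternative == "less":
        p = float(null[xs <= x].sum())
    else:
        p = float(null[null <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)

    odds = _cmle_odds_ratio(x, xs, logw)
    alpha = 1.0 - confidence
    at_min, at_max = x == xs.min(), x == xs.max()
    if alternative == "greater":
        lower = 0.0 if at_min else _invert_tail(x, xs, logw, alpha, upper=True)
        ci = (lower, math.inf)
    elif alternative == "less":
        upper = math.inf if at_max else _invert_tail(x, xs, logw, alpha, upper=False)
        ci = (0.0, upper)
    else:
        lower = 0.0 if at_min else _invert_tail(x, xs, logw, alpha / 2, upper=True)
        upper = (
            math.inf if at_max else _invert_tail(x, xs, logw, alpha / 2, upper=False)
        )
        ci = (lower, upper)
    return TestResult(
        method="fisher_exact",
        p_value=p,
        odds_ratio=odds,
        ci=ci,
        alternative=alternative,
    )


# -- Logistic regression ----------------------------------------------------


class SeparationWarning(UserWarning):
    """Quasi-separated data: coefficients diverge; estimates are unreliable."""


@dataclass(frozen=True)
class GlmFit:
    """A fitted logistic regression with Wald inference and fit diagnostics."""

    term_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    odds_ratio_ci: np.ndarray  # (k, 2)
    log_likelihood: float
    null_log_likelihood: float
    aic: float
    aicc: float
    mcfadden_r2: float
    vif: dict[str, float]
    n_obs: int
    n_events: int
    converged: bool
    separation: bool
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def importance(self) -> dict[str, float]:
        """Variable importance: |z| per term, the caret convention."""
        return {
            name: abs(float(z))
            for name, z in zip(self.term_names, self.z_values)
        }


def logistic_design(
    precision: np.ndarray, accuracy: np.ndarray, interaction: bool = True
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix for the precision x accuracy conservation model.

    ``precision``: 1 = ambiguous name, 0 = precise; ``accuracy``: 1 =
    mislabeled (conservative), 0 = correctly labeled.
    """
    precision = np.asarray(precision, dtype=float)
    accuracy = np.asarray(accuracy, dtype=float)
    cols = [np.ones_like(precision), precision, accuracy]
    names = ["intercept", "precision", "accuracy"]
    if interaction:
        cols.append(precision * accuracy)
        names.append("precision:accuracy")
    return np.column_stack(cols), tuple(names)


def _bernoulli_ll(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, float, bool, bool]:
    """IRLS for the Bernoulli GLM with logit link.

    Returns (beta, covariance, log-likelihood, converged, separation).
    The log-likelihood is non-decreasing across iterations (step-halving
    guards the rare overshoot).
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll = _bernoulli_ll(y, np.full(n, y.mean() if 0 < y.mean() < 1 else 0.5))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            step_beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            raise ValueError("design matrix is rank deficient") from None
        new_ll = _bernoulli_ll(y, special.expit(X @ step_beta))
        shrink = 0
        while new_ll < ll - 1e-12 and shrink < 30:
            step_beta = (step_beta + beta) / 2
            new_ll = _bernoulli_ll(y, special.expit(X @ step_beta))
            shrink += 1
        done = abs(new_ll - ll) < tol * (abs(ll) + 1.0)
        beta, ll = step_beta, new_ll
        if done:
            converged = True
            break
    separation = bool(np.abs(beta).max() > 15.0)
    mu = special.expit(X @ beta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    fisher_info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(fisher_info)
    return beta, cov, ll, converged, separation


def _vif(X: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    """Variance inflation factors from the predictor correlation inverse."""
    keep = [i for i, nm in enumerate(names) if nm != "intercept"]
    if len(keep) < 2:
        return {names[i]: 1.0 for i in keep}
    sub = X[:, keep]
    corr = np.corrcoef(sub, rowvar=False)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(corr)
    return {names[i]: float(inv[j, j]) for j, i in enumerate(keep)}


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    term_names: tuple[str, ...] | None = None,
    confidence: float = 0.95,
) -> GlmFit:
    """Fit a logistic regression by IRLS and report Wald inference.

    Requires at least one observation of each response class and a full-rank
    design.  AIC = 2k - 2l; AICc adds the small-sample correction
    2k(k+1)/(n-k-1).  McFadden's pseudo-R-squared is 1 - l/l0 against the
    intercept-only model.  Separation is flagged (diverging coefficients),
    never silently accepted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, k) aligned with y")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be 0/1")
    if y.min() == y.max():
        raise ValueError("need both response classes to fit a logistic model")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    n, k = X.shape
    if term_names is None:
        term_names = tuple(f"x{i}" for i in range(k))

    beta, cov, ll, converged, separation = _irls(X, y)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * sps.norm.sf(np.abs(z))
    zcrit = sps.norm.ppf(0.5 + confidence / 2)
    with np.errstate(over="ignore"):  # a separated fit's bound is +inf
        or_ci = np.exp(np.column_stack([beta - zcrit * se, beta + zcrit * se]))

    # Null (intercept-only) log-likelihood in closed form.
    pbar = y.mean()
    ll0 = _bernoulli_ll(y, np.full(n, pbar))

    aic = 2 * k - 2 * ll
    aicc = aic + (2 * k * (k + 1)) / (n - k - 1) if n > k + 1 else math.inf
    mcfadden = 0.0 if ll0 == 0 else 1.0 - ll / ll0
    return GlmFit(
        term_names=term_names,
        coefficients=beta,
        standard_errors=se,
        z_values=z,
        p_values=p,
        odds_ratios=np.exp(beta),
        odds_ratio_ci=or_ci,
        log_likelihood=ll,
        null_log_likelihood=ll0,
        aic=aic,
        aicc=aicc,
        mcfadden_r2=max(mcfadden, 0.0),
        vif=_vif(X, term_names),
        n_obs=n,
        n_events=int(y.sum()),
        converged=converged,
        separation=separation,
        fitted=special.expit(X @ beta),
    )


def compare_models(fits: list[GlmFit]) -> list[tuple[GlmFit, float]]:
    """Rank fits of the same response by AICc; returns (fit, delta-AICc).

    All fits must share the response vector (checked through n and the
    event count); mismatched data makes information criteria incomparable.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n0, e0 = fits[0].n_obs, fits[0].n_events
    for f in fits[1:]:
        if (f.n_obs, f.n_events) != (n0, e0):
            raise ValueError("fits do not share the same response vector")
    ranked = sorted(fits, key=lambda f: f.aicc)
    best = ranked[0].aicc
    return [(f, f.aicc - best) for f in ranked]
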