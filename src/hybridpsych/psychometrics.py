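"""Psychometric maximum-likelihood fitting and bias inference.

The choice model is a 4-parameter cumulative normal,

    p(x) = gamma + (1 - gamma - lambda) * Phi((x - mu) / sigma),

mapping the log visible-energy ratio x = ln(E_cardinal / E_intercardinal) to
the probability of selecting the cardinal component.  The *bias* is -mu, the
negated 50%-point shift: positive bias means the cardinal (or, after pooling,
the named-category) component dominates perception at equal visible energy.

Fitting maximizes the binomial log-likelihood over a bounded parameter box
with a deterministic multi-start strategy (coarse grid, then local
refinement), so fits are exactly reproducible from the data alone.  The bias
test compares the unconstrained fit against a nested fit with mu forced to 0
via a generalized likelihood-ratio test with one degree of freedom:
p = 1 - F_chi2(1)(-2 ln L), where L is the constrained/unconstrained
likelihood ratio.

Per-category ("categorical") biases pool the two conditions in which a
category occupied either filter band, re-expressing the stimulus axis as
ln(E_category / E_other) and recoding success as "category chosen".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

__all__ = [
    "ParameterBounds",
    "PsychometricFit",
    "BiasTest",
    "GroupStats",
    "DegenerateStatisticsError",
    "psychometric_function",
    "negative_log_likelihood",
    "fit_psychometric",
    "lr_test_bias",
    "profile_ci_mu",
    "aggregate_binomial",
    "fit_condition",
    "pool_categorical",
    "group_bias_stats",
    "cohens_d_from_t",
]


class DegenerateStatisticsError(ValueError):
    """Statistics are undefined for this input (e.g. zero variance)."""


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for (mu, sigma, gamma, lambda).

    sigma in [0.01, 20] ln-units; gamma, lambda in [0, 0.25] so the fitted
    function is always strictly increasing (1 - gamma - lambda >= 0.5).
    """

    mu: tuple[float, float] = (-20.0, 20.0)
    sigma: tuple[float, float] = (0.01, 20.0)
    gamma: tuple[float, float] = (0.0, 0.25)
    lam: tuple[float, float] = (0.0, 0.25)

    def as_list(self) -> list[tuple[float, float]]:
        return [self.mu, self.sigma, self.gamma, self.lam]


DEFAULT_BOUNDS = ParameterBounds()


def psychometric_function(x, mu: float, sigma: float, gamma: float, lam: float):
    """p(x) = gamma + (1 - gamma - lambda) Phi((x - mu)/sigma)."""
    x = np.asarray(x, dtype=float)
    return gamma + (1.0 - gamma - lam) * ndtr((x - mu) / sigma)


def negative_log_likelihood(params, x, k, n) -> float:
    """Binomial negative log-likelihood of (mu, sigma, gamma, lambda)."""
    mu, sigma, gamma, lam = params
    p = np.clip(psychometric_function(x, mu, sigma, gamma, lam), 1e-12, 1 - 1e-12)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


@dataclass
class PsychometricFit:
    mu: float
    sigma: float
    gamma: float
    lam: float
    log_likelihood: float
    converged: bool
    degenerate: bool = False
    levels: np.ndarray = field(default=None, repr=False)
    k: np.ndarray = field(default=None, repr=False)
    n: np.ndarray = field(default=None, repr=False)
    message: str = ""

    @property
    def bias(self) -> float:
        """Bias = -mu: positive when the cardinal/named component dominates."""
        return -self.mu

    def predict(self, x):
        return psychometric_function(x, self.mu, self.sigma, self.gamma, self.lam)


@dataclass
class BiasTest:
    deviance: float
    p_value: float
    significant: bool
    alpha: float
    unconstrained: PsychometricFit
    constrained: PsychometricFit


@dataclass
class GroupStats:
    n: int
    mean_bias: float
    t_statistic: float
    p_value: float
    cohens_d: float


def _validate_data(levels, k, n):
    x = np.asarray(levels, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if not (x.shape == k.shape == n.shape):
        raise ValueError("levels, k and n must have identical shapes")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct stimulus levels")
    if np.any(n < 1):
        raise ValueError("every level needs at least one trial")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")
    return x, k, n


def _grid_starts(x, k, n, bounds: ParameterBounds, fix_mu: float | None, top: int = 3):
    """Deterministic coarse grid; returns the `top` best parameter vectors."""
    span = max(x.max() - x.min(), 1e-3)
    if fix_mu is None:
        mus = np.unique(
            np.clip(
                np.concatenate([np.linspace(x.min(), x.max(), 7), [0.0]]),
                *bounds.mu,
            )
        )
    else:
        mus = np.array([fix_mu])
    sigmas = np.clip(span * np.array([0.05, 0.15, 0.4, 1.0, 2.0]), *bounds.sigma)
    rates = np.array([0.005, 0.05])

    grid = np.array(list(itertools.product(mus, sigmas, rates, rates)))
    mu_g, sg_g, ga_g, la_g = (grid[:, i : i + 1] for i in range(4))
    p = ga_g + (1.0 - ga_g - la_g) * ndtr((x[None, :] - mu_g) / sg_g)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    nll = -np.sum(k[None, :] * np.log(p) + (n - k)[None, :] * np.log1p(-p), axis=1)
    order = np.argsort(nll)[:top]
    return grid[order]


def fit_psychometric(
    levels,
    k_cardinal,
    n_total,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    fix_mu: float | None = None,
) -> PsychometricFit:
    """Bounded ML fit of the 4-parameter cumulative normal.

    Deterministic multi-start: the best points of a coarse parameter grid are
    refined with L-BFGS-B.  With ``fix_mu`` set, mu is held fixed and only
    (sigma, gamma, lambda) are optimized (the nested model of the bias test).

    Data in which every response is identical (all k == 0 or all k == n)
    leave mu unidentifiable; the fit is returned flagged ``degenerate`` and
    unconverged rather than raising.
    """
    x, k, n = _validate_data(levels, k_cardinal, n_total)

    degenerate = bool(np.all(k == 0) or np.all(k == n))
    starts = _grid_starts(x, k, n, bounds, fix_mu)

    box = bounds.as_list()
    if fix_mu is not None:
        box = box[1:]

    def objective(theta):
        params = theta if fix_mu is None else np.concatenate([[fix_mu], theta])
        return negative_log_likelihood(params, x, k, n)

    best = None
    any_success = False
    for start in starts:
        theta0 = start if fix_mu is None else start[1:]
        res = optimize.minimize(
            objective, theta0, method="L-BFGS-B", bounds=box,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x if fix_mu is None else np.concatenate([[fix_mu], best.x])
    return PsychometricFit(
        mu=float(theta[0]),
        sigma=float(theta[1]),
        gamma=float(theta[2]),
        lam=float(theta[3]),
        log_likelihood=float(-best.fun),
        converged=bool(any_success and not degenerate),
        degenerate=degenerate,
        levels=x,
        k=k,
        n=n,
        message=str(best.message),
    )


def lr_test_bias(
    levels,
    k_cardinal,
    n_total,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    alpha: float = 0.05,
) -> BiasTest:
    """Generalized likelihood-ratio test of zero bias (mu = 0).

    The constrained fit forces mu = 0 and re-optimizes (sigma, gamma,
    lambda); the deviance -2 ln L (L = constrained/unconstrained likelihood
    ratio) is referred to chi-square with 1 degree of freedom.
    """
    full = fit_psychometric(levels, k_cardinal, n_total, bounds=bounds)
    constrained = fit_psychometric(
        levels, k_cardinal, n_total, bounds=bounds, fix_mu=0.0
    )
    deviance = 2.0 * (full.log_likelihood - constrained.log_likelihood)
    deviance = max(deviance, 0.0)  # optimizer jitter can leave tiny negatives
    p_value = float(stats.chi2.sf(deviance, df=1))
    return BiasTest(
        deviance=float(deviance),
        p_value=p_value,
        significant=bool(p_value < alpha),
        alpha=alpha,
        unconstrained=full,
        constrained=constrained,
    )


def profile_ci_mu(
    levels, k_cardinal, n_total,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for mu.

    Finds where twice the profile log-likelihood drop from its maximum equals
    the chi-square(1) quantile; endpoints falling outside the mu bounds are
    truncated at the bounds.
    """
    full = fit_psychometric(levels, k_cardinal, n_total, bounds=bounds)
    threshold = stats.chi2.ppf(level, df=1)

    def drop(mu):
        prof = fit_psychometric(levels, k_cardinal, n_total, bounds=bounds, fix_mu=mu)
        return 2.0 * (full.log_likelihood - prof.log_likelihood) - threshold

    span = max(np.max(levels) - np.min(levels), 1.0)

    def search(direction):
        step = 0.1 * span
        lo = full.mu
        hi = full.mu + direction * step
        for _ in range(40):
            if not (bounds.mu[0] <= hi <= bounds.mu[1]):
                return float(np.clip(hi, *bounds.mu))
            if drop(hi) > 0:
                a, b = (hi, lo) if direction < 0 else (lo, hi)
                return float(optimize.brentq(drop, a, b, xtol=1e-4))
            lo, hi = hi, hi + direction * step
            step *= 1.5
        return float(np.clip(hi, *bounds.mu))

    return search(-1.0), search(+1.0)


# --------------------------------------------------------------------------
# trial-table plumbing


def aggregate_binomial(
    frame: pd.DataFrame,
    x_column: str = "log_ratio",
    success: str = "cardinal",
    neither_policy: str = "count",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse coded trials to per-level binomial counts (levels, k, n).

    ``neither_policy`` decides how responses naming a category absent from
    the hybrid are treated: "count" keeps them in the denominator as
    non-successes (default); "exclude" drops those trials.
    """
    if neither_policy not in ("count", "exclude"):
        raise ValueError(f"unknown neither_policy {neither_policy!r}")
    coded = frame["response_is_cardinal"]
    if coded.isna().any():
        raise ValueError("trials must be response-coded before aggregation")
    if neither_policy == "exclude":
        frame = frame[coded != "neither"]
    grouped = frame.groupby(x_column)["response_is_cardinal"]
    k = grouped.apply(lambda s: int((s == success).sum()))
    n = grouped.size()
    levels = k.index.to_numpy(dtype=float)
    return levels, k.to_numpy(dtype=float), n.to_numpy(dtype=float)


def fit_condition(
    frame: pd.DataFrame,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    neither_policy: str = "count",
) -> PsychometricFit:
    """Fit one condition's coded trials."""
    levels, k, n = aggregate_binomial(frame, neither_policy=neither_policy)
    return fit_psychometric(levels, k, n, bounds=bounds)


def pool_categorical(
    trials_as_cardinal: pd.DataFrame,
    trials_as_intercardinal: pd.DataFrame,
    category: str,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
) -> PsychometricFit:
    """Pooled fit of the bias for one category irrespective of filtering.

    The stimulus axis becomes x = ln(E_category / E_other): trials where the
    category was the cardinal component keep x = r; trials where it was the
    intercardinal component use x = -r.  Success is "the category was
    chosen".  The fit's bias is positive when perception favours the
    category.
    """
    if len(trials_as_cardinal) == 0 or len(trials_as_intercardinal) == 0:
        raise ValueError("both pooled trial sets must be nonempty")
    if not (trials_as_cardinal["cardinal_category"] == category).all():
        raise ValueError(f"first set must have {category!r} as the cardinal component")
    if not (trials_as_intercardinal["intercardinal_category"] == category).all():
        raise ValueError(
            f"second set must have {category!r} as the intercardinal component"
        )

    card = pd.DataFrame(
        {
            "x": trials_as_cardinal["log_ratio"].to_numpy(dtype=float),
            "chosen": (trials_as_cardinal["response_category"] == category).to_numpy(),
        }
    )
    inter = pd.DataFrame(
        {
            "x": -trials_as_intercardinal["log_ratio"].to_numpy(dtype=float),
            "chosen": (trials_as_intercardinal["response_category"] == category).to_numpy(),
        }
    )
    pooled = pd.concat([card, inter], ignore_index=True)
    grouped = pooled.groupby("x")["chosen"]
    levels = grouped.size().index.to_numpy(dtype=float)
    k = grouped.sum().to_numpy(dtype=float)
    n = grouped.size().to_numpy(dtype=float)
    return fit_psychometric(levels, k, n, bounds=bounds)


def group_bias_stats(biases) -> GroupStats:
    """One-sample two-tailed t-test of participant biases against zero.

    Cohen's d = mean/SD = t/sqrt(n); the identity is enforced exactly.
    """
    biases = np.asarray(biases, dtype=float)
    n = biases.size
    if n < 2:
        raise DegenerateStatisticsError("need at least 2 participants")
    if np.std(biases, ddof=1) == 0:
        raise DegenerateStatisticsError("biases have zero variance")
    t_res = stats.ttest_1samp(biases, popmean=0.0)
    t = float(t_res.statistic)
    return GroupStats(
        n=int(n),
        mean_bias=float(biases.mean()),
        t_statistic=t,
        p_value=float(t_res.pvalue),
        cohens_d=t / math.sqrt(n),
    )


def cohens_d_from_t(t_statistic: float, n: int) -> float:
    """One-sample identity d = t / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be positive")
    return t_statistic / math.sqrt(n)
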