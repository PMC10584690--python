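"""Two-component Student-t mixture thresholding of methylation residuals.

A large positive log-IPD residual at an adenine is evidence of
methylation.  To turn residuals into binary calls, a two-component
Student-t mixture is fit per adenine to residuals pooled from fully
methylated and unmethylated control molecules; the methylation cutoff
is the residual value equally likely to come from either component
(posterior responsibility 1/2 under the weighted densities).  Adenines
are kept for downstream decoding only when (1) at least one component
mean is positive, (2) the component means are separated by a minimum
gap, and (3) at least a minimum fraction of the training residuals
exceeds the cutoff.

EM details: the classical t-mixture ECM scheme with latent gamma
scaling weights; degrees of freedom are profiled per component by a 1-D
root solve and bounded below at 1 (heavy-tail floor) and above at 200
(numerically Gaussian).  Components are returned sorted by ascending
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.stats import t as t_dist

from .synthdata import ResidualSample

_DF_MIN, _DF_MAX = 1.0, 200.0


@dataclass(frozen=True)
class TMixture:
    """A two-component Student-t mixture (weights sum to 1)."""

    weights: tuple[float, float]
    means: tuple[float, float]
    scales: tuple[float, float]
    dfs: tuple[float, float]
    converged: bool = True
    log_likelihood: float = float("nan")
    n_iter: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1")
        if min(self.scales) <= 0:
            raise ValueError("scales must be positive")
        if min(self.dfs) <= 0:
            raise ValueError("degrees of freedom must be positive")

    def component_pdf(self, x, j: int) -> np.ndarray:
        return t_dist.pdf(x, self.dfs[j], loc=self.means[j], scale=self.scales[j])

    def pdf(self, x) -> np.ndarray:
        return self.weights[0] * self.component_pdf(x, 0) + self.weights[1] * self.component_pdf(x, 1)

    def log_pdf(self, x) -> np.ndarray:
        a = np.log(self.weights[0] + 1e-300) + t_dist.logpdf(
            x, self.dfs[0], loc=self.means[0], scale=self.scales[0]
        )
        b = np.log(self.weights[1] + 1e-300) + t_dist.logpdf(
            x, self.dfs[1], loc=self.means[1], scale=self.scales[1]
        )
        return np.logaddexp(a, b)


@dataclass(frozen=True)
class UsabilityDecision:
    """Outcome of the three adenine-usability filters."""

    usable: bool
    cutoff: float | None
    reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.usable and (self.reasons or self.cutoff is None or not np.isfinite(self.cutoff)):
            raise ValueError("a usable decision must have no reasons and a finite cutoff")


def _df_objective(nu: float, weighted_stat: float) -> float:
    # stationarity condition for nu in the t-mixture ECM
    return (
        -special.digamma(nu / 2.0)
        + np.log(nu / 2.0)
        + 1.0
        + weighted_stat
        + special.digamma((nu + 1.0) / 2.0)
        - np.log((nu + 1.0) / 2.0)
    )


def _update_df(resp_j: np.ndarray, u_j: np.ndarray) -> float:
    nj = resp_j.sum()
    if nj <= 0:
        return 10.0
    stat = float((resp_j * (np.log(u_j) - u_j)).sum() / nj)
    lo, hi = _DF_MIN, _DF_MAX
    flo, fhi = _df_objective(lo, stat), _df_objective(hi, stat)
    if flo <= 0:
        return lo
    if fhi >= 0:
        return hi
    return float(optimize.brentq(_df_objective, lo, hi, args=(stat,), xtol=1e-8))


def fit_t_mixture(
    residuals: ResidualSample | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    fix_df: float | None = None,
    n_init: int = 5,
) -> TMixture:
    """Fit a two-component Student-t mixture by EM.

    Iterates until the log-likelihood improves by less than ``tol`` or
    ``max_iter`` is reached (then ``converged=False`` on the result).
    The EM objective is multimodal (a broad component can absorb the
    tail of a dominant one), so ``n_init`` restarts are run — the first
    from the interquartile split, the rest from random data pairs — and
    the highest-likelihood solution is returned.  ``seed`` controls the
    initializations; ``fix_df`` pins both degrees of freedom instead of
    estimating them.
    """
    x = np.asarray(residuals.values if isinstance(residuals, ResidualSample) else residuals, float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least two residual values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all residuals identical")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")

    rng = np.random.default_rng(seed)
    best: TMixture | None = None
    for init in range(n_init):
        fit = _fit_t_mixture_once(x, tol, max_iter, rng, fix_df, init)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    return best


def _fit_t_mixture_once(
    x: np.ndarray,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
    fix_df: float | None,
    init: int,
) -> TMixture:
    spread = max(np.std(x), 1e-6)
    if init == 0:
        mu = np.quantile(x, [0.25, 0.75]).astype(float)
    else:
        mu = np.sort(rng.choice(x, size=2, replace=False).astype(float))
    mu = mu + rng.normal(0, 0.01 * spread, size=2)
    mu.sort()
    sigma = np.full(2, max(spread / 2.0, 1e-6))
    nu = np.full(2, fix_df if fix_df is not None else 10.0)
    w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        logp = np.stack(
            [
                np.log(w[j] + 1e-300) + t_dist.logpdf(x, nu[j], loc=mu[j], scale=sigma[j])
                for j in range(2)
            ]
        )
        tot = special.logsumexp(logp, axis=0)
        ll = float(tot.sum())
        resp = np.exp(logp - tot)
        delta = ((x[None, :] - mu[:, None]) / sigma[:, None]) ** 2
        u = (nu[:, None] + 1.0) / (nu[:, None] + delta)
        # M step
        for j in range(2):
            rj, uj = resp[j], u[j]
            nj = rj.sum()
            if nj < 1e-12:
                continue
            mu[j] = float((rj * uj * x).sum() / max((rj * uj).sum(), 1e-300))
            var = float((rj * uj * (x - mu[j]) ** 2).sum() / nj)
            sigma[j] = max(np.sqrt(var), 1e-8)
            if fix_df is None:
                delta_j = ((x - mu[j]) / sigma[j]) ** 2
                uj_new = (nu[j] + 1.0) / (nu[j] + delta_j)
                nu[j] = _update_df(rj, uj_new)
            w[j] = nj / len(x)
        w = w / w.sum()
        if ll - prev_ll < tol and it > 1:
            converged = True
            break
        prev_ll = ll

    order = np.argsort(mu)
    return TMixture(
        weights=tuple(w[order]),
        means=tuple(mu[order]),
        scales=tuple(sigma[order]),
        dfs=tuple(nu[order]),
        converged=converged,
        log_likelihood=ll,
        n_iter=it,
    )


def equal_likelihood_cutoff(
    mixture: TMixture,
    bracket: tuple[float, float] | None = None,
    weighted: bool = True,
) -> float:
    """Residual value equally likely under either component.

    Solves w1*f1(c) = w2*f2(c) (posterior responsibility 1/2) by root
    finding between the component means; ``weighted=False`` drops the
    mixing weights and equates the raw component densities.
    """
    m1, m2 = mixture.means
    if m1 == m2:
        raise ValueError("component means must be distinct")
    if bracket is None:
        bracket = (min(m1, m2), max(m1, m2))

    w1, w2 = (mixture.weights if weighted else (1.0, 1.0))

    def g(c: float) -> float:
        return float(
            np.log(w1 + 1e-300)
            + t_dist.logpdf(c, mixture.dfs[0], loc=m1, scale=mixture.scales[0])
            - np.log(w2 + 1e-300)
            - t_dist.logpdf(c, mixture.dfs[1], loc=m2, scale=mixture.scales[1])
        )

    lo, hi = bracket
    flo, fhi = g(lo), g(hi)
    if flo == 0.0:
        return float(lo)
    if fhi == 0.0:
        return float(hi)
    if np.sign(flo) == np.sign(fhi):
        raise ValueError("no equal-likelihood crossing inside the bracket")
    return float(optimize.brentq(g, lo, hi, xtol=1e-12))


def assess_adenine_usability(
    mixture: TMixture,
    cutoff: float | None,
    train: ResidualSample | np.ndarray,
    min_mean_gap: float = 0.2,
    min_frac_above: float = 0.02,
) -> UsabilityDecision:
    """Apply the three usability filters to one adenine's mixture fit.

    The mean-gap threshold defaults to 0.2, the midpoint of the 0.1-0.3
    range used per amplicon; ``min_frac_above`` defaults to 2%.
    """
    x = np.asarray(train.values if isinstance(train, ResidualSample) else train, float)
    reasons: set[str] = set()
    if max(mixture.means) <= 0:
        reasons.add("no_positive_mean")
    if mixture.means[1] - mixture.means[0] < min_mean_gap:
        reasons.add("mean_gap_too_small")
    if cutoff is None or not np.isfinite(cutoff):
        reasons.add("too_few_above_cutoff")
    elif np.mean(x > cutoff) < min_frac_above:
        reasons.add("too_few_above_cutoff")
    usable = not reasons
    return UsabilityDecision(
        usable=usable,
        cutoff=float(cutoff) if usable else (None if cutoff is None else float(cutoff)),
        reasons=frozenset(reasons),
    )


def call_methylation(residuals: ResidualSample | np.ndarray, cutoff: float) -> np.ndarray:
    """Binary calls: 1 iff residual strictly exceeds the cutoff."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    x = np.asarray(residuals.values if isinstance(residuals, ResidualSample) else residuals, float)
    return (x > cutoff).astype(int)
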