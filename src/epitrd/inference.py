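"""Bayesian inference for the TRD models.

A single-chain Metropolis-Hastings sampler with flat priors over boxed
parametric spaces, per-parameter reflected Gaussian random-walk
proposals updated in a fixed cyclic order within each iteration.
Evidence against the Mendelian null of each parameter is summarized by
a Savage-Dickey Bayes factor: prior density at zero over posterior
density at zero, the latter estimated by a Gaussian kernel density with
Silverman bandwidth. Model-level summaries are the deviance information
criterion (DIC) and the log10 likelihood ratio of the posterior-mean
parameters against the all-zero null.

Default chain lengths: 11,000 iterations with 1,000 burn-in for the
preliminary genome scan, 550,000 with 50,000 burn-in for accurate
re-estimation of selected pairs, and 110,000 with 10,000 burn-in for
the simplified single-parameter screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .allelic import AllelicLikelihood
from .genotypic import GenotypicLikelihood
from .trio_data import PairTrioData

__all__ = [
    "ChainConfig",
    "Chain",
    "PosteriorResult",
    "mh_sample",
    "bayes_factor",
    "dic",
    "likelihood_ratio",
    "fit_genotypic",
    "fit_allelic",
    "summarize_chain",
]


@dataclass(frozen=True)
class ChainConfig:
    """Metropolis-Hastings chain settings.

    ``proposal_sd`` may be a scalar (shared) or per-parameter sequence.
    With ``tune=True`` the proposal scales are adapted during burn-in
    toward a 20-40% acceptance rate (adaptation stops at the end of
    burn-in, preserving detailed balance for the retained draws).
    """

    n_iter: int = 11_000
    burn_in: int = 1_000
    proposal_sd: float | tuple = 0.05
    seed: int = 0
    thinning: int = 1
    tune: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @classmethod
    def preliminary(cls, seed: int = 0) -> "ChainConfig":
        return cls(n_iter=11_000, burn_in=1_000, seed=seed)

    @classmethod
    def accurate(cls, seed: int = 0) -> "ChainConfig":
        return cls(n_iter=550_000, burn_in=50_000, seed=seed)

    @classmethod
    def simplified(cls, seed: int = 0) -> "ChainConfig":
        return cls(n_iter=110_000, burn_in=10_000, seed=seed)


@dataclass
class Chain:
    """Post-burn-in draws of one MH run."""

    draws: np.ndarray  # (n_kept, n_params)
    acceptance_rate: float
    param_names: tuple
    bounds: tuple

    @property
    def n_kept(self) -> int:
        return self.draws.shape[0]

    def to_tsv(self, path) -> None:
        """Dump the chain as TSV (iteration, one column per parameter)."""
        import pandas as pd

        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df.insert(0, "iteration", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)


@dataclass
class PosteriorResult:
    """Posterior summaries of one model fit on one SNP pair.

    ``cv`` is posterior sd / |posterior mean| (NaN when the mean is 0);
    ``log10_bf`` is the Savage-Dickey Bayes factor per parameter
    (+inf when the posterior density at zero is estimated as zero).
    """

    param_names: tuple
    mean: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    log10_bf: np.ndarray
    log10_lr: float
    dic: float
    acceptance_rate: float
    n_kept: int

    def param(self, name: str) -> dict:
        i = self.param_names.index(name)
        return {
            "mean": float(self.mean[i]),
            "sd": float(self.sd[i]),
            "cv": float(self.cv[i]),
            "log10_bf": float(self.log10_bf[i]),
        }


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


def mh_sample(loglik, bounds, cfg: ChainConfig) -> Chain:
    """Single-chain Metropolis-Hastings over a boxed parameter space.

    ``loglik`` maps a parameter vector to a log-likelihood (flat priors,
    so the posterior kernel is the likelihood restricted to the box).
    The chain starts at the all-zero Mendelian null, which must have a
    finite likelihood.
    """
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    n_params = len(bounds)
    x = np.zeros(n_params)
    ll = loglik(x)
    if not np.isfinite(ll):
        raise ValueError(
            "log-likelihood is not finite at the Mendelian null; "
            "check the trio counts for impossible classes"
        )
    sd = np.asarray(cfg.proposal_sd, dtype=float)
    if sd.ndim == 0:
        sd = np.full(n_params, float(sd))
    sd = sd.copy()

    rng = np.random.default_rng(cfg.seed)
    n_keep = (cfg.n_iter - cfg.burn_in + cfg.thinning - 1) // cfg.thinning
    draws = np.empty((n_keep, n_params))
    accepted = 0
    proposed = 0
    tune_acc = np.zeros(n_params)
    tune_n = 0
    tune_window = 200
    kept = 0

    for it in range(cfg.n_iter):
        z = rng.standard_normal(n_params)
        u = rng.random(n_params)
        for k in range(n_params):
            lo, hi = bounds[k]
            xk_old = x[k]
            x[k] = _reflect(xk_old + sd[k] * z[k], lo, hi)
            ll_new = loglik(x)
            if np.log(u[k]) < ll_new - ll:
                ll = ll_new
                accepted += 1
                tune_acc[k] += 1
            else:
                x[k] = xk_old
            proposed += 1
        if cfg.tune and it < cfg.burn_in:
            tune_n += 1
            if tune_n == tune_window:
                rate = tune_acc / tune_window
                sd[rate > 0.40] *= 1.4
                sd[rate < 0.20] /= 1.4
                tune_acc[:] = 0.0
                tune_n = 0
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            draws[kept] = x
            kept += 1

    names = getattr(loglik, "param_names", tuple(f"p{k}" for k in range(n_params)))
    return Chain(
        draws=draws[:kept],
        acceptance_rate=accepted / proposed,
        param_names=tuple(names),
        bounds=bounds,
    )


def bayes_factor(draws: np.ndarray, bounds) -> float:
    """Savage-Dickey log10 Bayes factor against the point null at zero.

    Prior density at 0 is 1/width of the flat prior; posterior density at
    0 is a Gaussian KDE (Silverman bandwidth) of the post-burn-in draws
    evaluated at 0. Returns +inf when the posterior puts estimated zero
    density at the null, -inf for a degenerate chain sitting exactly at
    zero.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 1000:
        raise ValueError("need at least 1,000 post-burn-in draws")
    lo, hi = float(bounds[0]), float(bounds[1])
    prior0 = 1.0 / (hi - lo)
    if np.std(draws) == 0.0:
        # point-mass chain: density at 0 is 0 unless the chain sits at 0
        return -np.inf if draws[0] == 0.0 else np.inf
    kde = gaussian_kde(draws, bw_method="silverman")
    post0 = float(kde(0.0)[0])
    if post0 <= 0.0:
        return np.inf
    return float(np.log10(prior0) - np.log10(post0))


def posterior_density_histogram(draws: np.ndarray, at: float = 0.0, n_bins: int = 50) -> float:
    """Histogram estimator of the posterior density (cross-check for the KDE)."""
    draws = np.asarray(draws, dtype=float).ravel()
    counts, edges = np.histogram(draws, bins=n_bins, density=True)
    idx = np.searchsorted(edges, at, side="right") - 1
    if idx < 0 or idx >= n_bins:
        return 0.0
    return float(counts[idx])


def dic(draws: np.ndarray, loglik, max_evals: int = 2000) -> float:
    """Deviance information criterion from posterior draws.

    ``DIC = 2 * mean(D) - D(posterior mean)`` with deviance
    ``D = -2 log L``. The posterior-mean deviance is averaged over at
    most ``max_evals`` evenly spaced draws.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 2:
        raise ValueError("need at least 2 draws for DIC")
    step = max(1, draws.shape[0] // max_evals)
    sub = draws[::step]
    devs = np.array([-2.0 * loglik(t) for t in sub])
    if not np.all(np.isfinite(devs)):
        raise ValueError("deviance not finite on some posterior draws")
    d_at_mean = -2.0 * loglik(draws.mean(axis=0))
    if not np.isfinite(d_at_mean):
        raise ValueError(
            "deviance undefined at the posterior mean (zero-probability class)"
        )
    return float(2.0 * devs.mean() - d_at_mean)


def likelihood_ratio(loglik, theta_hat: np.ndarray) -> float:
    """log10 likelihood ratio of ``theta_hat`` against the all-zero null."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    ll_hat = loglik(theta_hat)
    ll_null = loglik(np.zeros_like(theta_hat))
    if not (np.isfinite(ll_hat) and np.isfinite(ll_null)):
        raise ValueError("log-likelihood not finite at theta_hat or the null")
    return float((ll_hat - ll_null) / np.log(10.0))


def summarize_chain(chain: Chain, loglik, compute_dic: bool = True) -> PosteriorResult:
    """Posterior means/sds/CVs, per-parameter Bayes factors, LR and DIC."""
    mean = chain.draws.mean(axis=0)
    sd = chain.draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0.0, sd / np.abs(mean), np.nan)
    bf = np.array(
        [bayes_factor(chain.draws[:, k], chain.bounds[k]) for k in range(chain.draws.shape[1])]
    )
    theta_hat = np.clip(
        mean, [b[0] for b in chain.bounds], [b[1] for b in chain.bounds]
    )
    lr = likelihood_ratio(loglik, theta_hat)
    dic_value = dic(chain.draws, loglik) if compute_dic else np.nan
    return PosteriorResult(
        param_names=chain.param_names,
        mean=mean,
        sd=sd,
        cv=cv,
        log10_bf=bf,
        log10_lr=lr,
        dic=dic_value,
        acceptance_rate=chain.acceptance_rate,
        n_kept=chain.n_kept,
    )


def fit_genotypic(data: PairTrioData, cfg: ChainConfig) -> PosteriorResult:
    """Fit the eight-parameter genotypic TRD model to one SNP pair."""
    loglik = GenotypicLikelihood(data)
    chain = mh_sample(loglik, loglik.bounds, cfg)
    return summarize_chain(chain, loglik)


def fit_allelic(data: PairTrioData, cfg: ChainConfig) -> PosteriorResult:
    """Fit the eight-parameter allelic TRD model to one SNP pair."""
    loglik = AllelicLikelihood(data)
    chain = mh_sample(loglik, loglik.bounds, cfg)
    return summarize_chain(chain, loglik)
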