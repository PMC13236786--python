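"""Hierarchical binomial-beta model of participant-level accuracy.

Each participant's correct-classification count is binomial,

    C_i ~ Binomial(N_i, p_i)
    p_i ~ Beta(alpha, beta)
    alpha ~ Exponential(rate 0.1)    (mean 10)
    beta  ~ Exponential(rate 0.05)   (mean 20)

so the weakly informative hyperpriors center the group-level beta mean,
alpha/(alpha+beta), near 1/3 — closer to the six-way chance level of 1/6
than a typical trained-network accuracy.  The posterior over
(alpha, beta, p_1..p_P) is explored with Hamiltonian Monte Carlo on the
unconstrained scale (log alpha, log beta, logit p_i), using leapfrog
integration with dual-averaging step-size adaptation during warm-up.
Split-R-hat and effective-sample-size diagnostics come from arviz.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import arviz as az
import numpy as np
from scipy.special import digamma, expit, gammaln

from .evaluation import AccuracyReport

__all__ = [
    "BayesModelSpec",
    "BayesFit",
    "sample_posterior",
    "beta_mean",
    "hpdi",
    "diagnostics",
]


@dataclass(frozen=True)
class BayesModelSpec:
    alpha_rate: float = 0.1
    beta_rate: float = 0.05
    chains: int = 4
    iterations: int = 1000        # per chain; the first half is warm-up
    warmup_fraction: float = 0.5
    n_leapfrog: int = 32
    target_accept: float = 0.8
    rates_are_rates: bool = True  # False reads 0.1/0.05 as scale parameters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_rate <= 0 or self.beta_rate <= 0:
            raise ValueError("hyperprior rates must be positive")
        if self.chains < 1 or self.iterations < 2:
            raise ValueError("need at least 1 chain and 2 iterations")

    @property
    def rates(self) -> Tuple[float, float]:
        if self.rates_are_rates:
            return self.alpha_rate, self.beta_rate
        return 1.0 / self.alpha_rate, 1.0 / self.beta_rate


@dataclass
class BayesFit:
    """Posterior draws (post warm-up) of the group-level shape parameters."""

    alpha: np.ndarray            # (chains, draws)
    beta: np.ndarray             # (chains, draws)
    beta_mean_draws: np.ndarray  # (chains, draws), alpha/(alpha+beta)
    hpdi_95: Tuple[float, float]
    diagnostics: Dict[str, Tuple[float, float]]  # param -> (r_hat, ess)
    accept_rate: float
    warnings: List[str] = field(default_factory=list)

    @property
    def posterior_mean(self) -> float:
        return float(self.beta_mean_draws.mean())

    def summary_frame(self):
        import pandas as pd

        rows = []
        for name, draws in (
            ("alpha", self.alpha),
            ("beta", self.beta),
            ("beta_mean", self.beta_mean_draws),
        ):
            flat = draws.ravel()
            lo, hi = hpdi(flat, 0.95)
            r, e = self.diagnostics[name]
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "hpdi_lo": lo,
                    "hpdi_hi": hi,
                    "ess": e,
                    "r_hat": r,
                }
            )
        return pd.DataFrame(rows)


def beta_mean(alpha, beta):
    """Mean of a Beta(alpha, beta) distribution: alpha / (alpha + beta)."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if (alpha <= 0).any() or (beta <= 0).any():
        raise ValueError("beta-distribution shape parameters must be positive")
    out = alpha / (alpha + beta)
    return float(out) if out.ndim == 0 else out


def hpdi(draws: np.ndarray, mass: float = 0.95) -> Tuple[float, float]:
    """Highest-probability-density interval: the narrowest window holding `mass`.

    Implemented as a sorted-window search — for n sorted draws the interval
    is the minimum-width window spanning ceil(mass * n) consecutive draws.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie strictly between 0 and 1")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("hpdi needs at least 100 draws")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def diagnostics(draws: np.ndarray) -> Tuple[float, float]:
    """(split-R-hat, bulk ESS) for draws of shape (chains, iterations)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("diagnostics need draws from at least 2 chains")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(draws[..., None])
        r = float(np.asarray(az.rhat(ds)["x"].values).ravel()[0])
        e = float(np.asarray(az.ess(ds)["x"].values).ravel()[0])
    return r, e


# ----- log posterior on the unconstrained scale -----------------------------


def _logpost_and_grad(theta: np.ndarray, C: np.ndarray, N: np.ndarray, rates):
    with np.errstate(over="ignore", invalid="ignore"):
        return _logpost_and_grad_inner(theta, C, N, rates)


def _logpost_and_grad_inner(theta: np.ndarray, C: np.ndarray, N: np.ndarray, rates):
    la, lb = rates
    a, b = theta[0], theta[1]
    if not np.isfinite(theta).all() or abs(a) > 500 or abs(b) > 500:
        return -np.inf, np.zeros_like(theta)
    q = theta[2:]
    alpha, beta = np.exp(a), np.exp(b)
    p = expit(q)
    log_p = -np.logaddexp(0.0, -q)       # log sigmoid(q), stable
    log_1mp = -np.logaddexp(0.0, q)
    P = C.size
    logB = gammaln(alpha) + gammaln(beta) - gammaln(alpha + beta)
    # priors with log/logit Jacobians folded in
    lp = (a - la * alpha) + (b - lb * beta)
    lp += float(np.sum((alpha + C) * log_p + (beta + N - C) * log_1mp)) - P * logB
    g = np.empty_like(theta)
    dig_ab = digamma(alpha + beta)
    g[0] = 1.0 - la * alpha + alpha * (np.sum(log_p) - P * (digamma(alpha) - dig_ab))
    g[1] = 1.0 - lb * beta + beta * (np.sum(log_1mp) - P * (digamma(beta) - dig_ab))
    g[2:] = (alpha + C) * (1.0 - p) - (beta + N - C) * p
    return lp, g


def _hmc_chain(C, N, spec: BayesModelSpec, seed: int):
    rng = np.random.default_rng(seed)
    P = C.size
    # moment-matched initialisation with chain-specific jitter
    phat = (C + 1.0) / (N + 2.0)
    m, v = float(phat.mean()), float(phat.var()) + 1e-6
    kappa = np.clip(m * (1 - m) / v - 1.0, 2.0, 200.0)
    theta = np.concatenate(
        [
            [np.log(max(m * kappa, 1e-2)), np.log(max((1 - m) * kappa, 1e-2))],
            np.log(phat / (1 - phat)),
        ]
    )
    theta += 0.1 * rng.standard_normal(theta.size)

    n_iter = spec.iterations
    n_warm = int(round(spec.warmup_fraction * n_iter))
    half = n_warm // 2
    eps = 0.1
    # dual averaging (Nesterov) targeting spec.target_accept
    mu, log_eps_bar, H_bar, da_t = np.log(10 * eps), 0.0, 0.0, 0
    gamma_da, t0, kappa_da = 0.05, 10.0, 0.75
    inv_mass = np.ones(theta.size)  # re-estimated mid-warm-up
    warm_hist = np.empty((half, theta.size))

    lp, grad = _logpost_and_grad(theta, C, N, spec.rates)
    draws = np.empty((n_iter - n_warm, 2))
    n_accept = 0
    kept = 0
    for it in range(n_iter):
        n_leap = int(rng.integers(max(1, spec.n_leapfrog // 2), spec.n_leapfrog + 1))
        r0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
        th, r, gr = theta.copy(), r0.copy(), grad.copy()
        r += 0.5 * eps * gr
        for step in range(n_leap):
            th += eps * inv_mass * r
            lp_new, gr = _logpost_and_grad(th, C, N, spec.rates)
            if step < n_leap - 1:
                r += eps * gr
        r += 0.5 * eps * gr
        log_accept = (lp_new - 0.5 * (inv_mass * r) @ r) - (lp - 0.5 * (inv_mass * r0) @ r0)
        accept_prob = min(1.0, np.exp(min(0.0, log_accept))) if np.isfinite(log_accept) else 0.0
        if rng.random() < accept_prob:
            theta, lp, grad = th, lp_new, gr
            n_accept += 1
        if it < n_warm:
            if it < half:
                warm_hist[it] = theta
            da_t += 1
            w = 1.0 / (da_t + t0)
            H_bar = (1 - w) * H_bar + w * (spec.target_accept - accept_prob)
            log_eps = mu - np.sqrt(da_t) / gamma_da * H_bar
            eta = da_t ** (-kappa_da)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it == half - 1 and half >= 10:
                # switch to a diagonal mass estimated from early warm-up
                var = warm_hist[half // 2 :].var(axis=0)
                inv_mass = np.clip(var, 1e-4, 1e4)
                mu, log_eps_bar, H_bar, da_t = np.log(10 * eps), 0.0, 0.0, 0
            if it == n_warm - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[kept] = np.exp(theta[:2])
            kept += 1
    return draws, n_accept / n_iter


def sample_posterior(
    report: AccuracyReport | Tuple[np.ndarray, np.ndarray],
    spec: Optional[BayesModelSpec] = None,
) -> BayesFit:
    """Fit the hierarchical model to per-participant (C_i, N_i) counts.

    Accepts either an :class:`~gazecnn.evaluation.AccuracyReport` or a raw
    ``(C, N)`` pair.  Runs ``spec.chains`` independent HMC chains; the first
    half of each chain is warm-up and discarded.  Reproducible for a fixed
    ``spec.seed``.  An R-hat above 1.05 on any parameter is surfaced in
    ``fit.warnings`` (and as a Python warning), never silently dropped.
    """
    spec = spec or BayesModelSpec()
    if isinstance(report, AccuracyReport):
        C, N = report.counts
    else:
        C, N = report
    C = np.asarray(C, dtype=float)
    N = np.asarray(N, dtype=float)
    if (N < 1).any():
        raise ValueError("every participant needs N_i >= 1 trials")
    if ((C < 0) | (C > N)).any():
        raise ValueError("counts must satisfy 0 <= C_i <= N_i")

    chains, rates = [], []
    for c in range(spec.chains):
        d, ar = _hmc_chain(C, N, spec, seed=(spec.seed * 9973 + c) % (2**31 - 1))
        chains.append(d)
        rates.append(ar)
    alpha = np.stack([d[:, 0] for d in chains])
    beta = np.stack([d[:, 1] for d in chains])
    bm = alpha / (alpha + beta)

    diag: Dict[str, Tuple[float, float]] = {}
    warn: List[str] = []
    for name, arr in (("alpha", alpha), ("beta", beta), ("beta_mean", bm)):
        if spec.chains >= 2:
            r, e = diagnostics(arr)
        else:
            r, e = np.nan, np.nan
        diag[name] = (r, e)
        if np.isfinite(r) and r > 1.05:
            msg = f"R-hat {r:.3f} > 1.05 for {name}: chains may not have converged"
            warn.append(msg)
            _warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return BayesFit(
        alpha=alpha,
        beta=beta,
        beta_mean_draws=bm,
        hpdi_95=hpdi(bm.ravel(), 0.95),
        diagnostics=diag,
        accept_rate=float(np.mean(rates)),
        warnings=warn,
    )
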