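"""Bayesian MCMC and maximum-likelihood fitting of CJS models.

The posterior is sampled with an adaptive random-walk Metropolis algorithm on
the marginalised likelihood (individual random effects integrated out by
quadrature), with parameters mapped to the real line by scaled logit
transforms.  Proposal scale and covariance adapt during burn-in only, so the
post-burn-in chain is a valid Markov chain targeting the posterior.

Priors follow the simulation protocol: U(0,1) on survival and on the mean
detection probability, U(0,10) on the logit-scale heterogeneity SD.

A fast maximum-likelihood path (:func:`fit_mle`) optimises the same
marginalised likelihood and reports observed-information standard errors; it
serves as an independent oracle for the Bayesian fits and as the engine for
scaled-down replicate studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .likelihood import CJSLikelihood, implied_detection_sd
from .scenarios import CaptureHistoryMatrix

__all__ = [
    "InferenceError",
    "Priors",
    "make_priors",
    "FitResult",
    "run_mcmc",
    "bgr_diagnostic",
    "fit_mle",
    "MODEL_TAGS",
]

logger = logging.getLogger(__name__)

MODEL_TAGS = ("constant_p", "re_p", "time_varying")


class InferenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Priors:
    """Independent uniform priors as (low, high) bounds per parameter kind."""

    phi: tuple[float, float] = (0.0, 1.0)
    p: tuple[float, float] = (0.0, 1.0)
    sigma: tuple[float, float] = (0.0, 10.0)

    def bounds(self, name: str) -> tuple[float, float]:
        if name.startswith("phi"):
            return self.phi
        if name.startswith("sigma"):
            return self.sigma
        return self.p

    def density(self, name: str, value: float) -> float:
        lo, hi = self.bounds(name)
        return 1.0 / (hi - lo) if lo <= value <= hi else 0.0

    def sample(self, name: str, rng: np.random.Generator) -> float:
        lo, hi = self.bounds(name)
        return float(rng.uniform(lo, hi))


def make_priors() -> Priors:
    """The study's prior specification: phi ~ U(0,1), mean detection ~ U(0,1),
    heterogeneity SD ~ U(0,10)."""
    return Priors()


def _param_names(model_tag: str, n_occasions: int) -> list[str]:
    if model_tag == "constant_p":
        return ["phi", "p"]
    if model_tag == "re_p":
        return ["phi", "p_mean", "sigma"]
    if model_tag == "time_varying":
        return [f"phi_{t}" for t in range(1, n_occasions)] + [
            f"p_{t}" for t in range(2, n_occasions + 1)
        ]
    raise ValueError(f"unknown model_tag {model_tag!r}; expected one of {MODEL_TAGS}")


def _make_loglik(
    lik: CJSLikelihood, model_tag: str
) -> Callable[[np.ndarray], float]:
    K = lik.n_occasions
    if model_tag == "constant_p":
        return lambda th: lik.constant(th[0], th[1])
    if model_tag == "re_p":
        return lambda th: lik.marginal_re(th[0], float(logit(th[1])), th[2])
    if model_tag == "time_varying":
        return lambda th: lik.time_varying(th[: K - 1], th[K - 1 :])
    raise ValueError(f"unknown model_tag {model_tag!r}")


def _to_natural(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * expit(u)


def _log_jacobian(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    # d theta / d u = (hi-lo) * s * (1-s); log s + log(1-s) computed stably
    return float(np.sum(np.log(hi - lo) - np.logaddexp(0.0, -u) - np.logaddexp(0.0, u)))


@dataclass
class FitResult:
    """Posterior (or ML) summaries per parameter.

    ``params`` is a DataFrame indexed by parameter name with columns
    ``mean, sd, q2.5, q50, q97.5, rhat``.  For ML fits ``mean`` is the point
    estimate, ``sd`` the observed-information SE and the quantiles a normal
    approximation; ``rhat`` is NaN.
    """

    params: pd.DataFrame
    model_tag: str
    method: str  # "mcmc" | "mle"
    n_kept_samples: int
    seed: Optional[int]
    settings: dict = field(default_factory=dict)
    samples: Optional[dict[str, np.ndarray]] = field(default=None, repr=False)
    boundary_sigma: bool = False
    loglik: Optional[float] = None

    def __post_init__(self) -> None:
        q = self.params
        bad = (q["q2.5"] > q["q50"] + 1e-12) | (q["q50"] > q["q97.5"] + 1e-12)
        if bad.any():
            raise ValueError("posterior quantiles must be ordered per parameter")

    def point(self, name: str) -> float:
        return float(self.params.loc[name, "mean"])

    def sd(self, name: str) -> float:
        return float(self.params.loc[name, "sd"])

    def credible_interval(self, name: str) -> tuple[float, float]:
        return (
            float(self.params.loc[name, "q2.5"]),
            float(self.params.loc[name, "q97.5"]),
        )

    def implied_detection_sd(self) -> float:
        """Probability-scale SD of detection implied by the fitted model."""
        if self.model_tag != "re_p":
            raise ValueError("implied detection SD requires the re_p model")
        return implied_detection_sd(float(logit(self.point("p_mean"))), self.point("sigma"))


def bgr_diagnostic(chains: Union[np.ndarray, Mapping[str, np.ndarray]]):
    """Brooks-Gelman-Rubin potential scale reduction factor.

    ``chains`` is an (m, n) array of m >= 2 equal-length chains for one
    parameter (returns a float) or a mapping of parameter name to such arrays
    (returns a dict).  Uses the corrected estimator
    sqrt(((m+1)/m) * Vhat/W - (n-1)/(m n)).
    """
    if isinstance(chains, Mapping):
        return {k: bgr_diagnostic(v) for k, v in chains.items()}
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InferenceError("BGR diagnostic requires >= 2 chains of equal length")
    m, n = x.shape
    if n < 2:
        raise InferenceError("BGR diagnostic requires chains of length >= 2")
    means = x.mean(axis=1)
    within = x.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    if within == 0.0:
        return 1.0
    vhat = (n - 1) / n * within + b_over_n
    r2 = (m + 1) / m * vhat / within - (n - 1) / (m * n)
    return float(np.sqrt(max(r2, 0.0)))


def _adaptive_rwm(
    logpost: Callable[[np.ndarray], float],
    u0: np.ndarray,
    iterations: int,
    burn_in: int,
    rng: np.random.Generator,
    target_accept: float = 0.3,
) -> np.ndarray:
    """Random-walk Metropolis with Haario-style covariance adaptation and
    Robbins-Monro scale tuning during burn-in; proposal frozen afterwards."""
    d = u0.size
    u = u0.copy()
    lp = logpost(u)
    if not np.isfinite(lp):
        raise InferenceError("non-finite posterior at initial values")
    draws = np.empty((iterations, d))
    log_scale = np.log(2.38 / np.sqrt(d))
    chol = np.eye(d) * 0.1
    for it in range(iterations):
        step = np.exp(log_scale) * (chol @ rng.standard_normal(d))
        prop = u + step
        lpp = logpost(prop)
        log_ratio = lpp - lp
        accept_prob = 1.0 if log_ratio >= 0 else float(np.exp(log_ratio))
        if rng.random() < accept_prob:
            u, lp = prop, lpp
        draws[it] = u
        if it < burn_in:
            log_scale += (accept_prob - target_accept) / (1.0 + it) ** 0.6
            if it >= 300 and it % 100 == 0:
                window = draws[max(0, it - 3000) : it]
                cov = np.cov(window.T) + 1e-8 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(np.atleast_2d(cov))
                except np.linalg.LinAlgError:
                    pass
    return draws


def run_mcmc(
    data: CaptureHistoryMatrix,
    model_tag: str = "re_p",
    chains: int = 1,
    iterations: int = 30_000,
    burn_in: int = 20_000,
    thin: int = 10,
    seed: Optional[int] = None,
    n_nodes: int = 20,
    init: Optional[Mapping[str, float]] = None,
) -> FitResult:
    """Sample the posterior of a CJS model.

    Defaults follow the single-chain production protocol (30000 iterations,
    burn-in 20000, thinning 10, hence 1000 kept samples).  With ``chains >= 2``
    the Brooks-Gelman-Rubin statistic is reported per parameter.
    """
    if iterations <= burn_in:
        raise InferenceError("iterations must exceed burn_in")
    if thin < 1:
        raise InferenceError("thin must be >= 1")
    kept_per_chain = (iterations - burn_in) // thin
    if kept_per_chain < 1:
        raise InferenceError("configuration keeps zero samples")

    lik = CJSLikelihood(data, n_nodes=n_nodes)
    names = _param_names(model_tag, data.n_occasions)
    priors = make_priors()
    lo = np.array([priors.bounds(nm)[0] for nm in names])
    hi = np.array([priors.bounds(nm)[1] for nm in names])
    loglik = _make_loglik(lik, model_tag)

    def logpost(u: np.ndarray) -> float:
        theta = _to_natural(u, lo, hi)
        ll = loglik(theta)
        if not np.isfinite(ll):
            return -np.inf
        return ll + _log_jacobian(u, lo, hi)

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)
    all_kept = np.empty((chains, kept_per_chain, len(names)))
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        u0 = None
        if init is not None and c == 0:
            theta0 = np.array([init[nm] for nm in names])
            u0 = logit((theta0 - lo) / (hi - lo))
        else:
            for _ in range(100):
                theta0 = np.array([priors.sample(nm, rng) for nm in names])
                cand = logit(np.clip((theta0 - lo) / (hi - lo), 1e-9, 1 - 1e-9))
                if np.isfinite(logpost(cand)):
                    u0 = cand
                    break
            if u0 is None:
                raise InferenceError("could not find finite initial values from the prior")
        draws = _adaptive_rwm(logpost, u0, iterations, burn_in, rng)
        kept_u = draws[burn_in:][::thin][:kept_per_chain]
        all_kept[c] = _to_natural(kept_u, lo, hi)

    samples = {nm: all_kept[:, :, j] for j, nm in enumerate(names)}
    pooled = {nm: s.reshape(-1) for nm, s in samples.items()}
    rows = []
    for nm in names:
        s = pooled[nm]
        q = np.percentile(s, [2.5, 50.0, 97.5])
        rhat = bgr_diagnostic(samples[nm]) if chains >= 2 else np.nan
        rows.append(
            dict(parameter=nm, mean=s.mean(), sd=s.std(ddof=1), **{"q2.5": q[0], "q50": q[1], "q97.5": q[2]}, rhat=rhat)
        )
    params = pd.DataFrame(rows).set_index("parameter")
    settings = dict(
        chains=chains, iterations=iterations, burn_in=burn_in, thin=thin, n_nodes=n_nodes
    )
    return FitResult(
        params=params,
        model_tag=model_tag,
        method="mcmc",
        n_kept_samples=kept_per_chain * chains,
        seed=seed,
        settings=settings,
        samples=samples,
    )


def _numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h
            ej[j] = h
            f_pp = f(x + ei + ej)
            f_pm = f(x + ei - ej)
            f_mp = f(x - ei + ej)
            f_mm = f(x - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4.0 * h * h)
    return H


def fit_mle(
    data: CaptureHistoryMatrix,
    model_tag: str = "re_p",
    n_nodes: int = 20,
    start: Optional[Mapping[str, float]] = None,
    sigma_boundary_tol: float = 0.02,
) -> FitResult:
    """Maximise the (marginalised) CJS likelihood.

    Optimisation runs on logit-transformed parameters with L-BFGS-B; standard
    errors come from the numerically differentiated observed information,
    delta-mapped to the natural scale.  A fitted heterogeneity SD below
    ``sigma_boundary_tol`` is flagged as a boundary solution (``sigma = 0``),
    where the SE of sigma is unreliable.
    """
    lik = CJSLikelihood(data, n_nodes=n_nodes)
    names = _param_names(model_tag, data.n_occasions)
    priors = make_priors()
    lo = np.array([priors.bounds(nm)[0] for nm in names])
    hi = np.array([priors.bounds(nm)[1] for nm in names])
    loglik = _make_loglik(lik, model_tag)

    def nll(u: np.ndarray) -> float:
        ll = loglik(_to_natural(u, lo, hi))
        return -ll if np.isfinite(ll) else 1e12

    defaults = {"phi": 0.7, "p": 0.4, "p_mean": 0.4, "sigma": 0.8}
    theta0 = np.array(
        [
            (start or {}).get(nm, defaults.get(nm, defaults.get(nm.split("_")[0], 0.5)))
            for nm in names
        ]
    )
    u0 = logit(np.clip((theta0 - lo) / (hi - lo), 1e-6, 1 - 1e-6))
    starts = [u0, u0 + 0.5, u0 - 0.5]
    best = None
    bounds = [(-15.0, 15.0)] * len(names)
    for s0 in starts:
        res = minimize(nll, s0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise InferenceError("MLE optimisation failed to produce a finite objective")
    if not best.success and best.fun >= 1e11:
        raise InferenceError(f"MLE optimisation did not converge: {best.message}")

    u_hat = best.x
    theta_hat = _to_natural(u_hat, lo, hi)
    boundary = False
    if model_tag == "re_p":
        j = names.index("sigma")
        if theta_hat[j] < sigma_boundary_tol:
            boundary = True

    H = _numeric_hessian(nll, u_hat)
    try:
        cov_u = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov_u = np.full((len(names), len(names)), np.nan)
    s = expit(u_hat)
    dtheta_du = (hi - lo) * s * (1.0 - s)
    var_theta = np.clip(np.diag(cov_u), 0.0, None) * dtheta_du**2
    se = np.sqrt(var_theta)

    rows = []
    for j, nm in enumerate(names):
        m = theta_hat[j]
        sd = se[j]
        half = 1.959963984540054 * sd if np.isfinite(sd) else np.nan
        lo_q = max(lo[j], m - half) if np.isfinite(half) else np.nan
        hi_q = min(hi[j], m + half) if np.isfinite(half) else np.nan
        rows.append(
            dict(parameter=nm, mean=m, sd=sd, **{"q2.5": lo_q, "q50": m, "q97.5": hi_q}, rhat=np.nan)
        )
    params = pd.DataFrame(rows).set_index("parameter")
    return FitResult(
        params=params,
        model_tag=model_tag,
        method="mle",
        n_kept_samples=0,
        seed=None,
        settings=dict(n_nodes=n_nodes, optimizer="L-BFGS-B"),
        boundary_sigma=boundary,
        loglik=float(-best.fun),
    )
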