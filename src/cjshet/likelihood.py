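"""Likelihood machinery for the state-space Cormack-Jolly-Seber model.

The model conditions on first capture.  The latent state z[i,t] (alive/dead)
evolves as Bernoulli survival trials with probability phi per interval; the
observation y[i,t] is Bernoulli(p_i) while alive and 0 with certainty when
dead.  Three detection structures are supported:

* constant: a single p shared by all individuals;
* logit-normal random effects: logit(p_i) = mu + eps_i with
  eps_i ~ Normal(0, sigma^2), marginalised by Gauss-Hermite quadrature;
* time-varying: fixed per-interval phi_t and per-occasion p_t (no
  individual heterogeneity).

The per-individual likelihood is evaluated by the forward algorithm on the
two-state (alive/dead) hidden Markov chain; the dead state is absorbing and
silent.  Identical capture histories have identical likelihood contributions,
so datasets are compressed to unique (first capture, history) patterns with
multiplicities before repeated evaluation.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit

from .scenarios import CaptureHistoryMatrix

__all__ = [
    "LikelihoodError",
    "forward_loglik_individual",
    "loglik_constant",
    "loglik_marginal_re",
    "loglik_time_varying",
    "implied_detection_sd",
    "CJSLikelihood",
]

logger = logging.getLogger(__name__)


class LikelihoodError(RuntimeError):
    """Non-finite or invalid likelihood evaluation."""


def _forward_likelihood(
    Y: np.ndarray, first: np.ndarray, phi: Union[float, np.ndarray], P: np.ndarray
) -> np.ndarray:
    """Forward recursion over the alive/dead chain.

    Parameters
    ----------
    Y : (n, K) int array of 0/1 observations.
    first : (n,) first-capture occasions (0-based).
    phi : scalar or (K-1,) per-interval survival probabilities.
    P : (n, m) detection probabilities (constant in time; m columns allow
        several candidate values per individual, e.g. quadrature nodes), or
        (n, m, K) per-occasion probabilities.

    Returns the (n, m) probability of each observed history under each
    detection column, conditional on first capture.
    """
    n, K = Y.shape
    time_p = P.ndim == 3
    m = P.shape[1]
    phi_arr = np.full(K - 1, float(phi)) if np.ndim(phi) == 0 else np.asarray(phi, dtype=float)
    if phi_arr.shape != (K - 1,):
        raise ValueError(f"phi must be scalar or length K-1 = {K - 1}")
    alive = np.ones((n, m))
    dead = np.zeros((n, m))
    for t in range(1, K):
        Pt = P[:, :, t] if time_p else P
        yt = Y[:, t].astype(bool)[:, None]
        det = np.where(yt, Pt, 1.0 - Pt)
        ph = phi_arr[t - 1]
        new_alive = alive * (ph * det)
        new_dead = np.where(yt, 0.0, alive * (1.0 - ph) + dead)
        started = (first < t)[:, None]
        alive = np.where(started, new_alive, alive)
        dead = np.where(started, new_dead, dead)
    return alive + dead


def forward_loglik_individual(
    history: Sequence[int],
    first: int,
    phi: Union[float, Sequence[float]],
    p_by_occasion: Union[float, Sequence[float]],
) -> float:
    """Exact log-probability of one capture history after first capture.

    ``p_by_occasion`` is either a scalar (constant detection) or a length-K
    vector whose entries at occasions after ``first`` are used.
    """
    y = np.asarray(history, dtype=np.int8)
    K = y.size
    if not 0 <= first < K:
        raise ValueError(f"first capture occasion {first} out of range for K={K}")
    if y[first] != 1:
        raise ValueError("history must be 1 at the first-capture occasion")
    if np.any(y[:first] != 0):
        raise ValueError("history must be 0 before the first-capture occasion")
    if np.ndim(p_by_occasion) == 0:
        P = np.full((1, 1), float(p_by_occasion))
    else:
        p_vec = np.asarray(p_by_occasion, dtype=float)
        if p_vec.shape != (K,):
            raise ValueError(f"p_by_occasion must be scalar or length K = {K}")
        P = p_vec[None, None, :]
    lik = _forward_likelihood(y[None, :], np.array([first]), phi, P)[0, 0]
    if lik <= 0:
        return -np.inf
    return float(np.log(lik))


class CJSLikelihood:
    """Compressed likelihood evaluator for one dataset.

    Individuals first captured at the final occasion contribute likelihood 1
    under the conditional CJS model; they are dropped from the evaluation and
    their count logged.
    """

    def __init__(self, data: CaptureHistoryMatrix, n_nodes: int = 20):
        if n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        Y = data.detections
        first = data.first_capture
        self.n_occasions = data.n_occasions
        informative = first < data.n_occasions - 1
        n_final = int((~informative).sum())
        if n_final:
            logger.debug(
                "%d individuals first captured at the final occasion contribute likelihood 1",
                n_final,
            )
        key = np.column_stack([first[informative], Y[informative]])
        if key.shape[0]:
            uniq, counts = np.unique(key, axis=0, return_counts=True)
        else:
            uniq = np.empty((0, data.n_occasions + 1), dtype=np.int64)
            counts = np.empty(0, dtype=np.int64)
        self._first = uniq[:, 0].astype(np.int64)
        self._Y = np.ascontiguousarray(uniq[:, 1:], dtype=np.int8)
        self._counts = counts.astype(float)
        self.n_patterns = uniq.shape[0]
        nodes, weights = hermgauss(n_nodes)
        self._gh_nodes = nodes
        self._gh_weights = weights / np.sqrt(np.pi)
        self.n_nodes = n_nodes

    def _sum_log(self, lik: np.ndarray) -> float:
        if np.any(lik <= 0.0):
            return -np.inf
        return float(self._counts @ np.log(lik))

    def constant(self, phi: float, p: float) -> float:
        """Log-likelihood under shared survival and detection probabilities."""
        P = np.full((self.n_patterns, 1), float(p))
        lik = _forward_likelihood(self._Y, self._first, phi, P)[:, 0]
        return self._sum_log(lik)

    def marginal_re(self, phi: float, mu_logit: float, sigma_logit: float) -> float:
        """Log-likelihood with logit-normal individual detection effects.

        The per-individual likelihood is integrated over eps ~ N(0, sigma^2)
        with p_i = expit(mu + eps) by Gauss-Hermite quadrature.  At sigma = 0
        this reduces exactly to :meth:`constant` with p = expit(mu).
        """
        if sigma_logit < 0:
            raise ValueError("sigma_logit must be >= 0")
        if sigma_logit == 0.0:
            return self.constant(phi, float(expit(mu_logit)))
        p_nodes = expit(mu_logit + np.sqrt(2.0) * sigma_logit * self._gh_nodes)
        P = np.broadcast_to(p_nodes, (self.n_patterns, self.n_nodes))
        lik = _forward_likelihood(self._Y, self._first, phi, P) @ self._gh_weights
        if not np.all(np.isfinite(lik)):
            bad = int(np.flatnonzero(~np.isfinite(lik))[0])
            raise LikelihoodError(f"non-finite marginal likelihood for history pattern {bad}")
        return self._sum_log(lik)

    def time_varying(self, phi_t: Sequence[float], p_t: Sequence[float]) -> float:
        """Log-likelihood with fixed per-interval survival and per-occasion
        detection (no individual heterogeneity).

        ``phi_t`` has length K-1 (intervals); ``p_t`` has length K-1 and
        applies to recapture occasions 2..K.
        """
        K = self.n_occasions
        phi_t = np.asarray(phi_t, dtype=float)
        p_t = np.asarray(p_t, dtype=float)
        if phi_t.shape != (K - 1,) or p_t.shape != (K - 1,):
            raise ValueError(f"phi_t and p_t must each have length K-1 = {K - 1}")
        P = np.empty((1, 1, K))
        P[0, 0, 0] = 0.5  # occasion 1 is never a recapture occasion; value unused
        P[0, 0, 1:] = p_t
        P = np.broadcast_to(P, (self.n_patterns, 1, K))
        lik = _forward_likelihood(self._Y, self._first, phi_t, P)[:, 0]
        return self._sum_log(lik)


def loglik_constant(data: CaptureHistoryMatrix, phi: float, p: float) -> float:
    """Log-likelihood of the {phi, p} model (homogeneous detection)."""
    return CJSLikelihood(data, n_nodes=1).constant(phi, p)


def loglik_marginal_re(
    data: CaptureHistoryMatrix,
    phi: float,
    mu_logit: float,
    sigma_logit: float,
    n_nodes: int = 20,
) -> float:
    """Marginal log-likelihood of the {phi, p_i} logit-normal random-effects model."""
    return CJSLikelihood(data, n_nodes=n_nodes).marginal_re(phi, mu_logit, sigma_logit)


def loglik_time_varying(
    data: CaptureHistoryMatrix, phi_t: Sequence[float], p_t: Sequence[float]
) -> float:
    """Log-likelihood of the fixed-time-effect model {phi_t, p_t}."""
    return CJSLikelihood(data, n_nodes=1).time_varying(phi_t, p_t)


def implied_detection_sd(mu_logit: float, sigma_logit: float, n_nodes: int = 80) -> float:
    """Probability-scale SD of p = expit(mu + eps), eps ~ Normal(0, sigma^2).

    Bridges the logit-scale heterogeneity parameter sigma to the probability
    scale on which generating SDs are specified.  Computed by Gauss-Hermite
    quadrature of the first two moments.
    """
    if sigma_logit < 0:
        raise ValueError("sigma_logit must be >= 0")
    if sigma_logit == 0.0:
        return 0.0
    nodes, weights = hermgauss(n_nodes)
    w = weights / np.sqrt(np.pi)
    g = expit(mu_logit + np.sqrt(2.0) * sigma_logit * nodes)
    m1 = float(w @ g)
    m2 = float(w @ (g * g))
    return float(np.sqrt(max(m2 - m1 * m1, 0.0)))
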