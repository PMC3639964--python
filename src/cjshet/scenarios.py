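"""Simulation of open-population capture-mark-recapture data with individual
detection heterogeneity.

A study releases a fixed number of newly marked animals at every sampling
occasion.  Conditional on first capture, each animal survives each annual
interval with probability ``phi`` and, while alive, is detected at each
occasion with its own probability ``p_i``.  Four generating regimes for the
``p_i`` are provided: three beta distributions (symmetric, right-skewed,
left-skewed) parameterised by mean and standard deviation, and a two-point
mixture of a low- and a high-detectability group.  A degenerate "constant"
regime (every ``p_i`` equal) is also available for null simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "InvalidMomentsError",
    "ScenarioSpec",
    "CaptureHistoryMatrix",
    "beta_from_moments",
    "draw_individual_p",
    "simulate_dataset",
    "simulate_study",
    "default_scenarios",
    "BETA_LABELS",
    "SCENARIO_LABELS",
]

logger = logging.getLogger(__name__)

BETA_LABELS = ("symmetric", "right_skewed", "left_skewed")
SCENARIO_LABELS = BETA_LABELS + ("two_group", "constant")

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


class InvalidMomentsError(ValueError):
    """Requested (mean, sd) pair lies outside the beta family."""


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters (alpha, beta) of the beta distribution with the given
    mean and standard deviation.

    Uses the closed-form moment inversion ``nu = mean(1-mean)/var - 1``,
    ``alpha = mean*nu``, ``beta = (1-mean)*nu``.  Raises
    :class:`InvalidMomentsError` when ``sd**2 >= mean*(1-mean)`` (the variance
    bound of the beta family) or the mean is not strictly inside (0, 1).
    """
    if not 0.0 < mean < 1.0:
        raise InvalidMomentsError(f"mean must lie in (0, 1), got {mean!r}")
    var = float(sd) ** 2
    bound = mean * (1.0 - mean)
    if not 0.0 < var < bound:
        raise InvalidMomentsError(
            f"invalid moments (mean={mean}, sd={sd}): require 0 < sd^2 < "
            f"mean*(1-mean) = {bound:.6g}, got sd^2 = {var:.6g}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class ScenarioSpec:
    """A generating regime for individual detection probabilities plus the
    study dimensions and the true survival probability.

    Parameters
    ----------
    label
        One of ``symmetric``, ``right_skewed``, ``left_skewed`` (beta-
        distributed ``p_i``), ``two_group`` (two-point mixture) or
        ``constant`` (homogeneous detection, used for null checks).
    n_occasions
        Number of annual sampling occasions (default 15).
    n_new_per_occasion
        Newly marked animals released at every occasion (default 50).
    phi_true
        Generating apparent-survival probability, constant in time.
    p_mean
        Mean detection probability for beta/constant regimes; a
        ``(p_group1, p_group2)`` pair for ``two_group``.
    p_sd
        Probability-scale SD of the ``p_i`` for beta regimes; must be 0 for
        ``constant``; ignored for ``two_group``.
    mixture_weight
        Probability that an animal belongs to group 1 (``two_group`` only).
    """

    label: str
    n_occasions: int = 15
    n_new_per_occasion: int = 50
    phi_true: float = 0.7
    p_mean: Union[float, tuple[float, float]] = 0.4
    p_sd: float = 0.0
    mixture_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_LABELS:
            raise ValueError(
                f"unknown scenario label {self.label!r}; expected one of {SCENARIO_LABELS}"
            )
        if self.n_occasions < 2:
            raise ValueError("n_occasions must be >= 2")
        if self.n_new_per_occasion < 1:
            raise ValueError("n_new_per_occasion must be >= 1")
        if not 0.0 < self.phi_true < 1.0:
            raise ValueError("phi_true must lie in (0, 1)")
        if self.label == "two_group":
            try:
                p1, p2 = self.p_mean  # type: ignore[misc]
            except TypeError:
                raise ValueError("two_group requires p_mean to be a (p1, p2) pair") from None
            if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
                raise ValueError("group detection probabilities must lie in (0, 1)")
            if not 0.0 < self.mixture_weight < 1.0:
                raise ValueError("mixture_weight must lie in (0, 1)")
        else:
            p = float(self.p_mean)  # type: ignore[arg-type]
            if not 0.0 < p < 1.0:
                raise ValueError("p_mean must lie in (0, 1)")
            if self.label == "constant":
                if self.p_sd != 0.0:
                    raise ValueError("constant scenario requires p_sd = 0")
            else:
                # triggers InvalidMomentsError on a bad (mean, sd) pair
                beta_from_moments(p, self.p_sd)

    @property
    def is_two_group(self) -> bool:
        return self.label == "two_group"

    @property
    def detection_mean_true(self) -> float:
        """Population mean of the generating individual detection probabilities."""
        if self.is_two_group:
            p1, p2 = self.p_mean  # type: ignore[misc]
            w = self.mixture_weight
            return w * p1 + (1.0 - w) * p2
        return float(self.p_mean)  # type: ignore[arg-type]

    @property
    def detection_sd_true(self) -> float:
        """Population SD of the generating individual detection probabilities."""
        if self.is_two_group:
            p1, p2 = self.p_mean  # type: ignore[misc]
            w = self.mixture_weight
            return abs(p2 - p1) * np.sqrt(w * (1.0 - w))
        return float(self.p_sd)


def default_scenarios(
    n_occasions: int = 15, n_new_per_occasion: int = 50, phi_true: float = 0.7
) -> dict[str, ScenarioSpec]:
    """The four heterogeneity scenarios of the simulation study.

    Beta regimes with (mean, SD) = (0.4, 0.148), (0.2, 0.163), (0.8, 0.163)
    and an equal-weight two-group mixture with p = 0.2 and p = 0.8.
    """
    dims = dict(
        n_occasions=n_occasions,
        n_new_per_occasion=n_new_per_occasion,
        phi_true=phi_true,
    )
    return {
        "symmetric": ScenarioSpec("symmetric", p_mean=0.4, p_sd=0.148, **dims),
        "right_skewed": ScenarioSpec("right_skewed", p_mean=0.2, p_sd=0.163, **dims),
        "left_skewed": ScenarioSpec("left_skewed", p_mean=0.8, p_sd=0.163, **dims),
        "two_group": ScenarioSpec("two_group", p_mean=(0.2, 0.8), **dims),
    }


@dataclass
class CaptureHistoryMatrix:
    """Binary detection records (individuals x occasions) with the first-
    capture occasion of every individual.

    ``detections[i, t]`` is 1 if individual ``i`` was detected at occasion
    ``t`` (0-based internally; user-facing files are 1-based).  The matrix
    always satisfies ``detections[i, first_capture[i]] == 1`` and is zero
    before first capture.  For simulated data the generating per-individual
    detection probability (``true_p``), group label (``true_group``) and,
    optionally, the latent alive/dead states are retained.
    """

    detections: np.ndarray
    first_capture: np.ndarray
    true_p: Optional[np.ndarray] = None
    true_group: Optional[np.ndarray] = None
    latent_alive: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.detections = np.ascontiguousarray(self.detections, dtype=np.int8)
        self.first_capture = np.asarray(self.first_capture, dtype=np.int64)
        if self.detections.ndim != 2:
            raise ValueError("detections must be a 2-D matrix")
        n, k = self.detections.shape
        if self.first_capture.shape != (n,):
            raise ValueError("first_capture must have one entry per individual")
        vals = np.unique(self.detections)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("detections must contain only 0/1 values")
        if n:
            if self.first_capture.min() < 0 or self.first_capture.max() >= k:
                raise ValueError("first_capture out of occasion range")
            rows = np.arange(n)
            if not np.all(self.detections[rows, self.first_capture] == 1):
                raise ValueError("detections[i, first_capture[i]] must equal 1")
            before = np.arange(k) < self.first_capture[:, None]
            if np.any(self.detections[before] != 0):
                raise ValueError("detections must be 0 before first capture")

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.detections.shape[1]

    def __eq__(self, other: object) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, CaptureHistoryMatrix):
            return NotImplemented
        return (
            self.detections.shape == other.detections.shape
            and np.array_equal(self.detections, other.detections)
            and np.array_equal(self.first_capture, other.first_capture)
        )


def draw_individual_p(
    spec: ScenarioSpec, n: int, rng_seed: SeedLike = None
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Draw ``n`` individual detection probabilities under ``spec``.

    Returns ``(p, group)`` where ``group`` is an int array of 1/2 labels for
    the two-group regime and ``None`` otherwise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(rng_seed)
    if spec.is_two_group:
        p1, p2 = spec.p_mean  # type: ignore[misc]
        in_group1 = rng.random(n) < spec.mixture_weight
        p = np.where(in_group1, p1, p2)
        group = np.where(in_group1, 1, 2)
        return p, group
    if spec.label == "constant":
        return np.full(n, float(spec.p_mean)), None
    a, b = beta_from_moments(float(spec.p_mean), spec.p_sd)  # type: ignore[arg-type]
    return rng.beta(a, b, size=n), None


def simulate_dataset(
    spec: ScenarioSpec, rng_seed: SeedLike = None, keep_latent: bool = False
) -> CaptureHistoryMatrix:
    """Simulate one capture-history dataset under ``spec``.

    ``n_new_per_occasion`` individuals are first marked at every occasion
    1..K (the final cohort carries no recapture information but is retained).
    Conditional on first capture, survival over each interval is
    Bernoulli(``phi_true``) and, while alive, detection at each subsequent
    occasion is Bernoulli(``p_i``).  Dead individuals are never detected.
    """
    rng = _as_rng(rng_seed)
    k = spec.n_occasions
    m = spec.n_new_per_occasion
    n = k * m
    first = np.repeat(np.arange(k), m)
    p, group = draw_individual_p(spec, n, rng)

    alive = np.zeros((n, k), dtype=bool)
    surv_draws = rng.random((n, k)) < spec.phi_true
    for t in range(k):
        newly = first == t
        alive[newly, t] = True
        if t > 0:
            ongoing = first < t
            alive[ongoing, t] = alive[ongoing, t - 1] & surv_draws[ongoing, t]

    det = (rng.random((n, k)) < p[:, None]) & alive
    det[np.arange(n), first] = True  # conditioned on first capture
    det[np.arange(k) < first[:, None]] = False

    return CaptureHistoryMatrix(
        detections=det.astype(np.int8),
        first_capture=first,
        true_p=p,
        true_group=group,
        latent_alive=alive if keep_latent else None,
    )


def simulate_study(
    spec: ScenarioSpec,
    n_replicates: int,
    rng_seed: Union[None, int, np.random.SeedSequence] = None,
    keep_latent: bool = False,
) -> list[CaptureHistoryMatrix]:
    """Simulate ``n_replicates`` independent datasets.

    Sub-seed contract: the study-level seed is wrapped in a
    ``numpy.random.SeedSequence`` and replicate ``r`` uses child ``r`` of
    ``SeedSequence(rng_seed).spawn(n_replicates)``.  The spawning algorithm is
    part of NumPy's stability guarantee, so the replicate -> stream mapping is
    reproducible across machines and independent of the replicate count order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    children = ss.spawn(n_replicates)
    return [simulate_dataset(spec, child, keep_latent=keep_latent) for child in children]
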