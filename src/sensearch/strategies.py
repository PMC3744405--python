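"""Movement decision rules: decoding functions times an intrinsic kernel.

A searcher alternates scanning and moving.  Each move ``(step length l,
turn angle theta)`` is drawn from a product of two ingredients:

* an *intrinsic movement distribution* ``psi(l)`` — here a (truncated)
  Pareto kernel with uniform turn angles, the canonical Levy-search prior
  used when no sensory information is available; and
* a *decoding function* — the likelihood of the scent count ``xi``
  observed in the previous scan, given a target at distance ``l``.

Three searcher types fall out of the choice of decoding function:

``perfect``
    a point mass at the nearest prey's displacement (the searcher knows
    exactly where prey are; the intrinsic kernel is irrelevant);
``uniform``
    a constant (signals ignored; moves are drawn from ``psi`` alone);
``scent_modulated``
    the Poisson likelihood ``Pois(xi; t0 * lambda(l))`` of the directionless
    scent count, so strong signals shorten steps and silence lengthens
    them.  Turn angles stay uniform — the signal carries no direction.

The searcher is memoryless: only the most recent scan's count enters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .scent import ScentModel, SignalObservation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParetoMovementKernel:
    """Pareto step-length law ``psi(l) = mu l0^mu / l^(mu+1)``, ``l >= l0``.

    ``tail_exponent`` (mu) controls diffusivity: small mu gives heavy tails
    and superdiffusive searches, large mu approaches diffusive behaviour.
    When ``max_move`` is set the density is renormalized on
    ``[min_move, max_move]``; simulations truncate at half the torus side so
    a single move never wraps ambiguously.
    """

    min_move: float = 1.0
    tail_exponent: float = 1.0
    max_move: float | None = None

    def __post_init__(self) -> None:
        if self.min_move <= 0 or self.tail_exponent <= 0:
            raise ValueError("min_move and tail_exponent must be positive")
        if self.max_move is not None and self.max_move <= self.min_move:
            raise ValueError("max_move must exceed min_move")

    @property
    def _trunc_mass(self) -> float:
        """P(l <= max_move) under the untruncated law (1 if untruncated)."""
        if self.max_move is None:
            return 1.0
        return 1.0 - (self.min_move / self.max_move) ** self.tail_exponent

    def density(self, l) -> np.ndarray | float:
        l_arr = np.asarray(l, dtype=float)
        mu, l0 = self.tail_exponent, self.min_move
        out = np.where(
            (l_arr >= l0) & (self.max_move is None or l_arr <= self.max_move),
            mu * l0**mu / np.maximum(l_arr, l0) ** (mu + 1) / self._trunc_mass,
            0.0,
        )
        return float(out) if np.ndim(l) == 0 else out

    def survival(self, x: float) -> float:
        """Untruncated tail probability P(l > x) = (l0/x)^mu."""
        if x <= self.min_move:
            return 1.0
        return (self.min_move / x) ** self.tail_exponent

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        """Inverse-CDF draw; for the truncated law U is scaled to the kept mass."""
        u = rng.random(size) * self._trunc_mass
        return self.min_move * (1.0 - u) ** (-1.0 / self.tail_exponent)


def intrinsic_density(l, kernel: ParetoMovementKernel):
    """Functional alias for :meth:`ParetoMovementKernel.density`."""
    return kernel.density(l)


def decode_move_perfect(nearest: tuple[float, float]) -> tuple[float, float]:
    """Deterministic move straight to the nearest prey: returns its (d, theta)."""
    d, theta = nearest
    return float(d), float(theta)


def decode_move_uniform(
    kernel: ParetoMovementKernel, rng: np.random.Generator
) -> tuple[float, float]:
    """Move from the intrinsic kernel alone: Pareto length, uniform angle."""
    return float(kernel.sample(rng)), float(rng.uniform(-math.pi, math.pi))


Kind = Literal["perfect", "uniform", "scent_modulated"]


@dataclass
class SearchStrategy:
    """A decoding rule plus intrinsic kernel, with the posterior step grid.

    For the scent-modulated searcher the step-length posterior is evaluated
    on a log-spaced grid of ``grid_size`` points spanning the kernel support;
    per-signal cumulative distributions are cached because small counts
    recur constantly during a search.
    """

    kind: Kind
    kernel: ParetoMovementKernel = field(default_factory=ParetoMovementKernel)
    scent_model: ScentModel | None = None
    grid_size: int = 512

    def __post_init__(self) -> None:
        if self.kind not in ("perfect", "uniform", "scent_modulated"):
            raise ValueError(f"unknown strategy kind: {self.kind!r}")
        if self.kind == "scent_modulated" and self.scent_model is None:
            raise ValueError("scent_modulated strategy needs a scent model")
        self._grid = None
        self._cdf_cache: dict[int, np.ndarray] = {}

    # -- posterior grid ---------------------------------------------------
    def _build_grid(self) -> None:
        k = self.kernel
        upper = k.max_move if k.max_move is not None else k.min_move * 1e6
        edges = np.geomspace(k.min_move, upper, self.grid_size + 1)
        centers = np.sqrt(edges[:-1] * edges[1:])
        widths = np.diff(edges)
        log_prior = np.log(np.asarray(k.density(centers))) + np.log(widths)
        lam = np.asarray(self.scent_model.rate(centers))
        self._grid = (centers, log_prior, lam)

    def posterior_masses(self, count: int) -> tuple[np.ndarray, np.ndarray]:
        """Grid centers and normalized posterior masses for signal ``count``.

        Mass_i is proportional to ``psi(l_i) * Pois(count; t0 * lambda(l_i))``
        times the grid-cell width.  If the likelihood underflows everywhere
        the intrinsic kernel is returned with a logged warning.
        """
        if self._grid is None:
            self._build_grid()
        centers, log_prior, lam = self._grid
        mean = self.scent_model.scan_duration * lam
        with np.errstate(divide="ignore"):
            log_like = np.where(
                mean > 0,
                count * np.log(np.where(mean > 0, mean, 1.0)) - mean,
                0.0 if count == 0 else -np.inf,
            )
        logw = log_prior + log_like
        top = np.max(logw)
        if not np.isfinite(top):
            logger.warning(
                "posterior underflow for signal count %d; falling back to the "
                "intrinsic kernel", count,
            )
            logw = log_prior
            top = np.max(logw)
        w = np.exp(logw - top)
        return centers, w / w.sum()

    def _signal_cdf(self, count: int) -> tuple[np.ndarray, np.ndarray]:
        cached = self._cdf_cache.get(count)
        if cached is None:
            centers, masses = self.posterior_masses(count)
            cached = np.cumsum(masses)
            cached[-1] = 1.0
            if len(self._cdf_cache) < 4096:
                self._cdf_cache[count] = cached
        else:
            centers = self._grid[0]
        return centers, cached

    def sample_step(self, count: int, rng: np.random.Generator) -> float:
        """Draw a step length from the signal-conditioned posterior."""
        centers, cdf = self._signal_cdf(count)
        j = int(np.searchsorted(cdf, rng.random(), side="right"))
        return float(centers[min(j, len(centers) - 1)])


def posterior_step_distribution(
    xi: SignalObservation | int,
    kernel: ParetoMovementKernel,
    scent: ScentModel,
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Discretized step-length posterior for one observed scent count."""
    count = xi.count if isinstance(xi, SignalObservation) else int(xi)
    if count < 0:
        raise ValueError("signal count must be non-negative")
    strat = SearchStrategy("scent_modulated", kernel, scent, grid_size)
    return strat.posterior_masses(count)


def sample_move(
    strategy: SearchStrategy,
    xi: SignalObservation | int | None,
    nearest: tuple[float, float] | None,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Dispatch one move draw for the strategy: returns ``(length, heading)``."""
    if strategy.kind == "perfect":
        if nearest is None:
            raise ValueError("perfect strategy requires a nearest-prey observation")
        return decode_move_perfect(nearest)
    if strategy.kind == "uniform":
        return decode_move_uniform(strategy.kernel, rng)
    count = xi.count if isinstance(xi, SignalObservation) else int(xi or 0)
    length = strategy.sample_step(count, rng)
    return length, float(rng.uniform(-math.pi, math.pi))
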