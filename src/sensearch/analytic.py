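"""Closed-form encounter-rate theory and the Brownian proximity baseline.

For a predator with perfect sensing that always walks straight to its
nearest prey, the encounter rate is governed by the nearest-neighbour
distance ``D`` of the Poisson prey process: the predator travels
``(D - delta)+`` per capture, where ``delta`` is the encounter radius, so

    rate = v / E[(D - delta)+],   E[(D - delta)+] = int_delta^inf
                                                    exp(-rho V_n r^n) dr.

At low density this scales as ``rho^(1/n)`` (square root in 2-D), not the
linear mass-action form; near ``rho ~ delta^-n`` the local slope steepens
toward linearity as an increasing fraction of the plane falls within the
encounter radius of some prey.

The module also provides the first-passage baseline used to interpret
proximity events: the probability that a constant-step isotropic walk that
has just entered a disc of radius ``r_prox`` reaches the central capture
disc of radius ``delta`` before leaving, together with the classical
continuous-limit annulus formula ``ln(r_prox/r0) / ln(r_prox/delta)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .environment import unit_ball_volume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalyticRateParams:
    """Inputs to the perfect-sensing rate: density in prey per bl^n."""

    density: float
    speed: float = 1.0
    encounter_radius: float = 1.0
    dimension: int = 2

    def __post_init__(self) -> None:
        if self.density <= 0 or self.speed <= 0:
            raise ValueError("density and speed must be positive")
        if self.encounter_radius < 0:
            raise ValueError("encounter_radius must be non-negative")
        if self.dimension not in (1, 2, 3):
            raise ValueError("dimension must be 1, 2, or 3")


def mean_nn_distance(density: float, dimension: int = 2) -> float:
    """Mean nearest-neighbour distance of a Poisson process.

    ``E[D] = Gamma(1 + 1/n) * (rho * V_n(1))^(-1/n)``; in 2-D this is the
    familiar ``1 / (2 sqrt(rho))``.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    n = dimension
    return math.gamma(1.0 + 1.0 / n) * (density * unit_ball_volume(n)) ** (-1.0 / n)


def mean_excess_distance(params: AnalyticRateParams) -> float:
    """``E[(D - delta)+]``: mean travel needed to reach the encounter radius.

    Evaluated as the integral of the nearest-neighbour survival function
    ``exp(-rho V_n r^n)`` above ``delta`` by adaptive quadrature; the 2-D
    case has the closed form ``erfc(sqrt(rho pi) delta) / (2 sqrt(rho))``.
    """
    rho, n, delta = params.density, params.dimension, params.encounter_radius
    vn = unit_ball_volume(n)
    # substitute u = rho^(1/n) r so the integrand has O(1) scale at any density
    scale = rho ** (1.0 / n)
    val, err = integrate.quad(
        lambda u: math.exp(-vn * u**n), delta * scale, math.inf, epsabs=1e-14, epsrel=1e-10
    )
    return val / scale


def mean_excess_distance_closed_form_2d(density: float, delta: float) -> float:
    """Closed-form 2-D ``E[(D - delta)+]`` via the complementary error function."""
    return float(special.erfc(math.sqrt(density * math.pi) * delta) / (2.0 * math.sqrt(density)))


def perfect_rate(params: AnalyticRateParams, scan_time: float = 0.0) -> float:
    """Encounter rate of the perfect-sensing searcher (prey per second).

    With ``scan_time > 0`` each capture cycle additionally pays one scanning
    phase, matching the simulator's bookkeeping:
    ``rate = 1 / (E[(D - delta)+]/v + t0)``.
    """
    from .environment import covered_fraction

    cover = covered_fraction(params.density, params.encounter_radius, params.dimension)
    if cover > 0.999:
        logger.warning(
            "encounter radius covers %.4f of the plane: rate is saturation-limited",
            cover,
        )
    travel = mean_excess_distance(params) / params.speed
    return 1.0 / (travel + scan_time)


def low_density_log_slope(
    params: AnalyticRateParams, rho_lo: float = 1e-6, rho_hi: float = 1e-5
) -> float:
    """Numeric d(log rate)/d(log rho) of the perfect rate at low density."""
    rates = [
        perfect_rate(AnalyticRateParams(r, params.speed, params.encounter_radius, params.dimension))
        for r in (rho_lo, rho_hi)
    ]
    return math.log(rates[1] / rates[0]) / math.log(rho_hi / rho_lo)


def annulus_hitting_probability(r0: float, delta: float, r_prox: float) -> float:
    """Continuous-limit probability a 2-D Brownian path started at radius
    ``r0`` hits radius ``delta`` before radius ``r_prox``."""
    if not (delta < r0 < r_prox):
        raise ValueError("need delta < r0 < r_prox")
    return math.log(r_prox / r0) / math.log(r_prox / delta)


def brownian_encounter_probability(
    delta: float,
    r_prox: float,
    step_length: float,
    rng: np.random.Generator,
    n_walks: int = 10_000,
    entry: str = "jump",
) -> tuple[float, float]:
    """Capture probability of a constant-step walk entering the proximity disc.

    Once inside, the walk takes fixed-length steps with uniform headings (a
    constant-diffusivity walk, the short-step limit of the signal-modulated
    searcher) until a scan falls within ``delta`` of the centre (capture) or
    at least ``r_prox`` from it (escape).  Two entry conventions are
    provided:

    ``"jump"`` (default)
        the first scan inside the disc is area-uniform.  This is the entry
        distribution induced by the search process itself, whose no-signal
        steps are much longer than the proximity radius, so entering scans
        land anywhere in the disc rather than hugging the rim.
    ``"boundary"``
        the walk starts on the boundary circle and its first step is
        redrawn until it lands inside — the rim-crossing construction whose
        small-step limit is the classical annulus hitting formula.

    Returns ``(probability, standard error)``.
    """
    if delta >= r_prox:
        raise ValueError("encounter radius must be smaller than the proximity radius")
    if step_length <= 0 or n_walks < 1:
        raise ValueError("step_length and n_walks must be positive")
    if entry not in ("jump", "boundary"):
        raise ValueError("entry must be 'jump' or 'boundary'")

    hits = 0
    for _ in range(n_walks):
        if entry == "jump":
            x = r_prox * math.sqrt(rng.random())
            y = 0.0  # isotropy: the prey sits at the origin
        else:
            # rejection-sample a first scan position strictly inside
            while True:
                phi = rng.uniform(-math.pi, math.pi)
                x = r_prox + step_length * math.cos(phi)
                y = step_length * math.sin(phi)
                if math.hypot(x, y) < r_prox:
                    break
        r = math.hypot(x, y)
        while delta < r < r_prox:
            phi = rng.uniform(-math.pi, math.pi)
            x += step_length * math.cos(phi)
            y += step_length * math.sin(phi)
            r = math.hypot(x, y)
        if r <= delta:
            hits += 1
    p = hits / n_walks
    se = math.sqrt(max(p * (1.0 - p), 1.0 / n_walks) / n_walks)
    return p, se
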