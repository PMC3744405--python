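"""Olfactory signal model: distance-dependent Poisson scent arrivals.

Each prey emits discrete scent patches.  In the absence of advection the
steady-state concentration of a substance that diffuses and dissipates in
two dimensions falls off with distance ``d`` from the source as the
modified Bessel function ``K0(d / xi)``, where ``xi`` is the decay length
set by the ratio of diffusivity to dissipation rate.  We normalize so that
the arrival rate at the patch radius ``a`` equals the emission rate ``R0``:

    lambda(d) = R0 * K0(d / xi) / K0(a / xi),   a <= d <= r_o

with ``lambda(d) = lambda(a)`` inside the source scale and a hard cutoff
(``lambda = 0``) beyond the olfaction radius ``r_o``.  During a scanning
phase of duration ``t0`` the predator counts a Poisson number of arrivals
with mean ``t0 * sum_i lambda(d_i)`` over living prey: scent from multiple
prey superposes, and the count carries no directional information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, special

from .environment import PreyField, TorusEnvironment, alive_distances


def bessel_k0_profile(a: float, decay_length: float) -> Callable[[np.ndarray], np.ndarray]:
    """2-D diffusion-dissipation steady-state profile, 1 at the patch radius."""
    norm = special.k0(a / decay_length)

    def profile(d: np.ndarray) -> np.ndarray:
        return special.k0(np.maximum(d, a) / decay_length) / norm

    return profile


@dataclass
class ScentModel:
    """Distance -> scent-arrival-rate map plus the scanning-phase sampler.

    Parameters
    ----------
    emission_rate
        ``R0``, arrival rate (patches per second) measured at the patch
        radius.
    decay_length
        ``xi``, spatial scale of the steady-state concentration field (bl).
    patch_radius
        ``a``, source/receptor scale (bl); the rate saturates below it.
    scan_duration
        ``t0``, length of one scanning phase (s).
    olfaction_radius
        ``r_o``, hard cutoff beyond which no scent is detectable (bl).
    profile
        Optional replacement for the Bessel-K0 shape; any callable mapping
        distance to a dimensionless factor equal to 1 at ``patch_radius``.
    """

    emission_rate: float = 100.0
    decay_length: float = 2.5
    patch_radius: float = 1.0
    scan_duration: float = 1.0
    olfaction_radius: float = 500.0
    profile: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("emission_rate", "decay_length", "patch_radius",
                     "scan_duration", "olfaction_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.profile is None:
            self.profile = bessel_k0_profile(self.patch_radius, self.decay_length)

    def rate(self, d) -> np.ndarray | float:
        """Arrival rate ``lambda(d)`` in patches per second."""
        d_arr = np.asarray(d, dtype=float)
        if np.any(d_arr < 0):
            raise ValueError("distance must be non-negative")
        lam = self.emission_rate * self.profile(d_arr)
        lam = np.where(d_arr > self.olfaction_radius, 0.0, lam)
        if np.ndim(d) == 0:
            return float(lam)
        return lam

    def total_rate(self, pos: np.ndarray, field_: PreyField) -> float:
        """Summed arrival rate at ``pos`` over all living prey."""
        _, dists = alive_distances(pos, field_)
        dists = dists[dists <= self.olfaction_radius]
        if dists.size == 0:
            return 0.0
        return float(np.sum(self.rate(dists)))

    def detection_probability(self, d: float) -> float:
        """Probability of a non-zero count in one scan at distance ``d``."""
        return -float(np.expm1(-self.scan_duration * self.rate(d)))


def scent_rate(d, model: ScentModel):
    """Functional alias for :meth:`ScentModel.rate`."""
    return model.rate(d)


@dataclass(frozen=True)
class SignalObservation:
    """Count of scent arrivals in one scanning phase."""

    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("signal count must be non-negative")


def sample_signal(
    pos: np.ndarray,
    field_: PreyField,
    env: TorusEnvironment,
    model: ScentModel,
    rng: np.random.Generator,
) -> SignalObservation:
    """Draw the scanning-phase scent count at ``pos``.

    The count is Poisson with mean ``t0 * sum_i lambda(d_i)`` over living
    prey within the olfaction radius.
    """
    mean = model.scan_duration * model.total_rate(pos, field_)
    return SignalObservation(int(rng.poisson(mean)))


def proximity_radius(model: ScentModel, p_detect: float = 0.05) -> float:
    """Distance at which one scan yields a non-zero signal with prob ``p_detect``.

    Solves ``1 - exp(-t0 * lambda(r)) = p_detect`` for ``r`` in
    ``(patch_radius, olfaction_radius)``.  If the detection probability just
    inside the cutoff still exceeds ``p_detect`` (scent everywhere stronger
    than the criterion), the olfaction radius itself is returned.
    """
    if not (0.0 < p_detect < 1.0):
        raise ValueError("p_detect must be in (0, 1)")
    a, r_o = model.patch_radius, model.olfaction_radius
    if model.detection_probability(a) < p_detect:
        raise ValueError("p_detect unattainable: signal too weak even at the source")
    # rate() is continuous and non-increasing on [a, r_o]
    just_inside = np.nextafter(r_o, a)
    if model.detection_probability(just_inside) > p_detect:
        return r_o
    f = lambda r: model.detection_probability(r) - p_detect
    return float(optimize.brentq(f, a, just_inside, xtol=1e-12))
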