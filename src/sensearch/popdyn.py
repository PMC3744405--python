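"""Coupled predator-prey dynamics driven by encounter-rate kinetics.

The daily consumption of a predator is derived from its encounter rate by a
renewal argument: each day the predator undertakes ``M`` hunts, each lasting
an exponentially distributed time with mean ``T`` unless a prey is found
first.  Treating encounters during a hunt as a Poisson process with rate
``f(N)`` (the encounter rate at prey density ``N``), the success
probability of one hunt is ``E[1 - exp(-f tau)] = f T / (1 + f T)`` and
Wald's identity over the ``M`` hunts gives the functional response

    g(N) = M * f(N) T / (1 + f(N) T),

a Holling type-II-like saturating form.  This feeds a generalized
Rosenzweig-MacArthur system

    dN/dt = r N (1 - N/K) - g(N) P,      dP/dt = c g(N) P - m P,

whose coexistence fixed point, local stability, critical carrying capacity
and limit cycles are analysed here.  The shape of ``f`` at low density —
linear for a purely random searcher, sublinear for a sensing one — decides
how far predators can depress prey and how little prey they can persist on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate as sp_integrate
from scipy import optimize

from .scaling import RateTable, SegmentedFit, compare_regimes, fit_powerlaw, fit_segmented


# --------------------------------------------------------------------------
# Encounter-rate functions f(N)
# --------------------------------------------------------------------------

def power_law_rate(a: float, gamma: float) -> Callable[[float], float]:
    """Encounter rate ``f(N) = a N^gamma`` (gamma in (0, 1])."""
    if a <= 0 or gamma <= 0:
        raise ValueError("a and gamma must be positive")

    def f(N):
        return a * np.power(np.maximum(N, 0.0), gamma)

    return f


def table_rate(table: RateTable) -> Callable[[float], float]:
    """Log-log linear interpolation of a simulated rate table.

    Outside the tabulated density range the rate extrapolates as a power
    law with the slope of the nearest edge segment.
    """
    order = np.argsort(table.log_density)
    lx, ly = table.log_density[order], table.log_rate[order]
    slope_lo = (ly[1] - ly[0]) / (lx[1] - lx[0])
    slope_hi = (ly[-1] - ly[-2]) / (lx[-1] - lx[-2])

    def f(N):
        N_arr = np.asarray(N, dtype=float)
        out = np.zeros_like(N_arr, dtype=float)
        pos = N_arr > 0
        x = np.log10(N_arr[pos])
        y = np.interp(x, lx, ly)
        y = np.where(x < lx[0], ly[0] + slope_lo * (x - lx[0]), y)
        y = np.where(x > lx[-1], ly[-1] + slope_hi * (x - lx[-1]), y)
        out[pos] = 10.0**y
        return float(out) if np.ndim(N) == 0 else out

    return f


def linearized_below(f: Callable, splice_density: float) -> Callable[[float], float]:
    """Replace ``f`` below ``splice_density`` by the line through the origin
    matching ``f`` at the splice.

    This is the 'linearized' construction used to isolate the effect of
    low-density nonlinearity: identical to ``f`` above the splice, linear
    (mass-action) below it.
    """
    if splice_density <= 0:
        raise ValueError("splice_density must be positive")
    slope = f(splice_density) / splice_density

    def g(N):
        N_arr = np.asarray(N, dtype=float)
        out = np.where(N_arr >= splice_density, f(N_arr), slope * np.maximum(N_arr, 0.0))
        return float(out) if np.ndim(N) == 0 else out

    return g


# --------------------------------------------------------------------------
# Wald functional response
# --------------------------------------------------------------------------

@dataclass
class FunctionalResponse:
    """Daily consumption ``g(N) = M f(N) T / (1 + f(N) T)``.

    ``hunts_per_day`` (M) bounds daily intake; ``mean_hunt_duration`` (T,
    days) sets how long the predator persists in an unsuccessful hunt;
    ``encounter_rate_fn`` maps prey density to encounters per day.
    """

    encounter_rate_fn: Callable[[float], float]
    hunts_per_day: int = 5
    mean_hunt_duration: float = 0.2

    def __post_init__(self) -> None:
        if self.hunts_per_day < 1:
            raise ValueError("hunts_per_day must be at least 1")
        if self.mean_hunt_duration <= 0:
            raise ValueError("mean_hunt_duration must be positive")

    def __call__(self, N):
        fT = np.asarray(self.encounter_rate_fn(N)) * self.mean_hunt_duration
        out = self.hunts_per_day * fT / (1.0 + fT)
        return float(out) if np.ndim(out) == 0 else out

    def derivative(self, N: float, h: float | None = None) -> float:
        """``g'(N)`` by central differences (relative step ``h``)."""
        h = h if h is not None else max(1e-6, 1e-6 * abs(N))
        return (self(N + h) - self(max(N - h, 0.0))) / (N + h - max(N - h, 0.0))


def functional_response(N, fr: FunctionalResponse):
    """Functional alias for ``fr(N)``."""
    return fr(N)


def monte_carlo_functional_response(
    fr: FunctionalResponse, N: float, n_days: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Simulate the hunt process directly: mean daily consumption and its SE.

    Each day the predator performs M hunts; hunt ``j`` draws an exponential
    patience ``tau_j`` (mean T) and succeeds if a Poisson encounter process
    with rate ``f(N)`` fires before ``tau_j`` elapses.
    """
    f = float(fr.encounter_rate_fn(N))
    M, T = fr.hunts_per_day, fr.mean_hunt_duration
    tau = rng.exponential(T, size=(n_days, M))
    success = rng.random((n_days, M)) < -np.expm1(-f * tau)
    daily = success.sum(axis=1)
    return float(daily.mean()), float(daily.std(ddof=1) / math.sqrt(n_days))


# --------------------------------------------------------------------------
# Rosenzweig-MacArthur system
# --------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Generalized Rosenzweig-MacArthur parameters (rates per day)."""

    response: FunctionalResponse
    growth_rate: float = 0.3  # r, prey offspring per prey per day
    carrying_capacity: float = 10.0  # K, prey density
    conversion_efficiency: float = 0.1  # c, predator offspring per prey eaten
    mortality: float = 0.05  # m, predator deaths per predator per day

    def __post_init__(self) -> None:
        for name in ("growth_rate", "carrying_capacity", "conversion_efficiency", "mortality"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def h(self, N):
        """Logistic prey growth ``h(N) = r N (1 - N/K)``."""
        return self.growth_rate * N * (1.0 - N / self.carrying_capacity)

    def h_prime(self, N: float) -> float:
        return self.growth_rate * (1.0 - 2.0 * N / self.carrying_capacity)


def rm_derivatives(N: float, P: float, model: PopulationModel) -> tuple[float, float]:
    """Right-hand side ``(dN/dt, dP/dt)`` of the predator-prey system."""
    if N < 0 or P < 0:
        raise ValueError("densities must be non-negative")
    g = model.response(N)
    dN = model.h(N) - g * P
    dP = model.conversion_efficiency * g * P - model.mortality * P
    return float(dN), float(dP)


@dataclass
class FixedPointReport:
    """Coexistence equilibrium and its linear stability."""

    exists: bool
    N_star: float = math.nan
    P_star: float = math.nan
    jacobian: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    classification: str = "no-coexistence"
    stable: bool | None = None


def coexistence_fixed_point(model: PopulationModel) -> FixedPointReport:
    """Interior equilibrium: ``N*`` solves ``c g(N*) = m``; ``P* = h(N*)/g(N*)``.

    Requires ``c g(K) > m`` (the predator can subsist at carrying capacity);
    otherwise a no-coexistence report is returned rather than an error.
    ``g`` is increasing for the response forms used here, so the root is
    unique.
    """
    c, m, K = model.conversion_efficiency, model.mortality, model.carrying_capacity
    excess = lambda N: c * model.response(N) - m
    if excess(K) <= 0:
        return FixedPointReport(exists=False)
    lo = K * 1e-12
    if excess(lo) >= 0:  # predator subsists on arbitrarily sparse prey
        return FixedPointReport(exists=False, classification="degenerate")
    N_star = float(optimize.brentq(excess, lo, K, xtol=1e-14, rtol=8.9e-16))
    g_star = float(model.response(N_star))
    P_star = float(model.h(N_star)) / g_star
    report = FixedPointReport(exists=True, N_star=N_star, P_star=P_star)
    return stability_analysis(model, report)


def stability_analysis(model: PopulationModel, fp: FixedPointReport) -> FixedPointReport:
    """Fill in the Jacobian, eigenvalues and classification at a fixed point.

    The Jacobian at ``(N*, P*)`` is ``[[h' - g' P*, -g], [c g' P*, 0]]``;
    its determinant is positive for increasing ``g``, so stability reduces
    to the sign of the trace ``h'(N*) - g'(N*) P*``.
    """
    if not fp.exists:
        return fp
    N, P = fp.N_star, fp.P_star
    g = float(model.response(N))
    gp = model.response.derivative(N)
    J = np.array(
        [
            [model.h_prime(N) - gp * P, -g],
            [model.conversion_efficiency * gp * P, 0.0],
        ]
    )
    eig = np.linalg.eigvals(J)
    fp.jacobian = J
    fp.eigenvalues = eig
    fp.stable = bool(np.all(eig.real < 0))
    kind = "focus" if np.any(np.abs(eig.imag) > 1e-12) else "node"
    fp.classification = ("stable " if fp.stable else "unstable ") + kind
    return fp


def critical_carrying_capacity(
    model: PopulationModel, k_lo: float | None = None, k_hi: float = 1e4, tol: float = 1e-8
) -> float:
    """Carrying capacity at which the coexistence point loses stability.

    ``N*`` does not depend on ``K``, so the Jacobian trace is a function of
    ``K`` alone; the Hopf threshold is located by bisection on the trace's
    sign change.  Returns NaN if the point is stable for every ``K`` in the
    bracket.
    """
    base = coexistence_fixed_point(model)
    if not base.exists:
        raise ValueError("model has no coexistence fixed point")
    N_star = base.N_star
    if k_lo is None:
        k_lo = N_star * (1.0 + 1e-9)

    def trace_at(K: float) -> float:
        m = PopulationModel(
            model.response, model.growth_rate, K, model.conversion_efficiency, model.mortality
        )
        P = float(m.h(N_star)) / float(m.response(N_star))
        return m.h_prime(N_star) - m.response.derivative(N_star) * P

    if trace_at(k_hi) < 0:
        return math.nan
    return float(optimize.brentq(trace_at, k_lo, k_hi, xtol=tol))


@dataclass
class TrajectorySummary:
    """Long-run behaviour of one integration."""

    t: np.ndarray
    N: np.ndarray
    P: np.ndarray
    converged_to_point: bool
    cycle_stats: dict | None = None


def integrate(
    model: PopulationModel,
    N0: float,
    P0: float,
    t_span: tuple[float, float],
    n_eval: int = 2000,
) -> TrajectorySummary:
    """Integrate the system (LSODA) and summarize the tail behaviour.

    The last 20% of the horizon is classified as either convergence to the
    coexistence point (within 1e-6) or a bounded oscillation, in which case
    min/max/mean of both densities over the tail are reported.
    """
    if N0 <= 0 or P0 < 0:
        raise ValueError("initial conditions must be positive (P0 may be zero)")

    def rhs(t, y):
        N, P = max(y[0], 0.0), max(y[1], 0.0)
        g = model.response(N)
        return [
            model.h(N) - g * P,
            model.conversion_efficiency * g * P - model.mortality * P,
        ]

    t_eval = np.linspace(t_span[0], t_span[1], n_eval)
    sol = sp_integrate.solve_ivp(
        rhs, t_span, [N0, P0], method="LSODA", t_eval=t_eval, rtol=1e-9, atol=1e-12
    )
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.3g}: {sol.message}")
    N, P = sol.y
    tail = slice(int(0.8 * len(sol.t)), None)
    fp = coexistence_fixed_point(model)
    converged = bool(
        fp.exists
        and np.all(np.hypot(N[tail] - fp.N_star, P[tail] - fp.P_star) < 1e-6)
    )
    cycle = None
    if not converged:
        cycle = {
            "N_min": float(N[tail].min()),
            "N_max": float(N[tail].max()),
            "N_mean": float(N[tail].mean()),
            "P_min": float(P[tail].min()),
            "P_max": float(P[tail].max()),
            "P_mean": float(P[tail].mean()),
        }
    return TrajectorySummary(sol.t, N, P, converged, cycle)


def steady_state_sweep(
    responses: dict[str, FunctionalResponse],
    growth_rate: float = 0.3,
    conversion_efficiency: float = 0.1,
    mortality: float = 0.05,
    carrying_capacity: float = 10.0,
    K_grid=None,
    cm_ratio_grid=None,
) -> "pd.DataFrame":
    """Steady-state summaries across a parameter grid, per encounter model.

    Exactly one of ``K_grid`` (carrying capacities) or ``cm_ratio_grid``
    (conversion-efficiency-to-mortality ratios, varying ``c`` at fixed
    ``m``) must be given.  Each row reports the coexistence densities, or
    the boundary equilibrium ``(K, 0)`` where the predator cannot persist.
    """
    import pandas as pd

    if (K_grid is None) == (cm_ratio_grid is None):
        raise ValueError("give exactly one of K_grid or cm_ratio_grid")
    rows = []
    grid = K_grid if K_grid is not None else cm_ratio_grid
    for label, fr in responses.items():
        for val in np.asarray(grid, dtype=float):
            if K_grid is not None:
                K, c = float(val), conversion_efficiency
            else:
                K, c = carrying_capacity, float(val) * mortality
            model = PopulationModel(fr, growth_rate, K, c, mortality)
            fp = coexistence_fixed_point(model)
            rows.append(
                {
                    "strategy": label,
                    ("K" if K_grid is not None else "cm_ratio"): val,
                    "persists": fp.exists,
                    "N_star": fp.N_star if fp.exists else K,
                    "P_star": fp.P_star if fp.exists else 0.0,
                    "stable": fp.stable,
                }
            )
    return pd.DataFrame(rows)
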