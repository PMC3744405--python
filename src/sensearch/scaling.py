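"""Piecewise power-law fits to encounter-rate vs density data.

Locally the encounter rate behaves as a power law ``R = c rho^beta``, so in
log-log coordinates the data are piecewise linear.  The number of scaling
regimes (1-3) and the breakpoints between them are estimated together by
the iterative-linearization scheme of segmented regression: at the current
breakpoint guesses ``psi_j`` the model is augmented with hinge terms
``(x - psi_j)+`` and working indicator terms, ordinary least squares is
solved, and each breakpoint is moved by the ratio of the indicator to the
hinge coefficient until the updates vanish.  Models with different regime
counts are compared by AIC under a Gaussian likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd


@dataclass
class RateTable:
    """(density, rate) observations, optionally with SE and replicate counts.

    Densities may be in any consistent unit; fitted breakpoints are
    reported in log10 of that unit.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("density", "rate"):
            if col not in df.columns:
                raise ValueError(f"RateTable requires a '{col}' column")
        if (df["density"] <= 0).any() or (df["rate"] <= 0).any():
            raise ValueError("densities and rates must be positive")
        if df["density"].duplicated().any():
            raise ValueError("densities must be distinct")

    @classmethod
    def from_arrays(cls, density, rate, se=None, n=None) -> "RateTable":
        df = pd.DataFrame({"density": np.asarray(density, float), "rate": np.asarray(rate, float)})
        if se is not None:
            df["se"] = np.asarray(se, float)
        if n is not None:
            df["n"] = np.asarray(n, int)
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        return cls(pd.read_csv(path))

    @property
    def log_density(self) -> np.ndarray:
        return np.log10(self.data["density"].to_numpy())

    @property
    def log_rate(self) -> np.ndarray:
        return np.log10(self.data["rate"].to_numpy())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SegmentedFit:
    """A continuous piecewise-linear fit in log10-log10 coordinates."""

    n_regimes: int
    breakpoints: np.ndarray  # log10 density, increasing; empty for 1 regime
    slopes: np.ndarray  # one exponent per regime
    intercept: float  # value of the first segment's line at x = 0
    rss: float
    aic: float
    n_obs: int
    converged: bool = True

    @property
    def n_params(self) -> int:
        # slopes + intercept + breakpoints + residual variance
        return self.n_regimes + 1 + len(self.breakpoints) + 1

    def predict_log(self, log_density) -> np.ndarray:
        """Fitted log10 rate at the given log10 densities."""
        x = np.asarray(log_density, dtype=float)
        y = self.intercept + self.slopes[0] * x
        for j, psi in enumerate(self.breakpoints):
            y = y + (self.slopes[j + 1] - self.slopes[j]) * np.clip(x - psi, 0.0, None)
        return y

    def predict(self, density) -> np.ndarray:
        return 10.0 ** self.predict_log(np.log10(np.asarray(density, dtype=float)))


def _gaussian_aic(rss: float, n: int, n_params: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * n_params


def fit_powerlaw(table: RateTable) -> SegmentedFit:
    """Single power law: OLS of log rate on log density."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    x, y = table.log_density, table.log_rate
    if np.ptp(x) == 0:
        raise ValueError("densities carry no variation")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    fit = SegmentedFit(
        n_regimes=1,
        breakpoints=np.empty(0),
        slopes=np.array([coef[1]]),
        intercept=float(coef[0]),
        rss=rss,
        aic=0.0,
        n_obs=len(table),
    )
    fit.aic = _gaussian_aic(rss, fit.n_obs, fit.n_params)
    return fit


def _segmented_ols(x: np.ndarray, y: np.ndarray, psi: np.ndarray):
    """One working OLS step: returns (coef, rss, hinge b_j, indicator c_j)."""
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.clip(x - p, 0.0, None))
    for p in psi:
        cols.append(-(x > p).astype(float))
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    k = len(psi)
    return coef, float(resid @ resid), coef[2 : 2 + k], coef[2 + k :]


def _final_fit(x: np.ndarray, y: np.ndarray, psi: np.ndarray):
    """Refit at fixed breakpoints (no working indicator terms)."""
    cols = [np.ones_like(x), x] + [np.clip(x - p, 0.0, None) for p in psi]
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_segmented(
    table: RateTable,
    n_regimes: int,
    init_breakpoints=None,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_restarts: int = 5,
    rng: np.random.Generator | None = None,
) -> SegmentedFit:
    """Segmented power-law fit with ``n_regimes`` (2 or 3) scaling regimes.

    Breakpoints initialize at data quantiles unless given; ``n_restarts``
    jittered initializations guard against local optima and the best
    residual sum of squares wins.  A fit whose breakpoints escape the data
    range is restarted; if no start converges the best last iterate is
    returned with ``converged=False``.
    """
    if n_regimes not in (2, 3):
        raise ValueError("n_regimes must be 2 or 3")
    if len(table) < 4 * n_regimes:
        raise ValueError(f"need at least {4 * n_regimes} rows for {n_regimes} regimes")
    rng = rng or np.random.default_rng(0)
    x, y = table.log_density, table.log_rate
    order = np.argsort(x)
    x, y = x[order], y[order]
    lo, hi = x[1], x[-2]  # keep breakpoints strictly interior
    k = n_regimes - 1

    if init_breakpoints is not None:
        base = np.sort(np.asarray(init_breakpoints, dtype=float))
        if len(base) != k:
            raise ValueError("init_breakpoints length must be n_regimes - 1")
    else:
        base = np.quantile(x, np.arange(1, k + 1) / (k + 1))

    starts = [base]
    span = (hi - lo) / (k + 1)
    for _ in range(n_restarts - 1):
        starts.append(np.sort(np.clip(base + rng.uniform(-0.5, 0.5, k) * span, lo, hi)))

    best = None
    for psi0 in starts:
        psi = psi0.copy()
        ok = True
        for _ in range(max_iter):
            _, _, b, c = _segmented_ols(x, y, psi)
            if np.any(np.abs(b) < 1e-12):
                ok = False
                break
            step = c / b
            psi_new = np.sort(psi + step)
            psi_new = np.clip(psi_new, lo, hi)
            if np.max(np.abs(psi_new - psi)) < tol:
                psi = psi_new
                break
            psi = psi_new
        else:
            ok = False
        if np.any(np.diff(psi) <= 0):
            ok = False
        coef, rss = _final_fit(x, y, psi)
        # converged fits beat unconverged ones; ties broken by RSS
        key = (not ok, rss)
        if best is None or key < best[0]:
            best = (key, coef, rss, ok, psi)

    _, coef, rss, ok, psi = best
    slopes = np.concatenate([[coef[1]], coef[1] + np.cumsum(coef[2:])])
    fit = SegmentedFit(
        n_regimes=n_regimes,
        breakpoints=psi,
        slopes=slopes,
        intercept=float(coef[0]),
        rss=rss,
        aic=0.0,
        n_obs=len(table),
        converged=ok,
    )
    fit.aic = _gaussian_aic(rss, fit.n_obs, fit.n_params)
    return fit


@dataclass
class RegimeComparison:
    """AIC comparison across 1/2/3-regime fits of the same data."""

    fits: dict[int, SegmentedFit]
    delta_aic: float  # AIC(1 regime) - AIC(best multi-regime); positive favours segmentation
    selected: SegmentedFit = dc_field(init=False)

    def __post_init__(self) -> None:
        self.selected = min(self.fits.values(), key=lambda f: f.aic)


def compare_regimes(fits: list[SegmentedFit]) -> RegimeComparison:
    """Compare single- vs multi-regime fits of one data set by AIC.

    ``delta_aic`` follows the convention AIC(single) minus AIC(best
    segmented model): positive values favour multiple scaling regimes.
    """
    by_n = {f.n_regimes: f for f in fits}
    if 1 not in by_n or not any(n > 1 for n in by_n):
        raise ValueError("need a 1-regime fit and at least one multi-regime fit")
    if len({f.n_obs for f in fits}) != 1:
        raise ValueError("fits must be of the same data")
    best_multi = min(f.aic for n, f in by_n.items() if n > 1)
    return RegimeComparison(fits=by_n, delta_aic=by_n[1].aic - best_multi)
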