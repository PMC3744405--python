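"""Periodic search domains and prey point patterns.

The search arena is an ``n``-dimensional torus (a square with wrap-around
boundaries for the simulations, which are two-dimensional).  Prey are
immobile point targets laid down either by a homogeneous Poisson process or
by a preferential-attachment cluster process in which most prey are
daughters of a small number of uniformly placed seed points.

Lengths are measured in predator body lengths (bl).  Every function in this
module takes *absolute* density (prey per bl^n).  Experiment sweeps quote
density in the more readable unit of prey per :data:`AREA_UNIT` bl**2; the
conversion (divide by ``AREA_UNIT``) happens once, at the experiment layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reference area for sweep bookkeeping: experiment density labels are prey
#: per ``AREA_UNIT`` squared body lengths (library functions use prey/bl^n).
AREA_UNIT = 1.0e4


class EmptyFieldError(RuntimeError):
    """Raised when an operation needs at least one living prey."""


def unit_ball_volume(n: int) -> float:
    """Volume of the unit ``n``-ball, pi^(n/2) / Gamma(n/2 + 1)."""
    return math.pi ** (n / 2.0) / math.gamma(n / 2.0 + 1.0)


@dataclass(frozen=True)
class TorusEnvironment:
    """A periodic hypercubic domain ``[0, L)^n``.

    Parameters
    ----------
    side_length
        Edge length ``L`` of the domain in body lengths.
    dimension
        Spatial dimension ``n``; the simulators use ``n = 2``.
    """

    side_length: float
    dimension: int = 2

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")

    @property
    def volume(self) -> float:
        return self.side_length ** self.dimension

    def wrap(self, pts: np.ndarray) -> np.ndarray:
        """Map coordinates into the fundamental domain ``[0, L)``."""
        return np.mod(pts, self.side_length)

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vector(s) from ``a`` to ``b``."""
        d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        L = self.side_length
        return d - L * np.round(d / L)


@dataclass
class PreyField:
    """Prey coordinates plus alive flags on a torus.

    ``positions`` has shape ``(count, n)`` with every coordinate in
    ``[0, L)``; ``alive`` is a boolean mask updated by destructive search.
    """

    positions: np.ndarray
    env: TorusEnvironment
    alive: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, self.env.dimension)
        if self.positions.shape[1] != self.env.dimension:
            raise ValueError("position dimension does not match environment")
        if np.any(self.positions < 0) or np.any(self.positions >= self.env.side_length):
            raise ValueError("prey coordinates outside [0, L)")
        if self.alive is None:
            self.alive = np.ones(len(self.positions), dtype=bool)
        else:
            self.alive = np.asarray(self.alive, dtype=bool)
            if self.alive.shape != (len(self.positions),):
                raise ValueError("alive mask length mismatch")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def density(self) -> float:
        """Realized prey density in prey per bl^n."""
        return len(self) / self.env.volume

    def copy(self) -> "PreyField":
        return PreyField(self.positions.copy(), self.env, self.alive.copy())

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": np.arange(len(self))}
        for j, name in enumerate("xyz"[: self.env.dimension]):
            cols[name] = self.positions[:, j]
        cols["alive"] = self.alive
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, env: TorusEnvironment) -> "PreyField":
        df = pd.read_csv(path)
        coords = df[list("xyz"[: env.dimension])].to_numpy(dtype=float)
        return cls(coords, env, df["alive"].to_numpy(dtype=bool))


def domain_for_density(density: float, mean_count: float, dimension: int = 2) -> TorusEnvironment:
    """Torus whose volume gives the requested density at the expected count.

    ``L`` is fixed from the *expected* prey count, not the realized Poisson
    draw, so the density is exact in expectation while individual fields
    fluctuate around it.
    """
    if density <= 0 or mean_count <= 0:
        raise ValueError("density and mean_count must be positive")
    L = (mean_count / density) ** (1.0 / dimension)
    return TorusEnvironment(L, dimension)


def sample_poisson_prey(
    density: float,
    mean_count: float,
    rng: np.random.Generator,
    dimension: int = 2,
) -> PreyField:
    """Homogeneous Poisson prey field at the given density.

    The prey count is Poisson with mean ``mean_count`` and positions are
    i.i.d. uniform on the torus sized by :func:`domain_for_density`.
    """
    env = domain_for_density(density, mean_count, dimension)
    count = int(rng.poisson(mean_count))
    pos = rng.uniform(0.0, env.side_length, size=(count, dimension))
    return PreyField(pos, env)


def sample_clustered_prey(
    density: float,
    mean_count: float,
    rng: np.random.Generator,
    seed_fraction: float = 0.1,
    local_density: float | None = None,
    dimension: int = 2,
) -> PreyField:
    """Preferential-attachment clustered prey field.

    A fraction of the prey act as uniformly placed *seed* points; each
    remaining prey is attached iteratively to seed ``i`` with probability
    proportional to ``1 + n_daughters_i`` (the Yule form), then placed
    uniformly in a disc around its seed.  Every cluster's disc radius is set
    from its final membership so that all clusters share the same local
    density ``local_density`` (prey per bl^n; default 100x the background).
    """
    if not (0.0 < seed_fraction <= 1.0):
        raise ValueError("seed_fraction must be in (0, 1]")
    env = domain_for_density(density, mean_count, dimension)
    if local_density is None:
        local_density = 100.0 * density  # clusters 100x denser than background
    if local_density < density:
        raise ValueError("local_density must be at least the global density")
    count = int(rng.poisson(mean_count))
    n_seeds = max(1, math.ceil(seed_fraction * count))
    n_seeds = min(n_seeds, count) if count > 0 else 0
    if count == 0:
        return PreyField(np.empty((0, dimension)), env)
    seeds = rng.uniform(0.0, env.side_length, size=(n_seeds, dimension))
    if n_seeds == count:
        return PreyField(seeds, env)

    # preferential attachment of daughters to seeds
    daughters = np.zeros(n_seeds, dtype=np.int64)
    for _ in range(count - n_seeds):
        w = 1.0 + daughters
        i = rng.choice(n_seeds, p=w / w.sum())
        daughters[i] += 1

    rho_local = local_density
    positions = [seeds]
    vn = unit_ball_volume(dimension)
    for i in range(n_seeds):
        k = daughters[i]
        if k == 0:
            continue
        # radius such that (k + 1) / V_n(radius) == rho_local
        radius = ((k + 1) / (rho_local * vn)) ** (1.0 / dimension)
        # uniform in the n-ball via normalized Gaussians and a radial CDF draw
        direc = rng.normal(size=(k, dimension))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        r = radius * rng.uniform(size=(k, 1)) ** (1.0 / dimension)
        positions.append(env.wrap(seeds[i] + direc * r))
    return PreyField(np.vstack(positions), env)


def torus_distance(a: np.ndarray, b: np.ndarray, env: TorusEnvironment) -> float:
    """Minimum-image (wrap-around) distance between two points."""
    return float(np.linalg.norm(env.displacement(a, b)))


def nearest_prey(
    pos: np.ndarray, field_: PreyField, env: TorusEnvironment | None = None
) -> tuple[int, float, float]:
    """Nearest living prey to ``pos``: ``(index, distance, angle)``.

    The angle is the direction of the minimum-image displacement (2-D only;
    NaN otherwise).  Ties resolve to the lowest prey index.
    """
    env = env or field_.env
    if field_.n_alive == 0:
        raise EmptyFieldError("no living prey in the field")
    idx_alive = np.flatnonzero(field_.alive)
    disp = env.displacement(pos, field_.positions[idx_alive])
    dist = np.linalg.norm(disp, axis=1)
    j = int(np.argmin(dist))  # argmin takes the first minimum: lowest index
    i = int(idx_alive[j])
    d = float(dist[j])
    theta = float(np.arctan2(disp[j, 1], disp[j, 0])) if env.dimension == 2 else float("nan")
    return i, d, theta


def alive_distances(pos: np.ndarray, field_: PreyField) -> tuple[np.ndarray, np.ndarray]:
    """Distances from ``pos`` to every living prey, with their indices."""
    idx = np.flatnonzero(field_.alive)
    disp = field_.env.displacement(pos, field_.positions[idx])
    return idx, np.linalg.norm(disp, axis=1)


def covered_fraction(density: float, radius: float, dimension: int = 2) -> float:
    """Fraction of the plane within ``radius`` of some Poisson prey.

    By Poisson thinning a location escapes all discs with probability
    ``exp(-rho * V_n(radius))``, so the covered fraction is its complement.
    """
    if density < 0 or radius < 0:
        raise ValueError("density and radius must be non-negative")
    return -math.expm1(-density * unit_ball_volume(dimension) * radius ** dimension)
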