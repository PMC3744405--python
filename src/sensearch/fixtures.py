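"""Deterministic prey layouts and signal sequences for tests and demos.

Every fixture is rebuilt from literals on each call, so regeneration is
byte-identical across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import PreyField, TorusEnvironment


@dataclass(frozen=True)
class FixtureSet:
    """Named deterministic layouts on small tori."""

    single_prey: PreyField  # one prey at a fixed offset from the origin
    grid_3x3: PreyField  # 3x3 lattice on a 30x30 torus
    two_clusters: PreyField  # two tight 5-prey clumps, far apart
    signal_sequence: tuple  # canned scent counts for decoder tests


def make_fixtures() -> FixtureSet:
    env_single = TorusEnvironment(100.0)
    single = PreyField(np.array([[60.0, 30.0]]), env_single)

    env_grid = TorusEnvironment(30.0)
    xs = np.array([5.0, 15.0, 25.0])
    gx, gy = np.meshgrid(xs, xs)
    grid = PreyField(np.column_stack([gx.ravel(), gy.ravel()]), env_grid)

    env_cl = TorusEnvironment(200.0)
    offsets = np.array([[0.0, 0.0], [1.5, 0.0], [0.0, 1.5], [-1.5, 0.0], [0.0, -1.5]])
    cluster_a = offsets + np.array([40.0, 40.0])
    cluster_b = offsets + np.array([150.0, 150.0])
    clusters = PreyField(np.vstack([cluster_a, cluster_b]), env_cl)

    signal = (0, 0, 1, 0, 3, 0, 0, 2, 0, 0, 0, 5, 1, 0, 0)
    return FixtureSet(single, grid, clusters, signal)
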