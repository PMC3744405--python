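"""Scan-move search loop, encounter detection, and proximity events.

A single predator alternates scanning phases (duration ``t0``, during which
it measures the scent signal and captures any living prey within the
encounter radius ``delta``) and movement phases (a straight move at constant
speed ``v`` drawn from its strategy).  Search is destructive: captured prey
are removed and the search ends after ``k_max`` captures.

Encounter times follow the bookkeeping convention that a capture is
registered at the end of the scanning phase that detects it, so
``total elapsed time = scan_count * t0 + path_length / v`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .environment import PreyField, TorusEnvironment, alive_distances
from .strategies import SearchStrategy


@dataclass
class SearcherConfig:
    """Physical parameters of the searching predator.

    ``speed`` is in body lengths per second, ``encounter_radius`` in body
    lengths; ``k_max`` sets how many prey are captured before the search
    ends (1 for first-encounter rates, 32 for destructive-search rates).
    ``scan_duration`` is only consulted for strategies without a scent
    model; otherwise the scent model's ``t0`` governs.
    """

    strategy: SearchStrategy
    speed: float = 1.0
    encounter_radius: float = 1.0
    k_max: int = 1
    scan_duration: float = 1.0
    max_scans: int = 10_000_000

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.encounter_radius <= 0:
            raise ValueError("speed and encounter_radius must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be at least 1")

    @property
    def scan_time(self) -> float:
        if self.strategy.scent_model is not None:
            return self.strategy.scent_model.scan_duration
        return self.scan_duration


@dataclass
class ProximityEvent:
    """One visit to the neighbourhood of a prey item.

    Opens at the first scan within ``r_prox`` of a living prey and closes
    either with a capture (outcome ``"encounter"``) or at the first scan at
    least ``r_prox`` from every living prey (outcome ``"escape"``).
    """

    entry_time: float
    exit_or_capture_time: float
    outcome: str
    prey_id: int


@dataclass
class SearchResult:
    """Outcome of one simulated search."""

    encounter_times: np.ndarray
    encounter_prey: np.ndarray
    scan_count: int
    total_path_length: float
    total_time: float
    truncated: bool = False
    scan_positions: np.ndarray | None = None
    scan_times: np.ndarray | None = None
    capture_scan_index: np.ndarray | None = None

    @property
    def first_encounter_time(self) -> float:
        if len(self.encounter_times) == 0:
            raise ValueError("search recorded no encounters")
        return float(self.encounter_times[0])

    def kth_encounter_time(self, k: int) -> float:
        if len(self.encounter_times) < k:
            raise ValueError(f"search recorded fewer than {k} encounters")
        return float(self.encounter_times[k - 1])


def run_search(
    env: TorusEnvironment,
    field_: PreyField,
    searcher: SearcherConfig,
    rng: np.random.Generator,
    record_trajectory: bool = False,
    start: np.ndarray | None = None,
) -> SearchResult:
    """Simulate one search until ``k_max`` captures (or the scan cap).

    The prey field is modified in place (captured prey are flagged dead);
    pass ``field_.copy()`` to preserve the original.  The searcher starts at
    ``start`` or, by default, a uniformly random location.
    """
    if field_.n_alive < searcher.k_max:
        raise ValueError("field has fewer living prey than k_max")
    if env.dimension != 2:
        raise ValueError("the search simulator is two-dimensional")

    strat = searcher.strategy
    scent = strat.scent_model
    t0 = searcher.scan_time
    v = searcher.speed
    delta = searcher.encounter_radius
    L = env.side_length

    pos = (
        np.array(start, dtype=float)
        if start is not None
        else rng.uniform(0.0, L, size=2)
    )
    t = 0.0
    path = 0.0
    scans = 0
    enc_times: list[float] = []
    enc_prey: list[int] = []
    traj: list[np.ndarray] = []
    traj_t: list[float] = []
    cap_scan: list[int] = []
    truncated = False

    while len(enc_times) < searcher.k_max:
        if scans >= searcher.max_scans:
            truncated = True
            break
        # ---- scanning phase ----
        scans += 1
        t += t0
        if record_trajectory:
            traj.append(pos.copy())
            traj_t.append(t)
        idx, dists = alive_distances(pos, field_)
        j = int(np.argmin(dists))
        if dists[j] <= delta:
            prey = int(idx[j])
            field_.alive[prey] = False
            enc_times.append(t)
            enc_prey.append(prey)
            if record_trajectory:
                cap_scan.append(scans - 1)
            continue  # rescan from the same spot; remaining prey may be close
        # ---- movement phase ----
        if strat.kind == "perfect":
            disp = env.displacement(pos, field_.positions[idx[j]])
            d = dists[j]
            # land a hair inside the encounter radius so the next scan's
            # capture test is robust to roundoff at large coordinates
            step = max(d - delta * (1.0 - 1e-6), 0.0)
            heading = math.atan2(disp[1], disp[0])
        elif strat.kind == "uniform":
            step = float(strat.kernel.sample(rng))
            heading = rng.uniform(-math.pi, math.pi)
        else:  # scent_modulated
            within = dists <= scent.olfaction_radius
            mean = t0 * float(np.sum(scent.rate(dists[within]))) if within.any() else 0.0
            count = int(rng.poisson(mean)) if mean > 0 else 0
            step = strat.sample_step(count, rng)
            heading = rng.uniform(-math.pi, math.pi)
        pos = np.mod(pos + step * np.array([math.cos(heading), math.sin(heading)]), L)
        path += step
        t += step / v

    return SearchResult(
        encounter_times=np.asarray(enc_times),
        encounter_prey=np.asarray(enc_prey, dtype=int),
        scan_count=scans,
        total_path_length=path,
        total_time=t,
        truncated=truncated,
        scan_positions=np.asarray(traj) if record_trajectory else None,
        scan_times=np.asarray(traj_t) if record_trajectory else None,
        capture_scan_index=np.asarray(cap_scan, dtype=int) if record_trajectory else None,
    )


def first_encounter_rate(results: list[SearchResult]) -> float:
    """Empirical first-encounter rate ``R1 = 1 / <T1>`` over replicates."""
    times = [r.first_encounter_time for r in results if len(r.encounter_times)]
    if not times:
        raise ValueError("no replicate recorded an encounter")
    return 1.0 / float(np.mean(times))


def destructive_rate(results: list[SearchResult], k: int) -> float:
    """Destructive-search rate ``Rk = k / <T_k>`` over replicates."""
    bad = [i for i, r in enumerate(results) if len(r.encounter_times) < k]
    if bad:
        raise ValueError(f"replicates with fewer than {k} encounters: {bad}")
    times = [r.kth_encounter_time(k) for r in results]
    return k / float(np.mean(times))


def extract_proximity_events(
    result: SearchResult,
    initial_field: PreyField,
    r_prox: float,
) -> tuple[list[ProximityEvent], float]:
    """Replay a recorded trajectory and segment it into proximity events.

    ``initial_field`` must be the prey field as it was at the start of the
    search (all eventually-captured prey alive); captures are replayed in
    recorded order.  Returns the events plus the empirical encounter
    probability (captures / events); the probability is NaN when no event
    occurred.
    """
    if result.scan_positions is None:
        raise ValueError("search was run without record_trajectory")
    field_ = initial_field.copy()
    env = field_.env
    cap_at = {int(s): int(p) for s, p in zip(result.capture_scan_index, result.encounter_prey)}

    events: list[ProximityEvent] = []
    open_entry: float | None = None
    open_prey: int = -1
    for s, (pos, t_s) in enumerate(zip(result.scan_positions, result.scan_times)):
        captured = cap_at.get(s)
        idx, dists = alive_distances(pos, field_)
        j = int(np.argmin(dists))
        dmin = float(dists[j])
        if open_entry is None:
            if dmin < r_prox:
                open_entry = float(t_s)
                open_prey = int(idx[j])
        if open_entry is not None:
            if captured is not None:
                events.append(ProximityEvent(open_entry, float(t_s), "encounter", captured))
                open_entry = None
            elif dmin >= r_prox:
                events.append(ProximityEvent(open_entry, float(t_s), "escape", open_prey))
                open_entry = None
        if captured is not None:
            field_.alive[captured] = False

    if not events:
        return events, float("nan")
    n_caught = sum(1 for e in events if e.outcome == "encounter")
    return events, n_caught / len(events)
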