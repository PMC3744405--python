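"""Reproducible experiment orchestration over the search simulator.

Densities at this layer are quoted in the sweep unit (prey per
:data:`~sensearch.environment.AREA_UNIT` bl^2) and converted to absolute
prey per bl^2 before reaching the library.  One master seed spawns
independent child streams per replicate, so results are bit-reproducible
and replicates are statistically independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .engine import (
    ProximityEvent,
    SearcherConfig,
    SearchResult,
    destructive_rate,
    extract_proximity_events,
    first_encounter_rate,
    run_search,
)
from .environment import AREA_UNIT, sample_clustered_prey, sample_poisson_prey
from .scaling import RateTable
from .scent import ScentModel, proximity_radius
from .strategies import ParetoMovementKernel, SearchStrategy


def build_scent_model(cfg: ExperimentConfig) -> ScentModel:
    s = cfg.scent
    return ScentModel(
        emission_rate=s.emission_rate,
        decay_length=s.decay_length,
        patch_radius=s.patch_radius,
        scan_duration=s.scan_duration,
        olfaction_radius=s.olfaction_radius,
    )


def build_strategy(cfg: ExperimentConfig, side_length: float) -> SearchStrategy:
    """Strategy for a torus of the given size: steps truncate at L/2."""
    k = cfg.kernel
    kernel = ParetoMovementKernel(
        min_move=k.min_move, tail_exponent=k.tail_exponent, max_move=side_length / 2.0
    )
    scent = build_scent_model(cfg) if cfg.strategy == "scent_modulated" else None
    return SearchStrategy(cfg.strategy, kernel, scent)


def _sample_field(cfg: ExperimentConfig, density_abs: float, rng: np.random.Generator):
    e = cfg.environment
    if e.clustered:
        return sample_clustered_prey(
            density_abs,
            e.mean_count,
            rng,
            seed_fraction=e.seed_fraction,
            local_density=e.local_density_factor * density_abs,
            dimension=e.dimension,
        )
    return sample_poisson_prey(density_abs, e.mean_count, rng, dimension=e.dimension)


def run_replicates(
    cfg: ExperimentConfig,
    density: float,
    replicates: int,
    seed_seq: np.random.SeedSequence,
    k: int | None = None,
    record_trajectory: bool = False,
    keep_fields: bool = False,
) -> tuple[list[SearchResult], list]:
    """Run independent replicate searches at one sweep density.

    Each replicate draws a fresh prey field (prey 'replenish and
    redistribute' between searches) and an independent RNG stream.
    """
    density_abs = density / AREA_UNIT
    k = k if k is not None else cfg.searcher.k_max
    results: list[SearchResult] = []
    fields: list = []
    for child in seed_seq.spawn(replicates):
        rng = np.random.default_rng(child)
        field_ = _sample_field(cfg, density_abs, rng)
        strategy = build_strategy(cfg, field_.env.side_length)
        searcher = SearcherConfig(
            strategy=strategy,
            speed=cfg.searcher.speed,
            encounter_radius=cfg.searcher.encounter_radius,
            k_max=k,
            scan_duration=cfg.scent.scan_duration,
            max_scans=cfg.searcher.max_scans,
        )
        initial = field_.copy() if keep_fields else None
        results.append(
            run_search(field_.env, field_, searcher, rng, record_trajectory=record_trajectory)
        )
        if keep_fields:
            fields.append(initial)
    return results, fields


def sweep_rates(
    cfg: ExperimentConfig,
    densities=None,
    replicates: int | None = None,
    k: int | None = None,
) -> tuple[RateTable, pd.DataFrame]:
    """Density sweep of encounter rates for the configured strategy.

    Returns the aggregated rate table (rate per density, with the standard
    error of the mean encounter time propagated to the rate scale) and the
    per-replicate records.
    """
    densities = list(densities if densities is not None else cfg.sweep.densities)
    replicates = replicates if replicates is not None else cfg.sweep.replicates
    k = k if k is not None else cfg.sweep.k
    master = np.random.SeedSequence(cfg.seed)
    per_density_seqs = master.spawn(len(densities))

    records = []
    agg = []
    for density, seq in zip(densities, per_density_seqs):
        results, _ = run_replicates(cfg, density, replicates, seq, k=k)
        times_k = np.array([r.kth_encounter_time(k) for r in results])
        rate = k / times_k.mean()
        se_rate = rate * times_k.std(ddof=1) / times_k.mean() / np.sqrt(len(times_k))
        agg.append(
            {"density": density, "rate": rate, "se": se_rate, "n": replicates,
             "strategy": cfg.strategy, "k": k}
        )
        for i, res in enumerate(results):
            records.append(
                {
                    "replicate": i,
                    "density": density,
                    "strategy": cfg.strategy,
                    "T_first": res.first_encounter_time,
                    "T_k": res.kth_encounter_time(k),
                    "k": k,
                    "scans": res.scan_count,
                    "path_length": res.total_path_length,
                }
            )
    table = RateTable(pd.DataFrame(agg))
    return table, pd.DataFrame.from_records(records)


def proximity_statistics(
    cfg: ExperimentConfig,
    density: float,
    replicates: int,
    p_detect: float = 0.05,
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[float, list[ProximityEvent], float]:
    """Empirical encounter probability from pooled proximity events.

    The proximity radius is fixed from the scent model by the ``p_detect``
    non-zero-signal criterion; trajectories at one density are replayed and
    all events pooled.  Returns ``(r_prox, events, probability)``.
    """
    r_prox = proximity_radius(build_scent_model(cfg), p_detect)
    seq = seed_seq if seed_seq is not None else np.random.SeedSequence(cfg.seed)
    results, fields = run_replicates(
        cfg, density, replicates, seq, record_trajectory=True, keep_fields=True
    )
    events: list[ProximityEvent] = []
    captures = 0
    for res, initial in zip(results, fields):
        evs, _ = extract_proximity_events(res, initial, r_prox)
        events.extend(evs)
        captures += sum(1 for e in evs if e.outcome == "encounter")
    prob = captures / len(events) if events else float("nan")
    return r_prox, events, prob


def run_experiment(cfg: ExperimentConfig, out_prefix) -> dict:
    """Full sweep -> CSV rate table + per-replicate CSV + JSON sidecar."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    table, records = sweep_rates(cfg)
    rates_path = out_prefix.with_suffix(".rates.csv")
    reps_path = out_prefix.with_suffix(".replicates.csv")
    meta_path = out_prefix.with_suffix(".meta.json")
    table.data.to_csv(rates_path, index=False)
    records.to_csv(reps_path, index=False)
    meta = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "defaulted_fields": cfg.defaulted_fields,
        "outputs": {"rates": rates_path.name, "replicates": reps_path.name},
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return meta
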