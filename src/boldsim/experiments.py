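"""Sweep designs and fully reproducible replication protocols.

The study's exploration design varies one parameter at a time away from the
baselines (``omega_difference = 0.001``, ``p_baseline = 0.001``,
``d_food = 100``, ``n = 10``) over fixed grids, running many independent
replicates per (rule, value) cell.  Two harvesting protocols exist:

* ``"focal"`` — one row per run with the six focal-individual statistics
  (the 10,000-replicate protocol of the parameter exploration);
* ``"full_group"`` — one row per individual per run (the 200-replicate
  protocol behind the variance-partitioning analyses).

Every run's seed is derived deterministically from
``(master_seed, rule, value_index, replicate_index)`` via
``numpy.random.SeedSequence``, so a sweep is bit-reproducible regardless of
execution order, and social arms can be paired replicate-by-replicate with
the non-social arm at the same cell (common random numbers for the
ordering-difference metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import RULES, SimulationConfig, run_simulation
from .observers import full_group_times, summarize_focal

#: Grids of the single-parameter explorations.
PUBLISHED_GRIDS: dict[str, tuple] = {
    "p_baseline": tuple(round(0.0001 * k, 4) for k in range(1, 21)),
    "omega_difference": tuple(round(0.0001 * k, 4) for k in range(1, 21)),
    "d_food": tuple(float(v) for v in range(20, 201, 10)),
    "n": tuple(range(5, 51, 5)),
}

PROTOCOLS = ("focal", "full_group")

#: Cap on periods used for sweep cells; the smallest p_baseline cells average
#: ~1e6 periods under the non-social rule, so the single-run default cap of
#: 1e6 would abort runs the design legitimately contains.
SWEEP_MAX_STEPS = 50_000_000

_RULE_INDEX = {rule: k for k, rule in enumerate(RULES)}


class ResourceGuardError(RuntimeError):
    """Raised when a sweep schedules more runs than its configured cap."""


@dataclass(frozen=True)
class SweepDesign:
    """One single-parameter exploration: grid, baseline, replication, seeds."""

    swept_parameter: str
    grid: tuple
    baseline: SimulationConfig
    replicates: int
    rules: tuple = RULES
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.swept_parameter not in PUBLISHED_GRIDS:
            raise ValueError(
                f"swept_parameter must be one of {tuple(PUBLISHED_GRIDS)}, "
                f"got {self.swept_parameter!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.grid:
            raise ValueError("grid must be non-empty")
        unknown = [r for r in self.rules if r not in RULES]
        if unknown:
            raise ValueError(f"unknown rules {unknown}; choose from {RULES}")
        if self.master_seed < 0:
            raise ValueError("master_seed must be >= 0")

    @property
    def n_runs(self) -> int:
        return len(self.rules) * len(self.grid) * self.replicates


def published_sweep(swept_parameter: str, replicates: int,
                    rules: tuple = RULES, master_seed: int = 0,
                    grid: tuple | None = None,
                    omega_indexing: str = "zero_based") -> SweepDesign:
    """A :class:`SweepDesign` with the published grid and baselines.

    Pass ``omega_indexing="one_based"`` for the variant that reproduces the
    published group-level statistics (see :mod:`boldsim.engine`).
    """
    return SweepDesign(
        swept_parameter=swept_parameter,
        grid=tuple(grid) if grid is not None else PUBLISHED_GRIDS[swept_parameter],
        baseline=SimulationConfig(max_steps=SWEEP_MAX_STEPS,
                                  omega_indexing=omega_indexing),
        replicates=replicates,
        rules=tuple(rules),
        master_seed=master_seed,
    )


def derive_seed(master_seed: int, rule: str, value_index: int,
                replicate_index: int) -> int:
    """Deterministic, platform-stable child seed for one run.

    Hashes the tuple ``(master_seed, rule index, value_index,
    replicate_index)`` through ``numpy.random.SeedSequence`` — effectively
    injective over practical ranges and independent of execution order.
    """
    ss = np.random.SeedSequence(
        [master_seed, _RULE_INDEX[rule], value_index, replicate_index])
    return int(ss.generate_state(1, np.uint64)[0])


def _config_for(design: SweepDesign, rule: str, value) -> SimulationConfig:
    kwargs = {design.swept_parameter: value, "rule": rule}
    if design.swept_parameter == "n":
        kwargs["n"] = int(value)
    return design.baseline.with_(**kwargs)


def run_cell(design: SweepDesign, rule: str, value_index: int,
             replicate_index: int, protocol: str = "focal") -> pd.DataFrame:
    """Run a single replicate of one sweep cell and return its tidy rows."""
    value = design.grid[value_index]
    seed = derive_seed(design.master_seed, rule, value_index, replicate_index)
    config = _config_for(design, rule, value).with_(seed=seed)
    rng = np.random.default_rng(seed)
    log = run_simulation(config, rng=rng)
    meta = {
        "rule": rule,
        "parameter": design.swept_parameter,
        "value": value,
        "value_index": value_index,
        "replicate": replicate_index,
        "seed": seed,
    }
    if protocol == "focal":
        focal = summarize_focal(log, rng)  # same stream, drawn after the run
        row = dict(meta)
        row.update(
            focal_identity=focal.focal_identity,
            leave_time=focal.leave_time,
            leave_latency=focal.leave_latency,
            arrival_time=focal.arrival_time,
            arrival_latency=focal.arrival_latency,
            travel_time=focal.travel_time,
            end_time=focal.end_time,
        )
        return pd.DataFrame([row])
    table = full_group_times(log)
    for key, val in reversed(meta.items()):
        table.insert(0, key, val)
    return table


def run_sweep(design: SweepDesign, protocol: str = "focal",
              max_runs: int = 2_000_000, progress: bool = False) -> pd.DataFrame:
    """Execute a sweep and return one tidy DataFrame.

    ``protocol="focal"`` gives one row per run; ``"full_group"`` gives one
    row per individual per run.  Raises :class:`ResourceGuardError` if the
    design schedules more than ``max_runs`` simulations.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}, got {protocol!r}")
    if design.n_runs > max_runs:
        raise ResourceGuardError(
            f"design schedules {design.n_runs} runs, above the cap "
            f"max_runs={max_runs}; raise the cap to proceed")
    cells = [
        (rule, vi, ri)
        for rule in design.rules
        for vi in range(len(design.grid))
        for ri in range(design.replicates)
    ]
    if progress:
        from tqdm import tqdm
        cells = tqdm(cells, desc=f"sweep {design.swept_parameter}", unit="run")
    frames = [run_cell(design, rule, vi, ri, protocol)
              for rule, vi, ri in cells]
    return pd.concat(frames, ignore_index=True)


def cell_summary(focal_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the six statistics per (rule, value) cell."""
    measures = ["end_time", "travel_time", "leave_time", "leave_latency",
                "arrival_time", "arrival_latency"]
    out = (focal_table
           .groupby(["rule", "parameter", "value"], sort=True)[measures]
           .agg(["mean", "std"]))
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()
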