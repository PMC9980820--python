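"""Deterministic micro-sweeps for fast analysis-layer tests and examples.

The bundle is a scaled-down single-parameter exploration (a short arena so
runs finish quickly) regenerated on demand rather than shipped as data:
with the compiled kernel it takes seconds, and regeneration with the pinned
seed is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .engine import RULES, SimulationConfig
from .experiments import SweepDesign, run_sweep

FIXTURE_GRID = (0.0005, 0.001, 0.002)
FIXTURE_REPLICATES = 20
FIXTURE_D_FOOD = 30.0


def fixture_design(seed: int = 0) -> SweepDesign:
    """3 omega_difference values x 20 replicates x all four rules, d_food=30."""
    return SweepDesign(
        swept_parameter="omega_difference",
        grid=FIXTURE_GRID,
        baseline=SimulationConfig(d_food=FIXTURE_D_FOOD),
        replicates=FIXTURE_REPLICATES,
        rules=RULES,
        master_seed=seed,
    )


def generate_fixtures(seed: int = 0, out_dir: str | Path | None = None,
                      ) -> dict[str, pd.DataFrame]:
    """Run the micro-sweep under both protocols; optionally write CSVs.

    Returns ``{"focal": ..., "full_group": ...}`` tidy tables.
    """
    design = fixture_design(seed)
    tables = {
        "focal": run_sweep(design, protocol="focal"),
        "full_group": run_sweep(design, protocol="full_group"),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out_dir / f"micro_sweep_{name}.csv", index=False)
    return tables
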