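"""Shared fixtures.

Heavy simulation batches (full wild-type runs, preset sweeps) are
session-scoped so several tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from eyecpm import (
    CellField,
    CellRegistry,
    ContactEnergyTable,
    EngineParameters,
    ShapeConstraints,
    SyntheticFieldSpec,
    generate_synthetic_field,
)
from eyecpm import runner as runner_mod


@pytest.fixture
def params_order1():
    return EngineParameters(neighbor_order=1, temperature=60.0)


@pytest.fixture
def params_order2():
    return EngineParameters(neighbor_order=2, temperature=60.0)


def make_field(labels, types, shape=None, neighbor_order=2):
    """Field + registry from a literal label array and per-id type list."""
    field = CellField(np.asarray(labels, dtype=np.int32))
    registry = CellRegistry.from_field(
        field, types, shape=shape or ShapeConstraints(),
        neighbor_order=neighbor_order)
    return field, registry


@pytest.fixture
def block_field():
    """6x6 periodic field with one 2x2 IPC cell (id 1), rest Medium."""
    labels = np.zeros((6, 6), dtype=np.int32)
    labels[2:4, 2:4] = 1
    return make_field(labels, ["Medium", "IPC"], neighbor_order=1)


def random_field(rng, size=16, n_cells=5, neighbor_order=2):
    """Random small periodic field with a mix of OC/IPC cells and Medium."""
    labels = rng.integers(0, n_cells + 1, size=(size, size)).astype(np.int32)
    types = ["Medium"] + ["OC" if i % 2 else "IPC" for i in range(1, n_cells + 1)]
    return make_field(labels, types, neighbor_order=neighbor_order)


@pytest.fixture
def small_synthetic():
    spec = SyntheticFieldSpec(rows=2, cols=2, seed=0)
    return generate_synthetic_field(spec)


# -- session-scoped simulation batches ---------------------------------------


@pytest.fixture(scope="session")
def wildtype_runs():
    """Five full wild-type runs (4x4 ommatidia, 50,000 MCS, seeds 1-5)."""
    outs = {}
    preset = runner_mod.build_preset("wild_type")
    for seed in (1, 2, 3, 4, 5):
        outs[seed] = runner_mod.run_experiment(preset, seed)
    return outs


@pytest.fixture(scope="session")
def death_level_runs():
    """Death-threshold comparison (L = 16/12/10): 3x3 ommatidia,
    20,000 MCS (10,000 of death), 5 seeds; per-run final metrics."""
    base = runner_mod.build_preset("wild_type", rows=3, cols=3,
                                   total_mcs=20_000)
    grid = {"variant": ["wild_type", "reduced_death_L12",
                        "reduced_death_L10"]}
    final, _ = runner_mod.run_sweep(base, grid, seeds=[1, 2, 3, 4, 5],
                                    keep_timeseries=False)
    assert (final["error"] == "").all()
    return final


@pytest.fixture(scope="session")
def expansion_variant_runs():
    """Expansion/death removal comparison at the full 50,000-MCS horizon
    (the IPC-growth handicap accrues over the whole run): 3x3 ommatidia,
    5 seeds."""
    base = runner_mod.build_preset("wild_type", rows=3, cols=3,
                                   total_mcs=50_000)
    grid = {"variant": ["wild_type", "growing_ipcs", "no_expansion",
                        "no_expansion_no_death"]}
    final, _ = runner_mod.run_sweep(base, grid, seeds=[1, 2, 3, 4, 5],
                                    keep_timeseries=False)
    assert (final["error"] == "").all()
    return final


@pytest.fixture(scope="session")
def temperature_runs():
    """Motility sweep T in {25, 60, 150}: 3x3 ommatidia, 20,000 MCS."""
    base = runner_mod.build_preset("wild_type", rows=3, cols=3,
                                   total_mcs=20_000)
    final, _ = runner_mod.run_sweep(base, {"T": [25.0, 60.0, 150.0]},
                                    seeds=[1], keep_timeseries=False)
    assert (final["error"] == "").all()
    return final
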