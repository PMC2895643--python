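"""Experiment presets, batch execution and run artefacts.

A :class:`ExperimentPreset` pins everything a run needs: engine
parameters, contact energies, the death rule, the expansion schedule, the
variant, and the synthetic-field geometry (or a tracing path).  The
wild-type preset uses the published working point: T = 60,
J_OC,IPC = 35, J_IPC,IPC = 55, survival threshold L = 16, death onset at
10,000 MCS, OC target doubling, 50,000 MCS total.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .engine import (
    IPC, OC, CellField, CellRegistry, ContactEnergyTable, EngineParameters,
    LatticeRNG, ShapeConstraints, run_mcs, total_energy,
)
from .eye_model import (
    VARIANTS, DeathRule, ExpansionSchedule, TypeExpansion, VariantSpec,
    apply_variant, expansion_step, mark_border_exempt, pcd_sweep,
    split_cell_in_half,
)
from .field_init import (
    SyntheticFieldSpec, TypeMap, export_field, generate_synthetic_field,
    import_tracing,
)
from .scoring import TimeSeriesRecorder, score_snapshot

__all__ = [
    "ExperimentPreset", "RunOutputs", "wild_type_preset", "build_preset",
    "run_experiment", "run_sweep", "preset_to_dict", "preset_from_dict",
    "save_preset", "load_preset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentPreset:
    name: str = "wild_type"
    engine: EngineParameters = dc_field(default_factory=EngineParameters)
    contact_energies: ContactEnergyTable = dc_field(
        default_factory=ContactEnergyTable.wild_type)
    death: DeathRule = dc_field(default_factory=DeathRule)
    expansion: ExpansionSchedule = dc_field(
        default_factory=ExpansionSchedule.wild_type)
    variant: VariantSpec = dc_field(default_factory=VariantSpec)
    field: SyntheticFieldSpec = dc_field(default_factory=SyntheticFieldSpec)
    tracing_path: str | None = None
    tracing_type_map: dict | None = None
    shape: ShapeConstraints = dc_field(default_factory=ShapeConstraints)
    report_interval: int = 500
    seeds: tuple = (1, 2, 3, 4, 5)


@dataclass
class RunOutputs:
    preset: ExperimentPreset
    seed: int
    timeseries: "object"          # pandas.DataFrame
    final_registry: "object"      # pandas.DataFrame
    final_score: "object"         # scoring.SnapshotScore
    manifest: dict
    field: CellField
    registry: CellRegistry
    paths: dict = dc_field(default_factory=dict)


def wild_type_preset(rows: int = 4, cols: int = 4,
                     total_mcs: int = 50_000, **field_kwargs
                     ) -> ExperimentPreset:
    return ExperimentPreset(
        engine=EngineParameters(total_mcs=total_mcs),
        field=SyntheticFieldSpec(rows=rows, cols=cols, **field_kwargs),
    )


def build_preset(name: str, rows: int = 4, cols: int = 4,
                 total_mcs: int = 50_000, **field_kwargs) -> ExperimentPreset:
    """Named experiment preset: the wild-type working point with one
    variant's overrides applied."""
    if name not in VARIANTS:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(VARIANTS)}")
    base = replace(wild_type_preset(rows, cols, total_mcs, **field_kwargs),
                   name=name)
    return apply_variant(base, VARIANTS[name])


def _build_initial_state(preset: ExperimentPreset):
    if preset.tracing_path is not None:
        type_map = TypeMap(mapping=preset.tracing_type_map or {0: "Medium"})
        field, registry = import_tracing(
            preset.tracing_path, type_map, shape=preset.shape,
            params=preset.engine)
    else:
        field, registry = generate_synthetic_field(
            preset.field, shape=preset.shape, params=preset.engine)
    return field, registry


def _central_oc(field: CellField, registry: CellRegistry) -> int:
    """The OC whose centroid is nearest the lattice centre."""
    best, best_d = None, None
    cy, cx = field.height / 2.0, field.width / 2.0
    for i in registry.living_ids(OC):
        rr, cc = np.nonzero(field.owner == int(i))
        d = (rr.mean() - cy) ** 2 + (cc.mean() - cx) ** 2
        if best is None or d < best_d:
            best, best_d = int(i), d
    if best is None:
        raise RuntimeError("field has no OC cells")
    return best


def run_experiment(preset: ExperimentPreset, seed: int,
                   outdir=None, snapshot_every: int | None = None,
                   progress: bool = False) -> RunOutputs:
    """Execute one full simulation.

    The synthetic field geometry is fixed by the preset (the paper-style
    'one representative tracing'); ``seed`` drives the Monte Carlo
    dynamics and the death draws.  Hooks run each MCS in the order
    expansion -> death -> scoring.  On an internal error the MCS index is
    reported and, if ``outdir`` is set, a post-mortem snapshot is dumped.
    """
    field, registry = _build_initial_state(preset)

    # per-variant field surgery and expansion enablement
    registry.expansion_enabled[registry.cell_type == OC] = (
        OC in preset.expansion.by_type)
    if preset.variant.oc_expansion == "all_but_one":
        registry.expansion_enabled[_central_oc(field, registry)] = False
    elif preset.variant.oc_expansion == "half_of_one":
        split_cell_in_half(field, registry, _central_oc(field, registry),
                           preset.engine, expansion_enabled=(True, False))
    if IPC in preset.expansion.by_type:
        registry.expansion_enabled[registry.cell_type == IPC] = True

    mark_border_exempt(field, registry, preset.engine)

    rng = LatticeRNG(seed)
    death_rng = np.random.default_rng([int(seed), 0xDEAD])
    recorder = TimeSeriesRecorder(preset.engine, preset.report_interval,
                                  count_fragments=True)

    def expansion_hook(f, r, mcs):
        expansion_step(r, preset.expansion, mcs)

    def death_hook(f, r, mcs):
        pcd_sweep(f, r, preset.death, death_rng, mcs, preset.engine)

    hooks = (expansion_hook, death_hook, recorder)

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    recorder(field, registry, 0)  # baseline record at MCS 0
    if snapshot_every and outdir is not None:
        export_field(field, registry, outdir / "snapshot_000000.png")

    try:
        for mcs in range(1, preset.engine.total_mcs + 1):
            accepted, _ = run_mcs(field, registry, preset.contact_energies,
                                  preset.engine, rng, hooks)
            if progress and mcs % 1000 == 0:
                h = total_energy(field, registry, preset.contact_energies,
                                 preset.engine, check=False)
                log.info("mcs=%d H=%.1f cells=%d acceptance=%.3f",
                         mcs, h.total, registry.n_cells,
                         accepted / field.n_sites)
            if snapshot_every and outdir is not None \
                    and mcs % snapshot_every == 0:
                export_field(field, registry,
                             outdir / f"snapshot_{mcs:06d}.png")
    except Exception as exc:
        if outdir is not None:
            export_field(field, registry, outdir / "postmortem.png",
                         outdir / "postmortem_registry.csv")
        raise RuntimeError(
            f"run aborted at MCS {field.mcs_counter}: {exc}") from exc

    timeseries = recorder.to_frame()
    final_score = recorder.records[-1]
    manifest = {
        "preset": preset_to_dict(preset),
        "seed": int(seed),
        "eyecpm_version": _pkg_version,
    }
    log.info("run %s seed=%d done: %d cells, %d 2-deg, %d 3-deg "
             "(central: %d / %d)", preset.name, seed, final_score.n_cells,
             final_score.n_secondary, final_score.n_tertiary,
             final_score.n_secondary_central, final_score.n_tertiary_central)

    paths = {}
    if outdir is not None:
        import yaml

        ts_path = outdir / "timeseries.csv"
        timeseries.to_csv(ts_path, index=False)
        reg_path = outdir / "final_registry.csv"
        final_label = outdir / "final_field.png"
        export_field(field, registry, final_label, reg_path)
        man_path = outdir / "manifest.yaml"
        man_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
        paths = {"timeseries": str(ts_path), "registry": str(reg_path),
                 "field": str(final_label), "manifest": str(man_path)}

    return RunOutputs(
        preset=preset, seed=int(seed), timeseries=timeseries,
        final_registry=registry.to_frame(), final_score=final_score,
        manifest=manifest, field=field, registry=registry, paths=paths)


#: sweepable parameter names -> how they modify a preset
def _apply_sweep_param(preset: ExperimentPreset, name: str, value):
    if name == "T":
        return replace(preset,
                       engine=replace(preset.engine, temperature=float(value)))
    if name == "L":
        return replace(preset, death=replace(
            preset.death, threshold_length=float(value)))
    if name == "adhesion_mode":
        return apply_variant(preset, replace(preset.variant,
                                             adhesion_mode=value))
    if name == "oc_expansion":
        return apply_variant(preset, replace(preset.variant,
                                             oc_expansion=value))
    if name == "ipc_growth":
        return apply_variant(preset, replace(preset.variant,
                                             ipc_growth=bool(value)))
    if name == "death_enabled":
        return replace(preset, death=replace(preset.death,
                                             enabled=bool(value)))
    if name == "variant":
        return apply_variant(preset, VARIANTS[value])
    raise KeyError(f"unknown sweep parameter {name!r}")


def run_sweep(base_preset: ExperimentPreset, grid: dict, seeds,
              keep_timeseries: bool = True):
    """One run per grid point per seed.

    ``grid`` maps parameter names (T, L, adhesion_mode, oc_expansion,
    ipc_growth, death_enabled, variant) to value lists.  Returns
    (final_df, timeseries_df): per-run end-state metrics and, optionally,
    the concatenated per-interval records.  Failures are recorded and the
    sweep continues.
    """
    import itertools

    import pandas as pd

    names = list(grid)
    final_rows = []
    ts_frames = []
    for values in itertools.product(*(grid[n] for n in names)):
        preset = base_preset
        for n, v in zip(names, values):
            preset = _apply_sweep_param(preset, n, v)
        point = dict(zip(names, values))
        for seed in seeds:
            row = dict(point, seed=int(seed))
            try:
                out = run_experiment(preset, seed)
            except Exception as exc:  # pragma: no cover - defensive
                log.error("sweep point %s seed %s failed: %s",
                          point, seed, exc)
                row["error"] = str(exc)
                final_rows.append(row)
                continue
            s = out.final_score
            row.update(
                n_cells=s.n_cells, n_secondary=s.n_secondary,
                n_tertiary=s.n_tertiary,
                n_secondary_central=s.n_secondary_central,
                n_tertiary_central=s.n_tertiary_central,
                mean_area_OC=s.mean_area["OC"],
                mean_area_IPC=s.mean_area["IPC"], error="")
            final_rows.append(row)
            if keep_timeseries:
                ts = out.timeseries.copy()
                for n, v in point.items():
                    ts[n] = v
                ts["seed"] = int(seed)
                ts_frames.append(ts)
    final_df = pd.DataFrame(final_rows)
    ts_df = (pd.concat(ts_frames, ignore_index=True)
             if ts_frames else pd.DataFrame())
    return final_df, ts_df


# -- configuration round-trip -------------------------------------------------


def preset_to_dict(preset: ExperimentPreset) -> dict:
    t = preset.contact_energies
    return {
        "name": preset.name,
        "engine": dataclasses.asdict(preset.engine),
        "contact_energies": {
            "oc_oc": t.j(OC, OC), "oc_ipc": t.j(OC, IPC),
            "ipc_ipc": t.j(IPC, IPC), "oc_medium": t.j(OC, 0),
            "ipc_medium": t.j(IPC, 0), "medium_medium": t.j(0, 0),
        },
        "death": dataclasses.asdict(preset.death),
        "expansion": {
            str(code): dataclasses.asdict(entry)
            for code, entry in preset.expansion.by_type.items()
        },
        "variant": dataclasses.asdict(preset.variant),
        "field": dataclasses.asdict(preset.field),
        "tracing_path": preset.tracing_path,
        "tracing_type_map": preset.tracing_type_map,
        "shape": dataclasses.asdict(preset.shape),
        "report_interval": preset.report_interval,
        "seeds": list(preset.seeds),
    }


def preset_from_dict(data: dict) -> ExperimentPreset:
    return ExperimentPreset(
        name=data["name"],
        engine=EngineParameters(**data["engine"]),
        contact_energies=ContactEnergyTable(**data["contact_energies"]),
        death=DeathRule(**data["death"]),
        expansion=ExpansionSchedule(by_type={
            int(code): TypeExpansion(**entry)
            for code, entry in data["expansion"].items()
        }),
        variant=VariantSpec(**data["variant"]),
        field=SyntheticFieldSpec(**data["field"]),
        tracing_path=data.get("tracing_path"),
        tracing_type_map=data.get("tracing_type_map"),
        shape=ShapeConstraints(**data["shape"]),
        report_interval=data.get("report_interval", 500),
        seeds=tuple(data.get("seeds", (1, 2, 3, 4, 5))),
    )


def save_preset(preset: ExperimentPreset, path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(preset_to_dict(preset),
                                         sort_keys=False))


def load_preset(path) -> ExperimentPreset:
    import yaml

    return preset_from_dict(yaml.safe_load(Path(path).read_text()))
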