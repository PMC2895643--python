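"""The two bespoke retinal mechanisms layered on the Potts engine, plus the
perturbation variants.

1.  Contact-gated programmed cell death (PCD): after an onset delay, each
    living interommatidial precursor cell (IPC) is evaluated once per MCS
    and dies with a probability that decreases with its contact length to
    ommatidial cores (OCs) and is zero at or above a survival threshold L.
    Death is modelled by dropping the cell's target area (and perimeter) to
    zero, so the area constraint shrinks it away.  IPCs on the tissue
    margin (touching Medium at initialisation) are exempt, mirroring the
    non-dying periphery of the pupal eye.

2.  Apical surface expansion: OC target areas and perimeters grow linearly
    in MCS until they reach a multiple (default 2x) of their initial
    values, emulating the apical nuclear migration that roughly doubles
    core profiles in vivo and "crowds" the surrounding IPCs into the
    hexagonal niche.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np

from .engine import (
    IPC, MEDIUM, OC, CellField, CellRegistry, EngineParameters,
    medium_contact_per_cell, oc_contact_per_cell,
)

__all__ = [
    "DeathRule", "death_probability", "pcd_sweep", "mark_border_exempt",
    "TypeExpansion", "ExpansionSchedule", "expansion_step",
    "VariantSpec", "VARIANTS", "apply_variant", "split_cell_in_half",
]


# -- programmed cell death ----------------------------------------------------


@dataclass(frozen=True)
class DeathRule:
    """Contact-length-gated death probability, applied once per MCS.

    P(death | CS_OC) = p_max * (1 - CS_OC / L)**lambda_death  for CS_OC < L
                     = 0                                       otherwise

    where CS_OC is the cell's aggregate contact length (boundary links)
    with OC neighbours.  The probability is p_max at zero contact, falls
    monotonically, and vanishes at and above the survival threshold L.
    """

    threshold_length: float = 16.0
    lambda_death: float = 1.2
    p_max: float = 0.01
    onset_mcs: int = 10_000
    enabled: bool = True

    def __post_init__(self):
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must be a probability")
        if self.threshold_length < 0:
            raise ValueError("threshold_length must be >= 0")
        if self.lambda_death < 0:
            raise ValueError("lambda_death must be >= 0")


def death_probability(cs_oc: float, rule: DeathRule) -> float:
    """Per-MCS death probability for an IPC with OC contact ``cs_oc``."""
    if cs_oc < 0:
        raise ValueError("contact length must be >= 0")
    L = rule.threshold_length
    if cs_oc >= L:
        return 0.0
    return rule.p_max * (1.0 - cs_oc / L) ** rule.lambda_death


def pcd_sweep(field: CellField, registry: CellRegistry, rule: DeathRule,
              rng: np.random.Generator, mcs: int,
              params: EngineParameters) -> list[int]:
    """Evaluate every living, non-exempt, not-yet-dying IPC for death.

    No-op before ``rule.onset_mcs`` or when the rule is disabled.  Each
    candidate draws one Bernoulli with probability
    ``death_probability(CS_OC)``; successes get A_T = P_T = 0 and are
    flagged dying (excluded from expansion and from future draws).
    Returns the identifiers flagged in this sweep.
    """
    if not rule.enabled or mcs < rule.onset_mcs:
        return []
    cs = oc_contact_per_cell(field, registry, params)
    candidates = np.flatnonzero(
        registry.alive & (registry.cell_type == IPC)
        & ~registry.dying & ~registry.death_exempt)
    newly_dying: list[int] = []
    for cell_id in candidates:
        p = death_probability(float(cs[cell_id]), rule)
        if p > 0.0 and rng.random() < p:
            registry.set_dying(int(cell_id))
            newly_dying.append(int(cell_id))
    return newly_dying


def mark_border_exempt(field: CellField, registry: CellRegistry,
                       params: EngineParameters) -> list[int]:
    """Permanently exempt from death every IPC that touches Medium by at
    least one boundary link in the current (initial) configuration."""
    medium_contact = medium_contact_per_cell(field, registry, params)
    border = np.flatnonzero(
        registry.alive & (registry.cell_type == IPC) & (medium_contact > 0))
    registry.death_exempt[border] = True
    return [int(i) for i in border]


# -- apical surface expansion -------------------------------------------------


@dataclass(frozen=True)
class TypeExpansion:
    """Linear target-growth schedule for one cell type.

    Every ``delta_mcs`` steps the target area and target perimeter of each
    enabled, non-dying cell are raised along a linear ramp that reaches
    ``max_multiplier`` x the cell's initial targets at ``duration_mcs``,
    then stops.  By default increments are proportional to each cell's own
    initial targets (so every cell completes at exactly the multiplier);
    absolute per-tick increments can be given instead, in which case they
    are clamped at ``max_multiplier`` x initial.
    """

    delta_mcs: int = 100
    duration_mcs: int = 20_000
    start_mcs: int = 10_000
    max_multiplier: float = 2.0
    perimeter_multiplier: float | None = None
    delta_target_area: float | None = None
    delta_target_perimeter: float | None = None

    def __post_init__(self):
        if self.delta_mcs <= 0 or self.duration_mcs <= 0:
            raise ValueError("delta_mcs and duration_mcs must be > 0")
        if self.start_mcs < 0:
            raise ValueError("start_mcs must be >= 0")
        if self.max_multiplier < 1.0:
            raise ValueError("max_multiplier must be >= 1")
        if self.perimeter_multiplier is not None \
                and self.perimeter_multiplier < 1.0:
            raise ValueError("perimeter_multiplier must be >= 1")

    @property
    def p_multiplier(self) -> float:
        """Target-perimeter multiplier at schedule completion.

        Defaults to sqrt(max_multiplier): the perimeter of a disc whose
        area has grown by ``max_multiplier`` while staying round.  Keeping
        the perimeter target on the round-growth curve (rather than
        doubling it outright) is what keeps expanding cores circular on
        the lattice; any surplus perimeter target would reward boundary
        convolution instead.
        """
        if self.perimeter_multiplier is not None:
            return self.perimeter_multiplier
        return float(np.sqrt(self.max_multiplier))


@dataclass(frozen=True)
class ExpansionSchedule:
    """Per-type expansion entries; types without an entry never grow."""

    by_type: dict = dc_field(default_factory=dict)

    @classmethod
    def wild_type(cls) -> "ExpansionSchedule":
        """OC targets double linearly between MCS 10,000 and 30,000.

        The ramp starts when the initial configuration has equilibrated
        (the same delay as the death onset) so the crowding acts while the
        contact-gated death rule can prune every cell it displaces; a
        faster ramp out-runs the death rule and crushes weak cells
        mechanically instead.
        """
        return cls(by_type={OC: TypeExpansion()})

    @classmethod
    def none(cls) -> "ExpansionSchedule":
        return cls(by_type={})

    def with_ipc_growth(self, total_mcs: int = 50_000) -> "ExpansionSchedule":
        """Add slow IPC doubling spread over the whole run."""
        by_type = dict(self.by_type)
        by_type[IPC] = TypeExpansion(start_mcs=0, duration_mcs=int(total_mcs))
        return ExpansionSchedule(by_type=by_type)


def _ramp_fraction(entry: TypeExpansion, mcs: int) -> float:
    """Completed fraction of the linear ramp at the last tick <= mcs."""
    ticked = (mcs // entry.delta_mcs) * entry.delta_mcs
    elapsed = min(max(ticked - entry.start_mcs, 0), entry.duration_mcs)
    return elapsed / entry.duration_mcs


def expansion_step(registry: CellRegistry, schedule: ExpansionSchedule,
                   mcs: int) -> None:
    """Per-MCS hook: move targets of enabled cells along their ramp.

    Targets are set from the closed-form ramp (initial * (1 + (m-1)*f))
    rather than accumulated, so completion lands exactly on
    ``max_multiplier`` x initial and dying cells (targets pinned at 0) are
    never touched.
    """
    for code, entry in schedule.by_type.items():
        if mcs % entry.delta_mcs != 0:
            continue
        sel = (registry.alive & (registry.cell_type == code)
               & registry.expansion_enabled & ~registry.dying)
        if not sel.any():
            continue
        if entry.delta_target_area is None:
            f = _ramp_fraction(entry, mcs)
            scale = 1.0 + (entry.max_multiplier - 1.0) * f
            p_scale = 1.0 + (entry.p_multiplier - 1.0) * f
            registry.target_area[sel] = registry.initial_target_area[sel] * scale
            registry.target_perimeter[sel] = (
                registry.initial_target_perimeter[sel] * p_scale)
        else:
            ticked = (mcs // entry.delta_mcs) * entry.delta_mcs
            elapsed = min(max(ticked - entry.start_mcs, 0),
                          entry.duration_mcs)
            ticks = elapsed // entry.delta_mcs
            registry.target_area[sel] = np.minimum(
                registry.initial_target_area[sel]
                + ticks * entry.delta_target_area,
                entry.max_multiplier * registry.initial_target_area[sel])
            dp = (entry.delta_target_perimeter
                  if entry.delta_target_perimeter is not None else 0.0)
            registry.target_perimeter[sel] = np.minimum(
                registry.initial_target_perimeter[sel] + ticks * dp,
                entry.max_multiplier * registry.initial_target_perimeter[sel])


# -- perturbation variants ----------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """A named deviation from the wild-type configuration.

    adhesion_mode
        'preferential' (J_OC,IPC < J_IPC,IPC, the wild-type hierarchy),
        'flat' (J_OC,IPC = J_IPC,IPC) or 'anti_preferential'
        (J_IPC,IPC < J_OC,IPC; the two wild-type values are swapped).
    death_L
        Override of the survival threshold L (None keeps the preset's).
    death_enabled
        Disable PCD entirely when False.
    oc_expansion
        'all' (wild type), 'none', 'all_but_one' (the most central OC is
        frozen) or 'half_of_one' (that OC is split into two compartments,
        one frozen).
    ipc_growth
        IPC targets slowly double over the whole run.
    """

    adhesion_mode: str = "preferential"
    death_L: float | None = None
    death_enabled: bool = True
    oc_expansion: str = "all"
    ipc_growth: bool = False

    def __post_init__(self):
        if self.adhesion_mode not in ("preferential", "flat",
                                      "anti_preferential"):
            raise ValueError(f"unknown adhesion_mode {self.adhesion_mode!r}")
        if self.oc_expansion not in ("all", "none", "all_but_one",
                                     "half_of_one"):
            raise ValueError(f"unknown oc_expansion {self.oc_expansion!r}")
        if self.death_L is not None and not self.death_enabled:
            raise ValueError(
                "conflicting overrides: death_L set while death is disabled")
        if self.death_L is not None and self.death_L <= 0:
            raise ValueError("death_L must be > 0")


#: the named in-silico experiments
VARIANTS: dict[str, VariantSpec] = {
    "wild_type": VariantSpec(),
    "reduced_death_L12": VariantSpec(death_L=12),
    "reduced_death_L10": VariantSpec(death_L=10),
    "adhesion_flat": VariantSpec(adhesion_mode="flat"),
    "adhesion_anti": VariantSpec(adhesion_mode="anti_preferential"),
    "no_expansion": VariantSpec(oc_expansion="none"),
    "no_expansion_no_death": VariantSpec(oc_expansion="none",
                                         death_enabled=False),
    "growing_ipcs": VariantSpec(ipc_growth=True),
    "blocked_single_oc": VariantSpec(oc_expansion="all_but_one"),
    "blocked_half_oc": VariantSpec(oc_expansion="half_of_one"),
}


def apply_variant(base_config, variant: VariantSpec):
    """Return a copy of an experiment preset with only the variant's
    parameters changed.  ``base_config`` is an
    :class:`eyecpm.runner.ExperimentPreset`-like dataclass exposing
    ``contact_energies``, ``death``, ``expansion`` and ``engine``."""
    table = base_config.contact_energies
    j_oc_ipc = table.j(OC, IPC)
    j_ipc_ipc = table.j(IPC, IPC)
    if variant.adhesion_mode == "flat":
        table = table.replace(oc_ipc=j_ipc_ipc)
    elif variant.adhesion_mode == "anti_preferential":
        table = table.replace(oc_ipc=max(j_oc_ipc, j_ipc_ipc),
                              ipc_ipc=min(j_oc_ipc, j_ipc_ipc))

    death = base_config.death
    if not variant.death_enabled:
        death = dataclasses.replace(death, enabled=False)
    elif variant.death_L is not None:
        death = dataclasses.replace(death,
                                    threshold_length=float(variant.death_L))

    expansion = base_config.expansion
    if variant.oc_expansion == "none":
        by_type = {c: e for c, e in expansion.by_type.items() if c != OC}
        expansion = ExpansionSchedule(by_type=by_type)
    if variant.ipc_growth:
        expansion = expansion.with_ipc_growth(base_config.engine.total_mcs)

    return dataclasses.replace(
        base_config, contact_energies=table, death=death,
        expansion=expansion, variant=variant)


def split_cell_in_half(field: CellField, registry: CellRegistry,
                       cell_id: int, params: EngineParameters,
                       expansion_enabled=(True, False)) -> int:
    """Split one cell into two same-type compartments along its short axis.

    The two compartments share a zero boundary energy (``partner`` link),
    so they adhere as one body; targets and lambdas are divided so the
    combined constraint matches the original.  Scoring merges partners
    back into one cell.  Returns the new compartment's identifier.
    Used for the half-frozen-OC experiment.
    """
    from .engine import measure_field

    cell_id = int(cell_id)
    if not registry.alive[cell_id]:
        raise LookupError(f"no living cell with id {cell_id}")
    rows, cols = np.nonzero(field.owner == cell_id)
    if rows.size < 2:
        raise ValueError("cell too small to split")
    # split across the axis of larger extent, at the median coordinate
    coord = cols if np.ptp(cols) >= np.ptp(rows) else rows
    half = coord > np.median(coord)
    if not half.any() or half.all():
        half = coord >= np.median(coord)  # ties: keep both sides non-empty
    old_ta = float(registry.target_area[cell_id])
    old_tp = float(registry.target_perimeter[cell_id])
    frac = half.sum() / rows.size
    new_id = registry.add_cell(
        int(registry.cell_type[cell_id]),
        target_area=old_ta * frac,
        target_perimeter=old_tp / 2.0,
        lambda_area=float(registry.lambda_area[cell_id]),
        lambda_perimeter=float(registry.lambda_perimeter[cell_id]),
        expansion_enabled=bool(expansion_enabled[1]),
        partner=cell_id)
    field.owner[rows[half], cols[half]] = new_id
    registry.partner[cell_id] = new_id
    registry.expansion_enabled[cell_id] = bool(expansion_enabled[0])
    registry.target_area[cell_id] = old_ta * (1.0 - frac)
    registry.target_perimeter[cell_id] = old_tp / 2.0
    registry.initial_target_area[cell_id] = old_ta * (1.0 - frac)
    registry.initial_target_area[new_id] = old_ta * frac
    registry.initial_target_perimeter[cell_id] = old_tp / 2.0
    registry.initial_target_perimeter[new_id] = old_tp / 2.0
    areas, perims = measure_field(field, params.neighbor_order,
                                  n_ids=registry.n_ids)
    registry.area[:] = areas[:registry.n_ids]
    registry.perimeter[:] = perims[:registry.n_ids]
    return new_id
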