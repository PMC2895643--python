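"""Contact-gated programmed cell death, apical expansion schedules and the
perturbation variants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eyecpm import (
    EngineParameters,
    VARIANTS,
    DeathRule,
    ExpansionSchedule,
    TypeExpansion,
    VariantSpec,
    apply_variant,
    death_probability,
    expansion_step,
    mark_border_exempt,
    pcd_sweep,
)
from eyecpm.engine import IPC, OC
from eyecpm.eye_model import split_cell_in_half
from eyecpm import runner as runner_mod

from conftest import make_field


# -- death probability --------------------------------------------------------


def test_death_probability_is_pmax_at_zero_contact():
    assert death_probability(0, DeathRule()) == pytest.approx(0.01)


@pytest.mark.parametrize("L", [10, 12, 16])
def test_death_probability_vanishes_at_and_above_threshold(L):
    rule = DeathRule(threshold_length=L)
    for cs in (L, L + 1, 2 * L, 10 * L):
        assert death_probability(cs, rule) == 0.0


def test_death_probability_default_form_midpoint():
    """P(8 | L=16, lambda=1.2, p_max=0.01) = 0.01 * 0.5**1.2."""
    rule = DeathRule(threshold_length=16, lambda_death=1.2, p_max=0.01)
    assert death_probability(8, rule) == pytest.approx(0.01 * 0.5 ** 1.2,
                                                       rel=1e-6)
    assert death_probability(8, rule) == pytest.approx(0.004353, abs=5e-6)


@settings(max_examples=200, derandomize=True)
@given(cs1=st.floats(0, 40), cs2=st.floats(0, 40),
       L=st.sampled_from([10.0, 12.0, 16.0]),
       lam=st.floats(0.5, 3.0))
def test_death_probability_monotone_non_increasing(cs1, cs2, L, lam):
    rule = DeathRule(threshold_length=L, lambda_death=lam)
    lo, hi = sorted((cs1, cs2))
    assert death_probability(lo, rule) >= death_probability(hi, rule)
    assert 0.0 <= death_probability(lo, rule) <= rule.p_max


def test_death_probability_rejects_negative_contact():
    with pytest.raises(ValueError):
        death_probability(-1, DeathRule())


# -- death sweep --------------------------------------------------------------


def _many_isolated_ipcs(n=1000):
    """Grid of 1-site IPCs, each surrounded by Medium (CS_OC = 0)."""
    side = int(np.ceil(np.sqrt(n))) * 2 + 2
    labels = np.zeros((side, side), dtype=np.int32)
    cid = 1
    for r in range(1, side - 1, 2):
        for c in range(1, side - 1, 2):
            if cid > n:
                break
            labels[r, c] = cid
            cid += 1
    types = ["Medium"] + ["IPC"] * (cid - 1)
    return make_field(labels, types)


def test_sweep_is_noop_before_onset():
    field, registry = _many_isolated_ipcs(100)
    rule = DeathRule(onset_mcs=10_000)
    rng = np.random.default_rng(0)
    out = pcd_sweep(field, registry, rule, rng, mcs=9_999,
                    params=EngineParameters())
    assert out == []
    assert not registry.dying.any()


def test_sweep_is_noop_when_disabled():
    field, registry = _many_isolated_ipcs(100)
    rule = DeathRule(enabled=False)
    out = pcd_sweep(field, registry, rule, np.random.default_rng(0),
                    mcs=20_000, params=EngineParameters())
    assert out == []


def test_cells_above_threshold_never_die():
    labels = np.zeros((12, 12), dtype=np.int32)
    labels[2:8, 2:8] = 1          # OC
    labels[2:8, 8:10] = 2         # IPC with long OC contact
    field, registry = make_field(labels, ["Medium", "OC", "IPC"])
    rule = DeathRule(threshold_length=16, onset_mcs=0)
    rng = np.random.default_rng(0)
    for mcs in range(1, 2_000):
        assert pcd_sweep(field, registry, rule, rng, mcs,
                         EngineParameters()) == []


def test_sweep_death_rate_matches_binomial_expectation():
    """1,000 zero-contact IPCs at p_max = 0.01: about 10 deaths per sweep
    (within 3 sigma over 20 repeated sweeps of fresh registries)."""
    rng = np.random.default_rng(99)
    n_sweeps, n_cells, p = 20, 1000, 0.01
    total = 0
    field, registry = _many_isolated_ipcs(n_cells)
    rule = DeathRule(onset_mcs=0)
    for _ in range(n_sweeps):
        reg = registry.copy()
        total += len(pcd_sweep(field, reg, rule, rng, mcs=1,
                               params=EngineParameters()))
    mean = total / n_sweeps
    sigma = np.sqrt(n_cells * p * (1 - p) / n_sweeps)
    assert abs(mean - n_cells * p) < 3 * sigma


def test_flagged_cells_have_zeroed_targets_and_skip_future_draws():
    field, registry = _many_isolated_ipcs(200)
    rule = DeathRule(onset_mcs=0, p_max=1.0)  # certain death
    rng = np.random.default_rng(1)
    first = pcd_sweep(field, registry, rule, rng, 1, EngineParameters())
    assert len(first) == 200
    assert (registry.target_area[1:] == 0).all()
    assert (registry.target_perimeter[1:] == 0).all()
    assert registry.dying[1:].all()
    second = pcd_sweep(field, registry, rule, rng, 2, EngineParameters())
    assert second == []


def test_exempt_cells_are_never_evaluated():
    field, registry = _many_isolated_ipcs(50)
    registry.death_exempt[:] = True
    rule = DeathRule(onset_mcs=0, p_max=1.0)
    out = pcd_sweep(field, registry, rule, np.random.default_rng(0), 1,
                    EngineParameters())
    assert out == []


# -- border exemption ---------------------------------------------------------


def test_border_exemption_marks_only_medium_touching_ipcs():
    labels = np.zeros((14, 14), dtype=np.int32)
    labels[1:13, 1:13] = 3        # big IPC frame touching Medium
    labels[3:11, 3:11] = 1        # OC
    labels[5:9, 5:9] = 2          # interior IPC fully inside the OC
    field, registry = make_field(labels, ["Medium", "OC", "IPC", "IPC"])
    exempt = mark_border_exempt(field, registry, EngineParameters())
    assert exempt == [3]
    assert registry.death_exempt[3]
    assert not registry.death_exempt[2]
    assert not registry.death_exempt[1]  # OCs are never marked


def test_fully_tiled_field_has_no_exemptions():
    labels = np.ones((8, 8), dtype=np.int32)
    labels[:, 4:] = 2
    field, registry = make_field(labels, ["Medium", "IPC", "IPC"])
    assert mark_border_exempt(field, registry, EngineParameters()) == []


# -- expansion ----------------------------------------------------------------


def _expansion_registry():
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[2:8, 2:8] = 1
    labels[10:18, 10:16] = 2
    field, registry = make_field(labels, ["Medium", "OC", "OC"])
    registry.expansion_enabled[1:] = True
    return registry


def test_targets_unchanged_at_mcs_zero():
    registry = _expansion_registry()
    before = registry.target_area.copy()
    expansion_step(registry, ExpansionSchedule.wild_type(), 0)
    np.testing.assert_array_equal(registry.target_area, before)


def test_completion_doubles_every_enabled_target_exactly():
    registry = _expansion_registry()
    schedule = ExpansionSchedule.wild_type()
    entry = schedule.by_type[OC]
    init = registry.initial_target_area.copy()
    end = entry.start_mcs + entry.duration_mcs
    for mcs in range(1, end + 1):
        expansion_step(registry, schedule, mcs)
    assert registry.target_area[1] == 2.0 * init[1]
    assert registry.target_area[2] == 2.0 * init[2]
    # further steps never overshoot the cap
    expansion_step(registry, schedule, end + entry.delta_mcs)
    assert registry.target_area[1] == 2.0 * init[1]


def test_no_growth_before_ramp_start():
    registry = _expansion_registry()
    schedule = ExpansionSchedule.wild_type()
    start = schedule.by_type[OC].start_mcs
    before = registry.target_area.copy()
    for mcs in (100, start // 2, start):
        expansion_step(registry, schedule, mcs)
    np.testing.assert_array_equal(registry.target_area, before)


def test_halfway_point_is_linear_interpolation():
    registry = _expansion_registry()
    schedule = ExpansionSchedule.wild_type()
    entry = schedule.by_type[OC]
    init = registry.initial_target_area.copy()
    expansion_step(registry, schedule,
                   entry.start_mcs + entry.duration_mcs // 2)
    assert registry.target_area[1] == pytest.approx(1.5 * init[1])


def test_disabled_and_dying_cells_are_skipped():
    registry = _expansion_registry()
    registry.expansion_enabled[2] = False
    registry.set_dying(1)
    expansion_step(registry, ExpansionSchedule.wild_type(), 20_000)
    assert registry.target_area[1] == 0.0      # dying: pinned at zero
    assert registry.target_area[2] == registry.initial_target_area[2]


def test_off_tick_mcs_leaves_targets_untouched():
    registry = _expansion_registry()
    before = registry.target_area.copy()
    expansion_step(registry, ExpansionSchedule.wild_type(), 150)  # tick = 100
    np.testing.assert_array_equal(registry.target_area, before)


def test_absolute_delta_mode_clamps_at_multiplier():
    registry = _expansion_registry()
    schedule = ExpansionSchedule(by_type={
        OC: TypeExpansion(delta_mcs=100, duration_mcs=10_000,
                          max_multiplier=2.0, delta_target_area=5.0,
                          delta_target_perimeter=1.0)})
    init = registry.initial_target_area.copy()
    for mcs in range(100, 20_001, 100):
        expansion_step(registry, schedule, mcs)
    np.testing.assert_allclose(registry.target_area[1:], 2.0 * init[1:])


# -- variants -----------------------------------------------------------------


def test_flat_adhesion_equalises_the_two_ipc_contact_energies():
    base = runner_mod.wild_type_preset()
    flat = apply_variant(base, VARIANTS["adhesion_flat"])
    t = flat.contact_energies
    assert t.j(OC, IPC) == t.j(IPC, IPC)


def test_anti_preferential_swaps_the_hierarchy():
    base = runner_mod.wild_type_preset()
    anti = apply_variant(base, VARIANTS["adhesion_anti"])
    t = anti.contact_energies
    assert t.j(IPC, IPC) < t.j(OC, IPC)
    assert t.j(OC, IPC) == base.contact_energies.j(IPC, IPC)


def test_wild_type_variant_changes_nothing():
    base = runner_mod.wild_type_preset()
    same = apply_variant(base, VARIANTS["wild_type"])
    assert same.contact_energies == base.contact_energies
    assert same.death == base.death
    assert same.expansion == base.expansion


def test_reduced_death_variants_override_threshold_only():
    base = runner_mod.wild_type_preset()
    v12 = apply_variant(base, VARIANTS["reduced_death_L12"])
    assert v12.death.threshold_length == 12
    assert v12.death.onset_mcs == base.death.onset_mcs
    assert v12.contact_energies == base.contact_energies


def test_no_expansion_no_death_disables_both():
    base = runner_mod.wild_type_preset()
    v = apply_variant(base, VARIANTS["no_expansion_no_death"])
    assert OC not in v.expansion.by_type
    assert not v.death.enabled


def test_growing_ipcs_adds_slow_ipc_doubling():
    base = runner_mod.wild_type_preset()
    v = apply_variant(base, VARIANTS["growing_ipcs"])
    entry = v.expansion.by_type[IPC]
    assert entry.max_multiplier == 2.0
    assert entry.duration_mcs == base.engine.total_mcs


def test_conflicting_overrides_rejected():
    with pytest.raises(ValueError, match="conflicting"):
        VariantSpec(death_L=12, death_enabled=False)


def test_half_split_preserves_area_and_freezes_one_compartment():
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[4:16, 4:16] = 1
    field, registry = make_field(labels, ["Medium", "OC"])
    registry.expansion_enabled[1] = True
    params = EngineParameters()
    area0 = int(registry.area[1])
    new_id = split_cell_in_half(field, registry, 1, params)
    assert registry.area[1] + registry.area[new_id] == area0
    assert registry.partner[1] == new_id
    assert registry.partner[new_id] == 1
    assert registry.cell_type[new_id] == OC
    assert registry.expansion_enabled[1]
    assert not registry.expansion_enabled[new_id]
    # compartment boundary carries no energy
    from eyecpm import ContactEnergyTable, total_energy

    table = ContactEnergyTable.wild_type()
    whole_field, whole_reg = make_field(labels, ["Medium", "OC"])
    e_split = total_energy(field, registry, table, params)
    e_whole = total_energy(whole_field, whole_reg, table, params)
    assert e_split.boundary_term == pytest.approx(e_whole.boundary_term)
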