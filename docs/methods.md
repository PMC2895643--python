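# Methods

## Model

The tissue is a periodic 2D square lattice whose sites carry cell
identifiers; identifier 0 is Medium, the unconstrained exterior. Each
cell has a type τ ∈ {OC, IPC, Medium} and evolves by Metropolis-accepted
boundary copy attempts against

H = Σ_links J(τ,τ′) + Σ_cells λ_A (A − A_T)² + Σ_cells λ_P (P − P_T)².

One Monte Carlo Step (MCS) is one copy attempt per lattice site: a target
site is drawn uniformly (with replacement), one of its four order-1
neighbours supplies the source identifier, and the copy is accepted with
probability min(1, exp(−ΔH/T)). ΔH is computed incrementally (no lattice
rescan); areas and perimeters are maintained incrementally and checked
against full recomputation in the test suite. The copy-attempt stream is
a splitmix64 generator owned by the run, so identical seeds give
bit-identical trajectories.

Discretisation conventions:

* Boundary energy, perimeters and contact lengths are counted over the
  **order-2 neighbourhood** (8 neighbours), which reduces lattice
  anisotropy; copy attempts propose between order-1 neighbours only.
  A cell's perimeter is the number of order-2 links from its sites to
  sites it does not own (≈3× the Euclidean boundary length: a digital
  disc of radius 9 has ~170 links).
* A cell whose area reaches 0 is dead and never returns; the constant
  residual λ_A·A_T² of a cell that died with a nonzero target is retained
  in the energy so the running total stays exactly consistent with the
  incremental ΔH (programmed death zeroes targets first, so the residual
  is 0 in practice).
* No connectivity constraint is imposed; pinch-off fragments are counted
  per snapshot (in practice a handful of transient 1–2-site specks).

## Parameters

| parameter | value | meaning |
|---|---|---|
| T | 60 | motility (energy scale of accepted fluctuations) |
| J_OC,IPC / J_IPC,IPC | 35 / 55 | preferential adhesion of IPCs for cores |
| J_OC,OC / J_OC,Med / J_IPC,Med | 200 / 90 / 70 | core exclusion, tissue compactness |
| λ_A (OC / IPC) | 6 / 4 | inverse compressibility (area) |
| λ_P (OC / IPC) | 0.05 / 0.02 | inverse membrane compressibility |
| L | 16 links (12, 10 in reduced-death presets) | PCD survival threshold |
| λ_Death, P_MAX | 1.2, 0.01 | PCD shape and per-MCS ceiling |
| PCD onset | 10,000 MCS | initial configuration equilibrated first |
| OC expansion | 2× targets, linear, MCS 10,000→20,000, 100-MCS ticks | apical surface expansion |
| run length | 50,000 MCS (≈27.8 h at 2 s/MCS) | past pattern equilibrium |

The adhesion hierarchy J_OC,OC ≫ J_OC,Med ≫ J_IPC,Med > J_IPC,IPC ≥
J_OC,IPC and the values T, J_OC,IPC, J_IPC,IPC, L, λ_Death, P_MAX and the
10,000-MCS onset are fixed by the published working point; the remaining
magnitudes are this package's defaults, calibrated once so that the
wild-type preset reproduces the qualitative endpoint (round
non-touching cores, single-file IPC rows, vertex cells, ~30–50% IPC
loss). Two calibration observations matter for reuse:

* **Soft-but-stable IPCs.** λ_A(IPC) must be small enough that crowding
  can deform cells and strip poorly-placed ones off the core boundary
  (stiff IPCs lock the configuration and PCD never fires), yet large
  enough that a squeezed cell is not annihilated outright by adhesion
  (λ_A·A_T² must exceed J × perimeter, else small cells evaporate and
  the death *rule* becomes irrelevant). λ_A(IPC) = 4 with ~40–60-site
  IPCs sits between the two failure modes; the per-preset death counts
  in the test battery are dominated by rule deaths at this setting.
* **Round-growth perimeter targets.** During expansion the OC target
  perimeter follows the round-growth curve (×√2 when the area target
  doubles; `TypeExpansion.perimeter_multiplier=None`). A perimeter target
  doubled outright sits ~40% above the perimeter of the doubled round
  disc under this discretisation, so any nonzero λ_P then *rewards*
  boundary convolution and the cores ruffle and fragment instead of
  staying circular. Passing `perimeter_multiplier=2.0` restores the
  literal doubling for comparison.
* **Expansion/death overlap.** The expansion ramp starts at the PCD
  onset (10,000 MCS) and spans 10,000 MCS — the ~5.5 h over which core
  profiles double in vivo at 2 s/MCS — so every cell the crowding
  displaces is evaluated by the death rule while it is being displaced.
  A ramp that completes before the onset lets the growing cores
  mechanically crush weak neighbours with the rule still silent; a ramp
  that ends much later delays pattern completion past the point the
  wild type should reach it.

## Programmed cell death

P(death per MCS) = P_MAX (1 − CS_OC/L)^λ_Death for CS_OC < L, else 0,
where CS_OC is the cell's aggregate contact length (order-2 links) with
OC neighbours. Each living, non-exempt, not-yet-dying IPC is evaluated
once per MCS after onset; a success sets A_T = P_T = 0 and the area
constraint shrinks the cell away. IPCs touching Medium at initialisation
are permanently exempt, mirroring the non-dying eye margin; the exemption
set is computed once because the tissue boundary is static at this scale.

## Synthetic initial field

The generator emulates a traced eye at the stage when every IPC touches
at least two cores but the vertices are unresolved: disc-shaped OCs
(radius 9) on a hexagonally offset grid (spacing 24), interstitial space
partitioned by watershed growth from seeds placed along each core–core
channel (3 per channel), a one-cell-deep bounding ring grown from seeds
on the phantom outer edges, and one surplus "ectopic" seed per
tri-junction scattered uniformly at random through the band — so the
initial 2° rows are roughly in place, the initial 3° count is ~0, and the
later crowding/death phase has real sorting work to do. Interior cells
that end up touching fewer than two cores are merged into their largest
IPC neighbour; generation fails loudly if the invariant cannot be met.
Targets are initialised to the measured areas/perimeters. The geometry is
deterministic given the spec (the seed drives only the jitter and the
ectopic scatter).

What the generator does **not** emulate: real tracings' irregular cell
shapes and size spread, bristle groups, the slow gradient of
developmental age across a real eye, and photoreceptors/cone cells within
the cores (the two-type reduction treats each core as one cell). Passing
tests on synthetic fields therefore demonstrates the mechanisms'
sufficiency on idealised geometry, not quantitative agreement with any
particular micrograph. Real tracings enter through
`field_init.import_tracing` (indexed label image + type map).

## Scoring

2°/3° classification is contact-topological on each snapshot: 3° = IPC
contacting exactly three distinct OCs, 2° = IPC contacting exactly two
OCs and exactly two 3°s. Two conventions make the counts robust on a
lattice:

* "contacting" requires ≥ 2·order − 1 links (3 at order 2): two cells
  meeting at a single lattice corner share 2 diagonal links, and counting
  such point contacts flips classifications every few hundred MCS;
* compartment pairs (the half-frozen-core experiment) are merged before
  counting, so scoring is variant-independent.

"Central ommatidia" are the OCs none of whose initial IPC contacts is
border-exempt, frozen at initialisation; a 2°/3° belongs to the central
subfield if it contacts at least one central OC. The time series records
whole-field and central counts, per-type mean area/perimeter and a
fragment count every 500 MCS.

`scoring.plateau_mcs` reports when a count series settles. A Metropolis
count is a stationary noisy signal once the pattern has formed — it keeps
fluctuating by one or two cells forever — so the statistic reads the
curve the way a plotted time course is read: the run-end value is the
sustained level (median of the last ten records), and the plateau is the
first record equal to that level whose forward ten-record medians never
depart from it by more than one cell afterwards (a transient touch
during the rise is rejected, as is a later drift to a different level;
the tolerance and guard are explicit parameters). On the default
wild-type battery the central 3° count rises from 0 and settles between
14 and 18 (of ~18 interior vertex niches on the 4×4 field); the count is
stationary in the mean from roughly 22,000–25,000 MCS, but single-vertex
events (one marginal cell gained or lost) continue at a low rate for the
whole run, so the measured plateau onset ranges from ~20,000 to ~46,000
MCS across seeds.

## Perturbation presets

`wild_type`; `reduced_death_L12` / `reduced_death_L10` (weaker death);
`adhesion_flat` (J_OC,IPC = J_IPC,IPC) and `adhesion_anti` (values
swapped); `no_expansion`; `no_expansion_no_death`; `growing_ipcs` (IPC
targets also double, spread over the whole run); `blocked_single_oc`
(most central core frozen); `blocked_half_oc` (that core split into two
zero-mutual-energy compartments, one frozen — scored as one cell). Sweeps
over T, L, adhesion mode and the expansion flags are provided by
`runner.run_sweep`.

## Numerical and design notes

* Tie proposals (ΔH = 0) are accepted (min(1, e⁰) = 1); a proposal whose
  source and target share an owner is a no-op that still consumes an
  attempt.
* Expansion ticks every 100 MCS set targets from the closed-form linear
  ramp (clamped), so completion lands exactly on the multiplier
  regardless of floating-point accumulation; per-cell increments are
  proportional to each cell's own initial targets.
* Lattice sizes: 4×4 ommatidia ≈ 146×131 sites; a 50,000-MCS run is
  ~7×10⁸ copy attempts, ~35 s on one CPU with the compiled kernel. The
  test batteries use 3×3 fields and 20,000-MCS horizons where a full run
  is not required, with preset comparisons always at matched MCS.
* Known limitations: no connectivity constraint (rare transient
  fragments); dead cells retain registry rows (identifiers are stable,
  memory grows with deaths); the energy of the half-core split is exact
  only for the boundary term (each compartment carries half the
  perimeter target); `import_tracing` trusts the type map and does not
  validate biological plausibility of a tracing. Cell loss is not purely
  rule-driven: at T = 60 with these adhesion energies a sufficiently
  squeezed small cell evaporates mechanically (removing its boundary
  releases more energy than its area constraint costs), so even the
  no-expansion/no-death preset loses roughly a quarter of its cells; in
  the wild-type preset rule deaths and mechanical deaths contribute about
  equally.
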