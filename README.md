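# eyecpm

A Glazier–Graner–Hogeweg (Cellular Potts) simulation of interommatidial
cell patterning in the *Drosophila* pupal eye.

## The problem

The fly compound eye is a crystal-like array of ~750 ommatidia. Between
21 and 40 hours after puparium formation, the interommatidial precursor
cells (IPCs) lying between the ommatidial cores (OCs — the cone-cell /
primary-pigment-cell clusters) resolve into a precise hexagonal lattice:
one **secondary pigment cell (2°)** per hexagon edge and one **tertiary
pigment cell (3°)** per vertex. Roughly a third of the precursors die by
programmed cell death (PCD) along the way. This package simulates that
process with three interacting mechanisms on a 2D lattice:

* **differential adhesion** between two simulated cell types (OC, IPC)
  plus the surrounding Medium;
* **contact-gated PCD** — an IPC dies with a probability that falls with
  its contact length to the OCs and vanishes at a survival threshold *L*;
* **apical surface expansion** — OC target areas double linearly in time,
  crowding the IPCs into the hexagonal niches.

It is aimed at quantitative/developmental biologists who want to rerun
the in-silico perturbation experiments (reduced death, altered adhesion,
blocked expansion, growing IPCs, half-frozen cores) or initialise the
model from their own segmented tracings.

## The model

Cells are connected sets of lattice sites evolving by Metropolis-accepted
boundary copy attempts against the effective energy

```
H = Σ_links J(τ(σ), τ(σ′))           adhesion (boundary energy)
  + Σ_cells λ_A (A_σ − A_T,σ)²       area constraint
  + Σ_cells λ_P (P_σ − P_T,σ)²       perimeter constraint
```

A copy that lowers `H` is always accepted, otherwise it is accepted with
probability `exp(−ΔH/T)`; one attempt per lattice site is a Monte Carlo
Step (MCS ≈ 2 s of development). The wild-type working point is `T = 60`,
`J_OC,IPC = 35 < J_IPC,IPC = 55` (preferential adhesion), survival
threshold `L = 16` boundary links with death probability
`P = P_MAX (1 − CS_OC/L)^λ_Death` (`P_MAX = 0.01`, `λ_Death = 1.2`)
evaluated once per MCS from 10,000 MCS on, and linear OC target doubling.
2°/3° cells are scored purely topologically: a 3° is an IPC contacting
exactly three OCs, a 2° an IPC contacting exactly two OCs and two 3°s.

See `docs/methods.md` for the full parameter table, discretisation
choices and limitations.

## A worked example

```
$ python examples/run_wild_type.py
initial cells: 92, final cells: 73
secondary (edge) cells: 2, tertiary (vertex) cells: 9
mean apical area  OC: 503 sites, IPC: 39 sites
simulated developmental time: 19.4 h
```

A 3×3-ommatidium synthetic field starts with 92 cells and no resolved
vertices; expansion-driven crowding plus selective death prune it to 73
cells, with nine IPCs settled singly into 3° vertex niches and OC apical
areas doubled (503 sites vs ~250 initially). `examples/` contains similar
narrative scripts for the death rule, the perturbation presets and
label-image import/export; the `eyecpm` command-line tool exposes
`run`, `sweep`, `generate` and `score` for shell use.

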