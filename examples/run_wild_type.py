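"""Simulate wild-type pupal-eye patterning on a small synthetic field.

Builds a 3x3-ommatidium field (a desk-scale version of the default 4x4),
runs the full mechanism stack — adhesion sorting, core expansion,
contact-gated death — and prints how the emergent lattice scores.
"""

from eyecpm import build_preset, mcs_to_hours, run_experiment

preset = build_preset("wild_type", rows=3, cols=3, total_mcs=35_000)
out = run_experiment(preset, seed=1)

ts = out.timeseries
s = out.final_score
print(f"initial cells: {ts.n_cells.iloc[0]}, final cells: {s.n_cells}")
print(f"secondary (edge) cells: {s.n_secondary}, "
      f"tertiary (vertex) cells: {s.n_tertiary}")
print(f"mean apical area  OC: {s.mean_area['OC']:.0f} sites, "
      f"IPC: {s.mean_area['IPC']:.0f} sites")
print(f"simulated developmental time: "
      f"{mcs_to_hours(preset.engine.total_mcs):.1f} h")
print()
print("The cell count falls as the expanding cores crowd out and kill")
print("poorly-contacted interommatidial cells; tertiary cells are the")
print("IPCs that end up wedged between exactly three cores (the hexagon")
print("vertices), secondaries the single cells spanning each edge.")
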