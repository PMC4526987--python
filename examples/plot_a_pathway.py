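"""Render a patient pathway to a PNG.

Draws the PSA trend as markers joined in time order, other timed events as
labelled vertical lines (diagnosis solid, treatments dashed, death bold),
and captions at diagnosis and death.  The renderer also returns a manifest
of everything it drew.
"""

from pathforge import Cohort, SimulationConfig, plot_pathway, simulate_cohort

master, truth = simulate_cohort(SimulationConfig(n_patients=50, seed=3))
cohort = Cohort.from_master(master)

# pick an intact (S5) pathway so the plot shows the full rise-and-fall trend
pid = truth[truth.ScoreClass == "S5"].Identifier.iloc[0]
manifest = plot_pathway(cohort[pid], out_path="pathway.png")

kinds = {}
for element in manifest:
    kinds[element["kind"]] = kinds.get(element["kind"], 0) + 1
print(f"wrote pathway.png for patient {pid}")
print("drawn elements:", kinds)

# 'marker' entries are biomarker readings, 'event_line' entries the vertical
# diagnosis/treatment/death lines, 'caption' the text along the x-axis.
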