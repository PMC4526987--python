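"""Score one pathway's completeness.

Builds a small prostate-cancer pathway — an elevated pre-diagnosis PSA,
diagnosis, Gleason grade, hormone therapy, radiotherapy, then three falling
PSA readings (two below the 0.1 ng/ml assay limit) — and runs the
biomarker-trend completeness rules over it.
"""

from pathforge import build_pathway, default_dictionary, score_pathway

rows = [
    ("1", -28, "P", "45"),
    ("1", 0, "D", "2"),
    ("1", 1, "G", "4+3"),
    ("1", 1, "H", "Cyproterone Acetate"),
    ("1", 151, "R", "37"),
    ("1", 260, "P", "0.2"),
    ("1", 340, "P", "<0.1"),
    ("1", 539, "P", "<0.1"),
]

pathway = build_pathway(rows, default_dictionary())
record = score_pathway(pathway)

print("codes:        ", "".join(pathway.codes))
print("positioning:  ", record.positioning)
print("substantiation:", record.substantiation)
print("overall:      ", record.overall)
drop = record.max_drop
print(f"max drop:      {drop.magnitude:.1f} ng/ml over days {drop.start.time}..{drop.end.time}")
print(f"drop ratio:    {record.drop_ratio:.4f}")

# Positioning 3 means PSA was sampled both before and after the first radical
# treatment; 'yes' means the 44.8 ng/ml collapse is explained by the hormone
# therapy (day 1) and radiotherapy (day 151) recorded inside the drop
# interval, so the pathway earns the top completeness level S5 — its PSA
# trend is usable for clinical analysis.
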