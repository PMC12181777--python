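"""Concentration screen: render, analyze, and tabulate bead intensities.

Renders the 4 x 6 alginate x CaCl2 grid with the synthetic camera, runs the
bead-isolation + intensity pipeline on every frame, and prints the mean
8-bit intensity per condition.  Each alginate row peaks at an intermediate
CaCl2 concentration: too little crosslinker gives a nearly invisible bead,
too much an over-crosslinked translucent one.
"""

from beadsim import CameraModel, simulate_screen, summarize_screen

records = simulate_screen(cam=CameraModel(seed=42, noise_sigma=2.0))
table = summarize_screen(records)

pivot = table.pivot(index="alginate_pct", columns="cacl2_pct", values="mean")
print("mean bead intensity (0-255) by condition:")
print(pivot.round(1).to_string())

for alg, row in table.groupby("alginate_pct"):
    row = row.sort_values("cacl2_pct")
    found = row[row["found"]]
    peak = found.loc[found["mean"].idxmax()]
    print(f"alginate {alg:>4}% -> brightest at CaCl2 {peak['cacl2_pct']}% "
          f"(mean {peak['mean']:.1f})")
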