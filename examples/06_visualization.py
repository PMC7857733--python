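"""The syndromic plot and companions, from the bundled example table.

Uses the 18-variable spinal-cord-injury motor-outcome loading table to
render one syndromic plot per component, a starred heatmap, a loading
barmap, and a VAF plot, all as deterministic SVG files.
"""

from pathlib import Path

import syndromics as sy
from syndromics import viz
from syndromics.datasets import sci_motor_loadings, sci_motor_vaf

out = Path("figures")
out.mkdir(exist_ok=True)
table = sci_motor_loadings()
vaf_labels = [f"{v}%" for v in sci_motor_vaf()]

spec = viz.PlotSpec(cutoff=0.45, vaf_labels=vaf_labels)
for pc, fig in viz.syndromic_plot(table, spec).items():
    viz.save_figure(fig, out / f"syndromic_{pc}.svg")
    n_arrows = len(viz.select_salient(table, 0.45, pc))
    print(f"{pc}: {n_arrows} variables with |loading| > 0.45 drawn as arrows")

heat = viz.heatmap_loadings(table, viz.PlotSpec(cutoff=[0.21, 0.25, 0.4]))
viz.save_figure(heat, out / "heatmap.svg")
bars = viz.barmap_loadings(table, viz.PlotSpec(cutoff=0.45))
viz.save_figure(bars, out / "barmap.svg")
scree = viz.vaf_plot(sci_motor_vaf(), style="line")
viz.save_figure(scree, out / "vaf.svg")
print(f"wrote {len(list(out.glob('*.svg')))} SVG files to {out}/")
print(
    "\nArrow width and color saturation encode |loading|; blue/red encode\n"
    "sign; the central triangle carries each component's VAF. Heatmap stars\n"
    "mark per-component salience (cutoffs 0.21 / 0.25 / 0.40)."
)
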