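"""Scratch-wound experiment in silico: distance-dependent calcium
signatures, the proximal/distal split at 100 um, and the Mann-Whitney
threshold sweep locating the distance of greatest significance.

Run:  python examples/wound_spatial_analysis.py
"""

import warnings

import numpy as np

from calsig import defaults as dflt
from calsig import signatures as sig
from calsig import spatial as spa
from calsig import synth

STIM = dflt.DEFAULT_PRESTIM_S

layout = synth.make_wound_layout(rng_seed=2)
edge_x = layout.wound.edge[0, 0]
grid = synth.default_time_grid("wound")

records = []
for i, cell in enumerate(layout.cells):
    trace = sig.denoise(synth.make_transient(cell.params, grid, 1000 + i,
                                             STIM))
    m = sig.compute_metrics(trace, STIM)
    d_um = spa.distance_to_wound(cell.centroid_px, layout.wound,
                                 layout.pixel_size_um)
    records.append(spa.SpatialRecord(i, d_um, m))

prox, dist = spa.split_proximal_distal(records)
summary = spa.summarize({
    "proximal": np.array([r.metrics.peak_height for r in prox]),
    "distal": np.array([r.metrics.peak_height for r in dist])})
print(f"{len(layout.cells)} surviving cells "
      f"({len(prox)} proximal < 100 um, {len(dist)} distal)")
print("\ninitial peak height by zone:")
print(summary.round(3).to_string())
u, p = spa.mann_whitney_u([r.metrics.peak_height for r in prox],
                          [r.metrics.peak_height for r in dist])
print(f"\ntwo-tailed Mann-Whitney U test: U = {u:.0f}, p = {p:.2e}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    sweep = spa.threshold_sweep(records, ["peak_height", "plateau_height"])
for feat, res in sweep.items():
    best = res.thresholds_um[np.nanargmin(res.p_values)]
    print(f"sweep {feat}: most significant split at {best:.0f} um "
          f"(p = {np.nanmin(res.p_values):.1e})")

print("\nProximal cells respond with larger, longer-lived calcium "
      "elevations than distal cells; the sweep shows where along the "
      "distance axis that contrast is sharpest.")
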