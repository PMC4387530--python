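"""Render a synthetic confluent monolayer and segment it.

Sums the first and last frames of both dye channels, normalizes, blurs,
masks, suppresses inter-cell borders, then iteratively grows ROIs from the
brightest remaining pixel with halo stripping.

Run:  python examples/segment_monolayer.py
"""

import warnings

from calsig import segment as seg
from calsig import synth

layout = synth.make_monolayer_layout(n_cells=121, rng_seed=4)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    seq, _ = synth.render_sequence(layout, frame_interval_s=300.0,
                                   duration_s=2220.0, rng_seed=104)

combined = seg.combine_channels(seq.red[[0, -1]], seq.green[[0, -1]])
prepared = seg.preprocess(combined)
roimap = seg.extract_rois(prepared)
recall, precision, rmse = seg.score_segmentation(roimap, layout,
                                                 match_radius_px=5.0)

print(f"true cells: {len(layout.cells)}   ROIs found: {len(roimap)}")
print(f"recall    : {100 * recall:.1f} %   (fraction of cells recovered)")
print(f"precision : {100 * precision:.1f} %   (fraction of ROIs that are "
      "real cells)")
print(f"centroid RMSE: {rmse:.2f} px")
print("\nRecall above 96% means the pipeline samples essentially the whole "
      "population instead of a hand-picked, bias-prone subset.")
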