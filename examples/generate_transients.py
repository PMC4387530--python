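"""Generate one calcium transient per taxonomy class and extract its
signature metrics (initial peak A, FWHM B, plateau C, spike rate from D).

Run:  python examples/generate_transients.py
"""

import numpy as np

from calsig import defaults as dflt
from calsig import signatures as sig
from calsig import synth

STIM = dflt.DEFAULT_PRESTIM_S
rng = np.random.default_rng(0)

print(f"{'class':>6} {'peak A':>7} {'FWHM(min)':>9} {'plateau C':>9} "
      f"{'rate(1/s)':>10}")
for protocol, priors in (("ATP", synth.atp_shape_priors(0.03)),
                         ("wound", synth.wound_shape_priors("proximal",
                                                            0.03))):
    grid = synth.default_time_grid(protocol)
    for cls, prior in priors.items():
        if protocol == "wound" and not cls.startswith("W"):
            continue  # shared classes already shown under ATP
        p = prior(rng)
        trace = synth.make_transient(p, grid, rng_seed=1,
                                     stimulus_time_s=STIM)
        m = sig.compute_metrics(sig.denoise(trace), STIM)
        print(f"{cls:>6} {m.peak_height:7.2f} {m.fwhm_min:9.2f} "
              f"{m.plateau_height:9.2f} {m.spike_rate_per_s:10.2e}")

print("\nEach row is one synthetic cell: A and C are ratio units above "
      "baseline, FWHM is the decay time to half the peak, and the rate is "
      "the reciprocal mean inter-spike interval (0 when the cell never "
      "enters a spiking mode).")
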