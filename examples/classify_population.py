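"""Draw a synthetic ATP-stimulated population, classify every transient
into the 14-class taxonomy and tabulate the primary classes.

Run:  python examples/classify_population.py
"""

import warnings

from calsig import defaults as dflt
from calsig import signatures as sig
from calsig import synth
from calsig.classify import classify_transient, tabulate

STIM = dflt.DEFAULT_PRESTIM_S

pop = synth.make_population(dflt.atp_pooled_mixture(), 200,
                            synth.atp_shape_priors(), rng_seed=3)
labels = []
correct = 0
for trace, true_class, params in pop:
    trace = sig.denoise(trace)
    metrics = sig.compute_metrics(trace, STIM)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cls = classify_transient(metrics, trace, "ATP", STIM)
    labels.append((1, cls))
    correct += cls.secondary == true_class

table = tabulate(labels)
print("secondary-class counts:")
print(table.counts.to_string())
print("\nprimary-class percentages:")
print(table.primary_summary.round(1).to_string())
print(f"\nclassifier agreement with the generating class: "
      f"{100 * correct / len(pop):.1f} %")
print("\nPrimary class 1 = slow or absent response, 2 = rapid peak then "
      "plateau, 3 = rapid peak then spiking; the three groups are "
      "expected near 21 / 33 / 47 % of the population.")
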