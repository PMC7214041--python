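"""Polar-label a tiny cohort and inspect every step of the algorithm.

Seven patients with disease-code counts 0, 0, 1, 3, 10, 100, 1000: the two
heavily coded patients land on the high pole (silver positive), the three
with at most one code land on the low pole (silver negative), and the
middle two are discarded as ambiguous.
"""

import pandas as pd

from polarlabel import (
    DiseaseCountVector,
    PolarConfig,
    assign_polar_labels,
    fit_poles,
    polar_label,
)

counts = pd.Series([0, 0, 1, 3, 10, 100, 1000],
                   index=[f"patient_{i}" for i in range(7)])
vector = DiseaseCountVector(counts=counts, target_concept="DX_EXAMPLE")
config = PolarConfig(alpha=0.5, train_size=3, seed=7)

cutoffs = fit_poles(vector, config)
print(f"potential silver positives (count >= 1): {cutoffs.n_psp}")
print(f"log-count mean {cutoffs.psp_mean:.4f}, sd {cutoffs.psp_sd:.4f}")
print(f"high pole cut-off = mean + {config.alpha} * sd = {cutoffs.high:.4f}")
print(f"low pole cut-off  = {cutoffs.low}")

partition = assign_polar_labels(vector, cutoffs)
print(f"\nsilver positive: {partition.silver_positive}  (log count >= high)")
print(f"silver negative: {partition.silver_negative}  (log count <= low)")
print(f"discarded middle: {partition.unlabeled_middle}")

silver = polar_label(vector, config)
print(f"\nemitted silver training set (train_size={config.train_size}):")
print(silver.records)
print("\nEach row is a training label: silver_label 1 means the patient sits"
      "\non the high pole of the log count distribution, 0 on the low pole.")
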