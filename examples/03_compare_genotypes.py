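"""Full pipeline: simulate a wild type and a resistant mutant, fit, compare.

The mutant's true half-life is 2.5x the wild type's. The ranked report shows
per-genotype mean RIT50, fold change versus the wild type, and significance
stars from the Welch t-test on the triplicate half-lives (plus Holm-adjusted
p-values).
"""

import pandas as pd

from ritfit import SimConfig, compare_dataset, fit_dataset, simulate_dataset

dataset = simulate_dataset(
    [
        SimConfig.from_half_life(10.0, genotype="WT", seed=11),
        SimConfig.from_half_life(25.0, genotype="ind-mutant", seed=12),
    ],
    reference="WT",
)

estimates, fits, failures = fit_dataset(dataset)
report = compare_dataset(estimates, reference="WT")

pd.set_option("display.width", 120)
print(report.round(4).to_string(index=False))
print("\nfold_change is each genotype's mean RIT50 over the wild-type mean; "
      "a value near 2.5 recovers the simulated resistance gain.")
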