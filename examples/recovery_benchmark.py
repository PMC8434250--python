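"""Benchmark how well the pipeline recovers known structure fractions.

Draws seeded ground truths from the gliadin-extract prior at several
noise levels, runs the full analysis on each (3-replicate averaging,
second-derivative seeding, constrained least squares, quantification),
and prints the per-label bias and RMSE of the recovered percentages.
"""

import warnings

from ramandecomp import recovery_experiment

warnings.simplefilter("ignore")

table = recovery_experiment(
    preset="gliadin_liquid",
    noise_grid=(0.0, 0.005, 0.01),
    n_per_cell=10,
    seed=0,
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# bias_pp / rmse_pp are in percentage points of structural fraction.  At
# zero noise recovery is exact; errors grow with the noise level while the
# composite correlation (min_pearson_r) stays near 1.
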