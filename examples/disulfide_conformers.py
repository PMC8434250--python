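"""Quantify disulfide-bridge rotamer populations from the S-S stretch region.

Generates one synthetic 495-555 cm^-1 spectrum with five sub-bands at the
conformer positions reported for wheat endosperm, removes the linear
background, decomposes the region, and prints the percentage of each S-S
rotamer class (gauche-gauche-gauche ~510, trans-gauche-gauche ~525,
trans-gauche-trans ~545 cm^-1).
"""

import warnings

from ramandecomp import (
    SS_CONFORMER_SCHEME,
    analyze_ss_conformers,
    baseline_correct,
    generate_spectrum,
    random_truth,
    truth_fractions,
)

warnings.simplefilter("ignore")

truth = random_truth("ss_region", seed=11, noise_sigma=0.005)
spectrum, _ = generate_spectrum(truth)
spectrum, _ = baseline_correct(spectrum)

report, fit = analyze_ss_conformers(spectrum)
want = truth_fractions(truth, SS_CONFORMER_SCHEME)

print(f"composite fit quality: pearson r = {fit.pearson_r:.5f}")
for label, pct in report.fractions.items():
    members = ", ".join(f"{c:.1f}" for c in sorted(report.member_bands[label]))
    print(f"{label:<8}{pct:>7.1f}%   sub-bands at {members} cm^-1   (true {want[label]:.1f}%)")
# Class percentages are summed sub-band areas over the regional total;
# higher trans-gauche-trans content indicates less stable S-S bridges.
# Note the asymmetry between the two quality measures: the composite fit
# tracks the data almost perfectly, yet individual class areas carry a
# few-percentage-point uncertainty because neighboring sub-bands overlap
# heavily and trade area under noise.
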