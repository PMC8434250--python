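# ramandecomp

Band decomposition and conformational quantification for FT-Raman spectra
of proteins and protein-rich plant material — the analysis chain used to
estimate wheat gliadin secondary structure, disulfide-bridge rotamer
populations, and aromatic side-chain markers from single-trace Raman
measurements.

The package is aimed at spectroscopists and cereal-protein researchers
who have wavenumber/intensity traces (CSV/TSV, or simple JCAMP-DX) and
want reproducible, scriptable versions of the classic curve-fitting
workflow: replicate averaging, fluorescence-baseline correction,
normalization to the ~1460 cm⁻¹ C–H deformation band, second-derivative
band seeding, constrained least-squares decomposition, and area-based
quantification.

## The model

A spectral region is modelled as a sum of *K* pseudo-Voigt components on
a local linear baseline:

```
I(ν̃) = a + b·ν̃ + Σₖ hₖ · [ ηₖ L(ν̃; cₖ, wₖ) + (1−ηₖ) G(ν̃; cₖ, wₖ) ]
```

where `G` and `L` are height-normalized Gaussian and Lorentzian profiles
sharing center `cₖ` (cm⁻¹) and FWHM `wₖ` (cm⁻¹), and `ηₖ ∈ [0,1]` is the
Lorentzian fraction. Component areas use the closed form on infinite
support,

```
Aₖ = ηₖ·(π/2)·hₖ·wₖ + (1−ηₖ)·hₖ·wₖ·√(π / 4 ln 2),
```

and conformational contents are area proportions:

* **Amide I (1590–1710 cm⁻¹)** — five structural sub-bands (β-sheet
  1634–1640, α-helix 1649–1652, random coil ~1663, β-turn 1677–1678,
  antiparallel β-sheet 1690–1692 cm⁻¹) plus two aromatic side-chain bands
  (1607–1610, 1620–1627 cm⁻¹) that are fitted but excluded from the
  structural denominator. Fraction(label) = 100·A(label)/ΣA(structural).
* **Disulfide stretch (500–550 cm⁻¹)** — rotamer classes
  gauche-gauche-gauche (~510), trans-gauche-gauche (~525) and
  trans-gauche-trans (~545 cm⁻¹), each possibly split into two sub-bands
  whose areas are summed per class.
* **Markers** — tyrosine Fermi doublet height ratio I(855)/I(835)
  (0.9–1.43: H-bond donor *and* acceptor; >1.43: positive-charge
  acceptor; ≥2: exposed anionic Tyr–O⁻), tryptophan indole height at
  760 cm⁻¹ on the normalized scale, C–S stretch bands in 640–745 cm⁻¹,
  and the starch/carbohydrate bands of kernel endosperm.

Fit quality is the Pearson correlation between the fitted composite and
the data over the region; values ≥0.9985 (disulfide region) and ≥0.9991
(amide I) indicate the component model fully accounts for the envelope.

Because no public spectra exist for this system, the package ships a
first-class seeded generator (`ramandecomp.synthetic`) producing
endosperm-like and gliadin-extract-like spectra with known component
truth, so every stage is testable end to end.

## Worked example

```python
from ramandecomp import (analyze_amide_i, average_replicates,
                         generate_replicates, random_truth)

truth = random_truth("gliadin_liquid", seed=7, noise_sigma=0.005)
spectrum, sd = average_replicates(generate_replicates(truth, 3))
report, fit = analyze_amide_i(spectrum)
print(f"pearson r = {fit.pearson_r:.5f}")
for label, pct in report.fractions.items():
    print(f"{label:<14}{pct:6.1f}%")
```

prints (exactly reproducible — the generator and the fit are
deterministic given the seed):

```
pearson r = 0.99995
beta_sheet      21.2%
alpha_helix     31.0%
random_coil     17.2%
beta_turn       23.6%
abeta_sheet      6.9%
```

The percentages are the secondary-structure contents implied by the
fitted sub-band areas (generator truth for this seed: 20.8 / 30.1 / 16.7
/ 26.3 / 6.1); the correlation of 0.99995 says the seven-band model
reproduces the measured envelope. The `examples/` directory holds one
short script per capability (amide I analysis, disulfide conformers,
marker bands, the configured end-to-end pipeline, and the
recovery benchmark); each prints its numbers with a note on what they
mean. A thin CLI mirrors the library:
`ramandecomp simulate|preprocess|decompose|quantify|run|recovery --help`.

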