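# Methods

This note documents the models, the numerical choices and the synthetic
data behind `ramandecomp`, in the order the pipeline applies them.

## Preprocessing

**Replicate averaging.** Replicates are linearly interpolated onto a
uniform grid over the intersection of their axes (default step: the
first replicate's median native spacing) and averaged pointwise; the
sample (n−1) SD profile is returned alongside. A warning is raised where
the relative SD exceeds 5% of the local mean — the replicate-quality
convention for this kind of solid-sample work (N ≥ 3, SD < 5%). With
additive noise the ratio is meaningless where the signal itself is near
zero, so the warning should be read against the signal regions.

**Cropping.** Closed intervals `[lo, hi]` cm⁻¹; kernel spectra are
analysed over 300–2000 cm⁻¹.

**Baseline.** The background is fitted by least squares through the
minimum-intensity point of each *anchor window* — a user-declared quiet
zone — and subtracted. Two models: a line (for region-local work and
liquid samples) and a polynomial of degree ≤ 5 (default 4) for the broad
fluorescence background of kernel endosperm. The package ships a
default anchor set for endosperm spectra
(`ramandecomp.pipeline.ENDOSPERM_BASELINE_ANCHORS`) placed between the
known marker bands. Anchor minima sit slightly above the true background
wherever band tails reach into a window, so dense anchors matter more
than polynomial degree; degree 4 matches the smooth single-hump
fluorescence this instrument class produces.

**Normalization.** Intensities are divided by the *height* (maximum) of
the reference C–H deformation band found in 1450–1470 cm⁻¹. Height, not
area, is used: the reference band is not decomposed at this stage, the
height is scale-consistent, and the subsequent fraction read-outs are
ratios that do not depend on the choice. The full chain is invariant
under multiplication of the raw intensities by any positive constant.

Order of operations is crop → baseline → normalize for kernel spectra;
for isolated-region fits (liquid amide I, the S–S window) a local linear
baseline is co-fitted inside the region instead. Both the order and the
anchors are config-driven.

**Derivatives.** Savitzky–Golay smoothing (polynomial order 3) with the
second derivative evaluated analytically from the local fit. Defaults:
window 11 points on the native grid for generic use; the decomposition
chooses a window spanning ≈ 0.7·(expected FWHM) in cm⁻¹, which smooths
noise-born wiggles while keeping doublets ~0.7 FWHM apart resolvable.
Local minima of the smoothed second derivative mark candidate band
centers.

## Band decomposition

Each region is modelled as pseudo-Voigt components (Gaussian/Lorentzian
mix with shared center and FWHM, mixing fraction η) plus an optional
local linear baseline, refined by bounded trust-region least squares
(`scipy.optimize.least_squares`, analytic Jacobian, ftol 1e-10, xtol/gtol
1e-14, iteration budget 2000 evaluations). Seeds come from qualifying
second-derivative minima (prominence ≥ `min_prominence` × the deepest
minimum). Component areas are always the closed form on infinite
support, so areas are comparable across shapes and regions.

**Assignment schemes constrain the fit.** When a scheme is supplied,
each seed is snapped to the scheme window containing it and its center
is bounded to the literature band-position range ± 2 cm⁻¹; windows that
attracted no derivative seed get a seed at the band position anyway —
heavily overlapped envelopes routinely hide a component the derivative
cannot resolve, and the quantification needs every class represented.
Seeds outside every recognized window are treated as noise-born and
dropped (except during residual-driven augmentation, below). The amide I
scheme declares one band per window; the disulfide scheme declares the
literature sub-band positions (513.5; 519 and 524.5; 532 and 545.5 cm⁻¹)
and guarantees one component near each.

**Width constraints and identifiability.** Amide I sub-bands 12–16 cm⁻¹
apart with FWHMs of 15–20 cm⁻¹ overlap so strongly that a fit with free
widths is nearly non-identifiable: a linearized error analysis at truth
gives structural-fraction standard deviations of 5–20 percentage points
at 0.5–1% noise, while the same analysis with known band shapes gives
~0.2 pp. Constraining each component's FWHM to its class-typical value
(±0.75 cm⁻¹ in the default scheme: 16/15/20/19/15 cm⁻¹ for β-sheet,
α-helix, random coil, β-turn and antiparallel β-sheet; 9 and 11 cm⁻¹ for
the aromatic bands) restores identifiability and is standard practice in
amide I curve-fitting protocols, where widths are taken from the
literature rather than floated. The S–S region has no fraction-accuracy
requirement attached, so its widths float inside the physically expected
6–18 cm⁻¹ (bounds 7.5–14.5 by default); its class areas consequently
carry a few-pp uncertainty under noise even when the composite fit is
near-perfect.

**Shape policy.** `gaussian` (η = 0), `lorentzian` (η = 1) or
`pseudo_voigt` (η fitted per component, initialized Gaussian). The
frozen amide I protocol uses pure Gaussians — the extra η degrees of
freedom trade against widths and worsen the identifiability problem
above; the disulfide protocol fits η.

**Multistart.** Bounded least squares on overlapped envelopes can stall
in shallow local minima. When the first fit's residual RMS exceeds
1e-10 of the data peak, up to 6 perturbed re-seeds (centers redrawn
inside their bounds, heights log-jittered, widths jittered ±25%) are
tried from a fixed restart seed; the best-cost result wins and the loop
exits early after two non-improving restarts. The whole procedure is
deterministic given identical inputs.

**Residual augmentation.** When a target correlation is configured and
the composite falls short, up to `max_extra` additional components are
seeded at the largest positive residual and the fit repeated. This
mirrors the practical rule that a reasonable fit of these regions may
require extra bands (neighboring-band wings, aggregated forms); such
components keep their position, are excluded from class quantification
when they fall outside every scheme window, and are reported in the
component table.

**Fit quality.** Pearson correlation between composite and data over the
quantification region. On synthetic data at 0.5% noise the minimum over
20 seeded spectra exceeds the published quality levels (0.9985 for the
S–S region, 0.9991 for amide I) with margin; `scripts/acceptance.py`
recomputes exactly this.

## Quantification

Components are assigned to scheme windows by center. Structural and
conformer fractions are `100 · member-area / total class area`; the two
aromatic amide I bands are fitted but excluded from the structural
denominator — the five structural labels alone account for 100% in the
reference tables this convention reproduces. Fractions are carried as
floats and sum to 100 within 1e-6 by construction (asserted on every
report); rounding to integers is display-only. Components matching no
window are reported as `unassigned` with a warning; the nearest-window
fallback is off by default.

Marker read-outs are peak heights after baseline correction and
normalization, measured at the local maximum nearest the nominal
position within ±6 cm⁻¹ windows: the tyrosine I(855)/I(835) height
ratio with its hydrogen-bonding category thresholds (0.9, 1.43, and a
≥2.0 exposed-anionic flag), the tryptophan height at 760 cm⁻¹ (a height,
not an area — the convention adopted here for the normalized-intensity
scale), and presence/position/height for a catalog of characteristic
bands. Shoulders are detected as second-derivative minima without a
strict local maximum and flagged `sh`. Overlap with neighboring bands
biases height markers by up to ~10–20% of the smaller peak; the marker
windows are deliberately narrow to bound this.

## Synthetic data

The generator emulates the two sample families of the study conditions:

* `endosperm` — 300–2000 cm⁻¹ at 1 cm⁻¹ step: the starch/carbohydrate
  marker bands (440, 480, 866, 940, 1052, 1084, 1127, 1260, 1340, 1380,
  1457, 1600, 1660 cm⁻¹) with the 1460-region band at height 1, the five
  S–S sub-bands with class areas drawn from a flat 3-simplex, C–S bands
  at 670/702/718 (the 640 cm⁻¹ gauche band genotype-dependent and
  switchable), the tyrosine doublet with a ratio prior uniform on
  0.9–2.6, a tryptophan band at height 0.11–0.15, and a degree-4
  fluorescence background (~40% of the strongest band) through smooth
  random control points. Band positions jitter ±1–1.5 cm⁻¹ and heights
  ±10% between samples.
* `gliadin_liquid` — 1585–1715 cm⁻¹ at 0.25 cm⁻¹ step: five structural
  bands with centers uniform inside the literature windows, areas from a
  flat 5-simplex, fixed class-typical FWHMs (the
  `AMIDE_FWHM_DEFAULTS` free parameters; see the width discussion
  above), two aromatic bands with areas 3–10% of the structural total,
  and a mild linear background.
* `ss_region` — 495–555 cm⁻¹ at 0.25 cm⁻¹ step: five sub-bands at the
  reported conformer positions, areas uniform on [0.3, 1], FWHMs uniform
  on 8–14 cm⁻¹, linear background.

Noise is additive Gaussian with SD = `noise_sigma` × the clean peak
intensity (default 0.5%, a realistic accumulated-scan floor); replicates
add an independent multiplicative scale jitter (default 2% SD,
constrained below the 5% replicate convention). Everything derives from
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
outputs.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: detector noise statistics
(multiplicative/shot components, spikes), cosmic rays, wavenumber
calibration error, water and buffer bands in liquid samples, deviations
of real band shapes from the pseudo-Voigt family, and any correlation
between structure fractions and band widths or positions. Recovery
results are exact-model results; on real spectra the model-mismatch
term dominates the noise term.

**Recovery experiment.** `recovery_experiment` draws seeded truths per
noise level, renders 3 replicates each (the study's averaging
convention; configurable), runs the full pipeline and tabulates
per-label bias and RMSE in percentage points plus the minimum composite
correlation. The acceptance suite runs it in spirit at 100 truths per
noise level: noiseless recovery is exact to well under 0.1 pp, and at 1%
noise the per-label RMSE stays within 2 pp. These are per-label
aggregate statistics: individual draws can deviate by several pp at 1%
noise because the overlap-induced flat directions described above are
truncated, not removed, by the constraints.

## Numerical choices and degenerate inputs

* Axes are strictly ascending after ingestion; descending files are
  re-sorted and exact duplicate wavenumbers collapsed by mean. Minimum
  length 2.
* Region bounds are closed intervals; crops and window searches include
  both endpoints.
* All fits run on a uniform grid (linear resampling at the native median
  step) since Savitzky–Golay requires one.
* Zero-height components are allowed (the bound is h ≥ 0); they are
  reported with a warning, contribute zero area and never produce NaN
  fractions. A region with zero total class area raises.
* Tie-breaks: two derivative seeds in one amide window keep the taller;
  two in one conformer window are both kept and their areas summed.
* Problem sizes in the shipped tests and the acceptance script (20
  spectra per fit-quality target, 100 truths per recovery level, grid
  steps as above) are the package's default study conditions; all are
  parameters.

## Known limitations

* Area fractions in heavily overlapped regions are only as identifiable
  as their constraints: the defaults encode literature band positions
  and widths, and analyses of systems where those priors do not hold
  must widen the scheme bounds and accept larger area uncertainty.
* The JCAMP-DX reader covers the uncompressed AFFN `XYDATA=(X++(Y..Y))`
  and `XYPOINTS` forms only (no DIFDUP/SQZ compression).
* No cosmic-ray despiking or scatter correction; inputs are assumed
  clean single traces.
* Uncertainty on individual band parameters is not propagated (no
  covariance report); the recovery experiment is the intended way to
  gauge fraction uncertainty under a noise model.
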