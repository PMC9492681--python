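# Methods

This note documents the models, numerical choices and synthetic-data design
behind `budscale`, and what the test suite does and does not demonstrate.

## Hydrodynamic forward model

The package models an unbaffled, orbitally shaken Erlenmeyer flask with the
standard engineering correlations: the flask Reynolds number
`Re = ρ n d² / η_app`, the modified Newton (power) number
`Ne′ = 70 Re⁻¹ + 25 Re⁻⁰·⁶ + 1.5 Re⁻⁰·²`, the volumetric power input
`P/V_L = Ne′ ρ n³ d⁴ / V_L^(2/3)` and a dimensional correlation for the
volumetric oxygen mass-transfer coefficient
`k_La = 0.5 d^(73/36) n d₀^(1/4) V_L^(−8/9) D^(1/2) ν^(−13/54) g^(−7/54)`.
Their product with a `d⁵` correction, `P_V,A = d⁵ · k_La · (P/V_L)`, is the
composite predictor of material size; it is reported in mW·m²/s so the
default optimal band 0.72–1.65 reads on its conventional scale.

Assumptions worth keeping in mind:

* The correlations hold for unbaffled flasks in the "in-phase" operating
  region; no turbulence modelling or CFD is attempted.
* Medium properties default to water-like values at 30 °C
  (ρ = 995.67 kg/m³, η_app = 7.97·10⁻⁴ Pa·s, ν = 8.005·10⁻⁷ m²/s,
  D = 2.5655·10⁻⁵ m²/s, g = 9.807 m/s²). These are used verbatim as model
  constants, including D, which is larger than the usual tabulated O₂
  diffusivity in water; the model is defined by its constants, and changing
  D only rescales `k_La` and `P_V,A` uniformly.
* `k_La` is the combined coefficient–area product. The correlation never
  separates `k_L` from `a`, so the package stores a single field and never
  pretends to know either factor alone.
* Static cultures (n = 0): Ne′ diverges as Re → 0, but `Ne′·n³ ∝ n²`, so
  the power input has a continuous zero limit. `modified_volumetric_power`
  short-circuits n = 0 to an all-zero result with Ne′ = NaN rather than
  evaluating the correlation.

Units are SI internally. Bench units (rpm, mL, cm) are converted exactly
once, at explicitly named boundaries (`from_practical`, `_mL`/`_rpm` CSV
columns). This matters because `P_V,A` scales roughly as `d¹¹ n³·⁸ V^−1.56`:
a silent cm/m or rpm/s⁻¹ slip changes the answer by orders of magnitude.
Dimensional consistency of the exponent bookkeeping (length exponent of the
`k_La` correlation sums to 0, time to −1; the power correlation to
kg·m⁻¹·s⁻³) is asserted with exact `Fraction` arithmetic in the tests.

Nominal flask diameters (125/250/500 mL → 6.6/8.5/10.5 cm) are typical
catalogue values shipped as clearly marked *assumed* presets; every public
interface accepts an explicit measured diameter, which should be preferred.

## Inverse design

`P_V,A` is strictly increasing in n (all n-exponents positive) and strictly
decreasing in `V_L` (exponents −2/3 and −8/9), so each one-variable design
problem has at most one solution on a bracket. Plain bisection
(`scipy.optimize.bisect`, relative tolerance 10⁻⁹ on the root) is used
deliberately instead of Newton-type methods: the map is cheap, monotone and
the bracket is explicit. Default brackets are 0.1–10 s⁻¹ (6–600 rpm) and
10–500 mL — artifact defaults, configurable per query. A target outside the
bracket's image returns a `converged=False` solution carrying the nearest
attainable value, never an exception, so design sweeps can partially
succeed. When converged, the solution's regime label is evaluated at the
*target* (achieved and target differ only by solver tolerance, which would
otherwise flip inclusive band edges).

## Apparent-size pipeline

Apparent-size measurements of this kind are often done with trained
pixel classifiers (e.g. ilastik autocontext), whose behaviour depends on a
training set and feature stack that cannot be reproduced from a written
description. This package instead uses a deterministic pipeline with the
same three-class semantics (background / scattered / bundled):

1. blue channel of the RGB photograph (best material contrast);
2. optional Gaussian smoothing (default σ = 0) and a global threshold —
   Ridler–Calvard isodata by default. Isodata was chosen over Otsu because
   on images whose foreground is a small pixel fraction over a graded
   background, the discrete Otsu implementation can return the brightest
   background bin itself (histogram-plateau argmax), leaking background
   into the foreground; the intermeans threshold lands between the modes.
   Both methods and fixed numeric thresholds are selectable;
3. 8-connected components; objects of ≥ `min_bundle_area_px` (default
   100 px) are *bundled*, smaller surviving ones *scattered*, and
   components below `min_object_px` (default 1, i.e. keep all) are
   discarded as noise. Border-touching objects are kept — flasks crop
   material arbitrarily.

Pixel areas convert to cm² with `scale = flask_inner_diameter_cm /
(2 · rim_radius_px)`; a plain linear scale, no lens-distortion or
wall-thickness model. The per-image summary is the mean area of bundled
objects at or above the 95th percentile of bundled-object areas
(numpy linear-interpolation percentile, threshold inclusive). Interpretive
choices stated explicitly: only the bundled class enters the summary, and
the percentile is computed per image. With no bundled objects the summary
is 0 with an `empty` flag.

## Overlap statistic

Binary-mask overlap, not an intensity correlation: per-channel global
thresholds (automatic or fixed), ROI = morphological closing of the union
mask (disk structuring element, default radius 5 px), cell-free region =
ROI minus the cell mask, and

`overlap % = 100 · |stain ∩ cellfree| / |cellfree|`.

The denominator expresses the question being asked — *what fraction of the
cell-free matrix is stained?* — and an ROI-normalised variant is available
by flag. An empty cell-free region yields an explicit undefined result, not
a number. Group summaries report mean, sample SD (n−1; NaN for a single
image), median and 25–75% quartiles. For genuinely absent stains automatic
thresholding is meaningless (there is no second mode); fixed thresholds are
provided for that case and for reproducibility.

## Unimodal response fit

The size response over `P_V,A` is fitted as a Gaussian bump in log10:
`size = A·exp(−(log₁₀p − μ)²/(2s²)) + b`, by bounded least squares
(`scipy.optimize.curve_fit`; A ≥ 0, s ≥ 10⁻⁶; peak initialised at the
largest observed response, width at a quarter of the log-span). The optimal
band is where the fitted size exceeds `b + f·A`, f = 0.5 by default — a
full-width-at-half-maximum analogue — giving
`10^(μ ± s√(2 ln(1/f)))`. The parametric form is this package's choice, made
to render the "optimal range" reproducible; a nonparametric mode
(`empirical_band`: span of conditions whose mean size reaches α× the best
condition, α = 0.5) is provided as an alternative. Neither mode is used to
derive the reference 0.72–1.65 band, which ships purely as the default
*regime classification* constant: fitting it would require the
condition–size measurements behind it, which the package does not carry.
Fits require ≥ 5 distinct positive predictor
values; flat or degenerate data return an explicit fit-failed result with a
message and no band, never a fabricated interval. R² is clipped to [0, 1].

`compare_parameters` ranks `P/V_L`, `k_La` and `P_V,A` by the R² of the same
fit. The comparison requires multiple flask diameters: at fixed geometry all
three are monotone transforms of n and therefore confounded, which the
function flags and warns about.

Via `UnimodalResponseModel` the fit is a scikit-learn estimator
(`fit`/`predict`, `get_params`/`set_params`, fitted attributes with trailing
underscores), so it composes with sklearn model selection; the segmentation
and overlap analyzers expose their tunables the same way.

## Synthetic data

The generators define the conditions under which the pipelines are tested.

* **Condition tables** — 30 conditions by default, flask diameters
  {6.6, 8.5, 10.5} cm, fill volumes log-uniform over 25–160 mL (the range
  actually varied at the bench), shaking frequency obtained by inverse-
  solving a log-uniformly sampled target of the response predictor over
  peak ± 2.5 widths. The planted response is Gaussian in log₁₀ of the
  chosen predictor with peak at the geometric midpoint of the reference
  band (log₁₀ ≈ 0.037), width 0.153 log₁₀ units (so its half-max band has
  the 0.72–1.65 shape), amplitude 4 cm² over a 0.5 cm² baseline, plus
  Gaussian noise with SD = 10% of the amplitude, truncated at zero. The
  response variable can be switched to `k_La` or `P/V_L` for the symmetric
  predictor-selection construction.
* **Flask images** — 512×512 uint8 RGB; linear background gradient
  (10→30), five bundled disks (radius 15–30 px, intensity 200), fifty
  scattered specks (radius 1–3 px, intensity 160), all mutually separated
  by ≥ 3 px so 8-connected labelling cannot merge them, and a calibration
  rim drawn in the red/green channels only so the segmented blue channel
  carries material alone. Ground-truth areas are recorded *after*
  rasterization — sidecar truth is the pixel count of each rendered disk —
  so any pipeline discrepancy is attributable to the pipeline, not to
  pixelation.
* **Overlap fields** — 256×256; the ROI is a rectangle and the cell-free
  regions are small disks (radius 2–3 px) strictly inside it. Because the
  hole radius is below the closing radius (5 px) and the closing of a
  rectangle by a symmetric disk is the rectangle itself, the downstream
  ROI-recovery is pixel-exact, making noiseless overlap recovery exact by
  construction. Exactly `round(fraction·|cellfree|)` cell-free pixels are
  stained; the sidecar stores the realized rational fraction.

One `numpy.random.default_rng(seed)` stream per generator call: identical
configuration and seed give identical outputs, byte-for-byte for images.

What passing on this synthetic data does **not** show: robustness to glare
and reflections on real flask photographs, to non-disk material morphology,
to uneven illumination beyond a linear gradient, to out-of-focus stain
images, or to the feature-rich texture cues the original trained classifier
exploited. The generators test correctness of the computations, not
photographic realism.

## Problem sizes and tolerances

The test suite and the acceptance script use 100-draw solver round trips,
single 512×512 images, 30-condition tables and 100 Monte-Carlo fit
replicates — sizes at which every check is exact or statistically stable
while the whole suite runs in seconds. Key tolerances: solver round trips
10⁻⁶ relative (solver itself 10⁻⁹), noiseless fit recovery 10⁻⁶, disk-area
pixelation bound 2%, noisy overlap recovery ±2 percentage points,
Monte-Carlo band coverage ≥ 95/100.

## Known limitations

* The correlations are phenomenological; nothing couples oxygen uptake or
  growth kinetics back into the model, and no shear-damage constraint is
  imposed on designs.
* Calibration assumes the rim circle is supplied (manually or from the
  generator); automatic circle detection is deliberately not silently
  trusted anywhere.
* The whole-image global threshold presumes reasonably uniform
  illumination; heavily vignetted photographs need preprocessing outside
  this package.
* `Re` vs `Re′` spelling in the source correlations is immaterial here:
  one Reynolds definition is used throughout.
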