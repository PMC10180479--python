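# Methods

## Peak shape

Each fluorophore band is a Half-Gaussian Modified Gaussian (GMG): the
convolution of a Gaussian of width σ_g with a one-sided half-Gaussian of
width σ_h. The sum of a Gaussian and a half-normal variate is skew-normal,
so the convolution has the closed form

    f(z) ∝ φ(z) · Φ(a z),   z = (λ − ξ)/ω,   a = σ_h/σ_g,  ω² = σ_g² + σ_h²

with φ/Φ the standard normal density/CDF. At a = 0 this is exactly a
Gaussian. The implementation evaluates this closed form and is validated in
the test suite against a brute-force numerical convolution oracle built
independently of it (fine-grid discrete convolution + spline readout).

Band tables specify the wavelength of the maximum (λ) and the composite
FWHM, which under-determines the three-parameter asymmetric shape. We
therefore treat λ as the **mode** and FWHM as the width of the composite
peak: for each asymmetry the unit-scale mode position, FWHM and peak value
of f are calibrated numerically (bracketed root finding on the analytic
derivative, cached per asymmetry), and (ξ, ω) are solved from (λ, FWHM).
Rendered bands then peak at λ with value equal to the amplitude and have the
requested FWHM for any asymmetry; at the default a = 0 the printed (λ, FWHM)
pairs are reproduced exactly. Band areas are analytic:
area = amplitude · ω/2 ÷ (unit-scale peak value).

Default asymmetry is 0 for every band; asymmetry is an explicit per-band
knob in the library schema rather than a fitted parameter.

## Band libraries

The emission libraries (310 nm and 366 nm excitation, 390–600 nm scans) fix
retinol and the fatty-acid bands at their reference-compound (λ, FWHM)
values. Three auxiliary curves complete them:

* **protein** — short-wavelength tail, center and FWHM free within
  [360, 420] nm × [30, 120] nm (defaults 400/80 at 310 nm, 400/70 at
  366 nm);
* **undefined** — minor band at 440 nm; the table gives its peak only, so a
  40 nm default FWHM is assigned (configurable);
* **band560** (366 nm library only) — optional minor band at 560 nm,
  default FWHM 50 nm, expected only in ischemia/reperfusion samples;
* **hemoglobin** — negative-amplitude absorption dip at 410 nm (default
  FWHM 20 nm; only "around 410 nm" is established), reflecting residual
  hemolysis. It is the only band allowed a negative sign.

The excitation library (detected at 570 nm, 300–540 nm scans) holds the
dominant 330/60 nm band plus the three bilirubin bands 400/35, 435/40,
470/70 nm. The 60 nm width of the dominant band is taken as its FWHM.
Libraries round-trip through a YAML schema for customisation.

## Fitting

`fit_spectrum` minimises the sum of squared deviations with
`scipy.optimize.least_squares` (trust-region reflective — a bounded
Levenberg–Marquardt-type algorithm) using an analytic Jacobian for both
amplitudes and the free protein shape. Constraints: fluorophore amplitudes
≥ 0, hemoglobin ≤ 0, protein center/FWHM inside their boxes. Tolerances:
relative cost change 1e-10, parameter change 1e-8, ≤ 2000 evaluations per
start.

With every shape fixed the problem is convex (bounded linear least
squares), so one start suffices and the solution provably equals
non-negative linear least squares — asserted against `scipy.optimize.nnls`
in the tests. With the free protein band the problem is nonlinear and a
multistart over 8 seeded amplitude/shape initializations guards against
local minima; the best solution is kept and the `converged` flag reports the
optimizer status honestly. The condition number of the band design matrix is
reported per fit to surface ill-conditioning among heavily overlapping
bands (e.g. 417 vs 425 nm at 310 nm excitation); no extra regularisation is
added.

Before fitting, spectra are peak-normalized to 100 a.u. Percentages are
areas over the **sum of fitted positive-component areas** (self-normalizing;
the trapezoidal area of the measured spectrum is available as an
alternative denominator, the two coincide for a perfect fit). The negative
hemoglobin band participates in the fit but is excluded from the percentage
denominator and reported with signed area — it is an absorption artifact,
not a fluorophore. Absolute contributions multiply fractions by the
pre-normalization **peak intensity** (the spectrum integral is available as
an alternative metric). Goodness of fit is r² = 1 − SS_res/SS_tot plus
residual RMS and lag-1 autocorrelation.

`check_minor_band_budget` flags fits whose auxiliary curves (undefined,
560 nm, |hemoglobin|) cover more than 10% (310 nm) or 3% (366 nm) of the
summed positive-band area; the flag trips strictly above the threshold.

## Markers

* **Bilirubin fraction** — the summed percentages of the three bilirubin
  bands in the exc570 fit.
* **Excitation ratio** — (Σ intensity > 407 nm)/(Σ intensity 404–407 nm),
  summed over grid points (not trapezoids) with a closed denominator window
  and a strict lower bound for the numerator; the uniform-spectrum value on
  the 300–540 nm, 1 nm grid is 133/4 = 33.25 and pins the convention. The
  ratio is computed on the measured (normalized) spectrum, not the fitted
  model, and is invariant under rescaling.
* **Albumin** — mean intensity in a 340 ± 10 nm window of the 280 nm-excited
  emission spectrum. The acquisition notes for this condition conflict on
  the recorded range, so the reader accepts any grid containing the window
  and the window is fully configurable; the generator records 300–450 nm.

## Synthetic cohorts

`generate_cohort` renders three groups (sham, IR, IR_OCA; defaults 5
animals × 10 replicates) on the standard scan grids. Per animal, band
abundances are log-normal around the group means (mean-preserving, CV 20%);
per replicate they are jittered again (CV 5%); spectra get additive Gaussian
detector noise (SD 1 a.u., i.e. peak SNR ≳ 50–150). Log-normal
between-animal variation encodes non-negative, multiplicative biology; the
variance structure is a modelling choice, as no empirical variance data are
available.

Group means are free parameters constrained only by the directional
findings the analysis must detect: overall gain IR (1.8) > sham (1.0) >
IR_OCA (0.85); arachidonic/oleic/linoleic and bilirubin raised in IR and at
or below sham levels under OCA; the retinol **fraction** lowered in IR while
its absolute level rises slightly (the gain outweighs the share loss);
albumin lowered in IR; the 560 nm band present only in IR 366 nm spectra at
< 1% of area; a small hemoglobin dip in every group. The magnitudes were
chosen once to sit in a realistic instrument range (peaks ~60–160 a.u.) and
are not tuned thereafter.

What the generator does **not** emulate: inner-filter and scattering
effects, photobleaching, instrument drift, wavelength-calibration error,
non-Gaussian detector noise, and any correlation between fluorophore
abundances beyond the shared group gain. Passing recovery tests therefore
demonstrates correctness of the unmixing arithmetic and statistics under
the stated noise model, not robustness to those instrumental artifacts.

## Statistics

The animal is the experimental unit: replicate scans are averaged into one
spectrum per animal × condition before fitting (averaging before the fit
also buys a √10 noise reduction), so each group contributes at most
n-animals values per test — never 10× that. Defaults are non-parametric
(Kruskal–Wallis omnibus; pairwise two-sided Mann–Whitney with Holm
adjustment over the three contrasts), the conservative choice for
five-animal groups where normality is unverifiable; one-way ANOVA with
Tukey HSD is available. At n = 5 vs 5 the exact Mann–Whitney floor is
2/252 ≈ 0.0079, i.e. 0.0238 after Holm — a fully separated contrast is
detectable at α = 0.05, and nothing smaller can be. The null rejection rate
of the omnibus at α = 0.05, measured over 1000 simulated null cohorts, is
≈ 0.04–0.05 (slightly conservative, as expected for rank tests at this n).

## Problem sizes and numerical choices

The shipped verification workloads use: the full default cohort (3 × 5 × 10
scans, four conditions) for the directional study; a 100-spectrum
single-replicate sweep for noisy fraction recovery; 50 random mixtures for
the linear-oracle equivalence; 1000 simulated cohorts for test calibration.
Fraction-recovery accuracy is quantified in the fixed-shape (linear)
configuration, where the target is identifiable: with the protein shape
free, overlapping-band trade-offs on single noisy replicates add ~1–2
percentage points of spread that reflects identifiability, not fitter
error. Degenerate inputs fail loudly: non-positive maxima, zero-variance
spectra, all-zero positive amplitudes, windows outside the grid and
mixed wavelength grids all raise typed errors rather than returning
silently repaired values.

## Known limitations

* Absolute molar concentrations are out of scope; "absolute AF" is the
  fraction re-expressed on the instrument's amplitude scale.
* The GMG parameter convention (λ = mode, FWHM = composite width) is one
  defensible reading of a two-parameter band table; a location-based
  convention would shift asymmetric bands.
* Heavily overlapping bands make individual amplitudes ill-conditioned at
  low SNR even though the total fit is excellent; consult the reported
  condition number and prefer replicate-averaged spectra.
* The excitation-ratio boundary convention (closed [404, 407] denominator,
  strict > 407 numerator, point sums) is an explicit choice, pinned by a
  test; results on grids other than 1 nm steps will scale with point
  counts.
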