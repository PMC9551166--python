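# Methods

This note documents the models and procedures implemented in `tristepir`,
the numerical conventions chosen where several defensible options exist, and
what the synthetic data generator does and does not emulate.

## Spectrum handling

Spectra are stored on a strictly ascending wavenumber grid (the descending
IR plotting convention is a display concern); duplicate grid points and
non-finite values are rejected at construction.  Three intensity modes are
tracked explicitly — percent transmittance, absorbance and second
derivative — and every operation declares which mode it accepts, so unit
errors surface as `ModeError` instead of silently wrong numbers.
Transmittance and absorbance are related by `A = 2 − log₁₀(%T)`; converting
absorbance back caps %T at 100 (negative absorbance occurs only as noise
around a zero baseline and a transmission instrument reports at most full
transmission).

The quality rule for transmission spectra accepts a pellet when the achieved
transmission reaches 60 %T **and** the strongest band bottoms out between 10
and 30 %T.  The first clause rejects pellets that transmit too little light
overall; the second rejects both saturated (min below 10) and too-dilute
(min above 30) preparations.  The source wording for this rule is ambiguous
about what "achieved transmission" refers to; reading it as the spectrum
maximum is a package choice, and the verdict object reports both measured
values and the failing clause so users can re-derive their own rule.

JCAMP-DX support is a deliberate 4.24 subset: `##XYDATA=(X++(Y..Y))` and
`##XYPOINTS` blocks, AFFN numbers plus SQZ/DIF digit compression, with
`XFACTOR`/`YFACTOR` honoured and mode inferred from `##YUNITS`.  DUP
compression and vendor binary formats are rejected explicitly rather than
guessed at.

## Preprocessing

The second-derivative transform uses a Savitzky–Golay filter with a 13-point
window and quadratic local polynomials — the minimum order supporting a
second derivative and the common instrument-software default; the window
matches the 13-point slope calculation used in the transmission workflow
this package implements.  Derivatives are scaled by the grid spacing
(per cm⁻¹), so values are resolution-independent; edge points come from the
terminal-window polynomial (scipy's `interp` mode) and the metadata records
the filter settings.  Absorbance maxima appear as SD minima, which is why
peak detection sign-flips SD spectra internally.

Baseline correction defaults to the rubber band — the lower convex hull of
the trace, computed by Andrew's monotone chain and interpolated onto the
grid — because it is parameter-free and reproducible; corrected spectra are
nonnegative with zero endpoints by construction.  Eilers' asymmetric least
squares (`lam=1e6`, `p=0.01`, 10 iterations) is available for baselines
that must be allowed to dip below the signal.  Normalisation (SNV or
min-max) is off by default: whether the original workflow normalised before
chemometrics is unknown, so the default does the least.

The composed `preprocess` step applies, in order: %T→absorbance, baseline,
smoothing (only when no derivative is requested — the SG derivative already
embeds its own smoothing), optional normalisation, optional second
derivative.  The applied steps are recorded in the output metadata.

## Generalized 2D correlation

A thermal perturbation series (default 11 spectra, 20–120 °C in 10 °C
steps) is centred on the series mean (first-spectrum reference available as
an option), giving dynamic spectra ỹⱼ(ν).  The synchronous map
Φ = ỸᵀỸ/(m−1) is the covariance of intensity fluctuations; the asynchronous
map Ψ = ỸᵀNỸ/(m−1) uses the discrete Hilbert–Noda matrix
N[j,k] = 1/(π(k−j)), zero on the diagonal.  Structural invariants (Φ
symmetric with nonnegative diagonal, Ψ antisymmetric with zero diagonal)
are asserted at 1e-10 on every computed map, and the vectorized maps are
tested against naive double-sum implementations at 1e-12.

Cross peaks are interpreted by Noda's rules: Φ > 0 means the two band
intensities respond in the same direction, Φ < 0 opposite directions, and
sign(Φ·Ψ) > 0 means ν₁ responds before ν₂.  Both comparisons use a
magnitude floor (default 5% of max|Φ|) below which variations count as
uncoordinated or the sequence as indeterminate.  Auto-peak extraction also
applies a numerical floor tied to the pre-centring intensity scale, so a
series of identical spectra yields an empty peak table instead of peaks in
floating-point cancellation dust.

## Chemometrics

**Split and cross-validation.** The stratified calibration/validation split
takes ⌈0.6·n⌉ samples per class (so 7 samples split 5/2).  Cross-validation
uses seven cancellation groups assigned by seeded round-robin over a random
within-class ordering — groups partition the set exactly and are balanced
per class.

**PCA.** Mean-centred SVD; explained variance from squared singular values.
The per-component Q² uses row-group cross-validation with *element
exclusion*: a held-out entry is reconstructed from scores estimated without
that entry (a rank-one Sherman–Morrison update of the loadings normal
equations).  Naive row projection predicts each element partly from itself
and reports Q² > 0 on pure noise; the element-exclusion scheme is unbiased
in that sense (pure noise gives Q² ≤ 0).  Q²(a) = 1 − PRESS(a)/SS(a−1) with
SS(a−1) the full-data residual after a−1 components.

**SIMCA.** One PCA model per class; component counts maximise the
cross-validated Q² per class, capped at 5.  Membership of class c uses the
distance to model DModX = s/s₀ with s² = ‖e‖²/(p−A).  Two conventions
needed a decision here:

* *Residual scale.* With thousands of correlated features and a few dozen
  samples, in-model calibration residuals are optimistically deflated (the
  class PCA absorbs calibration noise), so s₀ estimated from them
  undersizes the limit by several percent and inflates the false-rejection
  rate far above the nominal α.  s₀ is therefore estimated from
  *cross-validated* calibration residuals (each sample scored against a
  model fitted without it), which represent genuinely new observations.
* *Critical limit.* The classic F-based limit assumes iid residuals; when
  residuals retain structured within-class variation its tails are wrong.
  The limit here is a moment-matched scaled chi-square (g·χ²ₕ with g, h
  fitted to the mean and variance of the cross-validated residual sums of
  squares), the standard approach for squared-prediction-error control
  limits in multivariate statistical process control.  Measured coverage on
  the synthetic generator is within a point of the nominal 95% at α = 0.05.

A sample may belong to zero, one or several classes; "discriminated from
the flower group" means not a member of the flower class.  Note that a
correctly calibrated α = 0.05 limit rejects about 5% of genuine class
members; with 16 validation samples per class this makes occasional
per-split sensitivities of 87–94% an expected outcome, not a model failure.

**OPLS-DA.** Class labels are one-hot encoded (K−1 predictive components
for K classes by default) and X is centred but not scaled (all features
share absorbance units).  Y-orthogonal components are extracted iteratively:
the first predictive loading p is projected off the column space of XᵀY,
giving a weight w₀ whose scores have exactly zero covariance with every
response column; X is deflated by t₀p₀ᵀ and the step repeats.  The number
of orthogonal components is chosen by incrementing while the 7-group
cross-validated Q²Y improves by more than 0.01 (cap 5).  The predictive
core is PLS2 with X and Y deflation; each weight vector is the dominant
left singular vector of the current cross-covariance — the exact fixed
point of the NIPALS inner iteration, computed directly so near-degenerate
covariance spectra (typical under permuted labels) cannot stall it.

**Error metrics.** RMSEE = √(SSres/(N−1−A)) with A the total number of
fitted components (predictive + orthogonal) — the dof-corrected convention
of mainstream chemometrics software; RMSECV and RMSEP are plain root mean
squares of the cross-validation and validation residuals.  All three are
computed per response column and averaged (per-column values are reported
too).

**Permutation test.** Labels are permuted jointly 100 times; the model is
refitted with the fixed component counts of the reference fit, and R²Y/Q²Y
are regressed (ordinary least squares) on |corr(permuted Y, original Y)|
(flattened-matrix Pearson correlation), including the unpermuted point at
correlation 1.  Intercepts at correlation 0 below 0.3 (R²Y) and 0.05 (Q²Y)
declare the model valid.

**Classification statistics.** One-vs-rest sensitivity TP/(TP+FN),
specificity TN/(TN+FP) and accuracy (TP+TN)/total, in percent.  Zero
denominators are reported as NaN and flagged, never silently zeroed.
Argmax label ties resolve to the lowest class index in declared label
order.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the physics of pellet spectroscopy.  Each class template is a set of
Gaussian (optionally Lorentzian) bands with FWHM 20 cm⁻¹ at the packaged
library's class-characteristic positions (flower 1736/1626/1443/1145/1102/
1058; seed 1743/1648/1548/1459/1159/1079/1019; leaf 1729/1624/1318/1156/
1098/1050 cm⁻¹), a linear baseline, and additive Gaussian absorbance noise
(σ = 0.005).  Band amplitudes were fixed once so the simulated strongest
band sits near 20–25 %T and the baseline keeps maximum transmission above
60% — i.e. simulated pellets pass the QC window.  Within-class variation is
a global lognormal amplitude scale (σ = 0.05), per-band lognormal jitter
(σ = 0.03) and baseline jitter (σ = 0.005 absorbance); no real variance
estimates exist for the modelled material, so these are package choices
exposed in the template dataclass.  Default class sizes are 34 flowers, 80 leaves and
7 seeds — a realistically imbalanced collection.

Thermal series scale each band by 1 + c·(T−20) with band-specific
coefficients c (all-equal coefficients produce proportional dynamics and a
vanishing asynchronous map); an optional sigmoidal response with a per-band
midpoint temperature creates genuine lead/lag structure whose ground-truth
order is recorded in the series metadata.  Adulterated queries are convex
combinations of the flower and leaf band sets before noise, with the
mixture fraction recorded.  A single `separation` knob interpolates all
class templates toward their common mean (0 = indistinguishable classes,
1 = full distinctness) and monotonically drives downstream discriminability.
Every generator is bit-reproducible given (template, seed).

What passing tests on this generator show: the algorithms recover known
band positions, known response orders, known class structure and known
mixture fractions under realistic noise.  What they do not show: robustness
to scattering artefacts, water-vapour/CO₂ lines, detector nonlinearity,
wavenumber miscalibration or batch effects, none of which the generator
simulates.

## Problem sizes and determinism

All validation experiments run on the full 4000–400 cm⁻¹ grid at 1 cm⁻¹
(3601 features).  The acceptance script uses three classes × 40 samples —
large enough for a 7-group cross-validation and a stable 60/40 split,
small enough to regenerate from scratch in seconds.  Every source of
randomness (generation, splitting, cancellation groups, permutations) is
seeded from a single integer, and reports embed the seed and a
configuration digest.
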