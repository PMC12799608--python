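# Methods

This note records the models implemented in `cellmech`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## AFM contact mechanics (`cellmech.mechanics`)

### Forward models

The Hertz force of a rigid sphere of radius R on an incompressible
half-space is `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}`. Finite thickness over a
rigid substrate is handled by a multiplicative bottom-effect correction
`f_BEC(δ) = 1 + Σᵢ cᵢ χ^i` with `χ = √(Rδ)/h`. The default coefficient
series (1.133, 1.497, 1.469, 0.755) is the published bonded-sphere
correction of that functional form; it is exposed in `BECSpec` and fully
overridable, since correction families differ in their higher-order terms.

Viscoelasticity uses power-law rheology, `E(t) = E₀ t^(−α) + η δ_D(t)`:
`E₀` is the relaxation modulus at t = 1 s (Pa), `α ∈ [0, 1)` the relaxation
exponent (0 solid-like, →1 fluid-like) and `η` (Pa·s) a Newtonian term that
acts instantaneously through the Dirac delta. `plr_relaxation` returns only
the springpot part; the Dirac term is applied inside the hereditary
integral as `f_BEC·η·d(δ^{3/2})/dt` on approach.

Ting's solution extends the hereditary integral to non-monotone histories:
for t beyond the approach duration tm the upper integration limit is the
auxiliary time t₁(t) solving `∫_{t₁}^{t} E(t−ξ) δ′(ξ) dξ = 0` (the η term
contributes its instantaneous rate). t₁ is found by bisection on [0, tm] to
a tolerance of 1e−6·tm, warm-started from the previous time step (t₁ is
non-increasing); when the condition is negative even at t₁ = 0 the tip has
fully detached and the force is zero from then on.

### Quadrature

The kernel `(t−ξ)^(−α)` is weakly singular at ξ = t. Each evaluation uses a
product-integration rule: the weight `f_BEC(δ)·d(δ^{3/2})/dξ` is taken
piecewise constant per sampling interval — the secant slope of the
piecewise-linear `δ^{3/2}`, with `f_BEC` at the interval midpoint — and the
kernel is integrated analytically over each interval. Two consequences
motivated this choice over interpolating node derivatives:

* for α = 0 the rule telescopes to `δ^{3/2}(t)` exactly, so the elastic
  limit reproduces Hertz to machine precision on any ramp;
* derivative weights estimated across the approach/retract kink (or the
  contact point) do not leak into the neighbouring integrals, which
  otherwise produces a few-percent error exactly where the kernel weights
  the end of the approach most heavily.

Approach and retraction segments therefore carry separate one-sided
derivative sets split at tm. Accuracy on the α = ½ linear-ramp closed form
`F = π√R·E₀·v^{3/2}·t/(1−ν²)` is ~3·10⁻⁵ relative at the end of a
256-sample ramp; relative error is larger only within the first few samples
after contact, where the force itself is vanishingly small (absolute error
≲ 1e−13 N).

### Inverse fitting

`detect_contact_point` scores every candidate index by the residual of a
two-segment model (flat baseline + Hertzian 3/2-power rise) and subtracts
the baseline. `fit_hertz` then solves the BEC-corrected amplitude in closed
form over the post-contact approach (≥ 8 samples required), with
indentation reconstructed as piezo travel minus cantilever deflection,
`δ = (z − z_c) − F/k`.

`fit_plr` fits (E₀, α, η) *and the contact point* by bounded trust-region
least squares over approach + retraction, initialised at
(E_hertz, 0.2, 1 Pa·s, z_c from the detector), bounds E₀ > 0, α ∈ [0,
0.99], η ≥ 0. The contact point is freed because the Hertz-shaped detector
is systematically early on viscoelastic rises (their initial force growth
is shallower than δ^{3/2}), which otherwise biases η severely. The fitting
window opens a few samples before the detected contact; since the Ting
integral is invariant to leading zero-indentation samples, the contact
position can move freely inside the window without re-slicing the data.
Finite-difference steps of 1e−3 (relative) keep the Jacobian above the
bisection-tolerance noise floor. Residuals are normalized by the peak
force; ftol 1e−12, at most 200 function evaluations; non-convergence is
reported as a flag, not an exception.

Default geometry: R = 70 nm (nominal for pre-calibrated soft-cell paddle
probes; the true radius of any given probe should be supplied when known),
k = 0.1 N/m, ν = 0.5. Units are SI internally; result objects expose
kPa/Pa·s conveniences.

`apparent_modulus_linear_ramp` provides the closed-form rate-dependent
apparent modulus of a PLR material under a constant-rate ramp,
`E_app = 1.5·[E₀·B(3/2, 1−α)·t^(−α) + η/t]` (B the Beta function), used by
the scene generator and as the oracle for the loading-rate dependence of
E_hertz.

## Force-volume maps (`cellmech.maps`)

Topography is the contact-point z per pixel. The substrate plane is
estimated iteratively: the lowest 40 % of heights seed a least-squares
plane; pixels within 100 nm of the plane are re-selected and the plane
refit (2 passes). After subtraction the substrate sits at 0 and the
correction is idempotent to < 1 nm. Background is height < 200 nm; cells
are 4-connected components (8-connectivity by option); the central mask of
a cell keeps pixels strictly above 50 % of that cell's maximum height (a
count-quantile alternative is available by flag — the height-threshold
reading was chosen as the better-defined of the two published phrasings).
Cells touching the border are retained. Per-cell summaries are arithmetic
means over the central mask; failed-fit pixels are excluded and counted,
never interpolated.

## FLIM microviscosity (`cellmech.flim`)

Decays are tail-fitted from the peak bin with `A·exp(−t/τ) + B`. The first
weighted pass uses observed counts (weights 1/max(c,1)); two further passes
reweight by the fitted model counts (IRLS). Pure observed-count weighting
is measurably biased at the study photon budget (≈ −5 % on τ at 5000
photons over 256 bins) because photon-starved tail bins systematically
underweight upward fluctuations; model-based reweighting removes the bias
(< 0.7 % over τ ∈ [1.5, 3.5] ns) — this is the behaviour of standard
lifetime-analysis packages. The reduced χ² is evaluated over bins whose
expected counts are ≥ 1 photon, with dof = n_used − 3: bins expecting
essentially zero photons carry no information and would only deflate the
statistic. So computed, χ² is calibrated (mean ≈ 1.0, ≥ 93 % of correct
fits inside 0.8–1.2) and a 50 % short-lifetime contamination exceeds the
1.40 acceptance cutoff in 100 % of replicates. No IRF deconvolution is
performed — tail fitting from the peak is adequate at nanosecond lifetimes
with a femtosecond excitation source.

The Förster–Hoffmann law `η = C·τˣ` is calibrated by ordinary least squares
of log η on log τ. The built-in reference pairs (2.49 ns, 304 cP),
(3.13, 483), (2.06, 208), (1.55, 116) are mutually consistent with a single
power law (x ≈ 2.03, C ≈ 47.8 cP·ns⁻ˣ; each held-out point is predicted
within ~1 %), and that fit is the default calibration; probe-specific
constants can be supplied instead. ROI processing retains fits with
χ² ≤ 1.40 and reports retained/total counts.

## ToF-SIMS lipidomics (`cellmech.sims`)

Intensities are divided by the per-spectrum total ion count; the stored TIC
is carried as metadata (re-normalizing is a no-op only when the stored TIC
is reused, since the row sum of *listed* peaks is smaller than the true
TIC). PCA is column-centred (autoscaling optional); class ellipses are the
0.95 two-dimensional normal quantile on the per-class score covariance.
PLS-DA is NIPALS PLS1 on autoscaled X against centred ±1 class coding,
A = 2 components by default (matching two-dimensional score plots);

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/||w_a||)² / Σ_a SSY_a ),
    SSY_a = q_a² · t_aᵀt_a

so mean(VIP²) = 1 identically and VIP > 1 flags discriminant peaks. Fold
changes are ratios of class means of normalized intensities with 95 %
percentile-bootstrap CIs (2000 resamples, seeded); saturation analysis
forms per-spectrum MUFA/SFA and PUFA/SFA sums *before* the class
comparison. Peak picking, mass calibration and matrix-effect modelling are
out of scope — the module consumes vendor peak tables.

## Fiber coherency (`cellmech.coherency`)

Gradients by centred differences, tensor components Gaussian-smoothed at
σ = 2 px (default), coherency `(λ₁−λ₂)/(λ₁+λ₂)` with 0 assigned where the
tensor vanishes; border pixels excluded. The default ROI statistic is the
mean of per-pixel coherencies; the coherency of the ROI-mean tensor is
available by mode. The two differ on disordered fields: the per-pixel mean
has a positive small-sample bias (an isotropic field reads ≈ 0.2–0.45
depending on σ, which is in line with coherency values reported for
disorganized actin), while the mean-tensor statistic tends to 0. Sweeping
the generator's orientation dispersion gives a strictly decreasing
coherency (Spearman ρ < −0.9).

## Synthetic data (`cellmech.synth`)

One top-level seed is split through `numpy.random.SeedSequence` into
independent per-modality streams, so any modality can be regenerated alone.

* **AFM scenes**: spherical-cap cells (height profile of a sphere segment)
  placed without overlap on a tilted substrate; acquisition defaults follow
  the fast-force-volume protocol (3 μm ramp, 183 μm/s, trigger 0.75 nN
  within the 0.5–1 nN protocol range, k = 0.1 N/m, 5 nm contact-height
  noise, 25 pN force noise). Two presets encode the measured phenotypes:
  `mcf7-like` (cancer): α = 0.28 ± 0.06, height 7.8 ± 2.3 μm, E₀ = 600 ±
  200 Pa, η = 1.0 ± 0.25 Pa·s; `mcf10a-like` (normal): α = 0.14 ± 0.03,
  height 2.4 ± 0.5 μm, E₀ = 5000 ± 1500 Pa, η = 2.0 ± 0.4 Pa·s. The α and
  height moments are the published group values; E₀ and η group means are
  not published, so values were fixed once inside the published ranges
  (E₀ ≈ 0.5–10 kPa, η ≈ 0.9–2.2 Pa·s) preserving the reported orderings.
  Pixel-level parameter variation is 10 % CV around the cell mean. Curves
  are generated through the same Ting forward model the fitter uses, with
  the cantilever deflection superposed on the piezo coordinate so that
  indentation reconstruction is exact; per-pixel truth maps (thickness,
  E₀, α, η, and the closed-form rate-dependent apparent modulus at the
  nominal 1 μm indentation time) are recorded. Full-map curve generation is
  optional; the truth parameter maps drive the map-level pipeline tests.
* **FLIM**: monoexponential expected histograms over 256 bins / 12.5 ns (80
  MHz repetition), shifted by an 8-bin instrument delay, scaled to the
  photon budget (default 5000) and Poisson-sampled; optional short-lifetime
  contamination models cytoplasmic probe pools. Default population
  lifetimes follow the measured membrane values (2.49/3.13 ns in culture,
  2.06/1.55 ns in tissue).
* **Peak tables**: lognormal intensities (σ_log = 0.3, chosen as a typical
  between-spectrum spread for replicate SIMS measurements) with
  class-specific mean folds over a 20-peak panel (PI 1/7.1, PC 1/2, SM 2.2,
  cholesterol 1.0, shared SFA fold 1.5, MUFA 1.5·1.8 and PUFA 1.5/6 so the
  saturation-normalized truths are exactly 1.8 and 1/6); per-spectrum TIC
  lognormal around 10⁶ counts; default 20/21 spectra per class.
* **Fiber images**: sums of full-frame sinusoidal stripes whose normals are
  drawn around a mean angle with SD κ, plus Gaussian pixel noise; κ = 0
  yields coherency > 0.95.

What the generators deliberately omit: instrument drift, adhesion and
jump-off-contact in force curves, IRF shape and afterpulsing in TCSPC,
SIMS fragmentation chemistry and matrix effects, and optical PSF rendering
for fiber images. Passing tests therefore demonstrate correctness of the
*analysis chain* under the stated noise models, not robustness to every
instrumental artefact of real data.

## Statistics (`cellmech.stats`)

Mann–Whitney U uses the exact null distribution for pooled samples ≤ 20
without ties and the tie-corrected normal approximation otherwise;
two-sided throughout. ANOVA is one-way; pairwise two-sample t-tests are
Bonferroni-adjusted (raw p × number of pairs, capped at 1). The report
command wires Mann–Whitney to AFM/coherency tables and ANOVA+Bonferroni to
viscosity/SIMS tables by default, the published mapping. Empirical type-I
error at α = 0.05 is 0.03–0.07 for both tests under a null simulation
(n = 30 per group).

## Problem sizes

Defaults were chosen so a full test run is comfortable on a laptop: 48×48
maps with 3 cells, 10 maps per group for the 30-cell comparisons, 200-fold
replicate batches for decay-fit calibration, 20 seeded tables × 2000
bootstrap resamples for CI coverage, and 256-sample force curves (the
closed-form and round-trip tolerances are met from 128 approach samples
up).

## Known limitations

* Conical/pyramidal tips, adhesion models (JKR/DMT) and oscillatory
  microrheology are not implemented.
* The BEC series is applied inside the hereditary integral at the current
  indentation (its printed placement); for strongly non-monotone histories
  on very thin samples this is an approximation of unknown sign.
* The contact-point detector assumes a flat pre-contact baseline; curves
  with long-range interactions before contact will bias it.
* Watershed splitting of touching cells is not attempted — touching cells
  merge into one record.
* PLS-DA VIP ranking is relative: with many truly shifted variables,
  individual VIP scores are diluted toward 1 and permutation-based
  significance of any single peak loses power.
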