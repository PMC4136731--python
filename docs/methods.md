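# Methods

## Models

Mean visual-field sensitivity (VFS, dB) in a macular area is modelled as
a bounded logistic function of ganglion cell complex (GCC) thickness and,
in the multiple model, of age, sex and spherical equivalent:

    multiple:  VFS = θ1 / (1 + exp(b0 + b1·gcc + b2·age + b3·sex + b4·se))
    simple:    VFS = θ1 / (1 + exp(−θ3·(gcc − θ2)))

The form encodes three facts about perimetry in glaucoma: sensitivity
saturates at a plateau θ1 when ganglion cells are plentiful (functional
reserve), falls steeply once thickness passes a threshold, and never
leaves the instrument's detectable range. θ2 is the thickness at which
sensitivity has dropped to θ1/2; θ3 (per µm) sets the width of the
transition (a θ3 of 0.08–0.2/µm corresponds to a transition spanning a
few tens of µm, the physiologically sensible scale). With b2 = b3 = b4 = 0
the two forms are the same curve under θ2 = −b0/b1, θ3 = −b1; the test
suite checks this nesting numerically. Exponents are clipped at ±700
before exponentiation, which keeps predictions defined for arbitrary
covariates without changing any double-precision value.

Comparator families (linear, quadratic, cubic, broken-stick plateau) are
provided for R² comparison only; the broken-stick form is continuous,
zero below its thickness floor and linear above.

## Test-point geometry

The 10-2 grid is generated as all odd-integer degree pairs with
x² + y² ≤ 82, which yields exactly 68 points: 4 at eccentricity √2°, 8 at
√10°, 56 beyond. Field eccentricity converts to retinal distance through
a piecewise-linear map anchored at (1.67° → 0.5 mm), (5° → 1.5 mm),
(10° → 3.0 mm) and extended at 0.3 mm/° beyond 10°; the two innermost
rings instead use their directly published retinal locations (0.48 and
0.94 mm), which the generic interpolant misses by a few hundredths of a
millimetre — the published numbers win.

Ganglion-cell displacement is radial (polar angle preserved) with
magnitude interpolated from a configurable table: 0.60 mm at 0.48 mm
eccentricity and 0.55 mm at 0.94 mm (published values), decaying linearly
to 0 at the 3.0 mm circle. Only the two inner values are published; the
linear decay is this package's choice — it matches the qualitative
decline of the displacement with eccentricity and keeps all 56 remaining
points inside the 1.5–3.0 mm annulus, reproducing the 12/56 inner/outer
split and the 3/14 per-sector counts.

Sector numbering follows retinal quadrants for a right eye: 1 =
superior-temporal, 2 = superior-nasal, 3 = inferior-nasal, 4 =
inferior-temporal (sector 3 is pinned by the nasal-inferior-outer
convention; the remaining assignments are a documented package
convention). Field-to-retina inversion maps superior field to inferior
retina and temporal field to nasal retina; left-eye fields are mirrored
about the vertical meridian before mapping. Annuli are half-open
(r_in, r_out], so a locus exactly on a circle belongs to the inner of
the two rings; loci outside (0.5, 3.0] mm raise an error rather than
being dropped silently.

## Estimation

Fits minimise the residual sum of squares by Gauss–Newton iteration with
analytic Jacobians. A step that would increase the SSE is rejected and
retried with adaptive Levenberg–Marquardt damping (λ starts at 1e-3 on
first rejection, ×10 per rejection, ÷10 per acceptance), so accepted
iterations never increase the SSE. Convergence: relative SSE change
< 1e-10, at most 200 iterations — tighter than the 3-decimal reporting
precision of the reference estimates. Starting values are data-driven:
θ1 from the maximum observed VFS; θ2/θ3 from the median thickness and
0.1/µm; b0/b1 from a logit-linearised least-squares seed. If the default
start fails to converge, up to 10 seeded jittered restarts are tried and
the best-SSE converged fit wins (first index on ties). No parameter
bounds are imposed; a warning is emitted if θ1 leaves (0, 50] dB.

Uncertainty uses the standard asymptotic nonlinear-least-squares
covariance σ̂²(JᵀJ)⁻¹ with σ̂² = SSE/(n−p), and two-sided Wald p-values
from Student's t with n − p degrees of freedom (p = 6 multiple,
3 simple). Singular normal equations raise with a condition-number
diagnostic; a constant response is flagged non-identifiable.

## Diagnostics

* χ² goodness-of-fit: χ² = Σ(O−E)²/E over eyes, df = n − (number of
  fitted parameters), upper-tail p; large p (toward 1) indicates a good
  fit. The df convention is not externally documented for the reference
  analysis; n − p is the standard adjustment and the parameter count is
  an explicit argument so alternatives can be explored. Expected values
  ≤ 0.5 dB trigger a warning naming the eyes (terms are kept): the
  statistic divides by E, so near-floor expectations dominate it.
* Model-effect ANOVA: F = [(SST − SSE)/1] / [SSE/(n−2)], df = (1, n−2) —
  the regression-of-observed-on-predicted reading of "model effect".
  This convention is validated against the published per-area statistics:
  at n = 83, back-solving every published F through r² = F/(F+81)
  reproduces the published R² to its printed precision, which the p−1
  df convention does not.
* R² = 1 − SSE/SST with SST centred on the observed mean, so a
  biased-but-correlated predictor scores below 1.

Note the two diagnostics assume different error models: the χ² statistic
implicitly takes Var(O) = E, while the least-squares fit and ANOVA assume
homoscedastic noise.

## Synthetic cohorts

The generator reproduces the reference study conditions: 83 right eyes;
age ~ N(55.9, 11.9²) y truncated to [20, 90]; spherical equivalent
~ N(−3.8, 3.4²) D truncated to [−15, +6]; P(female) = 35/83; covariates
sampled independently (the reference cohort showed no significant
pairwise association). Per-area GCC thickness is drawn from a
two-component normal mixture — healthy N(95, 8²) with weight 0.4,
atrophic N(60, 12²) with weight 0.6, truncated to [20, 130] µm — chosen
so the sample spans the plateau, the transition and the floor of the
sigmoid; a single Gaussian sitting on the plateau would leave θ2/θ3
unidentifiable and make recovery tests vacuous. VFS is the multiple-model
prediction (published parameters as default truth) plus homoscedastic
Gaussian noise, clipped to [0, 40] dB; the clipped fraction is reported
in the table's metadata (≈7% under defaults).

The default noise SD is 5.9 dB, set by a one-off calibration: it is the
value at which refitting the default whole-field cohort reproduces the
reference whole-field R² of ≈0.72 (measured 0.727 ± 0.05 over 60
replicates). Under these defaults, 200-replicate recovery at n = 83
returns median θ1/b0/b1 within ~1% of truth with zero non-convergence.

What the generator does not emulate: spatial correlation between areas
(each area's thickness is drawn independently, whereas real atrophy is
regionally correlated), per-point 68-value fields (area means are
simulated directly), measurement floor effects in thickness, and the
variance-E noise the χ² statistic assumes — so the χ² p-values of
default synthetic fits are small even though the mean model is exactly
right, and passing recovery tests demonstrate estimator correctness, not
clinical realism. A variance-E noise mode is exercised separately in the
χ² calibration test, where the p-value distribution is uniform by
construction.

## Pipeline and filters

Record-level quality rules mirror the reference inclusion criteria:
perimetry kept iff fixation losses < 33% and false positives/negatives
< 20% (strict inequalities); OCT kept iff signal strength index ≥ 7/10.
Records lacking the fields pass with a warning; the two filters commute.
Reliability fields are accepted as fractions or percents only via an
explicit dialect flag — never auto-detected. The XLSX import adapter
requires an explicit source-header → canonical-column mapping, because
deposited spreadsheets carry their own headers. Pipeline bundles record
the seed, a config hash and library versions.

## Problem sizes in the test suite

The suite uses n = 83 cohorts (the study size) for recovery (200
replicates), n ∈ {83, 332, 1328} for the consistency check (12 replicates
each), 1000 replicates for the χ² calibration, and 20 datasets of n = 15
for the brute-force solver cross-check — sizes at which each property is
already sharply testable.

## Known limitations

* The displacement table beyond 0.94 mm eccentricity is a modelling
  choice, not published data; it is exposed as a configurable argument.
* The exact per-point-to-sector assignment cannot be verified beyond the
  group sizes and the inner/outer split.
* χ² df and the reference software's convergence tolerances are not
  documented; agreement with reference estimates is a tolerance target,
  not bit-exact.
* No mixed-effects structure across areas of the same eye; each area is
  fit independently, as in the reference analysis.
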