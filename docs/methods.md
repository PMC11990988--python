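# Methods

## The projection model

A DAD cube is a matrix A(t, λ) of absorbances (mAU) on a uniform time grid
(minutes) and an increasing wavelength grid (nm). The projection profile is
defined pointwise as

    P(t) = max over λ in [λ_lo, λ_hi] of A_corrected(t, λ),

with the per-time argmax wavelength recorded. At a peak apex the maximum is
attained at that compound's absorption maximum, so P reproduces each peak
exactly as the chromatogram at its λmax would; the projection therefore
"segments and reassembles" the cube at the compounds' λmax values without
altering any peak datum. Between peaks P rides the upper envelope of the
channel noise, which has two consequences documented below (noise pedestal;
inflated N).

The pointwise maximum was chosen over peak-wise stitching (detect peaks per
channel, then splice segments at each peak's λmax) because the two coincide
at every apex, but the maximum needs no prior segmentation, is deterministic,
and is monotone in the window: widening [λ_lo, λ_hi] can only raise P. The
default window is 205–450 nm: channels below ~205 nm are dominated by
mobile-phase absorbance and degrade quantitation; a "max-information" run may
use the full 194–450 nm range at a known cost in accuracy.

## Baseline correction

All seven estimators operate on a single channel y (one wavelength's
time trace) and return (baseline z, corrected y − z); cube correction applies
the chosen method independently to every channel. The conservation identity
corrected + baseline == input holds exactly because the corrected trace is
computed by subtraction.

**Whittaker core.** The PLS family solves
min_z Σ w_i (y_i − z_i)² + λ Σ (Δ^d z)² via the banded symmetric system
(W + λ DᵀD) z = W y (order d = 2 by default), in O(n·d²) time with no dense
intermediates; one step of iterative refinement recovers the ~6 digits the
raw factorization loses when λ is extreme (the system's condition number
grows like λ). A 5250-point channel solves in about a millisecond, so a full
5250 × 257 cube corrects in seconds.

**ALS** (default λ = 5·10⁴, p = 5·10⁻⁶): weights p above the running
baseline, 1 − p below. With p this small the baseline settles on the *lower
noise envelope*, roughly 2 SD below the noise mean — a deliberate property of
the published optimum, which the tests account for (a corrected channel
carries a ~2σ positive offset).

**airPLS** (λ = 5·10⁴, wep = 0.08, 20 iterations): weight 0 where y ≥ z,
exp(iter·|d_i|/‖d‖₁) below, with a `wep` fraction of points at each end
pinned to weight 1. Published optimal parameter sets list an asymmetry p for
this method; the published update rule has no such parameter, so it is
accepted for config compatibility and ignored.

**arPLS** (λ = 10⁷, ratio = 10⁻²): logistic weights from the mean and SD of
the below-baseline residuals; stops when the relative weight change falls
under `ratio`.

**MPLS** (λ = 10⁵, window = 40): a grey-scale opening (structuring element
2·window + 1 points) removes peaks narrower than the element; points whose
opening residual is within median + 3·MAD are treated as background (weight
1, others 10⁻³) and the Whittaker smoother is anchored on the opening.

**backcor** (order 4, s = 0.15, cost `atq`): the signal is rescaled to
[−1, 1]² and fitted on a Legendre basis; each iteration re-targets residuals
through a symmetric/asymmetric Huber or truncated-quadratic cost with
threshold s. Asymmetric costs ignore residuals above the polynomial, which is
what positive-going peaks require.

**LMV-RSA** (window = 100): block-wise local minima (plus the endpoints)
anchor a candidate baseline; anchors deviating from the interpolation of
their neighbours by more than median + 3·MAD are outlier peak feet, replaced
by interpolation iteratively; a centered moving average of the window width
smooths the result. The moving average is interior-only (shrinking edges
copy the input), so linear gradients are preserved exactly.

**SWiMA** (no parameters): cycles of min-clipping against an interior-only
moving average whose window sweeps 3, 5, …, n−1 points. Small windows strip
noise, large windows strip whole peaks; the interior-only average leaves
linear drift invariant, so once the peaks are gone a full cycle strips almost
nothing and the loop stops (relative stripped-area change < 10⁻⁴). A
strictly concave peak is stripped to its chord. Known limitation: strongly
*concave* broad backgrounds are slowly shaved toward their chord, and the
method is the slowest of the seven by an order of magnitude.

## Peak analysis

Detection runs on a pseudo-Gaussian smooth (three passes of an unweighted
centered moving average, default window 7 points ≈ a quarter of a typical
peak width): apex candidates are downward zero-crossings of the central-
difference first derivative, apex position is the smoothed argmax near the
crossing (noise-robust to well under one sampling step at SNR 100), and
borders are the flanking local minima, extended past minima that are not
significant (a lower smoothed value within the next window). Candidates must
clear slope, amplitude, height, width and area thresholds; the defaults
(min_height 5 mAU, others 0) suit projection profiles of major constituents.
Heights and all areas are measured on the raw, unsmoothed trace — smoothing
is a detection aid only, never part of quantitation.

Integration: PD assigns each peak the signal-above-zero trapezoid area
between its borders, so fused clusters split at the shared valleys and areas
sum exactly to the cluster total; TS subtracts the straight line joining the
two valley points (negative excursions clipped), making it immune to linear
local baseline error — TS is the recommended integrator. Gaussian and EGH
fits use the border-clipped segment with apex/half-width initialisation;
the EGH area is evaluated by adaptive quadrature over the model's support
(±20 decay lengths, clipped at the support boundary 2σ_g² + τ(t−t_R) = 0).
Fit failure marks the fit absent rather than raising. With τ = 0 the EGH is
exactly the Gaussian, and the symmetric fit's known bias on tailed peaks
(>2% area error at τ = 3σ_g) is asserted in the tests.

H′ (effective height) is the apex response minus the mean of the two valley
responses; the noise fluctuation N is the mean over configured peak-free
windows (defaults 1–2, 10.5–11, 32.5–33 min) of the detrended peak-to-peak
response; a peak is quantifiable when H′/N > 10 (with N = 0 every positive
peak counts).

## The EI objective and grid search

EI = ((P_N + P_D)/P_ALL) · ((A_N + A_D)/A_ALL) · 1/(P_B + 1) lies in [0, 4],
reaching 4 exactly when every detected peak is unaffected by noise
(H′/N > 10) and by drift, and no peak appears in the estimated baselines.
"Unaffected by drift" is operationalised as (H − H′)/H′ ≤ 5% — the source
never quantifies it; 5% of H′ keeps the criterion scale-free and is exposed
as `drift_tolerance`. P_B sums the peaks detected (same detection settings)
in the projected baseline and in the 210 nm channel baseline, without
deduplicating coincident artifacts. Areas are TS areas.

The λ grid is 20 points log-uniform on [1, 10¹⁰]. With more than two grid
parameters, pairs are optimised sequentially holding the rest fixed
("couple-by-couple"); failed corrections score EI = 0 and the search
continues; ties prefer the larger λ (smoother baseline). On simulated cubes
the sweep reproduces the expected structure: at λ ≈ 1 the baseline swallows
peaks (P_B > 0, EI ≪ 1); a broad mid-to-high-λ plateau attains EI = 4.

## Validation statistics and similarity

Normalization divides by the maximum response (valid because chromatographic
responses are non-negative with minima near zero). RSD uses the sample SD
(n − 1 — the source does not state the denominator). Linearity regresses
area on concentration (A = a + bC) by closed-form least squares; recovery is
(A_spiked − (m_i/m)·A_unspiked)/(c_control·b)·100 with the dilution factor
m_i/m applied to the unspiked area (the printed equation is typographically
ambiguous; the placement is configurable in principle via the arguments).

Peak matching pools all apex times, clusters them by single linkage (split
at gaps > rt_tolerance, default 0.2 min), anchors each cluster at its median
time, takes each sample's nearest in-tolerance TS area (0 when absent,
nearer peak kept with a warning on double mappings) and drops anchors
present in under 50% of samples. The reference fingerprint is the
coordinate-wise median. Zero-reference coordinates are excluded pairwise
from the ratio-based parameters (S_F′, S_R, M) with a warning; S_F, L and R
keep them. Cosine-type scores are clipped at 1 against float rounding.

Bias structure, as asserted in the tests: a proportional (+10%) error on the
strongest peak moves S_F and L far more than the same proportional error on
the weakest; a fixed absolute error moves S_F′ and M far more when it lands
on the weakest peak; S_R and R sit between. The two perturbation conventions
are both needed because under proportional perturbation the ratio-based
parameters are position-blind by construction.

## The synthetic generator

`simulate_cube` builds A(t, λ) = Σ_c EGH(t; H_c·s_c(λ), t_R, σ_g, τ)
+ baseline(t, λ) + ε with ε ~ N(0, noise_sd²) i.i.d. per cell, where s_c is
a sum of Gaussian absorption bands clipped at 1 (the unit band defines
λmax), and the solvent baseline is separable:
amplitude·exp(−t/time_decay)·exp(−(λ − λ_min)/wavelength_decay)
+ linear_drift·t — interference concentrated below ~210 nm, as a methanol/
acetonitrile gradient produces. Ground truth records each compound's λmax
and the trapezoid area of its pure trace at λmax on the simulation grid.

Default axes are 0–35 min at 2.5 Hz and 194–450 nm in 1 nm steps
(5250 × 257); the default five-compound mixture spans heights 60–250 mAU,
widths σ_g 0.06–0.13 min, tailing τ up to 0.06 min and λmax 207–310 nm.
noise_sd defaults to 0.05 mAU, the short-term noise scale of a modern DAD.
The generator does **not** emulate spectral realism beyond Gaussian bands,
gradient-dependent retention, detector drift correlated in λ, or matrix
interferences (distorted peak shapes) — so passing tests demonstrate correct
signal processing, not robustness to shape distortion, which projection
explicitly cannot repair.

Known noise-dependent limitation: between peaks the projection is the
maximum of ~250 noisy channels, a pedestal of roughly 2.8·noise_sd, while
under a peak only the ~20 in-band channels compete (~1.9·noise_sd). The TS
valley line therefore over-subtracts by ~1σ times the integration width.
At the realistic 0.05 mAU noise this is ≪1% of a minor peak's area; at 10×
that noise it reaches several percent of the smallest peaks. The same
mechanism inflates the projection's noise parameter N relative to any single
channel.

## Problem sizes and determinism

The test suite exercises full instrument resolution (5250 × 257) once, in
the end-to-end area-recovery and dominance checks; unit and property tests
use an 8-min, 31-channel cube and 1–2·10³-point profiles, which preserve all
the regimes that matter (steep solvent front, overlapping spectra, fused
peaks). All randomness flows through explicit seeds (generator specs carry
one; hypothesis suites are derandomized), so every run is bit-reproducible.
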