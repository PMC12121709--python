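# Methods

## Stimulus model

A trial is 1 s of motion at 120 Hz: 80 dots, alternating black/white,
uniform over the area of an annulus with inner radius 0.25° and outer
radius 8°, viewed at 880 mm on a 385 mm-wide screen. Dot angular
diameter at the fixation plane is 0.16°.

Retinal coordinates are degrees of visual angle, azimuth positive
rightward, elevation positive upward; polar angle runs counter-clockwise
from the right horizontal meridian in (−180°, 180°]. Disparity is
defined as right-eye minus left-eye azimuth, so crossed (near)
disparities are negative.

*Stereoscopic cue.* Each eye's dot images translate horizontally at
1.2°/s in opposite directions; disparity therefore changes at 2.4°/s and
dot size is constant. *Toward* motion makes disparity more crossed
(left-eye image moves rightward). The two printed speeds — 51.83 mm/s in
world units and 1.2°/s in retinal units — are not mutually derivable
from the viewing geometry, so the engine treats the retinal speed as
authoritative for stereoscopic frames and the world speed for
perspective/combined frames; both are carried in `MotionParams`.

*Perspective cue.* A single eye (the other is blanked) views dots whose
depth z changes at 51.83 mm/s; retinal position and angular diameter
follow from perspective projection from that eye's position (±31.5 mm
from the cyclopean axis; the interocular distance, 63 mm, is a
configurable default since only retinal speeds are fixed by the design).
Looming, density change and radial flow all follow from the projection;
no extra lateral translation is imposed. *Combined* presents the
perspective-projected stimulus to both eyes, so disparity changes arise
from the projection itself (≈ I·v/z² rad/s for midline dots, about a
tenth of the stereoscopic rate at these parameters).

*Re-seeding.* A dot whose cyclopean eccentricity leaves the annulus is
redrawn uniformly inside it — with zero disparity for stereoscopic
frames (fresh phase) or at its current depth for perspective frames. A
dot crossing the eye plane (z ≤ 0) is re-seeded at far depth and the
event logged. No fixed dot lifetime is imposed.

*Rotated control.* Every frame's retinal image is rotated 90°
counter-clockwise in both eyes (the direction is a convention; only
multiples of 90° are allowed). Rotation is an isometry of each eye's
image, so per-frame displacement magnitudes — and hence monocular motion
energy — are preserved exactly, while the stereoscopic condition becomes
opposite vertical motion in the two eyes with no 3D interpretation.

## Synthetic brain

### Vertex populations

Each vertex carries pRF eccentricity, polar angle, variance explained
(Beta(2, 8), mean 0.2), a tuning regime, a signed direction sensitivity
`s_v ~ N(0, s_scale²)`, bias coefficients (`g_ecc`, `g_rad`, `g_int`)
and a baseline `β₀` (0.35 % signal). Eccentricities are truncated to
[0°, 10°]. ROI presets encode the qualitative sign pattern of the
coarse-scale biases, not any measured magnitudes:

| ROI | vertices | ecc distribution | tuning | g_ecc (%/°) | g_rad (%) | s_scale |
|-----|---------:|------------------|--------|------------:|----------:|--------:|
| V1  | 400 | uniform-over-area 0.1–10° | retinal_2d | 0.06 | 0.05 | 0.10 |
| MT  | 180 | lognormal, median 3° | retinal_2d | 0.025 | 0 | 0.16 (HM) / 0.05 (NHM) |
| MST | 140 | lognormal, median 4.5° | retinal_2d | 0.03 | 0.15 | 0.10 |
| FST | 200 | lognormal, median 2° | percept_3d | 0 | 0 | 0.12 |

V1 is dense with a strong eccentricity gradient; MT's direction
sensitivity is concentrated near the horizontal meridian (a radial
*decoding* bias without a mean-BOLD bias); MST carries a positive HM
BOLD offset; FST is percept-tuned, flat in eccentricity, and foveally
concentrated (few vertices beyond 5°, so eccentricity splits there
routinely trip the <2-vertex skip rule, as intended). Vertex counts are
roughly half the per-participant counts implied by the reported
group-level degrees of freedom, chosen so a full session simulates in
about a second.

### Observers and percepts

Perspective and combined cues are perceived veridically by everyone.
Unrotated stereoscopic cues are veridical for stereo-pros and an
unbiased coin flip for stereo-strugglers (their deficit is modelled at
binocular integration, not as response noise). Rotated stereoscopic
stimuli yield no 3D percept. A lapse rate (default 0.02) flips the
button press, not the percept.

### Encoding equation and time series

Per-trial vertex amplitude:

    A(v,t) = β₀ + g_ecc·(ecc_v − ecc̄) + g_rad·1[HM] + d_eff·(s_v + g_int·(ecc_v − ecc̄))

`ecc̄` is the population mean eccentricity at creation. `d_eff ∈ {+1, −1, 0}`:
for `retinal_2d` vertices it is the true direction label in every
condition *including* rotated stereoscopic trials (rotation preserves
retinal motion energy — the mechanism behind the MT result); for
`percept_3d` vertices it follows the percept, hence 0 on rotated
stereoscopic trials and random for strugglers on unrotated ones (the
FST result).

The amplitude impulse train (onsets every 9 s: 1 s trial + 8 s blank, 40
trials filling a 360-TR run at TR = 1 s) is convolved with a canonical
double-gamma HRF (gamma shapes 6 and 16, undershoot ratio 1/6, peak
normalized to 1, 32 s support) — the design never states an HRF, only a
TR 6–9 averaging window, so the SPM-style canonical is used and is
configurable. Added to the signal: a per-vertex linear trend (end-to-end
SD 0.5), a slow sinusoid (period 120 s, amplitude SD 0.3), six
unit-variance random-walk motion regressors leaking with weights
N(0, 0.15²), a shared AR(1) global confound (SD 0.25), and AR(1)
observation noise (φ = 0.3, stationary SD 0.6). These magnitudes were
fixed once so that default-SNR single-trial decoding of the preset ROIs
lands in the 60–90 % range, leaving headroom for sensitivity tests in
both directions. The returned nuisance channels are the six motion
walks plus the global signal (vertex mean of the generated data).

## Single-trial extraction

Decoding path, per run: (1) high-pass at 1 cycle/40 s by projecting out
a discrete-cosine drift basis together with the mean — exact DC removal,
no edge ringing (a zero-phase Butterworth is available behind a flag);
(2) residualize against the six motion regressors and the global signal
(intercept included; collinear columns dropped with a warning); (3)
z-score across the run's 40 trials at each peristimulus lag 0–8
(degenerate SDs < 1e-12 produce zeros with a warning, not NaN); (4)
average the 6th–9th TRs after onset, read 1-based inclusive, i.e. 5–8 s
post-onset — four samples spanning the HRF peak. Ten runs concatenate to
the 400-trial session matrix (50 trials per direction × cue condition).
The stage order filter → nuisance → z-norm → window is pinned by a
regression test; swapping z-norm and averaging changes the result.

BOLD-level (`percent`) path, used by the bias diagnostics: global-signal
regression and z-normalization both remove the mean evoked amplitude
that these analyses measure, so this path regresses motion only, skips
z-normalization, and divides each trial's windowed response by the
windowed response of a unit-amplitude trial train passed through the
identical filter + regression operator. This calibration accounts for
HRF overlap between 9-s-spaced trials, filter attenuation, and
regression leakage; at zero noise it returns the generative % -signal
amplitudes to machine precision.

## Decoding

Linear maximum-margin classifier (SVC, linear kernel, C = 1; both
configurable), features standardized with training-fold statistics only.
Each of `n_boot` (default 5,000; tests and the pipeline default to
100–200 with correspondingly widened tolerances) bootstrap iterations
draws a balanced split: the test set gets `max(1, round(0.10 × min class
count))` trials per class; in the degenerate one-trial-per-class case
one trial goes to each set. The shuffled-label null refits the same
split with permuted *training* labels, keeping test labels intact. Each
bootstrap uses an independent child random stream, so results are
reproducible regardless of how many draws a split consumes. The two
monocular perspective conditions are decoded separately and averaged
element-wise across the paired bootstrap distributions.

## Bias diagnostics

Vertices enter the analyses with eccentricity in [0.2°, 8°] and VE >
0.05 (strictly greater). The eccentricity split assigns exactly 4° to
the *edge* group (the design's printed intervals share the endpoint; the
convention is documented and configurable). The HM wedge spans ±30°
around both the right (0°) and left (180°) horizontal meridians.
Decoding-accuracy bias equates vertex counts by subsampling the larger
group to the smaller on each of `n_resample` (default 500) draws and
reports 100 × (accuracy_A − accuracy_B) in percentage points, averaged
over draws; groups with fewer than two vertices are skipped with a
warning. BOLD-vs-eccentricity inference fits a participant-random-slope
mixed model (statsmodels MixedLM) and tests the fixed slope, reporting
Cohen's f² from nested OLS fits; with few participants the random-slope
variance can be weakly identified, so `method="auto"` falls back to the
exact signed-rank test on per-participant OLS slopes — both routes agree
in sign and significance on the package's simulations.

## Group statistics

Wilcoxon signed-rank (zeros dropped, average ranks for ties; two-sided
throughout) is exact by enumerating all 2ⁿ sign patterns for n ≤ 15;
Mann–Whitney U (pairs won + half-ties) is exact by enumerating all group
assignments for combined n ≤ 12; both use tie-corrected,
continuity-corrected normal approximations beyond their exact range.
Two-sided p-values double the smaller tail and cap at 1. The factorial
accuracy comparisons (cue × ROI with participant random intercept) are
provided at contract level over statsmodels MixedLM; the package's own
inferential guarantees rest on the exact rank tests.

## Orchestration and observer classification

`run_experiment` runs simulate → preprocess → decode → bias → group
stats per participant and session from one seeded YAML-serializable
config, writing TSV tables and a JSON summary validated against the
schema shipped in `stereomotion/schema/`. A participant is classified
stereo-struggler when stereoscopic accuracy does not exceed the upper
binomial 95 % bound around chance for their trial count (an explicit,
testable version of the qualitative grouping; the cut is configurable).
Participants without stereoscopic responses are excluded with a log
entry. The headline dissociation study simulates a stereo-pro cohort:
the percept-dependent rotation effect exists only in observers who have
the stereoscopic percept, so an all-pro cohort is the designed test of
that mechanism; strugglers merely dilute it.

## What the generator does and does not emulate

It reproduces the design arithmetic (8 motion types × 5 repeats × 10
runs, 360 volumes), pRF-structured encoding with injectable
eccentricity, radial and origin-of-motion biases, the
percept-vs-retina dissociation between tuning regimes, observer
heterogeneity, and fMRI-like noise (drift, motion, global, AR(1)). It
does not emulate spatial autocorrelation on the cortical surface,
vertex-to-vertex noise correlations beyond the global component,
nonlinear HRF effects, eye movements, pRF sizes (point pRFs only), or
any magnitude calibration to real scanner data. Passing tests therefore
validate the analysis logic and its sensitivity/specificity on a known
generative model — not claims about empirical effect sizes, which
require the original scans and are out of scope.

## Numerical choices and problem sizes

Seeds propagate through `numpy.random.Generator` children; identical
seeds give bitwise-identical outputs end to end. Degenerate inputs
(zero-variance lags, collinear regressors, empty vertex groups,
all-zero rank differences) produce warnings, documented fallbacks or
explicit errors rather than NaNs. Test and acceptance runs use reduced
sizes chosen to keep the full suite under a few minutes of CPU: 2–10
runs, 40–2,000 vertices, 25–200 bootstraps, 1–6 equating resamples;
recovery tolerances in the tests are set from the Monte-Carlo error at
those sizes.
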