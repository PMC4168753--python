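# Methods

This note documents the models behind each analysis stage, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Force-curve analysis

A force-distance curve records cantilever deflection d (nm) and piezo
extension z (µm) against time over one approach–dwell–retract cycle.
Force is F = k·d with the spring constant k in N/m, so forces come out
directly in nN; the default k = 39 N/m reflects the stiff etched-tip
cantilevers used for micro-Newton-range cell indentation.

**Segmentation.** The approach runs up to and including the first
attainment of maximum piezo extension; the dwell is the subsequent
contiguous run within a plateau tolerance (default 10⁻⁶ of the z range)
of the maximum; the rest is the retract. With a strict triangle (no
dwell), the single apex sample belongs to the approach.

**Baseline.** The pre-contact force baseline is estimated on the
approach prefix before force first exceeds 5% of the curve's force
range (with a small safety margin); when that prefix is uninformative —
a contact-free curve whose 5% level sits inside the noise — the first
20% of approach samples is used instead. Baseline statistics are
median/MAD so residual contamination by early post-contact samples
cannot inflate the detection thresholds. A fixed-fraction window alone
fails on deep indentations (a high-load curve spends ~90% of its
approach in contact), which is why the prefix rule exists.

**Contact point.** Contact is declared at the changepoint before force
exceeds baseline + 3 SD for at least 3 consecutive samples; the
reported contact sample is the last at-baseline sample before that
persistent rise, which makes the noiseless piecewise-linear case exact.
With the generator's 3 nN force noise and 400 nN/µm cell stiffness the
contact z is recovered within about one sample spacing.

**Rupture events.** After contact, the approach force is scanned for
decreases between consecutive local extrema exceeding
max(5 × baseline SD, 1% of the local pre-drop force). The pre-drop
force is the membrane rupture force. Events are reported largest drop
first; the earliest wins ties, and the earliest event defines the
penetration metrics. The relative term in the threshold matters because
a fixed absolute threshold either misses small drops at low force or
fires on noise at high force.

**Metrics.** Deformation extent = max(z) − contact z; penetration
depth = max(z) − z at the first rupture. Both use raw piezo extension
(not tip–sample separation), a unit convention documented here rather
than a physical claim. Hysteresis energy interpolates approach and
retract onto their merged z grid over the contact region and applies
the trapezoid rule to the force difference, in fJ (1 fJ = 1 nN·µm);
this is exact for piecewise-linear curves, invariant under time
reparameterization, and the retraction path starts at the apex sample
so no interval is extrapolated. Contact time runs from the contact
sample to the end of contact on retract, found by mirroring the
persistent-exceedance changepoint rule on the time-reversed retract;
a single "last sample above baseline" rule would latch onto noise
anywhere in the free retract tail and inflate short contact times by
tens of percent.

Out of scope by design: elasticity (Hertz/Sneddon) fitting, adhesion
analysis, cantilever calibration, drift correction.

## Calcium trace analysis

Traces are per-ROI means over pixels whose centers fall inside a 5 µm
circle at the indentation point (local responses) or an ellipse around
the whole cell (global responses); ROI placement is always an input,
never inferred.

The correction protocol is: (1) divide by the mean of the initial basal
window (default 10 pre-stimulus frames) so basal = 1; (2) divide out a
mono-exponential photobleaching decay fitted by log-linear least
squares to quiescent samples; (3) subtract the cantilever-reflection
component, modelled as linear in deflection resampled to frame times.
The original acquisition protocol corrected bleaching and reflection
against reference recordings of unstimulated cells; those references
are not part of this package's inputs, so both corrections here are
self-contained models fitted to the trace itself, and their failure
modes are documented below.

**Quiescent identification for the bleaching fit.** Three modes: an
exact mask; an anchor mask (the pipeline passes the pre-stimulus
frames) grown to all samples whose residual is consistent with the fit
within 2.5 robust SDs — anchor frames set the residual scale but are
not force-kept, so a spontaneous transient inside the anchor is
expelled; or, with no prior knowledge, iterative one-sided clipping of
positive residuals. The anchor mode exists because a stimulated cell
can spend most of its recording inside a transient (a global response
lasts ~10 s of a ~26 s recording), where a blind quiescent search can
lock onto the transient, while the pre-stimulus window alone is too
short to pin the decay rate over the whole recording (its extrapolation
error alone was enough to push noise peaks over the response
threshold).

**Reflection artifact.** Frames where |deflection| exceeds 5% of the
record's full swing count as contaminated; the underlying calcium
signal there is estimated by linear interpolation from the surrounding
clean frames, and the gain is the least-squares fit of the residual
against deflection. Fitting against this interpolated background keeps
a transient that overlaps the contact window from biasing the gain.
With fewer than 2 contaminated frames the gain is unidentifiable at
frame resolution and the trace is left untouched (the artifact is then
at most a single frame). Known limitation: a transient that peaks
inside the contact window and decays substantially before the first
clean frame violates the interpolation assumption and part of it will
be absorbed into the gain; the physical local-response geometry (signal
near its peak through probe release) satisfies the assumption.

**Noise.** Every contiguous 20-frame window outside sustained
excursions is fitted with a line; the linear portion is the window with
the smallest |slope|, and the reported noise pools (median) the
residual SDs of the flattest quartile of windows — a single 20-frame SD
carries ~17% sampling error, which would make the 4×noise threshold
itself noisy and produce both false responses and false spontaneous
flags. When transients break every contiguous run, a difference-based
fallback uses consecutive quiescent pairs (SD = robust SD of first
differences / √2). The excursion mask takes its noise scale from robust
first differences and its baseline from the lower cluster, and excludes
only runs of ≥ 2 consecutive supra-threshold frames: isolated high
frames are noise, and removing them would top-censor the estimate.

**Detection and quantification.** Responses are maximal contiguous
excursions above basal whose peak increase strictly exceeds 4 × noise
(with a 10⁻⁹ relative guard so float rounding at exact equality cannot
tip the comparison). Multi-peak excursions are split at interior local
minima below half of the larger peak. Amplitude = peak − basal;
duration = full width at half maximum with linear interpolation between
frames; amount = amplitude × duration, exactly, for every emitted
transient. A transient truncated by the recording boundary is flagged
partial and gets no duration or amount. Cells with a supra-threshold
excursion in the pre-stimulus window are flagged spontaneous and
excluded from downstream statistics.

In the manifest-driven pipeline a detected transient counts as a
*response* only if it peaks after the first contact and its FWHM is at
least 0.4 s: a single supra-threshold noise frame has an interpolated
FWHM of at most about one frame interval (0.345 s), so this floor
rejects single-frame spikes structurally while the shortest real
transients (≥ ~0.55 s) pass. The per-cell "amount" is that of the
largest-amplitude response, so a residual-artifact blip near contact
cannot displace the principal transient.

**Timebase alignment** cross-correlates the mean-subtracted trace with
the deflection envelope over integer frame shifts within ±max_lag;
flat inputs, or a best lag pinned at the search boundary, are an
alignment-undefined error.

## Response statistics

The decay rate α is the OLS slope of first-response-normalized
amplitudes against response onset time (abscissa in seconds, because α
is reported in s⁻¹); it is invariant under rescaling of the raw
amplitudes. For overlapping consecutive responses at short recovery
times, per-stimulation amplitudes are read as the maximum increase over
basal between one stimulation onset and the next, mirroring how
overlaid force/fluorescence records are read per indentation.

The recovery fit is nonlinear least squares of a·exp(−x·b) + c with
b > 0, initialized at c₀ = mean of the values at the two largest
recovery times, a₀ = min(y) − c₀, b₀ = 1 s⁻¹ — deterministic on
study-scale data; τ = 1/b. Fisher's exact test uses the two-sided
probability-mass criterion; Student's t is the equal-variance
two-sample variant (a config switch allows Welch), with zero-pooled-
variance inputs handled explicitly. No multiple-testing correction is
applied. In the pipeline's condition comparisons a degenerate 2×2
margin (all cells in both groups responded) reports p = 1.

## Synthetic data

The generator's defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
| --- | --- | --- |
| spring constant | 39 N/m | cantilever stiffness |
| low / high-load max force | 400 / 2800 nN | below / above rupture |
| rupture force (C2C12) | N(672, 100) nN, ≥ 100 | membrane rupture law |
| rupture force (primary) | N(516, 200) nN, ≥ 100 | membrane rupture law |
| frame interval | 345 ± 10 ms | camera timing |
| duration law | 0.98·contact + 0.60 s | local transient FWHM |
| recovery constant τ | 2.0 s | amplitude recovery |
| decay rate at rt → 0 | −0.06 s⁻¹ | amplitude decay scale |
| global peak delay | 2 s after release | micro-injury response |
| global refractory | 30 s | no re-response window |
| micro-injury seal time | 50 s | membrane resealing |
| relative noise | 0.02 | fluorescence noise |

Force curves are piecewise linear in z: zero force to the contact
point, a 400 nN/µm loading slope, for high loads a single force drop
(45% of the rupture force) at a rupture force drawn from the truncated
normal law and snapped to the sample grid (so the recorded pre-drop
force is exactly attained by one sample, removing a half-sample bias in
the ground truth), then a dwell plateau and a scaled-down unloading
line that reaches zero at the contact point, clipped below the approach
so the hysteresis area is non-negative. Gaussian force noise enters
through the deflection.

Transients are piecewise-linear pulses: a linear rise from contact
onset to the peak at maximum deflection, a near-flat shoulder (0.4 s,
declining 3%) so the sampled maximum sits on a flat top rather than a
cusp, then a linear decay sized so the FWHM is exact. FWHM, not shape,
is the calibrated quantity. The camera free-runs relative to the
stimulation trigger: frame times start at a uniform random phase within
one interval. Without that phase the stimulation onset is nearly
commensurate with the 345 ms grid, the phase-dependent FWHM
interpolation error stops averaging out, and the duration regression
acquires a spurious intercept bias — a generator artifact, not a
property of the measurement.

Consecutive local amplitudes decay linearly in time with a per-series
slope α(rt) = a·exp(−rt/τ) + c of the recovery time rt (a = −0.06 s⁻¹,
τ = 2 s, c = 0, floor 5%). This law makes the measured decay-rate
statistic follow the stated exponential dependence exactly. A
step-recovery law of the form A·(1 − (1 − r)·exp(−rt/τ)) was considered
and rejected: with it the OLS decay slope inherits a 1/(contact + rt)
factor from the stimulation period, so the fitted dependence of α on
rt is not a pure exponential and the recovered τ is biased low. In the
rt → ∞ limit amplitudes are equal under either law.

Global transients start at probe release, peak 2 s later, last 10 s
FWHM, have log-normal amplitude spread (σ_log = 0.25 — a stand-in; the
source experiments report no distribution for global amplitudes), are
independent of contact time, and are suppressed within the 30 s
refractory window. Traces are assembled as
baseline · exp(−bleach·t) · (1 + Σ pulses) + gain·deflection + noise;
in generated experiments the artifact is driven by the cell's actual
(noisy) curve deflection, contact-aligned to the schedule, so the
artifact has the same rupture-drop fine structure the analysis will
regress against.

Image stacks place a Gaussian bright spot (σ = 0.6 µm) at the
indentation point on an elliptical cell mask (local mode) or raise the
whole mask (global mode), with per-frame multiplicative illumination
flicker (1%) on top of pixel noise — without flicker, whole-cell
averaging over ~700 pixels would reduce noise so far that even the
diluted local spot would cross the 4×noise threshold, which real
illumination stability does not allow.

Multi-cell experiments draw each cell's response from
Bernoulli(responder probability of its condition): control and vehicle
0.8 (local) / 0.9 (global), Ca²⁺-free and Gd³⁺ 0, and the PLC inhibitor
Et-18-OCH₃ with control probabilities but amount scaled to 0.4. The
control probabilities are round values consistent with the reported
high C2C12 response rates; they are not published numbers.

What the generator does not emulate: cell-to-cell mechanical
heterogeneity (one stiffness slope), spatial calcium diffusion, motion
or focus drift, adhesion on retract, and realistic cell morphology.
Passing tests therefore demonstrate correctness of the measurement
chain under the stated statistical structure, not robustness to every
artifact of live-cell data.

## Problem sizes and determinism

Every stochastic routine takes a NumPy `Generator`; identical seeds
give bit-identical outputs, and the acceptance script derives one
independent child stream per target from its `--seed`. The replication
studies use 204 low-load stimulations (34 per contact-time level) for
the duration law, 20 replicates × 12 series for the recovery constant,
200 high-load curves per cell-line preset for the rupture force, and 20
cells per condition for the pharmacology pattern — sizes at which the
standard errors are a few times smaller than the calibrated effects,
chosen so the checks are informative rather than borderline.

## Known limitations

* The bleaching and reflection models are deliberately minimal
  (mono-exponential; linear in deflection). Slow non-exponential
  bleaching or a nonlinear reflection component would leave residual
  structure that the noise estimator partially absorbs.
* Durations of transients shorter than ~2 frame intervals carry large
  interpolation scatter (the 0.1 s contact-time level in the duration
  study has a duration SD of ~0.1 s); the regression handles this by
  averaging, not by resolving individual short transients better than
  the frame rate allows.
* The reflection gain is estimated per trace from few contact frames;
  its sampling error leaves a residual artifact of a few percent of
  basal at contact frames. The response-duration floor keeps this from
  creating false responses, but quantities read *at* contact frames
  inherit the residual.
* `fisher_exact` and `students_t` validate inputs and handle degenerate
  cases in this package but delegate the core computation to
  scipy.stats; the test suite checks them against exhaustive
  enumeration and the closed-form pooled-variance formula.
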