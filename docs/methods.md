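# Methods

This note documents the models, defaults and numerical choices behind
`perisim`, and what the simulation-based validation does and does not
show about real perimetry.

## Stimulus scale and calibration

Stimulus intensity is expressed as attenuation relative to the display
maximum: `dB(L) = 10·log₁₀(L_max/L)`, with `L_max = 120 cd/m²` at gray
level 255 and values clamped to the reportable range 0–49 dB. The
1 cd/m² black background is carried as metadata only — the dB reference
is the display maximum, not a Weber increment over background, because
the device convention binds 0 dB to 120 cd/m².

Calibration tables are piecewise-linear in gray level between measured
knots; the loader requires knots at gray 0 and 255, strictly increasing
gray levels and non-decreasing luminance. Inverse lookup
(`gray_for_luminance`) returns integers only — fractional gray levels
are not renderable — choosing the gray whose interpolated luminance is
nearest the target (ties to the lower gray).

**Nominal vs achieved.** The staircase operates on nominal commanded dB;
every logged event also records the gray-quantized *achieved* luminance.
The simulated observer responds to the nominal level. This is
deliberate: on the shipped two-knot linear curve an 8-bit ramp has a
0.47 cd/m² luminance step, so stimuli dimmer than ~24 dB all quantize to
gray 0 — a realistic display would use a nonlinear (gamma) ramp near
black, which users supply as a measured CSV. Keeping responses on the
nominal grid keeps threshold estimation exact at 1 dB resolution while
the log preserves display realism for analysis.

## Test patterns

The published protocol constants are counts and spacings (T-24: 50
points, 6° apart, central 24°; T-10: 68 points, 2° apart, central 10°);
the exact coordinates are reconstructed:

- **T-24 / S-24**: lattice `|x|,|y| ∈ {3, 9, 15, 21}` restricted to
  eccentricity ≤ 24° (52 points), minus the two temporal points
  `(±15, ±3)` adjacent to the physiologic blind spot → 50. The
  exclusions sit on the temporal side of the eye under test, so the OS
  grid is the x-mirror of the OD grid.
- **T-10**: lattice `|x|,|y| ∈ {1, 3, 5, 7, 9}` with `x² + y² ≤ 82`,
  the unique symmetric odd-lattice cutoff yielding exactly 68 points.

Quadrants (ST/SN/IN/IT) are resolved per eye (temporal = +x for OD, −x
for OS); the central region is eccentricity ≤ 12° (12 points on the
T-24), pericentral beyond. "Central 12°" is read as an eccentricity
disc rather than a square half-width; with this lattice the two
readings select the same points except at (9,9)-type corners, and the
disc is the convention used for region statistics. Anchors sit at
(±9,±9) on the T-24 and (±3,±3) on the T-10 — mid-eccentricity seeds
that propagate well both inward and outward. Location ids are row-major
from the superior-left corner, so event logs are comparable across
runs.

The expected blind-spot center is (±15, −2)° with a 3° search radius;
mapping probes a 7×7 grid at 1° spacing with 0 dB stimuli and takes the
centroid of non-responses (falling back to the expected center, with a
failure flag, if everything is seen).

## Threshold strategy

Each location runs a double-crossover staircase: 4 dB steps (dimmer
after seen, brighter after not-seen) until the first response reversal,
2 dB steps until the second reversal, which terminates the staircase.
The estimate is the last seen level — chosen for determinism and
convention; the estimator is config-visible so alternatives can be
swapped. Bound handling: two consecutive misses at 0 dB terminate
floored (estimate 0); two consecutive hits at 49 dB terminate ceilinged
(estimate 49).

Against a noiseless responder (seen iff level ≤ threshold) the
staircase recovers every integer threshold from every integer start
level within 2 dB (exhaustively verified over the 50×50 sweep; measured
maximum error 1 dB). Termination is guaranteed: the coarse phase is
monotone toward the threshold and the fine phase ends at the first
reversal after at most a handful of 2 dB steps.

Anchors start at 25 dB (configurable) — just below the dim side of the
healthy ~32 dB regime, so anchors approach threshold from the visible
side. Non-anchor locations unlock once a lattice neighbor (Chebyshev
distance ≤ spacing) finishes and start at the estimate of the nearest
finished neighbor, ties resolved by the mean of tied estimates rounded
half-to-even. The real device's propagation rule is proprietary; this
growth-pattern scheme is the documented stand-in and is isolated behind
the plan interface.

## Reliability machinery

- **Fixation losses** (Heijl-Krakau): 0 dB probes at the mapped
  blind-spot center, one per 10 threshold trials per eye. Gaze jitter in
  the observer model is what makes these nontrivial — with perfect
  fixation, a zero guess rate and a true blind spot the FL count is
  exactly 0.
- **False positives**: stimulus-free response windows (1 per 10 trials);
  the trigger probability is the observer's guess rate, and the measured
  rate converges to it binomially. The classical catch-trial design is
  used because the device's own FP procedure is not described.
- **False negatives**: a finished, previously-seen location is re-probed
  at a luminance offset from its last seen stimulus (1 per 20 trials).
  The default offset is **+0.5 cd/m² (brighter/easier)**: a dimmer
  stimulus could be missed legitimately and cannot indicate inattention.
  The device description reads "0.5 cd/m² lower intensity"; a `literal`
  mode implements that wording unchanged for comparison rather than
  guessing the intent.

Catch trials never feed staircases; all indices are pure recounts of the
event log.

## Session, timing, replay

Eye/location interleaving is uniform-random over the currently ready
(location, eye) pairs, driven by the session seed; "tests both eyes
simultaneously" is read as within-one-session, not dichoptic stimulus
simultaneity. Timing defaults (stimulus 200 ms, response window
1500 ms, inter-stimulus 400 ms) are engine choices — the device's
constants are unpublished — so simulated durations are config-dependent
outputs, not validated quantities; per-eye duration is total time
divided by eyes tested. A safety cap of 10× the expected presentation
count guards against non-terminating configurations.

Every presentation is an event (sequence, simulated time, eye, kind,
location, nominal dB, achieved gray/luminance, response, latency,
Goldmann III 0.43° metadata, background). `replay` re-runs the
staircase rule over the logged responses, verifies the logged levels
exactly, recounts catch trials, re-derives blind-spot centers and
durations, and must reproduce the original result byte-for-byte — the
result is a pure function of the log.

## Observer model

Detection follows a cumulative-Gaussian frequency-of-seeing curve
`p = guess + (1 − guess − lapse)·Φ((t − s)/σ)` with slope σ in dB —
the conventional psychometric form in perimetry simulation (logistic or
Weibull would serve equally; Gaussian keeps the σ parameter in dB).
At s = t the detection probability is exactly ½ for any σ, including
the near-deterministic limit. Gaze jitter displaces the effective
stimulus location by a bivariate-normal offset per trial. Inside the
blind spot the surface is *absolute*: only guesses produce responses.
Response times are lognormal and feed only duration accounting and
suprathreshold summaries.

Healthy cohorts draw hill-of-vision surfaces with peak ~ N(34, 1) dB and
slope ~ N(0.2, 0.05) dB/deg (floored at 0.05), default ψ parameters
σ = 1 dB, guess = lapse = 1 %, gaze jitter 0.5°. These constants put
the *true* T-24 global mean near 31 dB with central > pericentral in
every member; glaucomatous members add 1–3 circular scotomas (radius
2–6°, depth 5–30 dB). They are simulation fixtures chosen to emulate
the healthy regime, not fitted claims about patients.

What the simulations do **not** capture: learning and fatigue effects,
media opacities, pupil size, response-time dependence on stimulus
visibility, spatial correlation of sensitivity fluctuations, and the
true (proprietary) seeding strategy. Passing recovery tests therefore
demonstrates internal correctness of the engine under its stated
observer model, not clinical equivalence with the hardware device.

## Normative model and indices

Normative models store per-location mean and population SD over a
simulated cohort, with provenance (cohort size, regime, seed) embedded
and surfaced in reports as `normative: simulated`. SDs are floored at
1 dB: integer-dB thresholds can collide by chance at single locations
in small cohorts, and a zero SD would make probability grades
infinitely confident. A cohort of identical members is rejected
outright.

Known estimator bias: the last-seen estimate sits in [t−1, t] for a
noiseless observer, so normative means sit systematically ≈ 1 dB below
the generating continuous surface; the bias is common to all locations
and cancels in total deviation (measured field and norms share it).

Total deviation is measured minus normal mean; the general height is
the k-th best TD with k = max(1, ⌊0.15 n⌋) — the 7th-best location on
the 50-point grid, the standard pattern-deviation convention — and
pattern deviation subtracts it, making PD invariant to uniform shifts.
Probability grades use the one-sided normal tail z = TD/SD at
5/2/1/0.5 % (empirical percentile tables can be plugged in place of the
normal approximation). MD is the 1/σ²-weighted mean of TD and PSD the
matching weighted dispersion; "MD" is read as *mean* deviation (the
standard index) wherever source material expands it otherwise. The
grayscale map uses ten fixed 5 dB bins indexed 0 (darkest, 0–4 dB) to 9
(lightest, 45–49 dB).

## Validation sizes

The shipped validation runs are sized for a single CPU: the staircase
sweep is exhaustive (2 500 deterministic runs); stochastic threshold
recovery uses 50 seeded full binocular T-24 sessions (flat 32 dB
observer, σ = 1 dB, 1 % guess/lapse) with the mean absolute error bound
at 1.5 dB; the sector-ordering check uses a 40-member healthy cohort of
full sessions; FP convergence uses 10⁴ probes against a 3 % guess rate.
`scripts/acceptance.py` re-runs the same computations at comparable
sizes (30 sessions / 30 cohort members) from a single `--seed`.
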