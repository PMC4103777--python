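# Methods

This note documents the models, algorithms, defaults and design choices
behind `cardioetho`, and what the synthetic-data generator does and does
not emulate.

## Synthetic recordings

### Arterial pressure

The generator works in the beat domain. Beat *n* at time *t_n* has
systolic pressure

    S_n = SABP₀ + Δ(t_n) + A_LF sin(2π f_LF t_n) + A_R sin(2π f_R t_n) + ε_n

where Δ(t) is an optional piecewise-linear offset (used for pressor ramps;
it shifts systolic and diastolic pressure together, i.e. it is a MABP
offset), A_LF/f_LF model Mayer-wave vasomotor modulation (defaults
3 mmHg at 0.4 Hz), A_R/f_R respiratory modulation (2 mmHg at 1.5 Hz) and
ε ~ N(0, 1 mmHg). The pulse interval follows a lagged linear baroreflex
feed-forward

    PI_{n+1} = 60000/(HR₀ + ΔHR(t)) + G · (S_{n+1−lag} − SABP_ref(t)) + η_n

with gain G in ms/mmHg (default 1.5, lag 1 beat, η ~ N(0, 1 ms)). The
reference pressure tracks the slow offset Δ(t), so a pressor ramp does not
saturate the reflex. Intervals are floored at 30% of the local mean as a
physiological guard.

Each cycle [t_n, t_{n+1}) is rendered as an exponential-family runoff from
S_n to D_n over the first 70% of the interval followed by a raised-cosine
upstroke over the last 30% that peaks exactly at t_{n+1}. The runoff uses
exp(−τu²) (τ = 3) rather than exp(−τu): the quadratic argument gives the
rendered peak zero slope on both sides, which keeps the waveform maximum
on the true beat time; with the plain exponential the asymmetric peak
biased parabolic peak refinement by ~2 ms. The truth table (beat time,
S_n, D_n, PI_n) is returned with the trace and is never altered by
rendering.

Baseline levels — HR 360 bpm, SABP 125 / DABP 85 mmHg (MABP ≈ 100 mmHg),
f_R 100 cpm — are rat-typical modelling assumptions; the study protocol
this pipeline addresses reports no baseline numbers, only that groups did
not differ at baseline.

### Plethysmography

Chamber pressure is a sinusoid with configurable breathing rate (time-
varying via a piecewise-linear profile; the instantaneous phase is the
integral of the rate) and per-breath peak-to-trough deflection, plus a
square calibration pulse of known injected volume at a recorded time, plus
broadband Gaussian artifact (SD = 3× the deflection) inside movement
epochs. In cohorts, the movement epochs are the animal's grooming bouts,
so the grooming-exclusion rule of the ventilation stage is exercised
against genuinely corrupted signal.

### Ethograms

Behavior is a semi-Markov chain over the 20-code repertoire (12 grooming-
cluster codes, 8 others), with exponential dwell times (means 3 s for
grooming items, 8 s otherwise) and a block-structured embedded chain:
grooming states chain to other grooming states with probability 0.6, and
non-grooming states enter the cluster with probability 0.08. A dose effect
multiplies all transition probabilities *into* grooming states and
renormalizes; multipliers 1, 3 and 6 give long-run grooming occupancies of
about 7%, 30% and 56% (computed analytically from the stationary
distribution of the embedded chain weighted by dwell), spanning control
levels to hypergrooming. The analytic occupancy is the oracle for the
scoring tests.

### Cohorts

`generate_cohort` builds one recording set per animal from a design
mapping: group definitions with effect knobs (pressor ramp and its peak
time, HR step, respiratory-rate step with recovery, tidal-deflection step,
baroreflex-gain scale, SABP-modulation scales, grooming multiplier) and
per-animal seeds spawned from a master seed. Animals get log-normal
grooming propensities (SD 0.25 on the log scale — the random-intercept
structure the Poisson model assumes) and Gaussian baseline jitter (SABP
4 mmHg, HR 15 bpm, f_R 5 cpm, deflection 5%) for realistic between-animal
variance. `STUDY_DESIGN` encodes the four-arm layout (vehicle, low dose,
high dose inside the target, high dose outside) with n = 4 per arm and
effects only where the emulated study found them: the high-dose inside arm
carries a +30 mmHg ramp peaking at 50 min, +40 bpm sustained tachycardia,
+30 cpm/+25% ventilatory rise recovering by 40 min, 0.6× baroreflex gain,
doubled SABP modulation amplitudes and a 6× grooming multiplier; the
low-dose arm grooms (3×) but has no autonomic effects. n = 4 per arm is a
deliberate scale-down from a typical n = 8 cohort; the planted effects are
large relative to the jittered between-animal variance, so the pattern of
significance is stable at this size.

What the generator does **not** emulate: waveform morphology detail
(dicrotic notch, respiratory pulse-pressure variation), measurement drift,
pharmacokinetics, non-stationary variability within epochs, or behavioral
time-of-day structure. Passing tests therefore demonstrate correctness of
the analysis chain on signals with known structure, not robustness to
every artifact of real recordings — the artifact filter and movement
exclusion are exercised only against the artifact classes the generator
produces.

## Beat extraction

`find_peaks` with a refractory distance of 60000/max_HR ms (default
max 600 bpm) and a minimum prominence (default 10 mmHg) locates systoles;
peak time and value are refined by a three-point parabola, making beat
times sub-sample accurate. Beat *n* occupies the window between the
diastolic minima flanking its systole; DABP is the window minimum and MABP
the window time-average (not DABP + PP/3 — the directly-averaged value is
what an analog MABP channel would record). PI is the interval *ending* at
the beat, the convention assumed by the sequence method. The artifact
filter removes beats whose PI or SABP deviates more than 50% from an
11-beat running median; it never reorders or recomputes intervals.

## Variability

Beat values are interpolated onto a 10 Hz grid. The default interpolant is
a cubic spline rather than a linear one: at rat heart rates the beat
series samples the respiratory band at only ~4 samples per cycle, where
linear interpolation's sinc² roll-off loses ~35% of HF power; the spline
keeps band powers essentially unbiased (this is also the common choice in
HRV software). Linear interpolation remains available.

The PSD is a Welch average (Hann window, 512-sample ≈ 51.2 s segments,
50% overlap, per-segment linear detrend, density scaling), and band powers
are trapezoidal integrals with interpolated band edges so that disjoint
bands tile the axis exactly and a band covering [0, Nyquist] equals the
total power. The summary's variance is the time-domain sample variance of
the resampled series, making the Parseval check (|∫PSD − σ²|/σ² < 0.1)
meaningful. Band edges (LF 0.20–0.75, HF 0.75–3.0 Hz) are rat conventions,
configurable, and echoed in every output. Analyses require ≥ 60 s of
beats; the pipeline default window is the 10-min epoch starting 10 min
after injection.

## Baroreflex sequences

Defaults d_SABP = 1 mmHg, d_PI = 1 ms, min_len = 3 beats, lag = 1 beat,
r ≥ 0.85 follow common sequence-method practice; all are configurable and
echoed in reports. Runs are maximal (overlapping qualifying stretches
merge into the longest run, so nothing is double-counted), and the pooled
gain is the unweighted mean of accepted slopes. A NaN pulse interval (the
first beat, or a gap left by the artifact filter) produces NaN differences
and therefore simply breaks runs. With zero accepted sequences the report
flags `no_sequences` instead of inventing a slope.

## Ventilation

Breath cycles are delimited by rising zero-crossings of the 0.5–15 Hz
band-passed, mean-removed chamber signal; any cycle overlapping an
exclusion epoch (grooming bouts, the calibration pulse) is dropped. The
breathing rate is computed over the summed duration of the retained
complete cycles — not the raw retained wall time — so edge-clipped cycles
do not bias f_R. V_T applies the barometric correction factor F; for body
310.15 K, chamber 298.15 K, 760 mmHg, vapor pressures 47.1/23.8 mmHg,
F = 14.4685 (hand-verified before implementation). Vapor pressures
default to the Magnus saturation approximation, with chamber humidity 50%
(configurable; the protocol gives no humidity). V_E = f_R × V_T holds by
construction. In the pipeline, a closed-chamber window fully occupied by a
hypergrooming bout would leave nothing to analyze; the window is then
extended (up to 4×) until at least 10 s of clean signal remains, mirroring
what an experimenter does when a measurement window is unusable.

## Grooming score and Poisson model

Scoring is instantaneous time-sampling: probes every 15 s (configurable),
scoring 1 when any grooming-cluster code is active, summed over 5-min
windows (12 windows per hour). The longitudinal model is a Poisson GLMM
with a full group × window fixed-effect structure and a per-animal random
intercept, fitted by maximizing the marginal likelihood with 20-node
Gauss–Hermite quadrature (analytic gradient; L-BFGS-B with σ_b bounded in
[0, 5]). Standard errors come from a finite-difference observed-
information matrix; at the σ_b = 0 boundary the σ row is excluded from the
inversion and the fit reduces — verified against a plain Poisson GLM — to
fixed-effects maximum likelihood. Group contrasts are Wald tests of
group + group×window against the reference at each window; the headline
"group significant" flag applies a Bonferroni correction over the 12
windows. All-zero groups are reported as boundary flags, not errors.

## Dyad analysis

For each ordered behavior pair (a, b), the 2×2 table
{a→b, a→¬b, ¬a→b, ¬a→¬b} over the window's successions is tested with the
plain (uncorrected) chi-square against independence at 1 df; 3.84 is the
upper-5% critical value. Pairs with any expected cell below 1 are skipped
and flagged. No multiple-testing correction is applied by default (an
optional Bonferroni flag exists), matching standard neuroethological
flowchart practice. Flowchart edges are drawn only for significant dyads
with observed > expected: a deterministic A→B→C cycle makes the reverse
successions significantly *anti*-associated, and drawing those would turn
every cycle into a clique. Self-successions cannot occur in the event
stream and the diagonal is ignored.

## ANOVAs

The two-way repeated-measures analysis is the classical mixed-design
decomposition: group is tested against subjects-within-groups, time and
group×time against the within-subject residual. Strict balance (full time
grid per animal, equal group sizes) is required — no imputation — which
matches the fixed epoch grid of the protocol. No sphericity correction is
applied by default; a Greenhouse–Geisser option exists behind a flag.
Post-hoc comparisons are pairwise t-tests per time (RM design) or pooled-
MSE t-tests (one-way), Bonferroni-adjusted over the whole comparison
family. The implementation is verified against loop-based brute-force sums
of squares on all designs up to 4×4×4 and against an independent
mixed-ANOVA implementation.

## Pipeline

Epochs are half-open [start, end) in seconds from injection; defaults are
a 2-min baseline ending at injection, 2-min windows starting at 5, 20, 40
and 60 min, a 10-min variability window at 10 min, a 10–30 min baroreflex
window and four 5-min dyad windows over the first 20 min (the protocol
does not fix their placement; the first 20 min is where grooming activity
concentrates). Hemodynamic and ventilatory measures are analyzed as deltas
from each animal's baseline. All outputs are plain CSV plus a DOT file per
group and a provenance block (package version, seed, config hash); two
runs with the same config and seed produce byte-identical report
directories. Group significance flags come from the Bonferroni-protected
post-hoc pair (one-way tests additionally gated on the omnibus F), so the
family-wise false-flag rate per measure stays near the nominal 5%.

## Numerical and degenerate-input conventions

Flat or too-short signals raise typed errors (`InsufficientDataError`)
naming the requirement; invalid parameters raise `ParameterError` listing
every violation (config validation is itemized). Chi-square tests skip
rather than divide by small expectations; ANOVA F is flagged undefined
when the error mean square is zero; the Poisson fit reports boundary
conditions explicitly. Seeds: every generator is a pure function of
(params, seed); cohort per-animal seeds are spawned from the master seed
via `SeedSequence`, so adding animals never reshuffles existing ones.
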