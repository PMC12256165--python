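# Methods

This note documents the measurement conventions, the synthetic cell
model, the statistical ladder and the numerical choices behind
`obephys`.  Units are fixed internally — mV, pA, ms, MΩ, pF — with sweep
time grids stored in seconds; every formula below is stated in those
units.

## Measurement conventions

**Test pulse (R_s, R_i, C_m).**  The membrane test is a 10 ms, −10 mV
voltage-clamp step from a −60 mV holding potential at 50 kHz.  The
baseline current is the pre-step mean; the step window spans
[onset, onset + duration) so the off-transient is excluded.  R_s comes
from the peak deflection, R_i from the steady-state deflection with
I_ss taken as the mean over the final 20% of the step (the membrane time
constant of these high-impedance cells through the pipette,
τ' = R_s·R_i/(R_s+R_i)·C_m, is ≲ 0.2 ms, so a 10 ms step settles
completely).  C_m is the trapezoidal charge from the sampled peak
(inclusive) to the step end, divided by ΔV, with no extrapolation of the
charge missed before the sampled peak.  Two consequences are worth
knowing: the steady-state estimator returns R_s + R_i (≈ R_i when
R_s ≪ R_i, the usual ~1% overestimate at R_s ≈ 8 MΩ, R_i ≈ 870 MΩ); and
the transient-charge estimator converges, as the sampling rate grows, to
C_m·(R_i/(R_s+R_i))², not to C_m — an intrinsic ~2% attenuation from
access resistance at these values, quantified exactly by the analytic
circuit model in the test suite.

**Resting potential** is the mean over the first 5 s of an I = 0
recording and is excluded (reported missing) when the trace contains any
spike, spikes being detected exactly as in train analysis.  No
junction-potential correction is applied anywhere (the recordings the
pipeline targets were reported uncorrected, ~13 mV).

**Spike detection** finds contiguous regions with V > 0 mV; the spike
time is the time of the region maximum, so inter-spike intervals run
peak to peak.

**Single-spike features** are measured on the first sweep of a 10 ms
step ladder that crosses 0 mV *within* the step window.  The trace
(200 kHz) is smoothed with a 20-point (100 µs) sliding boxcar before
central-difference differentiation.  The 10 V/s threshold criterion is
applied to the smoothed derivative as a strict inequality, scanning
backwards from the peak to the last non-exceeding sample and taking the
next one — robust to early noise blips.  Width at half height uses the
midpoint between V_thresh and V_max with linear interpolation between
samples (at 200 kHz this changes whh by < 5 µs).  The boxcar is centred;
edge windows shrink symmetrically.  If several spikes fall in the step,
the first is analysed.  The optional phase-plane "bump" flag marks a
secondary local maximum of dV/dt on the rising phase, at least 5 V/s
prominent and clearly below (< 95% of) the main rise — the signature of
an axonal initiation site; flagging is advisory only, cells are never
dropped automatically.

**Train statistics.**  CV uses the sample (n−1) standard deviation; the
convention is configurable (`ddof`).  IF and SAA input–output slopes are
ordinary least squares (slope + intercept, intercept not forced) over
sweeps from the first suprathreshold step up to and including the first
sweep reaching 80% of the maximum spike count — the fit-range rule is
interpreted on spike counts, not currents.  CV, SFA and SWA are reported
from the sweep nearest 1.5× rheobase, ties broken toward the higher
current, missing when no sweep lies within 50% of the target.  Per-spike
widths inside trains use each spike's own local 10 V/s threshold, since
later spikes ride on accumulated depolarisation.  The fAHP window runs
from the first spike's peak to the next spike's threshold time or the
last in-step sample, whichever is earlier.

**mAHP** is measured on the point-wise mean of the sweeps that fired
exactly one spike per pulse (10 of 10); the amplitude is V_hold minus
the minimum of the mean trace within 250 ms after the train ends,
reported positive.  **Sag** is quantified per step as
(V_hold − V_ss)/(V_hold − V_sag) with V_ss the mean over the last 10% of
the step and V_sag the step minimum; the index at −100 mV is linearly
interpolated in V_ss between the bracketing steps (or taken from a step
within 2 mV of the target).  A ladder that never brackets −100 mV is
flagged and the interpolated value reported missing.

## The synthetic cell

The generator's purpose is recovery scoring, so its design priority is
*exact* ground truth rather than biophysical richness.

Subthreshold dynamics are a leaky integrator
τ_m·dV/dt = (E_L − V) + R_i·(I − w)/1000 with τ_m = R_i·C_m/1000 ms and a
current-based spike-triggered adaptation variable w (increment b per
spike, exponential decay τ_w), integrated by forward Euler in a numba
kernel.  Holding current pins the inter-protocol baseline at −60 mV.
Membrane noise is additive Gaussian per sample on the subthreshold
voltage (scaled by √(2·dt/τ_m) so its stationary amplitude matches the
nominal `noise_sd`); there is no synaptic noise, matching recordings
made in synaptic blockers.

Spikes are pasted stylised waveforms, not emergent: a triangular
rise/fall from threshold to peak and down through threshold to the reset
(threshold − fAHP depth), with the rise slope set by the nominal maximal
dV/dt and the fall length set by the requested half-width.  All vertices
are snapped to the sampling grid.  This makes the sampled maximum land
exactly on the analytic peak and keeps both half-height crossings on
pure linear segments, so the extractor's interpolated V_max, spike time
and whh reproduce the declared values exactly — the generator's
spike-time/amplitude/width ledger is a machine-precision oracle for the
train statistics (IF, CV, SFA, SAA agree to ~1e−13; SWA to ~0.5
percentage points, because per-spike thresholds inside trains are
estimated, not declared).  Per-spike amplitude decrement and fractional
width growth emulate amplitude and width adaptation.  With the default
width growth, later spikes are *wider*, so synthetic SWA is negative —
the physiological direction — whereas recorded populations have been
reported with positive mean SWA; nothing downstream depends on the sign.

Depolarisation block has no quantitative definition to borrow, so it is
emulated, not modelled: above a per-cell current ceiling pasted spike
amplitudes collapse to just above threshold (below 0 mV), which the
V > 0 detector reads as the spike count falling to zero; step ladders
stop one sweep past the ceiling, as an experimenter would.

Three protocols are built analytically rather than through the ODE, each
to give an exact oracle:

- **Membrane test:** the closed-form current response of the
  R_s–(R_i ∥ C_m) circuit, with the transient evaluated on the grid from
  the step onset.  Current noise is scaled from the voltage noise
  through R_i.
- **mAHP train:** pasted spikes at the ten pulse times; after the train
  the trace is exactly V_hold − A·exp(−t/τ_AHP), with
  A = 0.25 mV/nS × `ahp_conductance` (a stylised linear mapping chosen
  to put the default 1–3 mV amplitude range at 4–12 nS).  The trough of
  the mean trace is A at the train end by construction.  This protocol
  is generated noise-free: the post-train minimum is a noise-biased
  statistic (the minimum of n noisy samples sits ~σ√(2 ln n) below the
  true trough), and adding measurement noise would contaminate the
  oracle rather than test the estimator.  Sweeps can be forced to miss
  one spike to exercise the 10-spike exclusion rule.
- **Sag steps:** each hyperpolarising step is a double exponential
  V_ss + (V_hold − V_ss + A)e^(−t/τ_m) − A·e^(−t/τ_sag) whose
  coefficient A is solved by bisection so the *grid* minimum equals the
  target V_sag exactly.  The per-cell ground-truth index is
  s = 1/(1 + 0.01·`sag_conductance`), constant across steps (so the
  interpolation at −100 mV must return s); the default 8.7 nS gives the
  population-typical 0.92.  The ladder descends in −10 pA steps until
  V_ss passes −100 mV.

Spontaneous cells are pacemakers: the I = 0 trace carries pasted spikes
at ~4 Hz with small jitter; silent cells sit at E_L plus noise.  A cell
is spontaneous when its pacemaker drive pushes the resting trajectory
past threshold.

**Cohort defaults are the study conditions.**  Population draws centre
on the recorded values: R_i ~ N(870, 130) MΩ, C_m ~ N(20, 3) pF,
threshold ~ N(−34.5, 1.5) mV, peak ~ N(37, 3) mV, whh ~ N(0.36, 0.03) ms,
fAHP depth ~ N(25, 2) mV, mAHP amplitude 1–3 mV, sag index ≈ 0.92,
spontaneous fractions (0.13, 0.47, 0.40) for the 5-week, 9-week and
resident groups, sensory-deprivation (occlusion) effects as additive
shifts to spike peak (+3.5 mV) and maximal dV/dt (+40 V/s).  The
adaptation defaults (b = 25 pA, τ_w = 200 ms, ceiling 120 pA) were set
so that evoked trains land in the recorded regime — maximum spike counts
near 10–15, SFA in the 40–70% band, CV near 0.4 at 1.5× rheobase — and
are not revisited per experiment.  Sampling rates are 50 kHz everywhere
except the single-spike protocol's 200 kHz.

One property of the *statistic* (not the simulator) surfaced during
validation: SFA compares the first and last *completed* ISI, so near
rheobase a strong adaptation increment silences the train mid-step and
the would-be long final interval never completes — measured SFA then
*falls* as adaptation rises.  Monotonicity of SFA in the adaptation
increment holds whenever the train persists to the step end, and the
property test asserts it in that regime (100 pA).

What the generator does not emulate — and hence what passing recovery
tests do not show about real data: channel noise and bursty pacemaking,
biphasic (axon-bearing) waveforms, true conductance-based AHP/sag
interactions with spiking, electrode drift and partial-compensation
artefacts, and any dependence of spike shape on stimulus history beyond
the stylised adaptation rules.  Recovery results certify the
*extractors* against traces whose ground truth is known, not the
biological fidelity of the cell model.

## The statistical ladder

Normality is assessed with the D'Agostino–Pearson omnibus test when
n ≥ 8 and Shapiro–Wilk below that ("sufficiently large" is not
quantified anywhere authoritative; 8 is the smallest n scipy's omnibus
test accepts).  Data failing the battery are screened by the fraction of
variance a fitted normal leaves unexplained, computed as 1 − R² of the
ordered data against the quantiles of a normal fitted by mean/SD — a
documented Q–Q surrogate for an unpublished in-house criterion, not a
claim of equivalence.  If more than 10% is unexplained, the transform
ladder tries log10, √(x+1), 1/x and x+1 in that order (positivity
required where needed, with the +1 shift as the escape), accepting the
first that passes the battery; otherwise the analysis proceeds on pooled
mid-ranks — the Akritas rank-transform approach to a non-parametric
two-factor design.

One-way comparisons use ANOVA + Tukey when every group passes the
battery (a group with n < 3 forces the non-parametric branch), else
Kruskal–Wallis + Dunn; Dunn's z statistics are tie-corrected and
Bonferroni-adjusted over all pairs.  Two-factor comparisons use a
classical two-way ANOVA with **Type II** sums of squares (cell counts
are unbalanced; the choice is recorded in every report so deviations
from other software's conventions stay auditable), with Šidák-adjusted
(1 − (1−p)³, computed via expm1/log1p to survive tiny p) sham-vs-occluded
contrasts within each maturation level using the ANOVA residual
variance.  The full ladder holds its size: over 2000 null simulations of
a balanced 3 × 2 design (n = 10 per cell, a size chosen to keep the
calibration comfortably affordable at ~15 ms per fit), the measured
type-I error at nominal 5% is ~4–6%.

Fisher's exact test is two-sided by the minimum-likelihood rule (sum of
all margin-fixed tables no more probable than the observed one) — the
convention of the commercial packages this battery mirrors, and the
comparability-critical choice.  The 2×k Freeman–Halton extension
enumerates column fills recursively in log-space with an
configurable bound on the enumeration size; it reduces exactly to the
2×2 case.  Degenerate (zero-margin) tables return p = 1 by convention.
Spearman correlation uses exact permutation p for n ≤ 9 and the t
approximation above.  The pooled-variance t test also accepts
(mean, SEM, n) summaries so printed group statistics can be re-tested.

## qPCR

Efficiency comes from OLS of Ct on log10(dilution), E = 10^(−1/slope) − 1
(slope −3.3219 ⇒ E = 1, perfect doubling; non-negative slopes are
flagged).  Fold changes use the classic 2^(−ΔΔCt): technical replicates
averaged on the Ct scale, ΔCt = Ct_target − Ct_housekeeping per sample,
ΔΔCt referenced to the mean control ΔCt, fold = 2^(−ΔΔCt).  The method
assumes E = 1 even though measured efficiencies typically differ
slightly; an efficiency-corrected variant (per-gene log2(1+E) weighting)
is provided but off by default, for fidelity to the standard method.
Control-group mean ΔΔCt is zero by construction, and a common plate
offset cancels exactly.  Whether the control reference should be the
mean control ΔCt or the mean control fold is ambiguous in common usage;
both are implemented (`normalise="dct_mean"` default, `"fold_mean"`
alternative) and the choice is recorded in the output.

## Determinism and problem sizes

Cohorts are generated from a spawned `numpy` SeedSequence per cell, so a
(spec, master seed) pair reproduces byte-identical traces, feature
tables and reports; distinct seeds give distinct cohorts.  The
acceptance script scores 50 recovery cells (R_s ∈ [5, 10] MΩ, 0.1 mV
noise) and 2000 ladder calibrations — about a minute on one CPU.  The
feature-table CSV round-trips doubles bit-exactly (written at %.17g,
read with round-trip float parsing); missing features are explicit
nulls, never zeros.

## Known limitations

ABF/NWB ingestion is an interface hook only (delegating to pyabf/pynwb
when installed); the supported interchange format is the CSV/JSON sweep
layout.  Mixed-effects designs are out of scope: a repeated-measures
factorial question is approximated by the fixed-effects two-way family
and labelled as such in reports.  Biphasic-cell handling stops at the
advisory phase-plane flag.  Pacemaker analysis stops at the
spontaneous/silent dichotomy — no rate or pattern statistics.  The sag
and mAHP generators are stylised (see above): they validate extraction,
not channel biophysics.
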