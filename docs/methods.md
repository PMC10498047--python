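# Methods

This note documents the models, estimators and numerical choices behind
`circabeam`, the defaults that matter, and what the synthetic-data tests do
and do not establish about real recordings.

## Data model and conventions

Recordings are per-fly beam-crossing counts at 1-min cadence (the native
DAM resolution), carried as integers until smoothing so that binning
conservation is exact. Zeitgeber Time (ZT) alignment is metadata
(`zt0_offset`, minutes from recording start to the first lights-on), never
inferred from the data: recordings and light regimes are independent
records. Phases are reported in decimal ZT hours on [0, 24), with 24 h
mapping to 360°.

Light regimes tile the 1440-min cycle with constant or linear segments.
The skeleton photoperiods place 30-min pulses starting at dawn and ending
at dusk (SPP), or extend one pulse into a 6 h block contiguous with dawn
(aSPP-1: ZT00–06 + ZT11:30–12:00) or dusk (aSPP-2: ZT00:00–00:30 +
ZT06–12). The ramp is linear in time — the simplest monotone interpolant
between the stated endpoints — rising from a non-zero nadir at ZT00 to the
peak at ZT12 and back; a stair-quantized variant (`steps:`) is available
for incubators that approximate ramps discretely. Intensity units are
labels (µW cm⁻² or lux), never converted; a display-only constant
(≈0.57 µW cm⁻² per lux for a broad-spectrum white source) is provided.

## Savitzky–Golay smoothing

Startle bursts at discrete light transitions recur at exact 24 h intervals
and would dominate any periodogram. They are suppressed by Savitzky–Golay
least-squares smoothing with three named presets: (2, 251 min) before the
entrainment gate, (2, 81 min) for evening-peak finding, and (1, 41 samples
on 15-min bins) for peaks under ramped cycles. Frame lengths are counted in
samples of the series' current bin width. Boundaries use reflection
padding, which avoids edge transients that would corrupt first/last-day
phase estimates. The filter is exact for polynomial inputs up to its order
and linear; both properties are tested against a brute-force per-window
polynomial-fit oracle.

## χ² periodogram

For a trial period of *K* bins the series is folded into *K* columns and

  Q_P = Σ_h n_h (M_h − M̄)² / (SST/N),

with per-column counts n_h and means M_h, grand mean M̄, and total sum of
squares SST over all N bins. Under an iid null E[Q_P] = K−1 and Q_P is
asymptotically χ²(K−1), which supplies the significance line; the line is
Bonferroni-corrected across the trial-period grid (α = 0.05 by default,
uncorrected available by option). The default 20-min periodogram bin makes
the grid contain 23.67/24.00/24.33 h exactly — the two grid neighbours of
24 h that define the entrainment window. The peak is the significant period
maximizing Q_P − sig (the same quantity reported as *rhythmic power*);
ranking by raw Q_P would bias the peak toward long periods because the χ²
baseline grows with K. Bin width, α, correction and period range
(default 16–32 h) are all configurable.

**Smoothing-aware significance line.** Applying the χ²(K−1) line to
SG-smoothed data is badly anticonservative: smoothing correlates
neighbouring bins, the folded column means become serially correlated, and
pure noise acquires "significant" peaks (measured: >80% of smoothed
noise-only flies). Because the SG kernel is known, the null autocorrelation
of the smoothed-then-rebinned series is computed exactly from the kernel's
autocorrelation; the column means of a fold then form a circulant-correlated
Gaussian vector, and the null of Q_P is a weighted sum of χ²₁ variables
whose weights are the non-constant circulant eigenvalues (obtained by FFT).
The significance line is the Satterthwaite moment-matched scaled-χ² upper
quantile of that distribution, and reduces exactly to χ²(K−1) for iid
input. Measured familywise error on smoothed null series: ≈0.7% at nominal
5%; on raw white noise ≈1–2% (Bonferroni over a correlated grid is
conservative by construction — the guarantee is ≤ α, not = α).

## Morlet wavelet spectrum

Daily period estimates use the continuous Morlet transform (ω₀ = 6) over a
log₂-spaced 16–32 h period grid at 50 voices per octave, computed with
PyWavelets' complex Morlet (bandwidth chosen to match the standard
e^{iω₀t}e^{−t²/2} wavelet). Power is the bias-rectified spectrum |W|²/scale
normalized by series variance; rectification reduces the measured ridge
bias on pure sinusoids from ≈+1% to ≈−0.3%. The cone of influence uses the
standard Morlet e-folding relation (coi period ≈ 0.73 × distance to the
nearer edge). Each complete 24 h cycle contributes one ridge: the period of
maximal coi-masked, time-averaged power within the cycle (rows with <25%
valid coverage excluded; a fully coi-covered cycle yields no estimate).

## Entrainment verdicts

**Step-function gate** (`classify_skeleton`): SG(2, 251) smooth → 20-min
mean rebin → χ² periodogram with the smoothing-aware line → entrained iff
the significant peak ∈ [23.67, 24.33] h; free-running outside; arrhythmic
without a peak. The gate is scale-free (invariant to uniform count
scaling). A deliberate, documented property: under regimes with discrete
transitions, a clock-arrhythmic fly that startles is *behaviourally*
rhythmic at exactly 24 h, and the gate reports that rhythm (unit-tested).
Classification-fidelity validation therefore runs under constant darkness,
where the gate measures clock state alone.

**Ramped cycles** (`classify_ramp`, first match wins):

1. *arrhythmic* — no significant periodogram peak and no wavelet ridge
   (median per-cycle ridge power below 0.05 in variance-normalized units;
   calibrated on simulated cohorts where noise-only flies measure ≈0.005
   and weakly rhythmic flies ≈0.06–0.13);
2. *entrained* — daily wavelet periods from the sixth cycle onward all in
   [23.5, 24.5] h (a deliberately wider band than the periodogram window,
   matching the wavelet's larger estimator variance; the final cycle is
   excluded as edge-contaminated), |net peak-phase drift| ≤ 30 min/cycle
   over those cycles, and periodogram peak in [23.67, 24.33] h;
3. *free-running* — monotone directional drift exceeding the threshold, or
   a significant peak outside the window;
4. otherwise *relative coordination*.

The drift statistic is the least-squares slope through the unwrapped
per-cycle dominant-peak phases (15-min bins, SG(1, 41), circular peak
search) — a first-to-last difference would be dominated by single-cycle
peak jitter. The 30 min/cycle threshold is ≈2 sd of that slope estimator's
noise for a genuinely locked fly at typical DAM count rates, and half the
drift of a τ = 25 h free-runner; it, the bands, and the ridge threshold are
all config-exposed (`RampCriteria`). For loss-of-function clock mutants,
"rhythmic" means any significant periodogram peak or detectable wavelet
ridge (`is_rhythmic`).

## Phase extraction

Cohort profiles average per-fly day-means first, then take across-fly mean
and s.e.m. The *evening peak* is operationalized as the tallest smoothed
local maximum in a ZT06–ZT15 window, excluding bins within 30 min after any
discrete transition (startle guard); per-day phases over the last five
entrained days are combined by circular mean (one estimate per fly; a
per-fly profile-peak mode exists as an alternative). The release-day phase
is the dominant circular peak on the first full cycle after release, on
15-min binned SG(1, 41)-smoothed data.

## Statistics

Rayleigh p-values use the standard finite-n-corrected approximation
p = exp(√(1+4n+4(n²−R_n²)) − (1+2n)). The V-test statistic is
u = R cos(θ̄−μ₀)√(2n) with a one-sided normal upper tail; μ₀ always comes
from outside the tested sample (for phase control, the circular median of
the entrained phases — the angle minimizing mean circular absolute
deviation, ties broken toward the circular mean). All circular quantities
are rotation-invariant (property-tested).

The 4PL dose–response fit uses multi-start Levenberg–Marquardt least
squares (data-driven starts covering both slope signs plus seeded jitter;
best RSS wins; non-convergence is flagged, never silently dropped). The
dose axis is raw intensity in µW cm⁻² (log-dose by option). The flat-line
ANOVA is the extra-sum-of-squares F test; when the data hold fewer distinct
doses than the 4PL has parameters the curve saturates the per-dose means,
so the effective model dimension is the number of dose levels — with the
three-intensity design this makes the test the exact one-way F test
whenever the dose means are monotone. The residual conservatism (measured
type-I ≈3% at nominal 5%) is inherent to the monotone sigmoid class, which
cannot chase non-monotone noise patterns.

Wilcoxon rank-sum tests are exact for the smaller sample ≤ 25 without ties,
else tie-corrected normal approximation; the reported W is the
Mann–Whitney U of the first sample (the R convention), and tests are
two-sided by default. Kruskal–Wallis uses the tie-corrected H;
Bonferroni-corrected pairwise rank tests feed an insert–absorb compact
letter display (groups sharing a letter do not differ significantly).

## The simulator: what it emulates, and what it does not

Each fly carries a phase φ (hours on the 24 h circle) advanced per minute:

  dφ = dt · (24/τ) · (1 + ε · g(φ) · I_norm),  g(φ) = cos(2πφ/24).

g encodes the continuous action of light with the empirically required sign
structure — acceleration at subjective dawn, deceleration at subjective
dusk — as the smallest smooth kernel with those signs. Under constant
light the closed-form realized period is τ/√(1−(εI)²): longer than τ, and
monotone in both gain and intensity, which is the substrate for the
dose–response analyses. Discrete lights-on transitions can additionally
fire an instantaneous jump prc_amp·sin(2π(φ−18)/24): delays in the early
subjective night, advances in the late night and at dawn; lights-off steps
do not reset. Counts are inhomogeneous Poisson at 1-min resolution —
small non-negative integers with the right variance scaling for the
rank-based downstream tests — from

  rate = base_rate · waveform(φ) · e^(−κ·I_norm) + startle_amp · e^(−Δt/decay),

with a two-bump von Mises waveform (morning bump at phase 0.5 h, dominant
evening bump at 11 h; baseline 0.15; base rate 2 counts/min, a typical DAM
activity level), exponential bright-light masking (κ = 0 except in masker
mode), and startle bursts (8 counts/min decaying with a 4-min constant,
active for 60 min after a transition) modelling the brief lights-on
activity bursts seen in DAM data.

Fly categories: *entrained_locked* (τ = 24, no light action — a clock
locked to the zeitgeber), *oscillator* (τ = 24.5, ε = 0.3: locks to 24 h
cycles through the parametric action alone), *free_running* (ε = 0),
*relative_coordination* (either a gain too small to lock, giving modulated
unidirectional drift, or — the variant the classifier validation uses —
period segments alternating 23.5/24.6 h every 3 cycles, producing the
unstable daily periods that define the category), *arrhythmic* (flat
waveform), and *masker* (flat waveform with strong masking, so activity
tracks light and peaks at the intensity nadir). Ramp-experiment cohorts are
simulated with a 10-day burn-in under the entraining regime, emulating
rearing under the ramps: flies enter the recording at their steady-state
phase relation. The emergent entrained phase of oscillator flies under the
default ramp places the dominant activity peak near ZT19–20, in the falling
phase of the ramp.

All randomness flows from one explicit integer seed per fly (recorded in
the truth output); identical seeds give bit-identical recordings.

The generator is deliberately minimal. It does not emulate: within-fly
slow drifts of τ or activity level, sleep-bout structure or ultradian
rhythmicity, death/escape artifacts and beam failures (beyond flagged
rows), inter-fly parameter heterogeneity beyond the seeded Poisson noise,
or any molecular clock state. Passing tests therefore establish that the
estimators and decision rules are correct and calibrated for
Poisson-noise phase-oscillator data at realistic count rates — not that
the fixed thresholds are optimal for every real genotype or recording
condition; the thresholds are exposed precisely so they can be re-examined
on real data.

## Problem sizes and numerical conventions

Validation cohorts use 32 flies per class, 9–12 cycles (ramp) or 10 days
(DD/LL) at 1-min resolution, matching common experimental practice; null
calibrations use 500 replicates against exact binomial 99% bounds.
Report bundles are diffable directory trees (CSV with fixed float format,
sorted-key JSON, optional PNG); re-running a config byte-identically
reproduces every CSV, and the resolved config with all seeds is embedded in
each bundle. Degenerate inputs are defined, not special-cased: a
zero-variance series yields an all-zero periodogram with no peak; a flat
smoothed day yields "no qualifying peak" rather than an arbitrary phase;
empty cohorts and malformed monitor rows raise named errors.
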