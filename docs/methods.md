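# Methods

This note documents the models, defaults, and numerical choices behind
`sleepphys`, and what the synthetic-data tests do and do not establish
about real recordings.

## Synthetic sessions

The generator produces every input modality with known ground truth, at
the acquisition scales the pipeline targets: 2-s scoring epochs, 1 kHz
EEG/EMG, 10 frames/s calcium imaging, 100 Hz (demodulated) photometry,
10 kHz patch-clamp sweeps. One master seed per session feeds named
substreams (`hypnogram`, `eeg`, `emg`, `calcium`, `photometry`, `psp`),
so adding a generator call never shifts the draws of another stream and
identical seeds give byte-identical outputs.

**Hypnogram.** A first-order Markov chain over (W, N, R) per 2-s epoch.
The default transition matrix gives mean wake and NREM bouts of ~2 min,
mean REM bouts of ~1 min, forbids direct W→R transitions, and exits REM
only to wake — rodent light-phase statistics with stationary distribution
≈ (0.455, 0.455, 0.091). A perturbation schedule (e.g. the 30 s on / 90 s
off sweeping-rod pattern used for sleep deprivation) forces the chain to
wake during on-phases; the chain continues from the forced state, which
produces the intended dense wake–sleep transitions.

**EEG/EMG.** Each EEG channel mixes three independent unit-RMS Gaussian
noise streams band-limited to delta (0.5–4 Hz), theta (6–9 Hz) and
broadband (0.5–25 Hz), with per-state amplitude envelopes equal to the
square roots of the configured power weights — defaults W (1, 1, 2),
N (4, 1, 1), R (1, 4, 0.5). EMG is 10–100 Hz noise with power weights
W 4.0 vs 0.1 in both sleep states (~6× RMS contrast); real EMG
wake/sleep amplitude ratios are not standardized, so this contrast is a
free parameter of the generator. Envelopes are smoothed with a 0.5-s
raised-cosine so epoch boundaries cross-fade: scoring features must
reflect state, not stitching artifacts. The cross-fade is also the main
source of scoring error, concentrating misclassifications in the boundary
epochs.

**Calcium.** Per cell, events are an inhomogeneous Poisson process whose
rate (events/min) depends on the current state; the default population is
57% NREM-active, 16% REM-active, 27% wake-active at 5:1 preferred/other
rate contrast (5 vs 1 events/min). Events carry log-normal magnitudes
(median 1, σ = 0.3) and are convolved with a single-exponential kernel
(τ = 1.5 s at 10 Hz, GCaMP6f-scale — chosen so the deconvolution oracle is
analytic), on a flat baseline with Gaussian noise (SD 0.05).

**Photometry.** The isosbestic channel is baseline × exp(−t/τ_bleach)
(τ = 1200 s) plus a shared <1.5 Hz motion artifact (RMS 0.02) plus sensor
noise; the signal channel is an affine transform (gain 2.0, offset 0.5) of
the same bleach-plus-artifact, plus the calcium transient (default: a
0.2-amplitude double-exponential at every NREM-bout onset, reflecting an
NREM-active population) and independent noise. Keeping the artifact below
the 2 Hz analysis low-pass means the correction step must actually remove
it by regression, not filtering.

**PSP sweeps.** Flat baseline plus a difference-of-exponentials kernel
(rise 0.5 ms, decay 10 ms), normalized analytically to unit peak and
scaled to the requested amplitude, starting at stimulation onset +
latency, plus Gaussian noise. Rise ≥ decay is rejected (the kernel would
be non-positive).

## Scoring

The spectrogram uses a Hann-tapered 5-s window left-aligned to each 2-s
epoch onset (trailing partial windows dropped, so epoch count is
deterministic); Hann tapering limits leakage between the delta and theta
bands. Power is one-sided density, so integrating over frequency recovers
the windowed variance (Parseval, tested on white noise).

EMG is summarized as RMS of the 10–100 Hz band-passed signal per 2-s
epoch (band-passing is the default because raw RMS is dominated by DC
offsets on real amplifiers; `emg_band=None` gives raw RMS). The decision
rule is EMG-first: wake above the EMG threshold, then REM above the θ/δ
ratio threshold (default 1.0), then NREM. The automatic EMG threshold is
a deterministic two-component split of log EMG RMS (1-D 2-means
initialised at the 10th/90th percentiles); it errors on near-constant
features rather than guessing. Post-smoothing relabels single-epoch
islands flanked by identical states and converts REM directly after wake
to wake; both toggles mirror standard rodent scoring practice and a
sparse manual-override list is applied last. Short bouts below
`min_bout_s` are absorbed into the *preceding* bout (tie-break chosen for
determinism), and adjacent same-state bouts re-merged, so bout tables
always tile the session.

Relative delta divides per-epoch delta power by the *session-mean* total
power (0.5–25 Hz, matching the EEG analysis band); this makes the measure
exactly invariant to global gain and comparable across epochs.

## Calcium events

ΔF/F is (F − mean)/mean over the whole session. Deconvolution is a
pool-adjacent-violators non-negative AR(1) inversion with fixed
γ = exp(−Δt/τ): the isotonic projection of the trace onto the cone of
AR(1) responses to nonnegative inputs, i.e. the sparsity-free core of
fast online deconvolution algorithms. It was chosen over a full
sparsity-penalized deconvolver because a noiseless kernel inverts exactly
(tested), the event-magnitude scale stays interpretable, and no opaque
dependency is introduced. Contiguous supra-threshold runs of deconvolved
activity merge into single events (summed magnitude, timestamped at run
onset); the threshold defaults to 3× a MAD-based noise estimate from the
AR(1) innovations. Manual artifact review is replaced by this threshold
plus an exclusion-window interface.

Events are assigned to the epoch containing their onset (half-open
[onset, onset+2 s)), which makes the conservation identity exact: summed
over states, AUC/min × minutes equals total event magnitude.

Cell classification: NREM-active requires NREM AUC to be the strict
maximum *and* N–W index ≥ margin (default 0.2); REM-active analogously;
wake-active requires both indices ≤ −margin; otherwise unclassified. The
margin rule is a documented stand-in for expert curation of the index
plane; cells whose session covers any state for under 1 min (configurable)
are flagged unclassifiable rather than guessed — a 30-min Markov session
misses REM entirely often enough that analyses should apply this
inclusion rule before interpreting class fractions.

## Photometry

The low-pass is a zero-phase 4th-order Butterworth applied
forward–backward (no phase distortion of transient timing). The 405→465
fit includes an offset term by default (gain-only behind a flag): with an
offset the correction removes *any* shared affine artifact exactly in the
noiseless case (tested to 1e-6). ΔF/F uses the fitted signal as F₀ and
errors if F₀ approaches zero rather than dividing. Smoothing is a moving
average of one output period (200 ms; the window length is a free
parameter) followed by decimation to 5 Hz. Bootstrap CIs everywhere are
percentile CIs over 1000 seeded resamples of trials/snippets.

## PSP quantification

Baseline mean and SD come from the 10 ms before stimulation (sample SD,
ddof 1). The SD gets an epsilon floor (1e-9 of the sweep's full scale) so
noiseless synthetic sweeps with a real deflection are detected — a strict
>2×0 rule would be vacuous. The extremum is the maximum for depolarizing
potentials and the minimum for inward currents; amplitude is signed
relative to baseline. The 20%/80% crossings are found on the rising phase
walking back from the peak, with linear interpolation between samples for
sub-sample accuracy; rise time is their separation and onset latency is
the baseline intersection of the chord through them, t₂₀ − (t₈₀ − t₂₀)/3,
minus the stimulation onset. On a linear ramp of duration T this gives
exactly 0.6·T and zero latency. Chords that extrapolate to before the
stimulus (possible with noise) give negative latencies that are flagged,
not clamped. For the difference-of-exponentials kernel the chord method
carries a small systematic early bias (~0.1 ms at 0.5 ms rise), well
inside the 0.2-ms recovery tolerance used in tests. Default
quantification operates on the sweep average (5 sweeps per cell);
per-sweep mode is available. Condition comparisons use the two-sided
Mann–Whitney U (exact for small tie-free samples; asymptotic with tie
correction otherwise, no continuity correction so identical groups give
p = 1).

## Stimulation statistics

Closed-loop triggering scans a movement/wake indicator: a trigger fires
when activity has persisted 5 min (persistence resets on inactivity and
on each trigger) and ≥30 min has passed since the last trigger. The
wake→NREM success window runs from laser onset to 5 min after offset —
transitions are observed during stimulation for some stimulation targets
and after offset for others, so the default spans both; a success needs a
NREM bout of ≥30 s (avoiding single-epoch flickers) *beginning* inside
the window. Pre-state is the state of the epoch containing the onset;
non-wake trials are excluded from the denominator but kept in the trial
table. The CI is exact binomial; when trials carry multiple stimulation
frequencies a per-frequency breakdown is emitted (both per-trial and
per-group aggregations are derivable from the trial table).

Induced vs natural NREM: induced is the first NREM bout beginning within
10 min after each onset; natural is every NREM bout ≥15 min from all
onsets; both report duration and bout-mean relative delta, compared with
two-sided unpaired t-tests. In the synthetic model stimulation does not
change sleep dynamics, so these comparisons test machinery (windowing,
exclusion, statistics), not a biological effect.

## Pipeline and reproducibility

All artifacts are plain columnar text with a fixed float format, so
identical (config, seed) runs are byte-identical; the run log additionally
records wall-clock timestamps and is excluded from bitwise comparisons.
Unknown configuration keys are rejected before any stage runs. Problem
sizes in the test suite and acceptance script — 2-h scoring sessions,
30-min 50-cell imaging sessions, 6-h stimulation sessions, 500-replicate
coverage checks — were chosen as the smallest scales at which each
statistical property is stable.

## What passing tests do and do not show

The generator matches the *statistical* structure of the recordings
(band-power contrasts, state-dependent event rates, shared photometry
artifacts, PSP kinetics), not their biophysics: no 1/f EEG background,
movement artifacts, electrode drift, imaging neuropil contamination,
spike-to-calcium nonlinearity, or stimulation-coupled dynamics. Recovery
numbers (e.g. ~99% scoring accuracy at default separation) are therefore
upper bounds that degrade as the state spectral weights converge; they
validate the implementations, not expected field performance on real
animals.
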