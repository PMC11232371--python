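# Methods

This note documents the models and procedures `ecpkit` implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions that matter for reproducing
results.

## Conventions

Sample indexing is 0-based; all user-facing times are seconds and all
internal arithmetic is in samples; time windows are half-open `[t0, t1)`.
Voltages are microvolts, FSCV currents nA (calibration-relative). The
canonical recording container is HDF5 with one float64 dataset per channel
and root attributes `sample_rate_hz`, `start_time_s`, `units`; event tables
are CSV. Round-trips through the HDF5 container are bit-exact.

## Periodic-artifact removal

The removal pass is average → enhance → threshold → periodicity →
interpolate.

**Enhancement filters.** 4th-order Butterworth in second-order sections,
applied forward–backward (zero phase) so detected peak times are not
lag-shifted: band-pass 10–100 Hz for FSCV scans (their energy is
concentrated at the 10 Hz repetition rate and its low harmonics), high-pass
300 Hz for line-noise transients (sharp, broadband). The rectified output
is thresholded at 1.75 × SD (FSCV) or 8 × mean (line noise); the SD/mean is
computed on the rectified trace, i.e. after the absolute value, matching
the step order of the procedure. A zero-variance trace raises an error
rather than thresholding at 0.

**Crossing and peak conventions.** A crossing requires a sample strictly
above threshold preceded by one at or below it; a pulse that only touches
the threshold does not count. The stored peak is the first subsequent
sample not exceeded by its successor, so plateaus resolve to their earliest
sample.

**Periodicity enforcement.** The grid phase is the centre of the circular
phase window (width 2 × tolerance; tolerance defaults to 10% of the nominal
period, a value the source procedure leaves open) containing the most
candidates. Candidates outside the window are discarded as spurious;
missing grid slots are filled by extrapolating from the nearest preceding
detection (or the following one at the leading edge), re-anchoring at every
detection so slow clock drift does not accumulate, and the grid is extended
to the recording edges. Two guards reject the no-artifact case: the winning
phase window must hold at least twice the count expected under uniform
phases, and the retained peaks must be at least 5× the enhanced-trace
median (scan and line artifacts are 1–2 orders above background; noise
structure is not). For line noise, the validation grid is the **least
common multiple** of the configured harmonics (360 Hz for 60/120/180) —
the coarsest single grid containing every harmonic's peaks (a 120 Hz train
does not lie on a 180 Hz grid) — and interior gap-filling is disabled,
because empty harmonic-grid slots are legitimate (pure 60 Hz interference
occupies every sixth slot of a 360 Hz grid).

**Interpolation.** Samples strictly inside `[peak − 5 ms, peak + 7 ms]`
(FSCV; ±0.166 ms for line noise) are replaced by the line joining the
boundary samples on every channel; boundary samples are untouched, so
everything outside the windows is bit-identical to the input. Overlapping
windows merge with a warning; windows truncate at the recording edges. The
blanked samples are recorded in a per-sample mask that downstream stages
consult. A variant −3 to +7 ms window is accepted via configuration but is
not the default. With the default window, 12 ms × 10 Hz = 12% of the
recording is blanked (11.97% exactly, since the boundary samples of each
361-sample span survive).

**Idempotence.** The interpolation ramps leave a faint 10 Hz rhythm in the
background that the detector would re-find. A second pass therefore checks
the existing mask: when the median overlap between the newly identified
windows and already-blanked samples is ≥ 50%, the pass concludes it has
already been applied and returns the recording unchanged. A *different*
pass (line noise after FSCV, or vice versa) blankets mostly fresh samples
and proceeds; measured cross-mode overlap is ≲ 8%.

## Artifact emulation

The source procedure defers artifact shapes to prior work, so the emulator
defines them canonically:

- **R (resistive)**: the scan command expressed as deviation from the
  −0.4 V hold — a 0 → peak → 0 triangle over 8.5 ms — scaled to a 500 µV
  default peak.
- **RC (resistive–capacitive)**: the R waveform through a single-pole RC
  high-pass (τ = 1 ms default), giving a biphasic transient with
  exponential edges and near-zero integral (capacitive coupling passes no
  DC).
- **rail (saturating)**: a commanded 3 mV peak clipping at the ±1 mV
  amplifier input range, followed by overload recovery modelled as a
  damped ~500 Hz ringing of the saturated input stage with a 3.5 ms decay
  constant. The ringing is deliberate: a smooth one-sided exponential
  recovery is annihilated by the causal 250 Hz detection high-pass and
  could not corrupt spike extraction at all, whereas saturated
  instrumentation amplifiers in practice settle with oscillatory
  high-frequency content — which is what makes rail artifacts, whose
  disruption extends well beyond the 12 ms interpolation window, the worst
  case for spike recovery. The decay constant was chosen so the emulated
  rail regime reproduces the qualitative rail-worst outcome with a
  several-point recovery deficit.

Injection adds the waveform coherently on all channels at the 10 Hz
schedule with 5% Gaussian per-event amplitude jitter (artifacts should not
be perfectly learnable); rail injection additionally clips the summed
signal at the rails, which destroys information and makes rail — unlike
R/RC — non-invertible by subtraction.

## Synthetic recordings

Units are parametric 48-sample templates (sums of Gaussians): MSN-like,
narrow and biphasic (~0.4 ms trough-to-peak), firing sparsely (< 1 Hz) in
Poisson bursts with short intra-burst intervals; TAN-like, broad with a
prolonged after-hyperpolarization (~0.9 ms), firing tonically at 2–12 Hz
(gamma-jittered regular ISIs, CV 0.2). All firing models enforce a 1 ms
refractory period. Noise is white (default 25 µV SD, a typical striatal
high-pass background) with optional 1/f and line components (sinusoidal or
sharp one-sample transients, the shape a shared ground injects).

**SNR convention.** Unit amplitude is the trough depth *in the detection
band*, i.e. after the causal 4-pole 250 Hz high-pass used for spike
detection, following the spike-sorting convention of quoting SNR on the
filtered recording; templates are normalized so their filtered trough is
−1. (The causal filter attenuates the raw trough by ~40%, so defining SNR
on the raw template would make nominal SNR 8 behave like ~5 at the
detector.) Default SNR is 8.

The generator emulates what the validation needs — periodic artifacts over
sparse/tonic units on a stationary noise floor — and deliberately omits
electrode drift, bursting nonstationarity, overlapping spikes from
multiple units on one channel, and movement artifacts in the EPhys band.
Recovery rates measured on it therefore isolate the dead-time and
residual-artifact effects of the removal algorithm; they do not certify
sorting quality on drifting or multi-unit recordings.

## Spike pipeline

Causal (forward-only) 4-pole Butterworth high-pass at 250 Hz; NaN spans are
filtered around, segment by segment. Detection takes negative-going
crossings of a threshold (−4 × SD default; the source procedure sets
thresholds manually) with 1 ms dead time; waveforms span 8 samples before
to 39 after the crossing (48 samples, 1.6 ms). Events whose waveform
window touches an interpolation-masked sample are invalidated rather than
kept — interpolation flattens any true spike there, and this is the
mechanism behind the ~12% recovery loss. Features: energy Σv², nonlinear
(Teager) energy Σ(vᵢ² − vᵢ₋₁vᵢ₊₁), and principal-component scores whose
basis is computed from valid waveforms only and recomputed after any
invalidation. Automated curation invalidates events above the 99.5th
energy/nonlinear-energy percentiles (a deterministic stand-in for manual
rejection of glitches); clustering is seeded k-means on (PC1, PC2) with
labels ordered by cluster size. ISI histograms round intervals to 1 ns
before binning to keep exactly periodic trains in a single bin.

## Validation (spike recovery rate)

Recovery is the percentage of reference events matched one-to-one (greedy,
nearest-first) within ±0.5 ms in the processed recording. The reference is
the events detected on the clean recording — the definition used for the
headline numbers — with simulator ground truth available as a second,
`truth`-labelled basis. `run_validation` injects each artifact kind with a
seed-derived schedule, removes with default settings, re-detects per
channel, and reports one row per (channel, kind) plus per-kind and grand
means. Expected values under the defaults: R ≈ 87 (dead-time bound
100 × (1 − 0.12) minus waveform-window edge losses), RC ≈ 1 point lower
(its undershoot tail extends past the window), rail ≈ 4–5 points lower
still (exposed overload ringing).

## FSCV chemometrics

The scan is generated at 100 kHz intra-scan sampling (851 points; the
digitizer rate is not specified by the source procedure). Components are
the uncentered SVD of the stacked standards (so a zero CV maps to zero
concentration and the estimate is linear); the dopamine calibration is the
no-intercept least-squares map from training scores to known
concentrations. Q is the squared off-subspace residual; Q_α defaults to
the 95th percentile of training-standard residuals (floored at 1e−9 so
noise-free standards remain admissible). Because Q scales with the square
of the input, concentrations far above the trained range are nulled rather
than extrapolated — screening, not a defect. Movement correlation is the
maximum Pearson r against each movement template over the full CV,
compared to 0.8; Q-screening is checked first, movement second, and a
nulled scan carries exactly one reason. Nulled scans propagate as NaN and
are excluded from peri-event averages.

Synthetic standards use analytic CV templates (dopamine: oxidation peak
near +0.6 V on the rising limb, reduction trough near −0.2 V falling; pH:
broad low-voltage features; movement: slow baseline deflection) with
measurement noise 0.02 a.u. — deliberately conservative relative to the
synthetic series' instrument noise (0.01 a.u.) so that Q_α, derived from
the standards, tolerates background-subtracted measurement noise (which is
√2 larger than single-scan noise). The synthetic series's background is a
20× charging-current CV with small (5 × 10⁻⁴) drift; background
subtraction at a reference scan removes it to within the Q_α budget.

## Problem sizes

The default test and reproduction runs use 15–60 s recordings for property
checks and a single 10-minute, one-unit, 30 kHz recording for the
end-to-end recovery and ordering measurements — large enough that the
binomial error of a recovery percentage is ≈ 0.5 points, which is the
precision the comparisons need.

## Known limitations

- Spikes inside interpolation windows are unrecoverable by design; the
  algorithm trades them for artifact-free sorting of the rest.
- The periodicity model assumes a single stable scan clock per file;
  clock drift is absorbed by re-anchoring but discontinuous clock jumps
  are not handled.
- The tonic firing model can phase-lock with the 10 Hz schedule (its mean
  ISI is an integer multiple of the scan period), biasing recovery on
  short recordings; the uniform-phase expectation of 88% applies to
  Poisson units.
- Dopamine concentration is calibration-relative unless absolute standards
  are supplied; the chemometric false-positive/negative rates of the
  original in-vivo procedure are not characterized here.
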