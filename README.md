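# ecpkit

Toolkit for concurrent electrophysiology + fast-scan cyclic voltammetry
(FSCV) recordings: removal of periodic scan artifacts from extracellular
voltage recordings by temporal interpolation, spike extraction and
characterization, validation of spike recovery with emulated artifacts, and
PCA-based dopamine concentration estimation from FSCV scans.

## The problem

Measuring dopamine and spiking activity at the same striatal site requires
two instruments on neighbouring carbon-fiber sensors: an electrophysiology
(EPhys) amplifier sampling extracellular voltage at 30 kHz, and an FSCV
system that applies a triangular voltage sweep (−0.4 → 1.3 → −0.4 V at
400 V/s, i.e. 8.5 ms) ten times per second to measure dopamine redox
currents. The scan couples through the conductive tissue into the EPhys
electrodes as a large 10 Hz transient that spike-sorting pipelines readily
mistake for action potentials. `ecpkit` implements an automated time-domain
solution that needs no hardware clock:

1. **average** up to 5 EPhys channels (artifacts are coherent across the
   array; spikes and field potentials are not);
2. **enhance**: band-pass 10–100 Hz and rectify, `|BPF₁₀₋₁₀₀(x̄)|`;
3. **threshold** at 1.75 × SD, keeping the local peak after each
   positive-going crossing;
4. **enforce periodicity**: retain only peaks on the 10 Hz scan grid,
   inserting peaks at grid positions where an artifact fell below
   threshold;
5. **interpolate** linearly across a −5 to +7 ms window around each peak
   on every channel, recording blanked samples in a mask.

The same machinery with a 300 Hz high-pass, an 8 × mean threshold,
±0.166 ms windows and a harmonic grid removes sharp 60 Hz (+harmonics)
line-noise transients.

Because 12 ms of every 100 ms scan interval is blanked, spikes with
uniformly distributed times are recovered at ≈ 88%; the package ships an
artifact **emulator** (resistive, resistive–capacitive, and saturating
"rail" coupling) plus a **synthetic recording generator** (sparse bursty
MSN-like and tonic TAN-like units over realistic noise) so this *spike
recovery rate* can be measured end-to-end without any recorded data.

On the FSCV side, each scan's background-subtracted cyclic voltammogram is
projected onto principal components trained on dopamine / pH / movement
standards; the dopamine score maps to a concentration change [ΔDA], and
scans are nulled when the off-subspace residual exceeds a tolerance
(Q > Q_α) or when they correlate with a movement-artifact template
(r > 0.8).

## Worked example

```python
import ecpkit as ek

# 60 s synthetic striatal recording: one 5 Hz Poisson unit at SNR 8
rec, truth = ek.generate_recording(
    [ek.UnitSpec(cell_class="TAN", mean_rate=5.0, firing_model="poisson")],
    ek.NoiseSpec(), duration=60.0, seed=1)

# inject resistive scan artifacts at 10 Hz, then remove them
art, times = ek.inject_artifacts(rec, ek.ArtifactModel.preset("R"), seed=2)
cleaned, peaks = ek.remove_fscv_artifacts(art)
print(f"artifact windows interpolated: {len(peaks)}")
print(f"fraction of samples blanked:   {cleaned.mask.mean():.3f}")

# spike recovery: clean-recording events still present after processing
ref  = [e.time for e in ek.detect_spikes(ek.spike_filter(rec)) if e.valid]
proc = [e.time for e in ek.detect_spikes(ek.spike_filter(cleaned)) if e.valid]
print(f"clean-recording events:        {len(ref)}")
print(f"events after inject+interp:    {len(proc)}")
print(f"spike recovery rate:           {ek.recovery_rate(ref, proc):.1f}%")
```

prints

```
artifact windows interpolated: 600
fraction of samples blanked:   0.120
clean-recording events:        568
events after inject+interp:    503
spike recovery rate:           87.1%
```

All 600 scans (10 Hz × 60 s) were found and blanked; the 12 ms window at
10 Hz accounts for the 12% masked fraction, and recovery lands at the
dead-time expectation of roughly 88% (events whose 1.6 ms waveform window
touches a blanked span are also invalidated, which costs another point or
so).

The same steps are available from the shell:

```sh
ecpkit simulate --seed 1 --duration 60 --out rec.h5 --truth truth.csv
ecpkit inject   --in rec.h5 --kind R --seed 2 --out art.h5
ecpkit despike  --in art.h5 --out clean.h5 --report peaks.csv
ecpkit detect   --in clean.h5 --out events.csv
ecpkit validate --in rec.h5 --kinds R,RC,rail --seed 7 --out recovery.csv
```

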