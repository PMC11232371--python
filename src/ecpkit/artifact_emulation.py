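"""Emulated FSCV scan artifacts for validating the removal algorithm.

Three coupling regimes are modelled, reflecting electrode spacing and
electrode properties:

- ``R`` (resistive): the triangular scan command (the -0.4 -> 1.3 -> -0.4 V
  sweep over 8.5 ms, expressed as deviation from the -0.4 V hold) couples
  conductively and appears linearly scaled at the recording electrode.
- ``RC`` (resistive-capacitive): the same waveform passed through a
  single-pole RC high-pass stage, giving a biphasic transient with
  exponential edges and (as capacitive coupling passes no DC) near-zero
  integral.
- ``rail`` (saturating): a commanded amplitude beyond the amplifier input
  range (+/-1 mV) clips at the rail; the overdriven input stage then
  settles back with a fast fall and an opposite-polarity undershoot that
  recovers exponentially, making this the broadest of the three.

Injecting these at the 10 Hz scan schedule onto recordings made without
FSCV provides ground truth for the spike recovery rate.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .signal_model import ContinuousRecording

__all__ = ["ArtifactModel", "make_artifact", "inject_artifacts"]

ARTIFACT_KINDS = ("R", "RC", "rail")


@dataclasses.dataclass
class ArtifactModel:
    """Parametric description of one scan-coupling artifact type.

    ``peak_amplitude`` is the commanded peak in microvolts; for ``rail`` it
    must exceed ``saturation_level`` (otherwise nothing would clip and the
    model degenerates to ``R``).  ``recovery_time_constant_ms`` sets the
    slow settling of the post-saturation undershoot.  ``amplitude_jitter``
    is the fractional per-event amplitude variation applied at injection.
    """

    kind: str
    peak_amplitude: float = 500.0
    scan_duration_ms: float = 8.5
    rc_time_constant_ms: float = 1.0
    saturation_level: float = 1000.0
    recovery_time_constant_ms: float = 3.5
    amplitude_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"kind must be one of {ARTIFACT_KINDS}, got {self.kind!r}")
        if self.scan_duration_ms <= 0:
            raise ValueError("scan_duration_ms must be > 0")
        if self.kind == "rail" and self.saturation_level <= 0:
            raise ValueError("saturation_level must be > 0 for rail artifacts")
        if not np.isfinite(self.peak_amplitude):
            raise ValueError("peak_amplitude must be finite")

    @classmethod
    def preset(cls, kind: str) -> "ArtifactModel":
        """Default model per kind: R/RC peak 500 uV, rail commanded 3 mV
        clipping at the +/-1 mV input range."""
        if kind == "rail":
            return cls(kind="rail", peak_amplitude=3000.0)
        return cls(kind=kind)


def _triangle(model: ArtifactModel, sample_rate: float) -> np.ndarray:
    """Scan-command shape (deviation from hold), unit peak, over the scan span."""
    n = int(round(model.scan_duration_ms * 1e-3 * sample_rate))
    if n < 3:
        raise ValueError("scan duration shorter than 3 samples at this rate")
    t = np.arange(n) / (n - 1)
    return 1.0 - np.abs(2.0 * t - 1.0)


def make_artifact(model: ArtifactModel, sample_rate: float) -> np.ndarray:
    """Single-event artifact waveform in microvolts.

    The waveform starts and ends at (or decays to < 1% of its peak by) its
    last sample, so injected artifacts have compact support.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    if model.peak_amplitude == 0:
        # degenerate: no coupling
        return np.zeros(int(round(model.scan_duration_ms * 1e-3 * sample_rate)))
    tri = _triangle(model, sample_rate)
    if model.kind == "R":
        return model.peak_amplitude * tri
    if model.kind == "RC":
        tau = model.rc_time_constant_ms * 1e-3
        dt = 1.0 / sample_rate
        pad = int(round(8 * tau * sample_rate))
        x = np.concatenate([tri, np.zeros(pad)])
        alpha = tau / (tau + dt)
        y = np.empty_like(x)
        y[0] = x[0]
        for k in range(1, x.size):
            y[k] = alpha * (y[k - 1] + x[k] - x[k - 1])
        peak = np.abs(y).max()
        return model.peak_amplitude * y / peak
    # rail
    if abs(model.peak_amplitude) <= model.saturation_level:
        raise ValueError("rail artifact requires |peak_amplitude| > saturation_level "
                         "(the commanded peak must clip)")
    commanded = model.peak_amplitude * tri
    sat = model.saturation_level
    clipped = np.clip(commanded, -sat, sat)
    over = np.flatnonzero(np.abs(commanded) >= sat)
    exit_idx = int(over[-1])
    # overload recovery: the saturated input stage settles back with a
    # damped oscillation (ring frequency ~500 Hz, decay = recovery time
    # constant); the high-frequency ringing is what lets rail artifacts
    # corrupt spike extraction beyond the interpolated span
    tau_rec = model.recovery_time_constant_ms * 1e-3
    ring_freq = 500.0
    tail_n = int(np.ceil(8 * tau_rec * sample_rate))  # exp(-8) << 1% of peak
    total = exit_idx + 1 + tail_n
    w = np.zeros(total)
    w[:exit_idx + 1] = clipped[:exit_idx + 1]
    t_rel = np.arange(1, tail_n + 1) / sample_rate
    rail_sign = np.sign(clipped[exit_idx])
    w[exit_idx + 1:] = (rail_sign * sat * np.exp(-t_rel / tau_rec)
                        * np.cos(2 * np.pi * ring_freq * t_rel))
    return w


def inject_artifacts(rec: ContinuousRecording, model: ArtifactModel,
                     schedule_freq: float = 10.0, phase: float = 0.0,
                     seed: int | None = None,
                     ) -> tuple[ContinuousRecording, np.ndarray]:
    """Add the artifact waveform at a periodic schedule on every channel.

    The artifact couples coherently into all channels (the physical scan is
    common to the array).  Per-event amplitudes are jittered by the model's
    fractional jitter (Gaussian, seeded).  For ``rail`` artifacts the summed
    signal is additionally clipped at ``+/-saturation_level``, emulating
    amplifier input saturation; this destroys information and makes rail
    injection non-invertible, unlike R/RC.

    Returns the artifacted recording and the scheduled event start times in
    seconds relative to the recording start.
    """
    if schedule_freq <= 0:
        raise ValueError("schedule_freq must be > 0")
    fs = rec.sample_rate
    w = make_artifact(model, fs)
    out = rec.copy()
    rng = np.random.default_rng(seed)
    period = 1.0 / schedule_freq
    times = []
    t = phase
    while t * fs < rec.n_samples - 1:
        times.append(t)
        t += period
    for t0 in times:
        s = int(round(t0 * fs))
        avail = min(w.size, rec.n_samples - s)
        gain = 1.0 + model.amplitude_jitter * rng.standard_normal()
        out.data[:, s:s + avail] += gain * w[:avail]
    if model.kind == "rail":
        np.clip(out.data, -model.saturation_level, model.saturation_level,
                out=out.data)
    return out, np.asarray(times)
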