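"""Ground-truth synthetic striatal recordings.

Generates 30 kHz extracellular recordings containing the two principal
striatal unit classes — medium spiny neurons (MSNs), which fire sparsely
(< 1 Hz) in bursts with a narrow biphasic waveform, and tonically active
neurons (TANs), which fire regularly at 2–12 Hz with a broad waveform and
prolonged after-hyperpolarization — over a configurable noise background
(white, 1/f, and optional 60 Hz + harmonic line interference).  Every spike
time is returned as ground truth, so artifact removal and spike detection
can be scored without any recorded data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .signal_model import Channel, ContinuousRecording

__all__ = ["UnitSpec", "NoiseSpec", "make_template", "generate_recording",
           "TEMPLATE_LEN", "TROUGH_INDEX"]

TEMPLATE_LEN = 48   # samples at 30 kHz = 1.6 ms
TROUGH_INDEX = 8    # pre-trough span matches the 8-sample pre-threshold period

DEFAULT_NOISE_STD = 25.0  # uV, typical striatal high-pass background
DEFAULT_SNR = 8.0         # trough amplitude / noise std


@dataclasses.dataclass
class UnitSpec:
    """One synthetic unit: cell class, firing statistics and amplitude.

    ``amplitude`` is the (positive) magnitude of the negative trough in
    microvolts as seen in the spike detection band (after the causal
    250 Hz high-pass); the default gives SNR 8 over the default noise
    floor, with SNR quoted on the filtered signal as is conventional in
    spike sorting.
    ``firing_model`` is one of ``poisson``, ``bursty`` (Poisson bursts of
    short-ISI spikes, the MSN default) or ``tonic`` (jittered regular
    firing with a refractory period, the TAN default).
    """

    cell_class: str = "MSN"
    mean_rate: float | None = None
    firing_model: str | None = None
    amplitude: float = DEFAULT_SNR * DEFAULT_NOISE_STD
    channel: int | None = None
    template: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_class not in ("MSN", "TAN"):
            raise ValueError("cell_class must be 'MSN' or 'TAN'")
        if self.mean_rate is None:
            self.mean_rate = 0.5 if self.cell_class == "MSN" else 5.0
        if self.firing_model is None:
            self.firing_model = "bursty" if self.cell_class == "MSN" else "tonic"
        if self.firing_model not in ("poisson", "bursty", "tonic"):
            raise ValueError(f"unknown firing_model {self.firing_model!r}")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be > 0")


@dataclasses.dataclass
class NoiseSpec:
    """Background noise model: white + optional 1/f and line components.

    ``line_noise`` maps harmonic frequency (Hz) to amplitude (uV);
    ``line_waveshape`` is ``sinusoid`` or ``sharp`` (one-sample spike train,
    emulating the sharp transients a shared ground injects).
    """

    white_std: float = DEFAULT_NOISE_STD
    pink_std: float = 0.0
    pink_exponent: float = 1.0
    line_noise: dict | None = None
    line_waveshape: str = "sinusoid"

    def __post_init__(self) -> None:
        if self.white_std < 0 or self.pink_std < 0:
            raise ValueError("noise stds must be >= 0")
        if self.line_waveshape not in ("sinusoid", "sharp"):
            raise ValueError("line_waveshape must be 'sinusoid' or 'sharp'")


def make_template(cell_class: str, sample_rate: float = 30000.0) -> np.ndarray:
    """48-sample spike template with the trough at sample 8.

    Templates are parametric (sums of Gaussians): MSN is narrow and biphasic
    (~0.4 ms trough-to-peak); TAN is broad with a prolonged
    after-hyperpolarization (~0.9 ms), so its full width at half-trough
    exceeds the MSN's.

    Normalization follows the spike-sorting convention of quoting unit
    amplitude and SNR on the detection-band signal: the template is scaled
    so its trough equals -1 *after* the causal 4-pole 250 Hz high-pass
    used for spike detection (the raw trough is therefore somewhat deeper
    than -1, since the filter attenuates the spike).
    """
    if cell_class not in ("MSN", "TAN"):
        raise ValueError("cell_class must be 'MSN' or 'TAN'")
    t = (np.arange(TEMPLATE_LEN) - TROUGH_INDEX) / sample_rate * 1e3  # ms
    if cell_class == "MSN":
        w = (-np.exp(-0.5 * (t / 0.10) ** 2)
             + 0.45 * np.exp(-0.5 * ((t - 0.40) / 0.18) ** 2))
    else:
        w = (-np.exp(-0.5 * (t / 0.20) ** 2)
             + 0.35 * np.exp(-0.5 * ((t - 0.90) / 0.45) ** 2))
    sos = signal.butter(4, 250.0, btype="highpass", fs=sample_rate, output="sos")
    pad = np.zeros(TEMPLATE_LEN)
    filtered = signal.sosfilt(sos, np.concatenate([pad, w, pad]))
    return w / -filtered.min()


# ---------------------------------------------------------------------------
# Spike-time models (all enforce a 1 ms refractory period)
# ---------------------------------------------------------------------------

_REFRACTORY = 1e-3


def _poisson_times(rate, duration, rng):
    n = rng.poisson(rate * duration * 1.2) + 10
    isi = rng.exponential(1.0 / rate, size=n) + _REFRACTORY
    t = np.cumsum(isi)
    return t[t < duration]


def _tonic_times(rate, duration, rng):
    # regular firing with ~20% gamma jitter on the ISI
    n = int(rate * duration * 1.5) + 10
    shape = 25.0  # CV = 1/sqrt(shape) = 0.2
    isi = rng.gamma(shape, (1.0 / rate) / shape, size=n)
    isi = np.maximum(isi, _REFRACTORY)
    t = np.cumsum(isi)
    return t[t < duration]


def _bursty_times(rate, duration, rng, burst_mean=3.0, intra_isi=5e-3):
    burst_rate = rate / burst_mean
    onsets = _poisson_times(burst_rate, duration, rng)
    times = []
    for t0 in onsets:
        n_spk = 1 + rng.geometric(1.0 / burst_mean)
        jit = rng.normal(0.0, 0.5e-3, size=n_spk).cumsum()
        tt = t0 + np.arange(n_spk) * intra_isi + np.abs(jit)
        times.extend(tt[tt < duration])
    t = np.sort(np.asarray(times))
    if t.size > 1:  # enforce refractory
        keep = np.concatenate([[True], np.diff(t) >= _REFRACTORY])
        t = t[keep]
    return t


_FIRING = {"poisson": _poisson_times, "tonic": _tonic_times, "bursty": _bursty_times}


def _pink(n, exponent, rng):
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * scale, n)
    return x / x.std()


def generate_recording(units: list[UnitSpec], noise: NoiseSpec | None = None,
                       n_channels: int = 1, duration: float = 60.0,
                       sample_rate: float = 30000.0, seed: int | None = None,
                       ) -> tuple[ContinuousRecording, dict[int, np.ndarray]]:
    """Synthesize a recording plus per-unit ground-truth spike times.

    Ground-truth times are the template trough times in seconds.  Each unit
    is assigned to one channel (``unit.channel`` or round-robin).  The same
    seed yields a bit-identical recording and truth table.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    data = np.zeros((n_channels, n))
    if noise.white_std > 0:
        for c in range(n_channels):
            data[c] += noise.white_std * rng.standard_normal(n)
    if noise.pink_std > 0:
        for c in range(n_channels):
            data[c] += noise.pink_std * _pink(n, noise.pink_exponent, rng)
    if noise.line_noise:
        t = np.arange(n) / sample_rate
        for freq, amp in noise.line_noise.items():
            if noise.line_waveshape == "sinusoid":
                comp = amp * np.sin(2 * np.pi * freq * t)
                data += comp[None, :]
            else:
                idx = np.round(np.arange(0, duration, 1.0 / freq) * sample_rate)
                idx = idx[idx < n].astype(np.int64)
                data[:, idx] += amp

    truth: dict[int, np.ndarray] = {}
    for i, u in enumerate(units):
        tmpl = u.template if u.template is not None else make_template(u.cell_class, sample_rate)
        if tmpl.size > n:
            raise ValueError("template longer than the recording")
        ch = u.channel if u.channel is not None else i % n_channels
        times = _FIRING[u.firing_model](u.mean_rate, duration, rng)
        kept = []
        for tt in times:
            trough = int(round(tt * sample_rate))
            a = trough - TROUGH_INDEX
            if a < 0 or a + tmpl.size > n:
                continue
            data[ch, a:a + tmpl.size] += u.amplitude * tmpl
            kept.append(trough / sample_rate)
        truth[i] = np.asarray(kept)

    channels = [Channel(f"ch{c:02d}") for c in range(n_channels)]
    rec = ContinuousRecording(sample_rate, data, channels)
    return rec, truth
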