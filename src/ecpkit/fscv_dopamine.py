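"""FSCV scan generation, voltammograms and PCA-based dopamine estimation.

Fast-scan cyclic voltammetry applies a triangular voltage sweep
(-0.4 V -> 1.3 V -> -0.4 V at 400 V/s, 8.5 ms, repeated at 10 Hz with a
-0.4 V hold in between) to a carbon-fiber sensor and measures the current.
Each scan yields a cyclic voltammogram (CV); subtracting a reference scan
removes the large nonfaradaic background and leaves analyte redox currents
(dopamine oxidizes near +0.6 V on the rising sweep and its quinone reduces
near -0.2 V on the falling sweep).

Dopamine concentration change [dDA] is estimated chemometrically: CVs are
projected onto principal components trained on standards of dopamine, pH
shift and movement artifact; a calibration maps dopamine-component scores
to concentration.  Two screens null scans that cannot be attributed to the
trained chemistry: the squared off-subspace residual Q above a tolerance
Q_alpha (95th percentile of training residuals by default), and Pearson
correlation above r = 0.8 with any movement-artifact template.  Nulled
scans carry NaN and a reason, and are excluded from downstream averages.

Concentration units are calibration-relative (arbitrary units) unless the
user supplies standards with absolute concentrations.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np

__all__ = [
    "ScanWaveform", "FSCVSeries", "ChemStandards", "ChemometricModel",
    "DopamineTrace", "make_scan", "background_subtract",
    "dopamine_cv_template", "ph_cv_template", "movement_cv_template",
    "make_standard_set", "fit_chemometric_model", "estimate_dopamine",
    "color_plot_matrix", "synth_fscv", "read_fscv", "write_fscv",
]

Q_ALPHA_FLOOR = 1e-9


@dataclasses.dataclass
class ScanWaveform:
    """Triangular FSCV scan parameters (defaults: dopamine-optimized sweep)."""

    v_min: float = -0.4
    v_max: float = 1.3
    scan_rate: float = 400.0
    hold: float = -0.4
    scan_freq: float = 10.0
    intra_sample_rate: float = 100_000.0

    def __post_init__(self) -> None:
        if self.v_max <= self.v_min:
            raise ValueError("v_max must exceed v_min")
        if self.scan_rate <= 0 or self.scan_freq <= 0 or self.intra_sample_rate <= 0:
            raise ValueError("rates must be > 0")

    @property
    def duration(self) -> float:
        """Scan duration in seconds: up and down at the scan rate."""
        return 2.0 * (self.v_max - self.v_min) / self.scan_rate


def make_scan(params: ScanWaveform | None = None) -> np.ndarray:
    """Applied-voltage vector for one scan (endpoints inclusive).

    Rises from ``v_min`` to ``v_max`` and returns, at ``scan_rate`` V/s on
    both limbs; with the defaults, 8.5 ms sampled at 100 kHz (851 points).
    """
    p = params or ScanWaveform()
    n = int(round(p.duration * p.intra_sample_rate)) + 1
    t = np.linspace(0.0, p.duration, n)
    half = p.duration / 2.0
    up = p.v_min + p.scan_rate * t
    down = p.v_max - p.scan_rate * (t - half)
    return np.where(t <= half, up, down)


@dataclasses.dataclass
class FSCVSeries:
    """Per-scan current vectors (nA) on the 10 Hz scan grid."""

    scans: np.ndarray          # (n_scans, n_intra_samples)
    times: np.ndarray          # scan start times, s
    voltage: np.ndarray        # applied voltage per intra-scan sample
    params: ScanWaveform = dataclasses.field(default_factory=ScanWaveform)

    def __post_init__(self) -> None:
        self.scans = np.atleast_2d(np.asarray(self.scans, dtype=np.float64))
        self.times = np.asarray(self.times, dtype=np.float64)
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        if self.scans.shape[0] != self.times.size:
            raise ValueError("one time per scan required")
        if self.scans.shape[1] != self.voltage.size:
            raise ValueError("scan length must match the voltage vector")

    @property
    def n_scans(self) -> int:
        return self.scans.shape[0]


def background_subtract(series: FSCVSeries, reference) -> FSCVSeries:
    """Subtract the (mean of the) reference scan(s) from every scan.

    ``reference`` is a scan index or an ``(start, stop)`` index window;
    it is typically chosen at an alignment event such as the target cue so
    all task-modulated signals share a uniform baseline.
    """
    if isinstance(reference, tuple):
        a, b = reference
        if not (0 <= a < b <= series.n_scans):
            raise IndexError(f"reference window {reference} out of range")
        ref = series.scans[a:b].mean(axis=0)
    else:
        if not (0 <= reference < series.n_scans):
            raise IndexError(f"reference scan {reference} out of range")
        ref = series.scans[int(reference)]
    return FSCVSeries(series.scans - ref, series.times.copy(),
                      series.voltage.copy(), series.params)


# ---------------------------------------------------------------------------
# Analyte CV templates (synthetic standards)
# ---------------------------------------------------------------------------

def dopamine_cv_template(params: ScanWaveform | None = None) -> np.ndarray:
    """Synthetic background-subtracted dopamine CV, peak current 1 (a.u.).

    Oxidation peak near +0.6 V on the rising limb; reduction trough near
    -0.2 V on the falling limb — the redox signature used to identify
    dopamine on color plots.
    """
    p = params or ScanWaveform()
    v = make_scan(p)
    apex = int(np.argmax(v))
    cv = np.zeros_like(v)
    cv[:apex + 1] = np.exp(-0.5 * ((v[:apex + 1] - 0.6) / 0.15) ** 2)
    cv[apex + 1:] = -0.75 * np.exp(-0.5 * ((v[apex + 1:] + 0.2) / 0.15) ** 2)
    return cv / np.abs(cv).max()


def ph_cv_template(params: ScanWaveform | None = None) -> np.ndarray:
    """Synthetic basic-pH-shift CV: broad low-voltage features, peak 1 (a.u.)."""
    p = params or ScanWaveform()
    v = make_scan(p)
    apex = int(np.argmax(v))
    cv = np.zeros_like(v)
    cv[:apex + 1] = -np.exp(-0.5 * ((v[:apex + 1] - 0.2) / 0.45) ** 2)
    cv[apex + 1:] = 0.6 * np.exp(-0.5 * ((v[apex + 1:] - 1.0) / 0.35) ** 2)
    return cv / np.abs(cv).max()


def movement_cv_template(params: ScanWaveform | None = None) -> np.ndarray:
    """Synthetic movement-artifact CV: slow baseline deflection across the
    sweep (no localized redox peaks), peak 1 (a.u.)."""
    p = params or ScanWaveform()
    v = make_scan(p)
    n = v.size
    x = np.linspace(-1.0, 1.0, n)
    cv = np.tanh(2.0 * x) + 0.3 * x ** 2
    return cv / np.abs(cv).max()


@dataclasses.dataclass
class ChemStandards:
    """Training standards: dopamine CVs at known concentrations, pH and
    movement exemplars."""

    dopamine_cvs: np.ndarray       # (n_da, n_samples)
    dopamine_conc: np.ndarray      # (n_da,)
    ph_cvs: np.ndarray
    movement_cvs: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.vstack([self.dopamine_cvs, self.ph_cvs, self.movement_cvs])


def make_standard_set(params: ScanWaveform | None = None,
                      concentrations=(0.25, 0.5, 1.0),
                      ph_amplitudes=(0.5, 1.0),
                      movement_amplitudes=(0.5, 1.0),
                      n_reps: int = 3, noise_std: float = 0.02,
                      seed: int = 0) -> ChemStandards:
    """Synthetic training standards with measurement noise (seeded).

    Replicated noisy copies of each template at each amplitude, giving the
    residual distribution from which Q_alpha is derived.
    """
    p = params or ScanWaveform()
    rng = np.random.default_rng(seed)
    da_t = dopamine_cv_template(p)
    ph_t = ph_cv_template(p)
    mv_t = movement_cv_template(p)

    def reps(template, amps):
        rows, scale = [], []
        for a in amps:
            for _ in range(n_reps):
                rows.append(a * template + noise_std * rng.standard_normal(template.size))
                scale.append(a)
        return np.vstack(rows), np.asarray(scale)

    da_cvs, da_conc = reps(da_t, concentrations)
    ph_cvs, _ = reps(ph_t, ph_amplitudes)
    mv_cvs, _ = reps(mv_t, movement_amplitudes)
    return ChemStandards(da_cvs, da_conc, ph_cvs, mv_cvs)


@dataclasses.dataclass
class ChemometricModel:
    """Retained components, concentration calibration and nulling rules."""

    components: np.ndarray          # (k, n_samples), orthonormal rows
    calibration: np.ndarray         # (k,), score -> concentration
    q_alpha: float
    movement_templates: np.ndarray  # (m, n_samples)
    movement_r_threshold: float = 0.8

    def project(self, cvs: np.ndarray) -> np.ndarray:
        return np.atleast_2d(cvs) @ self.components.T

    def residual_q(self, cvs: np.ndarray) -> np.ndarray:
        cvs = np.atleast_2d(cvs)
        recon = self.project(cvs) @ self.components
        return np.sum((cvs - recon) ** 2, axis=1)


def fit_chemometric_model(standards: ChemStandards,
                          n_components: int | None = None,
                          variance_kept: float = 0.99,
                          q_alpha_percentile: float = 95.0) -> ChemometricModel:
    """Principal components of the training standards + concentration calibration.

    Components come from the (uncentered) SVD of the stacked standards, so a
    zero CV maps to zero concentration and the estimate is linear in the
    input.  The component count keeps ``variance_kept`` of the training
    variance unless ``n_components`` is given (rank-deficient standards
    reduce it further).  The dopamine calibration is the least-squares map
    from training scores to known concentrations, with no intercept.
    Q_alpha is the ``q_alpha_percentile`` of training residuals (floored at
    a small positive value so noise-free standards remain admissible).
    """
    X = standards.stacked()
    if standards.dopamine_cvs.shape[0] < 2:
        raise ValueError("need >= 2 dopamine standards for calibration")
    _u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10))
    if n_components is None:
        var = s ** 2 / np.sum(s ** 2)
        k = int(np.searchsorted(np.cumsum(var), variance_kept) + 1)
    else:
        k = n_components
    if k > rank:
        import warnings
        warnings.warn(f"standards have rank {rank}; reducing components from {k}")
        k = rank
    components = vt[:k]
    scores_da = standards.dopamine_cvs @ components.T
    calibration, *_ = np.linalg.lstsq(scores_da, standards.dopamine_conc, rcond=None)
    resid = np.sum((X - (X @ components.T) @ components) ** 2, axis=1)
    q_alpha = max(float(np.percentile(resid, q_alpha_percentile)), Q_ALPHA_FLOOR)
    return ChemometricModel(components, calibration, q_alpha,
                            np.atleast_2d(standards.movement_cvs))


@dataclasses.dataclass
class DopamineTrace:
    """[dDA] per scan with residual Q and per-scan null reason."""

    times: np.ndarray
    delta_da: np.ndarray           # NaN where nulled
    q: np.ndarray
    null_reason: np.ndarray        # 'none' | 'Q_exceeded' | 'movement_correlated'

    @property
    def n_nulled(self) -> int:
        return int(np.sum(self.null_reason != "none"))


def _pearson_max(cvs: np.ndarray, templates: np.ndarray) -> np.ndarray:
    x = cvs - cvs.mean(axis=1, keepdims=True)
    t = templates - templates.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    tn = np.linalg.norm(t, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x / np.where(xn == 0, 1, xn)) @ (t / np.where(tn == 0, 1, tn)).T
    return np.nanmax(r, axis=1)


def estimate_dopamine(series: FSCVSeries, model: ChemometricModel) -> DopamineTrace:
    """Project background-subtracted CVs onto the model; screen and calibrate.

    Per scan: scores -> [dDA] via the calibration; Q = squared off-subspace
    residual.  Scans with ``Q > Q_alpha`` are nulled (reason
    ``Q_exceeded``); scans whose Pearson correlation with any movement
    template exceeds the threshold are nulled (``movement_correlated``).
    """
    if series.scans.shape[1] != model.components.shape[1]:
        raise ValueError("scan length does not match the chemometric model")
    scores = model.project(series.scans)
    da = scores @ model.calibration
    q = model.residual_q(series.scans)
    reason = np.full(series.n_scans, "none", dtype=object)
    reason[q > model.q_alpha] = "Q_exceeded"
    r = _pearson_max(series.scans, model.movement_templates)
    moved = (r > model.movement_r_threshold) & (reason == "none")
    reason[moved] = "movement_correlated"
    da = np.where(reason == "none", da, np.nan)
    return DopamineTrace(series.times.copy(), da, q, reason)


def color_plot_matrix(series: FSCVSeries) -> np.ndarray:
    """Voltage x time matrix of current change (the standard color plot).

    Rows follow the applied-voltage ordering -0.4 -> 1.3 -> -0.4 V; columns
    are scans at the 100 ms sampling interval.
    """
    return series.scans.T.copy()


def synth_fscv(duration: float = 60.0, transients=((5.0, 1.0),),
               noise_std: float = 0.01, seed: int = 0,
               params: ScanWaveform | None = None,
               background_amplitude: float = 20.0,
               drift: float = 5e-4) -> FSCVSeries:
    """Synthetic FSCV series: drifting background + dopamine transients + noise.

    ``transients`` is a list of ``(time_s, amplitude)``; each adds the
    dopamine template scaled by an exponential rise (0.3 s) / decay (1.0 s)
    kernel whose on-grid peak equals the amplitude.  The background is a
    large charging-current CV (default 20x the unit transient) drifting by
    the fractional ``drift`` over the recording; background subtraction at
    a reference scan removes it.  Seeded and reproducible.
    """
    p = params or ScanWaveform()
    rng = np.random.default_rng(seed)
    v = make_scan(p)
    n_scan = v.size
    times = np.arange(0.0, duration, 1.0 / p.scan_freq)
    n = times.size
    apex = int(np.argmax(v))
    sweep_dir = np.where(np.arange(n_scan) <= apex, 1.0, -1.0)
    background = background_amplitude * sweep_dir * (0.6 + 0.4 * np.exp(-((v - 0.45) / 1.2) ** 2))
    da_t = dopamine_cv_template(p)
    scans = np.empty((n, n_scan))
    drift_gain = 1.0 + drift * np.linspace(0.0, 1.0, n)
    amp = np.zeros(n)
    for t0, a in transients:
        dt_rel = times - t0
        kern = np.where(dt_rel >= 0,
                        (1.0 - np.exp(-dt_rel / 0.3)) * np.exp(-dt_rel / 1.0), 0.0)
        peak = kern.max()
        if peak > 0:
            amp += a * kern / peak
    scans[:] = drift_gain[:, None] * background[None, :] + amp[:, None] * da_t[None, :]
    if noise_std > 0:
        scans += noise_std * rng.standard_normal(scans.shape)
    return FSCVSeries(scans, times, v, p)


# ---------------------------------------------------------------------------
# HDF5 I/O for scan series
# ---------------------------------------------------------------------------

def write_fscv(series: FSCVSeries, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("scans", data=series.scans)
        f.create_dataset("times", data=series.times)
        f.create_dataset("voltage", data=series.voltage)
        for k, val in dataclasses.asdict(series.params).items():
            f.attrs[k] = val
    return path


def read_fscv(path) -> FSCVSeries:
    with h5py.File(path, "r") as f:
        params = ScanWaveform(**{k: float(f.attrs[k]) for k in
                                 ("v_min", "v_max", "scan_rate", "hold",
                                  "scan_freq", "intra_sample_rate")})
        return FSCVSeries(f["scans"][...], f["times"][...], f["voltage"][...], params)
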