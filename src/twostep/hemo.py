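"""Minimal fNIRS processing chain for task-evoked hemodynamics.

Dual-wavelength (760/850 nm) optical-density changes are converted to
oxy-/deoxy-hemoglobin concentration changes with the modified
Beer-Lambert law, summed into total hemoglobin, band-pass
filtered/detrended, and reduced to trial-wise response amplitudes by a
GLM with one stick-convolved hemodynamic response regressor per stage-1
choice. A forward generator synthesises optical time series from known
amplitudes (HRF + physiological sinusoids + white noise) so the chain
is testable end to end. Concentration units are arbitrary ("a.u.")
since the default coefficient set is used as printed, without a unit
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "OpticalTimeSeries", "MbllCoefficients", "HemoSeries",
    "DEFAULT_COEFFICIENTS", "mbll_convert", "mbll_forward", "preprocess",
    "canonical_hrf", "glm_trial_amplitudes", "synth_nirs",
]

WAVELENGTHS = (760, 850)


@dataclass(frozen=True)
class MbllCoefficients:
    """Extinction/absorption matrix and differential pathlength factors.

    ``extinction[i, j]`` pairs wavelength i (760, 850 nm) with
    chromophore j (O2Hb, HHb). Defaults are the instrument's standard
    coefficient set.
    """

    extinction: np.ndarray = field(
        default_factory=lambda: np.array([[1486.0, 3843.0],
                                          [2526.0, 1798.0]]))
    dpf: np.ndarray = field(default_factory=lambda: np.array([7.25, 6.38]))

    def __post_init__(self):
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (2, 2) or abs(np.linalg.det(ext)) < 1e-12:
            raise ValueError("extinction matrix must be 2x2 and invertible")
        object.__setattr__(self, "extinction", ext)
        object.__setattr__(self, "dpf", np.asarray(self.dpf, dtype=float))


DEFAULT_COEFFICIENTS = MbllCoefficients()


@dataclass(frozen=True)
class OpticalTimeSeries:
    """Optical-density changes, shape (time, channel, wavelength)."""

    delta_od: np.ndarray
    sampling_rate: float
    source_detector_distance: float = 30.0  # mm; short channels ~10

    def __post_init__(self):
        od = np.asarray(self.delta_od, dtype=float)
        if od.ndim != 3 or od.shape[2] < 2:
            raise ValueError("delta_od must be (time, channel, wavelength>=2)")
        if not np.all(np.isfinite(od)):
            raise ValueError("delta_od must be finite")
        object.__setattr__(self, "delta_od", od)


@dataclass(frozen=True)
class HemoSeries:
    """Concentration changes (time, channel) in arbitrary units."""

    delta_o2hb: np.ndarray
    delta_hhb: np.ndarray
    sampling_rate: float

    @property
    def delta_thb(self) -> np.ndarray:
        """Total hemoglobin: the sum of the oxy and deoxy changes."""
        return self.delta_o2hb + self.delta_hhb


def _mbll_matrix(coef: MbllCoefficients, distance: float) -> np.ndarray:
    # delta_OD(lambda) = extinction(lambda, chrom) . delta_c * d * DPF(lambda)
    return coef.extinction * distance * coef.dpf[:, None]


def mbll_convert(od: OpticalTimeSeries,
                 coef: MbllCoefficients = DEFAULT_COEFFICIENTS) -> HemoSeries:
    """Invert the modified Beer-Lambert law per sample and channel."""
    a = _mbll_matrix(coef, od.source_detector_distance)
    inv = np.linalg.inv(a)
    conc = np.einsum("ij,tcj->tci", inv, od.delta_od[:, :, :2])
    return HemoSeries(delta_o2hb=conc[:, :, 0], delta_hhb=conc[:, :, 1],
                      sampling_rate=od.sampling_rate)


def mbll_forward(hemo: HemoSeries, coef: MbllCoefficients = DEFAULT_COEFFICIENTS,
                 distance: float = 30.0) -> OpticalTimeSeries:
    """Forward Beer-Lambert map from concentrations to optical densities."""
    a = _mbll_matrix(coef, distance)
    conc = np.stack([hemo.delta_o2hb, hemo.delta_hhb], axis=-1)
    od = np.einsum("ij,tcj->tci", a, conc)
    return OpticalTimeSeries(delta_od=od, sampling_rate=hemo.sampling_rate,
                             source_detector_distance=distance)


def preprocess(series: HemoSeries, detrend: bool = True,
               band: tuple = (0.01, 0.2), order: int = 3) -> HemoSeries:
    """Baseline-correct, linearly detrend and zero-phase band-pass filter."""
    fs = series.sampling_rate
    nyq = fs / 2.0
    if band is not None and not (0.0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq})")

    def _one(x):
        x = x - x[0]
        if detrend:
            x = signal.detrend(x, axis=0, type="linear")
        if band is not None:
            sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
            x = signal.sosfiltfilt(sos, x, axis=0)
        return x

    return HemoSeries(delta_o2hb=_one(series.delta_o2hb),
                      delta_hhb=_one(series.delta_hhb),
                      sampling_rate=fs)


def canonical_hrf(t: np.ndarray, peak: float = 5.0, undershoot: float = 12.0,
                  ratio: float = 0.35) -> np.ndarray:
    """Double-gamma hemodynamic response (peak ~5 s, unit peak height)."""
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    pos = gamma_dist.pdf(t, a=peak, scale=1.0)
    neg = gamma_dist.pdf(t, a=undershoot, scale=1.0)
    h = pos / pos.max() - ratio * neg / max(neg.max(), 1e-12)
    h[t < 0] = 0.0
    return h / np.abs(h).max()


def _hrf_regressors(n_samples: int, fs: float, onsets: np.ndarray,
                    hrf_kwargs: dict | None) -> np.ndarray:
    duration = 30.0
    t_hrf = np.arange(0.0, duration, 1.0 / fs)
    h = canonical_hrf(t_hrf, **(hrf_kwargs or {}))
    x = np.zeros((n_samples, len(onsets)))
    for j, onset in enumerate(onsets):
        sticks = np.zeros(n_samples)
        k = int(round(onset * fs))
        if not 0 <= k < n_samples:
            raise ValueError(f"onset {onset}s outside the series duration")
        sticks[k] = 1.0
        x[:, j] = np.convolve(sticks, h)[:n_samples]
    return x


def glm_trial_amplitudes(series: HemoSeries, onsets, hrf_kwargs: dict = None,
                         drift_order: int = 2,
                         nuisance: np.ndarray = None) -> np.ndarray:
    """Least-squares per-trial response amplitudes, (trial, channel).

    The design has one stick-at-onset convolved HRF regressor per trial
    plus polynomial drift terms; the trial-wise betas on the total
    hemoglobin signal are returned. ``nuisance`` adds optional
    (time, k) regressors — e.g. a short-channel signal to absorb
    superficial-tissue contributions. A rank-deficient design (onsets
    packed tighter than the HRF can separate) raises with a hint about
    the inter-trial interval.
    """
    y = series.delta_thb
    n = y.shape[0]
    fs = series.sampling_rate
    onsets = np.asarray(onsets, dtype=float)
    x_trials = _hrf_regressors(n, fs, onsets, hrf_kwargs)
    t = np.linspace(-1.0, 1.0, n)
    drift = np.column_stack([t ** k for k in range(drift_order + 1)])
    cols = [x_trials, drift]
    if nuisance is not None:
        cols.append(np.atleast_2d(np.asarray(nuisance, float).T).T.reshape(n, -1))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            "rank-deficient GLM design: onsets are too dense for the HRF; "
            "increase the inter-trial interval or drop trials")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return beta[: len(onsets)]


def synth_nirs(amplitudes, onsets, duration: float, sampling_rate: float = 10.0,
               noise_sd: float = 0.0, physio_amp: float = 0.0,
               hhb_ratio: float = -0.3, coef: MbllCoefficients = DEFAULT_COEFFICIENTS,
               distance: float = 30.0, hrf_kwargs: dict = None,
               seed=None) -> OpticalTimeSeries:
    """Forward-synthesise a dual-wavelength optical series from trial amplitudes.

    O2Hb responses are HRF-shaped with the given per-trial amplitudes;
    HHb is a scaled mirror (``hhb_ratio``). Physiological nuisance
    (Mayer ~0.1 Hz and respiratory ~0.3 Hz sinusoids) and white noise
    are added on the optical-density side. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    amplitudes = np.asarray(amplitudes, dtype=float)
    x = _hrf_regressors(n, sampling_rate, np.asarray(onsets, float), hrf_kwargs)
    o2 = (x @ amplitudes)[:, None]
    hemo = HemoSeries(delta_o2hb=o2, delta_hhb=hhb_ratio * o2,
                      sampling_rate=sampling_rate)
    od = mbll_forward(hemo, coef, distance).delta_od
    if physio_amp:
        t = np.arange(n) / sampling_rate
        physio = (np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
                  + 0.5 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi)))
        od = od + physio_amp * physio[:, None, None]
    if noise_sd:
        od = od + noise_sd * rng.standard_normal(od.shape)
    return OpticalTimeSeries(delta_od=od, sampling_rate=sampling_rate,
                             source_detector_distance=distance)
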