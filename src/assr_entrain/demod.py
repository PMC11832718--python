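"""Complex demodulation of the RESS component and derived measures.

The single-channel steady-state response is modeled as
``R(t) = A(t) cos(2 pi f t + phi(t)) + N(t)``.  Complex demodulation (CD)
recovers the envelope ``A(t)`` and phase ``phi(t)``: narrowband bandpass at
the stimulation frequency, multiplication by ``exp(-j 2 pi f t)`` to shift
the band to baseband, then a lowpass to remove the ``2f`` image, leaving
``A(t) exp(j phi(t)) / 2``.

From the demodulated trials this module computes the trial-averaged
amplitude-modulation profile AM(t), the inter-trial phase coherence ITPC(t)
(resultant length of unit phasors across trials, in [0, 1]), average 40 Hz
band power, per-channel 40 Hz topographies, and evoked spectral perturbation
(ERSP) maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .preprocess import EpochedData
from .ress import gaussian_narrowband  # noqa: F401  (re-export convenience)
from .preprocess import design_cheby2

__all__ = [
    "DemodSettings",
    "DemodulatedEpochs",
    "ModulationProfile",
    "Topography",
    "complex_demodulate",
    "amplitude_modulation",
    "itpc",
    "modulation_profile",
    "assr_bandpower",
    "topography_40hz",
    "ersp",
    "ersp_image",
]


@dataclass(frozen=True)
class DemodSettings:
    """Filter parameters for complex demodulation.

    Chebyshev type-II zero-phase filters: a bandpass whose *passband corners*
    are ``bp_band`` (the stimulation band) with stopband edges
    ``bp_transition`` Hz further out, and a lowpass that limits the baseband
    envelope to ``lp_cutoff`` Hz.  The transition band must be wide enough to
    pass the envelope's sidebands: a carrier with an envelope of bandwidth B
    occupies ``f +/- B``, so squeezing the stopband against the passband
    distorts exactly the modulation the method is meant to measure.  The
    lowpass is the effective envelope-bandwidth limit; out-of-band tones
    beyond ``lp_cutoff`` of the carrier are rejected after the frequency
    shift even when the bandpass transition still passes them.
    """

    f: float = 40.0
    bp_band: tuple[float, float] = (39.5, 40.5)
    lp_cutoff: float = 2.0
    bp_order: int = 8
    lp_order: int = 6
    bp_transition: float = 3.5
    rs: float = 40.0

    def __post_init__(self) -> None:
        if not self.bp_band[0] < self.f < self.bp_band[1]:
            raise ValueError("bp_band must bracket f")
        if self.lp_cutoff <= 0:
            raise ValueError("lp_cutoff must be positive")
        if self.bp_transition <= 0:
            raise ValueError("bp_transition must be positive")

    @property
    def bp_stop_edges(self) -> tuple[float, float]:
        return (self.bp_band[0] - self.bp_transition,
                self.bp_band[1] + self.bp_transition)


@dataclass
class DemodulatedEpochs:
    """Complex baseband epochs: ``2 |data|`` estimates the envelope A(t) and
    ``arg(data)`` the phase phi(t)."""

    data: np.ndarray  # complex, (n_trials, n_samples)
    times: np.ndarray
    fs: float
    baseline_window: tuple[float, float]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_mask(self, window) -> np.ndarray:
        return (self.times >= window[0]) & (self.times < window[1])


@dataclass
class ModulationProfile:
    """Baseline-subtracted AM(t) and ITPC(t) series on a shared time axis."""

    t: np.ndarray
    am: np.ndarray
    itpc: np.ndarray
    am_baseline: float
    itpc_baseline: float
    K: int


@dataclass
class Topography:
    channel_labels: tuple[str, ...]
    value: np.ndarray
    p: np.ndarray | None = None


def complex_demodulate(component: EpochedData, settings: DemodSettings | None = None
                       ) -> DemodulatedEpochs:
    """Complex demodulation of a single-channel epoch container.

    Per trial: zero-phase narrowband bandpass, multiplication by
    ``exp(-j 2 pi f t)`` with ``t`` the epoch time axis (relative to stimulus
    onset), then zero-phase lowpass on the real and imaginary parts.
    """
    settings = settings or DemodSettings()
    if component.fs <= 2 * settings.bp_band[1]:
        raise ValueError("sampling rate too low for the bandpass band")
    if component.n_channels != 1:
        raise ValueError("complex_demodulate expects a single-channel component")
    x = component.data[:, 0, :]
    t = component.times

    bp = design_cheby2("bandpass", settings.bp_stop_edges, settings.bp_order,
                       component.fs, rs=settings.rs)
    lp = design_cheby2("lowpass", settings.lp_cutoff, settings.lp_order,
                       component.fs, rs=settings.rs)
    x_bp = signal.sosfiltfilt(bp, x, axis=-1)
    shifted = x_bp * np.exp(-2j * np.pi * settings.f * t)[None, :]
    filt = (signal.sosfiltfilt(lp, shifted.real, axis=-1)
            + 1j * signal.sosfiltfilt(lp, shifted.imag, axis=-1))
    return DemodulatedEpochs(data=filt, times=t.copy(), fs=component.fs,
                             baseline_window=component.baseline_window)


def _baseline_mean(series: np.ndarray, dm: DemodulatedEpochs, baseline_window) -> float:
    mask = dm.time_mask(baseline_window)
    if not mask.any():
        raise ValueError("empty baseline window")
    vals = series[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else 0.0


def amplitude_modulation(dm: DemodulatedEpochs, baseline_window=None):
    """AM(t): trial mean of ``2 |demod|`` minus its baseline-window mean.

    Returns ``(am, baseline)`` with ``am`` already baseline-subtracted.
    """
    if dm.n_trials < 1:
        raise ValueError("need at least one trial")
    baseline_window = baseline_window or dm.baseline_window
    pre = 2.0 * np.abs(dm.data).mean(axis=0)
    baseline = _baseline_mean(pre, dm, baseline_window)
    return pre - baseline, baseline


def itpc(dm: DemodulatedEpochs, baseline_window=None, zero_tol: float = 1e-12):
    """ITPC(t): resultant length of unit phasors across trials, baseline-subtracted.

    Samples whose modulus is below ``zero_tol`` times the series maximum are
    excluded from the phasor average at that time point (0/0 guard); a sample
    where every trial is excluded is carried as NaN.
    Returns ``(itpc, baseline)``.
    """
    if dm.n_trials < 2:
        raise ValueError("ITPC needs at least two trials")
    mod = np.abs(dm.data)
    thresh = zero_tol * max(mod.max(), np.finfo(float).tiny)
    valid = mod > thresh
    phasors = np.where(valid, dm.data / np.where(valid, mod, 1.0), 0.0)
    counts = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        resultant = np.abs(phasors.sum(axis=0)) / counts
    # the resultant length mathematically cannot exceed 1; floating-point
    # normalization can overshoot by a few ulp, so clamp to the bound
    resultant = np.minimum(resultant, 1.0)
    resultant[counts == 0] = np.nan
    baseline_window = baseline_window or dm.baseline_window
    baseline = _baseline_mean(resultant, dm, baseline_window)
    return resultant - baseline, baseline


def modulation_profile(dm: DemodulatedEpochs, baseline_window=None) -> ModulationProfile:
    am, am_b = amplitude_modulation(dm, baseline_window)
    it, it_b = itpc(dm, baseline_window)
    return ModulationProfile(t=dm.times.copy(), am=am, itpc=it,
                             am_baseline=am_b, itpc_baseline=it_b, K=dm.n_trials)


def assr_bandpower(component: EpochedData, f0: float = 40.0, half_width: float = 0.5,
                   window: tuple[float, float] = (0.0, 6.0)) -> float:
    """Average 40 Hz band power: per-epoch power in ``f0 +/- half_width`` over
    the stimulation window, averaged across epochs.  A pure sine of amplitude
    ``a`` yields ``a^2 / 2`` (µV²)."""
    mask = component.time_mask(window)
    n = int(mask.sum())
    if n / component.fs < 2.0:
        raise ValueError("stimulation window must be >= 2 s for 0.5 Hz resolution")
    seg = component.data[:, 0, mask]
    freqs, psd = signal.periodogram(seg, fs=component.fs, axis=-1)
    df = freqs[1] - freqs[0]
    band = (freqs >= f0 - half_width) & (freqs <= f0 + half_width)
    return float((psd[:, band].sum(axis=-1) * df).mean())


def topography_40hz(epochs: EpochedData, f0: float = 40.0,
                    window: tuple[float, float] = (0.0, 6.0)) -> Topography:
    """Per-channel average 40 Hz band power map."""
    mask = epochs.time_mask(window)
    seg = epochs.data[:, :, mask]
    freqs, psd = signal.periodogram(seg, fs=epochs.fs, axis=-1)
    df = freqs[1] - freqs[0]
    band = (freqs >= f0 - 0.5) & (freqs <= f0 + 0.5)
    values = (psd[:, :, band].sum(axis=-1) * df).mean(axis=0)
    return Topography(channel_labels=epochs.channel_labels, value=values)


def ersp(tf_stack: np.ndarray) -> np.ndarray:
    """Evoked spectral perturbation: trial mean of the squared modulus of a
    time-frequency stack (trials x freq x time)."""
    tf_stack = np.asarray(tf_stack)
    if tf_stack.ndim != 3 or tf_stack.shape[0] < 1:
        raise ValueError("tf stack must be non-empty (trials x freq x time)")
    return (np.abs(tf_stack) ** 2).mean(axis=0)


def ersp_image(component: EpochedData, win_dur: float = 0.5, overlap: float = 0.9,
               out_shape: tuple[int, int] | None = (224, 224)):
    """ERSP map of the component via a short-time Fourier transform.

    Hann window of ``win_dur`` seconds with 90% overlap; the trial-averaged
    map is optionally resampled to ``out_shape`` (default 224 x 224, the
    input geometry of standard image classifiers).  Returns
    ``(freqs, times, map)``; with resampling the axes are linearly
    interpolated to the new grid.
    """
    fs = component.fs
    nperseg = int(round(win_dur * fs))
    noverlap = int(round(overlap * nperseg))
    x = component.data[:, 0, :]
    freqs, times, tf = signal.stft(x, fs=fs, window="hann", nperseg=nperseg,
                                   noverlap=noverlap, axis=-1)
    # stft output: (trials, freq, time)
    ersp_map = ersp(tf)
    times = times + component.times[0]
    if out_shape is not None:
        zoom = (out_shape[0] / ersp_map.shape[0], out_shape[1] / ersp_map.shape[1])
        ersp_map = ndimage.zoom(ersp_map, zoom, order=1)
        freqs = np.linspace(freqs[0], freqs[-1], out_shape[0])
        times = np.linspace(times[0], times[-1], out_shape[1])
    return freqs, times, ersp_map
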