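"""Rhythmic Entrainment Source Separation (RESS).

A spatial filter that maximizes power at the stimulation frequency relative
to neighboring frequencies.  Per-trial channel covariances of the epochs
narrowband-filtered at 40 Hz (matrix S) and at the two neighbor frequencies
(matrix R) enter a generalized eigendecomposition S v = lambda R v; the
eigenvector with the largest eigenvalue is the spatial filter, and projecting
every trial through it yields a single "virtual channel" with accentuated
40 Hz content.  Because R^-1 S is non-symmetric the eigenvectors are not
orthogonal, unlike PCA.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .preprocess import EpochedData

__all__ = [
    "RessSettings",
    "RessResult",
    "gaussian_narrowband",
    "narrowband_covariances",
    "ress_decompose",
    "project_component",
    "snr_spectrum",
    "ress_analysis",
]

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class RessSettings:
    """Narrowband filter geometry for the RESS covariance pair.

    The signal covariance uses a Gaussian filter centered at ``f0`` with
    ``fwhm_signal``; the reference covariance averages filters at
    ``f0 +/- neighbor_dist`` with ``fwhm_neighbor``.  Covariances are taken
    over ``window`` (the stimulation period), which maximizes SNR estimated
    from non-stimulation frequencies.
    """

    f0: float = 40.0
    fwhm_signal: float = 0.5
    neighbor_dist: float = 1.0
    fwhm_neighbor: float = 1.0
    window: tuple[float, float] = (0.0, 6.0)
    shrinkage: float = 0.01

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.fwhm_signal <= 0 or self.fwhm_neighbor <= 0:
            raise ValueError("f0 and FWHMs must be positive")
        if self.neighbor_dist <= self.fwhm_signal / 2:
            raise ValueError("neighbor_dist must exceed fwhm_signal / 2")
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage must be in [0, 1]")


@dataclass
class RessResult:
    S: np.ndarray
    R: np.ndarray
    eigenvalues: np.ndarray
    weights: np.ndarray
    component: EpochedData
    snr: float
    snr_capped: bool


def gaussian_narrowband(x: np.ndarray, fs: float, fc: float, fwhm: float) -> np.ndarray:
    """Spectral Gaussian narrowband filter along the last axis.

    Multiplies the amplitude spectrum by a Gaussian centered at ``fc`` whose
    full width at half maximum is ``fwhm`` (gain 1 at fc, 0.5 at
    fc +/- fwhm/2).  Zero-phase by construction.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < fc < fs / 2:
        raise ValueError(f"fc={fc} must lie in (0, {fs / 2})")
    if fwhm >= fc:
        raise ValueError("fwhm must be smaller than fc")
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sd = fwhm / _FWHM_TO_SD
    gain = np.exp(-0.5 * ((freqs - fc) / sd) ** 2)
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * gain, n=n, axis=-1)


def _avg_trial_cov(seg: np.ndarray) -> np.ndarray:
    """Average over trials of per-trial channel covariance (demeaned)."""
    seg = seg - seg.mean(axis=-1, keepdims=True)
    n = seg.shape[-1]
    return np.einsum("kct,kdt->cd", seg, seg) / ((n - 1) * seg.shape[0])


def narrowband_covariances(epochs: EpochedData, settings: RessSettings):
    """Build the (S, R) covariance pair from epoched data.

    Per-trial covariances are computed on the narrowband-filtered stimulation
    window and then averaged over trials.
    """
    if epochs.n_channels < 2:
        raise ValueError("RESS requires >= 2 channels")
    mask = epochs.time_mask(settings.window)
    if mask.sum() < epochs.n_channels:
        import warnings
        warnings.warn("fewer window samples than channels: rank-deficient "
                      "covariances; regularization is mandatory", UserWarning,
                      stacklevel=2)
    seg = epochs.data[:, :, mask]
    s_filt = gaussian_narrowband(seg, epochs.fs, settings.f0, settings.fwhm_signal)
    S = _avg_trial_cov(s_filt)
    R = np.zeros_like(S)
    for fc in (settings.f0 - settings.neighbor_dist, settings.f0 + settings.neighbor_dist):
        r_filt = gaussian_narrowband(seg, epochs.fs, fc, settings.fwhm_neighbor)
        R += _avg_trial_cov(r_filt)
    R /= 2.0
    return S, R


def ress_decompose(S: np.ndarray, R: np.ndarray, shrinkage: float = 0.01):
    """Solve the generalized symmetric-definite eigenproblem S V = R V Lambda.

    R is regularized as ``(1 - g) R + g mean(diag(R)) I`` before the solve.
    Returns eigenvalues in descending order and unit-norm eigenvectors
    (columns), each with its largest-magnitude element made positive.
    """
    S = np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    if S.shape != R.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and R must be square matrices of the same size")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must be in [0, 1]")
    S = (S + S.T) / 2.0
    R = (R + R.T) / 2.0
    r_reg = (1.0 - shrinkage) * R + shrinkage * np.mean(np.diag(R)) * np.eye(len(R))
    try:
        evals, evecs = linalg.eigh(S, r_reg)
    except linalg.LinAlgError as err:
        raise RuntimeError(
            "R is not positive definite after regularization; increase "
            f"shrinkage (got {shrinkage})") from err
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    norms = np.linalg.norm(evecs, axis=0)
    evecs = evecs / norms
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    return evals, evecs * flip


def project_component(epochs: EpochedData, weights: np.ndarray) -> EpochedData:
    """Project every trial through the spatial filter: comp(t) = sum_i w_i x_i(t)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (epochs.n_channels,):
        raise ValueError(
            f"weights length {weights.shape} does not match {epochs.n_channels} channels")
    comp = np.einsum("c,kct->kt", weights, epochs.data)[:, None, :]
    return replace(epochs, data=comp, channel_labels=("RESS",))


SnrEstimate = namedtuple("SnrEstimate", ["value", "capped"])

_SNR_CAP = 1e12


def snr_spectrum(component: EpochedData, f0: float = 40.0, exclude: float = 0.5,
                 flank: float = 2.0, window: tuple[float, float] = (0.0, 6.0)) -> SnrEstimate:
    """Spectral SNR: power at the FFT bin nearest ``f0`` over the mean power
    of flanking bins (within ``+/- flank`` Hz but outside ``+/- exclude``),
    on the trial-averaged power spectrum of the stimulation window.

    A noise-free input drives the flank power to ~0; the ratio is then capped
    at 1e12 and flagged.
    """
    mask = component.time_mask(window)
    n = int(mask.sum())
    if n / component.fs < 2.0:
        raise ValueError("window must be >= 2 s for 0.5 Hz resolution")
    seg = component.data[:, 0, mask]
    spec = np.abs(np.fft.rfft(seg, axis=-1)) ** 2
    spec = spec.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / component.fs)
    i0 = int(np.argmin(np.abs(freqs - f0)))
    dist = np.abs(freqs - freqs[i0])
    flank_mask = (dist > exclude) & (dist <= flank)
    if not flank_mask.any():
        raise ValueError("no flanking bins available; widen flank or window")
    denom = spec[flank_mask].mean()
    if denom <= spec[i0] / _SNR_CAP:
        return SnrEstimate(_SNR_CAP, True)
    return SnrEstimate(float(spec[i0] / denom), False)


def ress_analysis(epochs: EpochedData, settings: RessSettings | None = None) -> RessResult:
    """Full RESS pass: covariances, decomposition, projection and SNR.

    One spatial filter is estimated per subject from all trials jointly and
    applied to each trial.
    """
    settings = settings or RessSettings()
    S, R = narrowband_covariances(epochs, settings)
    evals, evecs = ress_decompose(S, R, settings.shrinkage)
    weights = evecs[:, 0]
    component = project_component(epochs, weights)
    snr = snr_spectrum(component, f0=settings.f0, window=settings.window)
    return RessResult(S=S, R=R, eigenvalues=evals, weights=weights,
                      component=component, snr=snr.value, snr_capped=snr.capped)
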