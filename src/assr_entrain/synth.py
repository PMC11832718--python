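"""Seeded synthetic ASSR recordings and cognition tables.

The generator emulates the statistical structure the analysis assumes: a
40 Hz cortical component whose amplitude envelope follows an MCGF within
each 6 s stimulation window, per-trial phase offsets (wrapped normal) that
control inter-trial phase coherence, a phenomenological per-channel spatial
gain map, additive 1/f background noise, and cognitive scores generated from
declared GLM relations on the ASSR features and back-transformed to their
native scales.

Two group presets encode the qualitative contrast the analysis is designed
to detect: a cognitively stable profile (focal temporal entrainment, larger
envelope magnitude, earlier latency) and a declining profile (diffuse
frontocentral entrainment with higher total band power, delayed latency,
larger phase jitter).  The magnitudes are free parameters of the simulator,
not empirical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS_64, channel_positions
from .mcgf import McgfParams, mcgf_eval
from .preprocess import EpochedData, RawRecording

__all__ = [
    "SessionTimeline",
    "SynthConfig",
    "make_session_timeline",
    "spatial_profile",
    "group_preset",
    "one_over_f_noise",
    "simulate_assr_epochs",
    "simulate_raw",
    "simulate_cognition",
    "default_glm_truth",
    "write_dataset",
]

CARRIER_HZ = 40.0


@dataclass(frozen=True)
class SessionTimeline:
    """Stimulation schedule: ``n_trials`` stimulations of ``stim_dur`` seconds
    separated by ``iti`` seconds, onsets relative to the first onset."""

    n_trials: int
    stim_dur: float
    iti: float
    onsets: tuple[float, ...]
    total_dur: float


def make_session_timeline(n_trials: int, stim_dur: float, iti: float) -> SessionTimeline:
    """Build the session timeline; e.g. 40 trials of 6 s with 5 s ITI span
    435 s (7 min 15 s) from first onset to last offset."""
    if n_trials < 1 or stim_dur <= 0:
        raise ValueError("n_trials must be >= 1 and stim_dur > 0")
    if iti < 0:
        raise ValueError("iti must be >= 0")
    period = Fraction(stim_dur).limit_denominator() + Fraction(iti).limit_denominator()
    onsets = tuple(float(i * period) for i in range(n_trials))
    total = (n_trials * Fraction(stim_dur).limit_denominator()
             + (n_trials - 1) * Fraction(iti).limit_denominator())
    return SessionTimeline(n_trials=n_trials, stim_dur=float(stim_dur),
                           iti=float(iti), onsets=onsets, total_dur=float(total))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic subject's recording."""

    carrier_env_params: McgfParams
    channel_labels: tuple[str, ...] = CHANNELS_64
    fs: float = 250.0
    phase_jitter_sd: float = 0.5       # radians; controls ITPC
    spatial_profile: tuple[float, ...] | None = None  # per-channel gain
    noise_exponent: float = 1.0        # 1/f^beta slope
    noise_scale: float = 0.5           # noise SD as a fraction of envelope A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz (Nyquist margin above 40 Hz)")
        if self.phase_jitter_sd < 0:
            raise ValueError("phase_jitter_sd must be >= 0")
        if self.spatial_profile is not None:
            gains = np.asarray(self.spatial_profile, dtype=float)
            if gains.shape != (len(self.channel_labels),):
                raise ValueError("spatial_profile length must match channel count")
            if not np.all(np.isfinite(gains)):
                raise ValueError("spatial_profile gains must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def gains(self) -> np.ndarray:
        if self.spatial_profile is None:
            return np.ones(self.n_channels)
        return np.asarray(self.spatial_profile, dtype=float)


def spatial_profile(labels, kind: str, spread: float | None = None) -> np.ndarray:
    """Phenomenological per-channel gain map.

    ``focal_temporal``: Gaussian falloff (default spread 0.045 m) from the
    bilateral temporal electrodes T7/T8.  ``diffuse_frontocentral``: broad
    falloff (default spread 0.10 m) from FCz.  Gains are in [0, 1].
    """
    pos = channel_positions(labels)
    if kind == "focal_temporal":
        spread = 0.045 if spread is None else spread
        centers = channel_positions(["T7", "T8"])
    elif kind == "diffuse_frontocentral":
        spread = 0.10 if spread is None else spread
        centers = channel_positions(["FCz"])
    else:
        raise ValueError(f"unknown spatial profile {kind!r}")
    d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2 * spread**2)).max(axis=1)


#: Group presets: the declining group shows a delayed envelope latency,
#: a more diffuse scalp distribution with higher total band power, and less
#: consistent phase across trials.
_GROUP_PRESETS = {
    "highCog": dict(profile="focal_temporal",
                    env=McgfParams(A=1.0, d=1.0, mu=0.3, sigma=0.15, alpha=0.1),
                    phase_jitter_sd=0.5),
    "lowCog": dict(profile="diffuse_frontocentral",
                   env=McgfParams(A=1.2, d=1.0, mu=0.6, sigma=0.15, alpha=0.1),
                   phase_jitter_sd=0.8),
}


def group_preset(group: str, seed: int = 0, channel_labels=CHANNELS_64,
                 latency_offset: float = 0.0) -> SynthConfig:
    """Synthetic-subject configuration for a cognition group.

    ``latency_offset`` shifts the envelope latency mu (seconds), e.g. to
    plant a known between-group latency difference.
    """
    try:
        preset = _GROUP_PRESETS[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}; choose from {sorted(_GROUP_PRESETS)}") from None
    env: McgfParams = preset["env"]
    if latency_offset:
        env = replace(env, mu=env.mu + latency_offset)
    gains = spatial_profile(channel_labels, preset["profile"])
    return SynthConfig(
        carrier_env_params=env, channel_labels=tuple(channel_labels),
        phase_jitter_sd=preset["phase_jitter_sd"],
        spatial_profile=tuple(gains), seed=seed,
    )


def one_over_f_noise(rng: np.random.Generator, shape, fs: float,
                     exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance,
    independent along all leading axes; time is the last axis."""
    shape = tuple(shape)
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec *= freqs ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _envelope(t: np.ndarray, cfg: SynthConfig, stim_dur: float) -> np.ndarray:
    env = np.zeros_like(t)
    active = (t >= 0) & (t < stim_dur)
    env[active] = mcgf_eval(t[active], cfg.carrier_env_params)
    return env


def simulate_assr_epochs(
    cfg: SynthConfig,
    timeline: SessionTimeline,
    window: tuple[float, float] = (-1.0, 6.0),
    baseline_window: tuple[float, float] = (-0.5, -0.25),
) -> EpochedData:
    """Simulate epoched data directly (one epoch per timeline trial).

    Each trial carries ``gain_c * A(t) cos(2 pi 40 t + phi_k)`` with the MCGF
    envelope active during stimulation, a per-trial wrapped-normal phase
    offset, and additive 1/f noise; epochs are baseline-corrected like the
    preprocessing output.  Bit-identical for identical config + seed.
    """
    if CARRIER_HZ >= cfg.fs / 2:
        raise ValueError("carrier above Nyquist")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n_pre = int(round(-window[0] * fs))
    n_len = int(round((window[1] - window[0]) * fs))
    t = (np.arange(n_len) - n_pre) / fs
    env = _envelope(t, cfg, timeline.stim_dur)
    gains = cfg.gains()

    phases = rng.normal(0.0, cfg.phase_jitter_sd, size=timeline.n_trials)
    carrier = env[None, :] * np.cos(
        2 * np.pi * CARRIER_HZ * t[None, :] + phases[:, None])
    data = gains[None, :, None] * carrier[:, None, :]
    if cfg.noise_scale > 0:
        noise_sd = cfg.noise_scale * cfg.carrier_env_params.A
        data = data + noise_sd * one_over_f_noise(
            rng, (timeline.n_trials, cfg.n_channels, n_len), fs, cfg.noise_exponent)

    out = EpochedData(data=data, fs=fs, t0_index=n_pre, window=tuple(window),
                      baseline_window=tuple(baseline_window),
                      channel_labels=cfg.channel_labels)
    bl = out.time_mask(baseline_window)
    out.data = out.data - out.data[:, :, bl].mean(axis=2, keepdims=True)
    return out


def simulate_raw(cfg: SynthConfig, timeline: SessionTimeline,
                 pad: float = 2.0) -> RawRecording:
    """Simulate a continuous recording with stimulus events.

    The session is padded by ``pad`` seconds before the first onset and after
    the last offset so that full epoch windows fit.  Noise runs continuously;
    the 40 Hz component is active only inside stimulation windows.
    """
    if CARRIER_HZ >= cfg.fs / 2:
        raise ValueError("carrier above Nyquist")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    total = timeline.total_dur + 2 * pad
    n = int(round(total * fs))
    t = np.arange(n) / fs
    gains = cfg.gains()

    comp = np.zeros(n)
    phases = rng.normal(0.0, cfg.phase_jitter_sd, size=timeline.n_trials)
    for k, onset in enumerate(timeline.onsets):
        t_on = onset + pad
        tt = t - t_on
        active = (tt >= 0) & (tt < timeline.stim_dur)
        comp[active] += (mcgf_eval(tt[active], cfg.carrier_env_params)
                         * np.cos(2 * np.pi * CARRIER_HZ * tt[active] + phases[k]))
    data = gains[:, None] * comp[None, :]
    if cfg.noise_scale > 0:
        noise_sd = cfg.noise_scale * cfg.carrier_env_params.A
        data = data + noise_sd * one_over_f_noise(
            rng, (cfg.n_channels, n), fs, cfg.noise_exponent)
    events = [(onset + pad, "stim") for onset in timeline.onsets]
    return RawRecording(data=data, fs=fs, channel_labels=cfg.channel_labels,
                        events=events)


# ---------------------------------------------------------------------------
# Cognition tables


def default_glm_truth() -> dict[str, dict[str, float]]:
    """Default generating coefficients on the transformed response scales.

    Signs follow the reported directions (larger AM magnitude with better
    cognition, higher band power and later latency with worse); magnitudes
    are chosen so back-transformed scores stay on their native ranges
    (SOC moves >= 4, problems solved in 0..12).
    """
    return {
        "IQ": {"Intercept": -0.6, "Intercept:highCog": 1.1,
               "A_AM:lowCog": 0.5, "A_ITPC:lowCog": 0.3, "P:lowCog": -0.8},
        "SOCmove": {"Intercept": 0.18, "Intercept:highCog": 0.02,
                    "A_AM:highCog": 0.01, "A_AM:lowCog": 0.01, "P:lowCog": -0.02},
        "SOCprob": {"Intercept": 1.35, "mu_AM:highCog": -0.4, "mu_AM:lowCog": 0.4},
    }


#: Group-level means for the cognitive scores that are not generated through
#: a GLM relation (youth IQ shows no group difference; midlife IQ does).
_SCORE_MEANS = {
    "highCog": dict(BPP18=46.4, IST56=40.9),
    "lowCog": dict(BPP18=45.4, IST56=23.9),
}

SOC_PROB_MAX = 12


def simulate_cognition(
    glm_truth: dict[str, dict[str, float]],
    features: pd.DataFrame,
    noise_sd: float | dict[str, float] = 0.0,
    seed: int = 0,
    integer_outcomes: bool = True,
) -> pd.DataFrame:
    """Generate a cognition table from ASSR features via declared GLM truths.

    For each response the declared coefficients are applied to the design
    matrix built from ``features`` (missing terms count as zero, unknown term
    names raise), Gaussian noise is added on the transformed scale, and the
    result is back-transformed: IQ stays on the z-scale (mapped affinely to
    an IST-like score), SOC mean moves is the reciprocal, problems solved is
    ``12 - exp(y)`` clipped to [0, 12] and, when ``integer_outcomes``,
    rounded to an integer count.

    ``noise_sd`` is a single SD applied to every transformed response, or a
    mapping per response id — the transformed scales differ by an order of
    magnitude (reciprocal moves ~0.2, z-scores and reflected logs ~1), so
    cohort simulations normally pass a mapping.
    """
    from .stats_glm import build_design

    if not isinstance(noise_sd, dict):
        noise_sd = {rid: float(noise_sd) for rid in ("IQ", "SOCmove", "SOCprob")}
    if any(sd < 0 for sd in noise_sd.values()):
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(features)

    transformed = {}
    for response_id in ("IQ", "SOCmove", "SOCprob"):
        X, names = build_design(features, response_id)
        coeffs = dict(glm_truth.get(response_id, {}))
        beta = np.zeros(len(names))
        for term, value in coeffs.items():
            if term not in names:
                raise KeyError(
                    f"unknown design term {term!r} for response {response_id!r}; "
                    f"valid terms: {names}")
            beta[names.index(term)] = value
        sd = noise_sd.get(response_id, 0.0)
        mean_part = X @ beta
        if response_id == "SOCmove" and coeffs and np.any(mean_part <= 0):
            raise ValueError(
                "SOCmove truth produced non-positive transformed values")
        transformed[response_id] = mean_part + rng.normal(0.0, sd, size=n)

    noisy = any(sd > 0 for sd in noise_sd.values())
    groups = features["group"].astype(str).to_numpy()
    means = np.array([[_SCORE_MEANS[g]["BPP18"], _SCORE_MEANS[g]["IST56"]]
                      for g in groups])
    bpp18 = means[:, 0] + rng.normal(0, 4.0 * noisy, size=n)
    ist56 = means[:, 1] + rng.normal(0, 6.0 * noisy, size=n)
    ist60 = 31.5 + 6.0 * transformed["IQ"]

    # noise can push individual reciprocal responses to zero; floor at 25 moves
    soc_moves = np.maximum(1.0 / np.maximum(transformed["SOCmove"], 0.04), 4.0)

    soc_prob = np.clip(SOC_PROB_MAX - np.exp(transformed["SOCprob"]), 0, SOC_PROB_MAX)
    if integer_outcomes:
        soc_prob = np.rint(soc_prob)

    think_init = np.maximum(rng.normal(8.0, 3.0 * noisy + 1e-12, size=n), 0.0)
    think_sub = np.maximum(rng.normal(2.0, 1.0 * noisy + 1e-12, size=n), 0.0)

    ids = (features["id"] if "id" in features.columns
           else pd.Series([f"S{i:03d}" for i in range(n)]))
    return pd.DataFrame({
        "id": np.asarray(ids), "group": groups,
        "BPP18": bpp18, "IST56": ist56, "IST60": ist60,
        "SOC_moves_4": soc_moves, "SOC_prob_min": soc_prob,
        "SOC_init_think": think_init, "SOC_subseq_think": think_sub,
    })


def write_dataset(out_dir, cfg: SynthConfig, timeline: SessionTimeline,
                  cognition: pd.DataFrame | None = None, stem: str = "subject") -> dict:
    """Write one subject's EDF recording + events CSV (+ optional cognition
    CSV); paths round-trip through the preprocessing readers."""
    from .edf import write_edf, write_events_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = simulate_raw(cfg, timeline)
    edf_path = out_dir / f"{stem}.edf"
    events_path = out_dir / f"{stem}_events.csv"
    write_edf(edf_path, raw.data, raw.fs, raw.channel_labels)
    write_events_csv(events_path, [e[0] for e in raw.events], timeline.stim_dur)
    paths = {"edf": edf_path, "events": events_path}
    if cognition is not None:
        cog_path = out_dir / "cognition.csv"
        cognition.to_csv(cog_path, index=False)
        paths["cognition"] = cog_path
    return paths
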