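"""Minimal EDF (European Data Format) writer.

Writes standard 16-bit EDF with one-second data records and physical units
of µV, sufficient for round-tripping synthetic recordings through any EDF
reader.  Only writing lives here; reading goes through MNE
(:func:`assr_entrain.preprocess.read_raw_edf`), which serves as an
independent parser for round-trip checks.
"""

from __future__ import annotations

import datetime

import numpy as np

__all__ = ["write_edf", "write_events_csv"]


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, channel_labels,
              physical_dim: str = "uV") -> None:
    """Write ``data`` (channels x samples, µV) to an EDF file.

    ``fs`` must be a positive integer (samples per one-second record).  The
    last record is zero-padded if the signal length is not a whole number of
    seconds; 16-bit quantization limits round-trip accuracy to about
    ``peak / 32767`` per channel.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels length mismatch")
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = data

    # Per-channel symmetric physical range; digital range is the full int16 span.
    peak = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    phys_max = peak
    phys_min = -peak
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate 01-JAN-2000 X X X", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(256 * (n_ch + 1), 8),
        _field("", 44),
        _field(n_rec, 8),
        _field(1, 8),
        _field(n_ch, 4),
    ])

    def sig_fields(values, width):
        return b"".join(_field(v, width) for v in values)

    def fmt8(x: float) -> str:
        # EDF numeric header fields are 8 ASCII chars; shrink precision to fit
        for prec in range(8, 0, -1):
            s = f"{x:.{prec}g}"
            if len(s) <= 8:
                return s
        raise ValueError(f"cannot format {x} in 8 characters")

    header += sig_fields(channel_labels, 16)
    header += sig_fields(["EEG"] * n_ch, 80)
    header += sig_fields([physical_dim] * n_ch, 8)
    header += sig_fields([fmt8(v) for v in phys_min], 8)
    header += sig_fields([fmt8(v) for v in phys_max], 8)
    header += sig_fields([dig_min] * n_ch, 8)
    header += sig_fields([dig_max] * n_ch, 8)
    header += sig_fields([""] * n_ch, 80)
    header += sig_fields([fs] * n_ch, 8)
    header += sig_fields([""] * n_ch, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        # record-major layout: all samples of channel 1, then channel 2, ...
        records = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(records).tobytes())


def write_events_csv(path, onsets, duration: float, label: str = "stim") -> None:
    """Write a stimulus-onset table with columns onset_s, duration_s, label."""
    import pandas as pd

    pd.DataFrame({
        "onset_s": list(onsets),
        "duration_s": [duration] * len(onsets),
        "label": [label] * len(onsets),
    }).to_csv(path, index=False)
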