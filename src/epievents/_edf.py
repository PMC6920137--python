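"""Minimal EDF writer (16-bit, one-second data records).

Covers exactly what the synthetic fixtures need: multichannel signals with a
shared sampling rate, microvolt units and per-channel physical scaling.
Readable by any EDF reader (the package reads fixtures back through MNE).
"""

from __future__ import annotations

import numpy as np


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, samples: np.ndarray, fs: float,
              channel_labels: list[str], patient_id: str = "X") -> None:
    """Write (n_channels, n_times) microvolt data to an EDF file.

    ``fs`` must be a positive integer (samples per one-second data record).
    The final partial record, if any, is zero-padded.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n_ch, n_times = samples.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels length mismatch")
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("fs must be a positive integer for 1 s data records")
    spr = int(round(fs))  # samples per record per channel
    n_rec = int(np.ceil(n_times / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_times] = samples

    amax = max(float(np.abs(padded).max()), 1.0)
    phys_max = float(np.ceil(amax))
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    header = b""
    header += _field("0", 8)
    header += _field(patient_id, 80)
    header += _field("synthetic iEEG", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(256 * (1 + n_ch), 8)
    header += _field("", 44)
    header += _field(n_rec, 8)
    header += _field(1, 8)  # record duration, seconds
    header += _field(n_ch, 4)
    for lab in channel_labels:
        header += _field(lab, 16)
    header += b"".join(_field("", 80) for _ in range(n_ch))
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{phys_min:g}", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{phys_max:g}", 8) for _ in range(n_ch))
    header += b"".join(_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))
    header += b"".join(_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))

    digital = np.round((padded - phys_min) * scale + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]  # channel-sequential
            fh.write(block.tobytes())
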