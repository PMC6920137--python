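"""Short-time power spectrogram averaged into eight spectral bands.

The working representation of the detector: power in non-overlapping 0.25 s
Hann-tapered windows on a 4 Hz frequency grid (at the default window length),
averaged into eight bands spanning theta through three ripple sub-bands.  The
ripple range (>124 Hz) is split into three sub-bands with gaps around 120,
180 and 200 Hz where line-interference harmonics can appear; the gap between
gamma1 and gamma2 similarly avoids 60 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import EegRecord


@dataclass(frozen=True)
class Band:
    name: str
    low: float   # Hz, inclusive
    high: float  # Hz, exclusive


class BandSet:
    """Ordered, non-overlapping set of frequency bands.

    Band membership is half-open ``[low, high)`` on the spectrogram frequency
    grid; with a 4 Hz grid a printed shared edge (e.g. 8 Hz between theta and
    alpha) is counted once, in the upper band.
    """

    def __init__(self, bands: list[Band]):
        if len(bands) != len({b.name for b in bands}):
            raise ValueError("duplicate band names")
        for a, b in zip(bands, bands[1:]):
            if b.low < a.high:
                raise ValueError(f"bands {a.name} and {b.name} overlap or are unordered")
        self.bands = list(bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def band_of(self, freq: float) -> str | None:
        """Name of the band containing ``freq``, or None if it falls in a gap."""
        for b in self.bands:
            if b.low <= freq < b.high:
                return b.name
        return None

    def masks(self, freqs: np.ndarray) -> list[np.ndarray]:
        out = []
        for b in self.bands:
            m = (freqs >= b.low) & (freqs < b.high)
            if not m.any():
                raise ValueError(
                    f"band {b.name} [{b.low}, {b.high}) contains no frequency-grid point"
                )
            out.append(m)
        return out


#: The eight analysis bands (Hz): theta, alpha, beta, gamma1, gamma2 and
#: three ripple sub-bands.  Gaps around 60, 120, 180 and 200 Hz avoid line
#: interference and its harmonics.
DEFAULT_BANDS = BandSet([
    Band("theta", 4, 8),
    Band("alpha", 8, 13),
    Band("beta", 13, 30),
    Band("gamma1", 30, 56),
    Band("gamma2", 64, 116),
    Band("rip1", 124, 176),
    Band("rip2", 184, 196),
    Band("rip3", 204, 236),
])

RIPPLE_BANDS = ("rip1", "rip2", "rip3")


@dataclass
class BandSpectrogram:
    """Per-channel, per-band, per-time-bin spectral power.

    ``power`` has shape (n_channels, n_bands, n_bins); ``bin_duration`` is the
    window length in seconds (default 0.25); ``hop_s`` is the stride between
    successive windows (default half the window — see :func:`stft_power`);
    ``t0`` is the start time of the first bin.
    """

    power: np.ndarray
    bin_duration: float
    band_set: BandSet
    hop_s: float | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.hop_s is None:
            self.hop_s = self.bin_duration

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]

    @property
    def n_bins(self) -> int:
        return self.power.shape[2]

    def bin_time(self, b: int) -> float:
        """Start time of bin ``b`` (s)."""
        return self.t0 + b * self.hop_s


def _hop_samples(nper: int, fs: float, hop_s: float | None) -> int:
    """Window stride in samples; default half the window (floor for odd
    window lengths, so bin times stay exact multiples of the sample period)."""
    hop = nper // 2 if hop_s is None else int(round(hop_s * fs))
    if hop < 1 or hop > nper:
        raise ValueError("hop_s must be positive and at most the window length")
    return hop


def stft_power(record: EegRecord, window_s: float = 0.25,
               window_fn: str = "hann",
               hop_s: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Short-time FFT power on left-aligned Hann windows.

    Returns ``(power, freqs)`` where ``power`` has shape
    (n_channels, n_freqs, n_bins) and ``freqs`` is the one-sided grid with
    step ``1/window_s`` (4 Hz for 0.25 s windows).  Power is the one-sided
    squared spectrum scaled so that its sum over frequencies equals the
    energy of the tapered window (Parseval); the detector only ever uses
    power *ratios*, so the absolute scale is a convention.

    ``hop_s`` is the stride between window starts; the default is half the
    window (50% overlap).  A tapered window is nearly zero at its edges, so
    with *no* overlap a brief event straddling a window boundary is strongly
    attenuated in both adjacent windows and can be missed entirely; the
    half-window hop keeps every instant near the centre of some window while
    preserving the window length and frequency resolution.  Pass
    ``hop_s=window_s`` for non-overlapping windows.  The trailing partial
    window is dropped.
    """
    nper = window_s * record.fs
    if abs(nper - round(nper)) > 1e-9:
        raise ValueError("window_s * fs must be an integer number of samples")
    nper = int(round(nper))
    if nper < 8:
        raise ValueError("window too short")
    if record.n_times < nper:
        raise ValueError(
            f"record of {record.n_times} samples shorter than one "
            f"{nper}-sample window"
        )
    hop = _hop_samples(nper, record.fs, hop_s)
    n_bins = (record.n_times - nper) // hop + 1
    starts = np.arange(n_bins) * hop
    idx = starts[:, None] + np.arange(nper)[None, :]
    x = record.samples[:, idx]  # (channels, n_bins, nper)
    from scipy.signal import get_window
    w = get_window(window_fn, nper, fftbins=True)
    xw = x * w
    spec = np.fft.rfft(xw, axis=2)
    power = np.abs(spec) ** 2 / nper
    # one-sided: double everything except DC (and Nyquist when nper is even)
    mult = np.full(power.shape[2], 2.0)
    mult[0] = 1.0
    if nper % 2 == 0:
        mult[-1] = 1.0
    power *= mult
    power = np.transpose(power, (0, 2, 1))  # (channels, freqs, bins)
    freqs = np.fft.rfftfreq(nper, d=1.0 / record.fs)
    return power, freqs


def band_average(power: np.ndarray, freqs: np.ndarray,
                 band_set: BandSet = DEFAULT_BANDS,
                 bin_duration: float = 0.25, hop_s: float | None = None,
                 t0: float = 0.0) -> BandSpectrogram:
    """Average the full spectrogram over frequencies within each band."""
    if freqs.max() < band_set.bands[-1].low:
        raise ValueError("frequency grid does not cover the requested bands")
    masks = band_set.masks(freqs)
    out = np.stack([power[:, m, :].mean(axis=1) for m in masks], axis=1)
    return BandSpectrogram(power=out, bin_duration=bin_duration,
                           band_set=band_set, hop_s=hop_s, t0=t0)


def band_spectrogram(record: EegRecord, window_s: float = 0.25,
                     band_set: BandSet = DEFAULT_BANDS,
                     hop_s: float | None = None) -> BandSpectrogram:
    """Convenience chain: :func:`stft_power` then :func:`band_average`."""
    power, freqs = stft_power(record, window_s=window_s, hop_s=hop_s)
    nper = int(round(window_s * record.fs))
    hop_actual = _hop_samples(nper, record.fs, hop_s) / record.fs
    return band_average(power, freqs, band_set=band_set,
                        bin_duration=window_s, hop_s=hop_actual)
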