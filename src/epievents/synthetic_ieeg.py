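"""Synthetic multichannel iEEG with annotated epileptiform events.

The generator emulates the statistical structure the detector and classifier
operate on: Gaussian 1/f^alpha background activity, sharp biphasic interictal
spikes (20-70 ms), Hann-enveloped ripple bursts (>3 oscillation cycles at
120-250 Hz inside the rip1/rip2/rip3 passbands), ripples-on-spikes (joint
injection), optional 60 Hz line interference, and per-subject multiplicative
morphology jitter on amplitude, duration and ripple frequency — the driver
of limited between-subject generalisation.  Every injection is recorded in a
log that serves as the synthetic ground truth, standing in for the visual
verification used with clinical recordings.

Events of different classes never overlap (>= 1 s separation), so each
0.25 s bin has a unique true label.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .baseline_detector import EventLabel
from .io_preprocess import EegRecord

#: Ripple sub-band passbands (Hz); injected ripple frequencies must lie
#: inside one of these (a burst in an inter-band gap would be invisible to
#: the band set).
RIPPLE_PASSBANDS = ((124.0, 176.0), (184.0, 196.0), (204.0, 236.0))
_RIPPLE_MARGIN = 3.0  # Hz kept clear of passband edges


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Amplitudes are in multiples of the background SD (= RMS of the zero-mean
    background).  Defaults: spikes at 8-12x SD and ripples at 4-6x SD on an
    alpha=1 background — amplitudes at which the threshold detector recovers
    the injections reliably, making the injection log a faithful ground
    truth.  ``morphology_jitter_sigma`` is the log-normal sigma of the
    per-subject multiplicative offsets.
    """

    n_subjects: int = 7
    n_channels: int = 4
    fs: float = 500.0
    segment_duration: float = 600.0
    alpha: float = 1.0
    background_rms: float = 20.0          # uV
    spike_amp_range: tuple[float, float] = (8.0, 12.0)
    spike_duration_ms: tuple[float, float] = (20.0, 70.0)
    ripple_freq_range: tuple[float, float] = (127.0, 233.0)
    ripple_cycles: tuple[int, int] = (5, 9)
    ripple_amp_range: tuple[float, float] = (4.0, 6.0)
    spike_rate: float = 2.0               # events per minute per class
    ripple_rate: float = 2.0
    rons_rate: float = 2.0
    line_noise_amp: float = 0.0           # uV, 60 Hz
    morphology_jitter_sigma: float = 0.2
    min_separation_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.spike_duration_ms
        if not (20.0 <= lo <= hi <= 70.0):
            raise ValueError("spike durations must lie within 20-70 ms")
        if self.ripple_cycles[0] < 4:
            raise ValueError("ripple bursts must contain more than 3 cycles")
        if not 0.5 <= self.alpha <= 2.0:
            raise ValueError("background exponent alpha must be in [0.5, 2]")


@dataclass
class Injection:
    """One ground-truth event in the log."""

    subject: str
    channel: int
    onset_s: float
    duration_s: float
    label: EventLabel
    amplitude: float              # peak, uV
    centre_freq: float | None = None  # Hz, ripples/RonS only


class InjectionLog:
    """The synthetic ground truth: every injected event with its class."""

    def __init__(self, injections: list[Injection] | None = None):
        self.injections: list[Injection] = list(injections or [])

    def __len__(self) -> int:
        return len(self.injections)

    def __iter__(self):
        return iter(self.injections)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for inj in self.injections:
            out[inj.label.value] = out.get(inj.label.value, 0) + 1
        return out

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject", "channel", "onset_s", "duration_s",
                        "label", "amplitude", "centre_freq"])
            for i in self.injections:
                w.writerow([i.subject, i.channel, f"{i.onset_s:.4f}",
                            f"{i.duration_s:.4f}", i.label.value,
                            f"{i.amplitude:.3f}",
                            "" if i.centre_freq is None else f"{i.centre_freq:.2f}"])

    @classmethod
    def from_csv(cls, path) -> "InjectionLog":
        out = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                out.append(Injection(
                    subject=row["subject"], channel=int(row["channel"]),
                    onset_s=float(row["onset_s"]),
                    duration_s=float(row["duration_s"]),
                    label=EventLabel(row["label"]),
                    amplitude=float(row["amplitude"]),
                    centre_freq=(float(row["centre_freq"])
                                 if row["centre_freq"] else None)))
        return cls(out)


def make_background(duration: float, fs: float, alpha: float = 1.0,
                    rms: float = 20.0, seed=None) -> np.ndarray:
    """Gaussian 1/f^alpha noise with the exact target RMS.

    Spectral shaping in the Fourier domain: white Gaussian noise is scaled by
    f^(-alpha/2) (power then falls as 1/f^alpha), DC removed, and the series
    rescaled to ``rms``.
    """
    if duration < 10.0:
        raise ValueError("background segments must be at least 10 s")
    if not 0.5 <= alpha <= 2.0:
        raise ValueError("alpha must be in [0.5, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x -= x.mean()
    return x * (rms / np.sqrt(np.mean(x ** 2)))


def make_spike(duration_ms: float, amplitude: float, fs: float) -> np.ndarray:
    """Biphasic sharp transient: a fast positive lobe followed by a slower
    opposite deflection, zero mean, peak at ``amplitude`` (uV).

    Built from two Gaussians (smooth, so spectral energy concentrates in the
    beta-gamma range and decays fast above ~120 Hz: a real spike has no
    genuine ripple-band power — any post-highpass oscillation is a filter
    artifact, the classic "false ripple").
    """
    if not 20.0 <= duration_ms <= 70.0:
        raise ValueError("spike duration must be within 20-70 ms")
    if amplitude == 0:
        return np.zeros(int(round(duration_ms * 1e-3 * fs)))
    dur = duration_ms * 1e-3
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    # fast lobe: width scales with duration but never below 2.5 ms, so the
    # spectrum decays fast above ~120 Hz (a spike has no genuine ripple power)
    s1 = max(0.10 * dur, 2.5e-3)
    t1 = max(0.30 * dur, 1.25 * s1)
    t2, s2 = 0.65 * dur, 0.160 * dur   # slow opposite lobe
    g1 = np.exp(-0.5 * ((t - t1) / s1) ** 2)
    g2 = np.exp(-0.5 * ((t - t2) / s2) ** 2)
    w = g1 - (s1 / s2) * g2            # equal areas -> near-zero mean
    # remove the residual mean smoothly (Hann-shaped correction keeps edges at 0)
    hann = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1))
    w = w - (w.sum() / hann.sum()) * hann
    return w * (amplitude / np.abs(w).max())


def spike_peak_offset(duration_ms: float) -> float:
    """Time (s) from spike onset to the fast-lobe peak."""
    return 0.30 * duration_ms * 1e-3


def make_ripple(centre_freq: float, n_cycles: int, amplitude: float,
                fs: float) -> np.ndarray:
    """Hann-enveloped sinusoidal burst of ``n_cycles`` oscillations.

    ``centre_freq`` must lie inside one of the three ripple passbands — a
    burst at e.g. 180 Hz would fall in an inter-band gap and be invisible to
    the band set.  More than 3 cycles are required for a ripple.
    """
    if n_cycles < 4:
        raise ValueError("a ripple must contain more than 3 oscillation cycles")
    if not any(lo <= centre_freq < hi for lo, hi in RIPPLE_PASSBANDS):
        raise ValueError(
            f"{centre_freq} Hz falls outside the ripple passbands "
            f"{RIPPLE_PASSBANDS} (inter-band interference gap)")
    dur = n_cycles / centre_freq
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    env = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1))
    return amplitude * env * np.sin(2 * np.pi * centre_freq * t)


def _snap_ripple_freq(f: float) -> float:
    """Clip a jittered frequency into the nearest allowed passband interior."""
    best, dist = None, np.inf
    for lo, hi in RIPPLE_PASSBANDS:
        c = float(np.clip(f, lo + _RIPPLE_MARGIN, hi - _RIPPLE_MARGIN))
        if abs(c - f) < dist:
            best, dist = c, abs(c - f)
    return best


@dataclass
class _Morphology:
    amp: float
    dur: float
    freq: float


def _subject_morphology(spec: SyntheticSpec, rng: np.random.Generator) -> _Morphology:
    s = spec.morphology_jitter_sigma
    return _Morphology(*np.exp(s * rng.standard_normal(3)))


def generate_subject(spec: SyntheticSpec, subject_index: int,
                     include_rons: bool = True,
                     ) -> tuple[EegRecord, InjectionLog]:
    """Generate one subject's record and its injection log.

    Reproducible from (spec.seed, subject_index).  Events are scheduled as a
    merged Poisson process thinned to classes, with the >= 1 s separation
    enforced by pushing each event past the previous one; at the default
    rates the push is rarely binding and per-class counts stay Poisson-like.
    ``include_rons=False`` emulates a subject in whom no RonS occur.
    """
    rng = np.random.default_rng([spec.seed, subject_index])
    subject_id = f"S{subject_index}"
    morph = _subject_morphology(spec, rng)
    n = int(round(spec.segment_duration * spec.fs))
    samples = np.stack([
        make_background(spec.segment_duration, spec.fs, spec.alpha,
                        spec.background_rms, seed=rng)
        for _ in range(spec.n_channels)
    ])
    phase = rng.uniform(0, 2 * np.pi)  # drawn unconditionally: keeps the
    # event schedule identical whether or not line noise is enabled
    if spec.line_noise_amp > 0:
        t = np.arange(n) / spec.fs
        samples += spec.line_noise_amp * np.sin(2 * np.pi * 60.0 * t + phase)

    rates = {EventLabel.SPIKE: spec.spike_rate,
             EventLabel.RIPPLE: spec.ripple_rate,
             EventLabel.RONS: spec.rons_rate if include_rons else 0.0}
    total_rate = sum(rates.values()) / 60.0  # per second
    log = InjectionLog()
    if total_rate > 0:
        labels = [k for k, v in rates.items() if v > 0]
        probs = np.array([rates[k] for k in labels]) / (total_rate * 60.0)
        sd = spec.background_rms
        t_cursor = 1.0
        prev_end = 1.0
        max_dur = 0.25
        while True:
            t_cursor += rng.exponential(1.0 / total_rate)
            onset = max(t_cursor, prev_end + spec.min_separation_s)
            if onset + max_dur + 1.0 > spec.segment_duration:
                break
            lab = labels[rng.choice(len(labels), p=probs)]
            ch = int(rng.integers(spec.n_channels))
            if lab in (EventLabel.SPIKE, EventLabel.RONS):
                d_ms = float(np.clip(rng.uniform(*spec.spike_duration_ms)
                                     * morph.dur, 20.0, 70.0))
                amp = rng.uniform(*spec.spike_amp_range) * morph.amp * sd
                wave = make_spike(d_ms, amp, spec.fs)
                dur_s = len(wave) / spec.fs
                cf = None
                if lab is EventLabel.RONS:
                    cf = _snap_ripple_freq(rng.uniform(*spec.ripple_freq_range)
                                           * morph.freq)
                    cyc = int(rng.integers(spec.ripple_cycles[0],
                                           spec.ripple_cycles[1] + 1))
                    ramp = rng.uniform(*spec.ripple_amp_range) * morph.amp * sd
                    rip = make_ripple(cf, cyc, ramp, spec.fs)
                    # centre the burst on the spike peak
                    off = int(round(spike_peak_offset(d_ms) * spec.fs)) - len(rip) // 2
                    off = max(off, 0)
                    full = wave.copy()
                    if off + len(rip) > len(full):
                        full = np.concatenate([full,
                                               np.zeros(off + len(rip) - len(full))])
                    full[off:off + len(rip)] += rip
                    wave = full
                    dur_s = len(wave) / spec.fs
            else:  # ripple
                cf = _snap_ripple_freq(rng.uniform(*spec.ripple_freq_range)
                                       * morph.freq)
                cyc = int(rng.integers(spec.ripple_cycles[0],
                                       spec.ripple_cycles[1] + 1))
                amp = rng.uniform(*spec.ripple_amp_range) * morph.amp * sd
                wave = make_ripple(cf, cyc, amp, spec.fs)
                dur_s = len(wave) / spec.fs
            i0 = int(round(onset * spec.fs))
            if i0 + len(wave) > n:
                break
            samples[ch, i0:i0 + len(wave)] += wave
            log.injections.append(Injection(
                subject=subject_id, channel=ch, onset_s=onset,
                duration_s=dur_s, label=lab,
                amplitude=float(np.abs(wave).max()), centre_freq=cf))
            prev_end = onset + dur_s
            t_cursor = max(t_cursor, onset)

    labels_ch = [f"CH{c + 1}" for c in range(spec.n_channels)]
    rec = EegRecord(samples=samples, fs=spec.fs, channel_labels=labels_ch,
                    subject_id=subject_id)
    return rec, log


def write_fixture(record: EegRecord, log: InjectionLog, path) -> tuple[str, str]:
    """Write an EDF fixture plus its CSV injection log; returns both paths.

    The EDF round-trips through :func:`epievents.read_edf` within 16-bit
    quantization error of the configured physical range.
    """
    from ._edf import write_edf

    edf_path = str(path)
    csv_path = edf_path.rsplit(".", 1)[0] + "_injections.csv"
    write_edf(edf_path, record.samples, record.fs, record.channel_labels,
              patient_id=record.subject_id or "X")
    log.to_csv(csv_path)
    return edf_path, csv_path
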