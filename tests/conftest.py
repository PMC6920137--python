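"""Shared fixtures: short synthetic records and the full two-site cohort.

Expensive end-to-end artifacts (the cohort, the 100-trial injection runs)
are session-scoped so several tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import epievents as ep
from epievents.baseline_detector import EventLabel


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def short_record(rng):
    """20 s, 2 channels of 1/f background, no events."""
    fs = 500.0
    x = np.stack([ep.make_background(20.0, fs, 1.0, 20.0, seed=rng)
                  for _ in range(2)])
    return ep.EegRecord(x, fs, ["CH1", "CH2"], subject_id="test")


def single_event_trial(kind: str, seed: int, fs: float = 500.0,
                       duration: float = 25.0, amp_mult: float | None = None):
    """Inject one event on 1/f background, run the detection pipeline, and
    return (labels at the event's bin +/-1, rel powers at the best bin,
    highpassed-record, onset, wave length).
    """
    rng = np.random.default_rng(seed)
    bg = np.stack([ep.make_background(duration, fs, 1.0, 20.0, seed=rng)])
    if kind == "spike":
        d_ms = rng.uniform(20, 70)
        amp = (amp_mult if amp_mult is not None else rng.uniform(8, 12)) * 20.0
        wave = ep.make_spike(d_ms, amp, fs)
    else:
        freq = rng.uniform(127, 173)
        wave = ep.make_ripple(freq, int(rng.integers(5, 10)),
                              (amp_mult if amp_mult is not None
                               else rng.uniform(4, 6)) * 20.0, fs)
    onset = rng.uniform(8.0, duration - 8.0)
    i0 = int(onset * fs)
    raw = bg.copy()
    raw[0, i0:i0 + len(wave)] += wave
    rec = ep.preprocess(ep.EegRecord(raw, fs, ["CH1"]))
    bs = ep.band_spectrogram(rec)
    rel = ep.normalize(bs, ep.compute_baseline(bs))
    cands = {c.bin: c for c in ep.detect_candidates(rel)}
    b = ep.injection_bin(onset, len(wave) / fs, rel.bin_duration, rel.hop_s)
    bins = [cands[bb] for bb in (b - 1, b, b + 1) if bb in cands]
    labels = [c.label for c in bins]
    best = max(bins, key=lambda c: c.rel_powers.max())
    return labels, best.rel_powers, raw, onset, len(wave)


@pytest.fixture(scope="session")
def spike_trials():
    """100 seeded single-spike pipelines (8-12x SD amplitudes)."""
    return [single_event_trial("spike", s) for s in range(100)]


@pytest.fixture(scope="session")
def ripple_trials():
    """100 seeded single-ripple pipelines (4-6x SD amplitudes)."""
    return [single_event_trial("ripple", s) for s in range(100)]


@pytest.fixture(scope="session")
def cohort():
    """The two-site synthetic cohort of the global-network protocol:
    7 training-site + 2 held-out-site subjects, 200 events/class/subject,
    morphology jitter sigma=0.2, master seed 42."""
    from epievents.benchmark import build_cohort

    return build_cohort(seed=42, n_train_site=7, n_holdout=2,
                        events_per_class=200, jitter=0.2)


def prototype_features(n_per_class: int, n_subjects: int, seed: int = 0,
                       separation: float = 10.0):
    """Synthetic feature sets with one informative cell per class — a fast
    stand-in for pipeline output in structural/scaling tests."""
    rng = np.random.default_rng(seed)
    by_subject = {}
    for s in range(n_subjects):
        feats = []
        for k, lab in enumerate(ep.CLASS_ORDER):
            for j in range(n_per_class):
                f = rng.random((8, 3))
                f[k, 1] += separation * (k + 1)
                feats.append(ep.EventFeature(features=f, label=lab,
                                             subject_id=f"P{s}", channel=0,
                                             bin=len(feats)))
        by_subject[f"P{s}"] = feats
    return by_subject
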