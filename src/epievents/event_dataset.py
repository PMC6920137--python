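"""Feature extraction, balanced ground-truth sets and randomized splits.

Each event is represented by an 8 bands x 3 time steps matrix of relative
powers: the candidate's own 0.25 s bin plus the preceding and the following
bin.  The 3-bin context avoids losing events split across a bin edge and
gives the sequence classifier temporal context.  Balanced per-subject sets
(default 1000 events per class) are drawn uniformly without replacement
across all channels and segments, and train/test splits are disjoint within
every randomization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .baseline_detector import (
    CLASS_ORDER,
    EventCandidate,
    EventLabel,
    RelativeSpectrogram,
)


@dataclass
class EventFeature:
    """One classifier input: 8 bands x 3 bins (t-1, t, t+1) of relative power."""

    features: np.ndarray  # (8, 3)
    label: EventLabel
    subject_id: str = ""
    channel: int = 0
    bin: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (8, 3):
            raise ValueError(f"features must be 8x3, got {self.features.shape}")
        if (self.features < 0).any():
            raise ValueError("relative powers must be nonnegative")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.subject_id, self.channel, self.bin, self.label.value)


def extract_feature(rel: RelativeSpectrogram,
                    candidate: EventCandidate,
                    subject_id: str = "") -> EventFeature:
    """8x3 feature matrix for one candidate.

    The middle column is the candidate's own bin; flanks are its neighbours.
    At segment edges the missing neighbour column is replicated from the
    candidate bin so the 8x3 shape is preserved.
    """
    r = rel.rel_power[candidate.channel]  # (8, n_bins)
    b = candidate.bin
    mid = r[:, b]
    prev = r[:, b - 1] if b > 0 else mid
    nxt = r[:, b + 1] if b < rel.n_bins - 1 else mid
    return EventFeature(features=np.stack([prev, mid, nxt], axis=1),
                        label=candidate.label, subject_id=subject_id,
                        channel=candidate.channel, bin=b)


@dataclass
class GroundTruthSet:
    """Balanced event sets grouped by (subject, class).

    ``cells`` maps (subject_id, label) to a list of :class:`EventFeature`.
    A cell flagged *short* has fewer events than the configured size; a
    missing class for a subject (e.g. no RonS found) is an empty cell, not an
    error.
    """

    cells: dict[tuple[str, EventLabel], list[EventFeature]] = field(default_factory=dict)
    n_per_class: int = 1000

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.cells})

    def events(self, subject: str, label: EventLabel) -> list[EventFeature]:
        return self.cells.get((subject, label), [])

    def counts(self) -> dict[tuple[str, str], int]:
        return {(s, lab.value): len(v) for (s, lab), v in self.cells.items()}

    def short_cells(self) -> list[tuple[str, EventLabel]]:
        return [k for k, v in self.cells.items() if len(v) < self.n_per_class]

    def all_events(self) -> list[EventFeature]:
        out: list[EventFeature] = []
        for s in self.subjects:
            for lab in CLASS_ORDER:
                out.extend(self.events(s, lab))
        return out


def assemble_ground_truth(candidates_by_subject: dict[str, list[EventFeature]],
                          n_per_class: int = 1000,
                          seed: int | None = 0) -> GroundTruthSet:
    """Uniform random subsample, without replacement, stratified by
    (subject, class), across all channels/segments.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    gt = GroundTruthSet(n_per_class=n_per_class)
    for subject in sorted(candidates_by_subject):
        feats = candidates_by_subject[subject]
        for lab in CLASS_ORDER:
            pool = [f for f in feats if f.label is lab]
            # de-duplicate on (subject, channel, bin, label)
            seen: set[tuple] = set()
            uniq = []
            for f in pool:
                if f.key not in seen:
                    seen.add(f.key)
                    uniq.append(f)
            if not uniq:
                gt.cells[(subject, lab)] = []
                continue
            if len(uniq) <= n_per_class:
                sel = list(uniq)
            else:
                idx = rng.choice(len(uniq), size=n_per_class, replace=False)
                sel = [uniq[i] for i in sorted(idx)]
            gt.cells[(subject, lab)] = sel
    return gt


def injection_bin(onset_s: float, duration_s: float,
                  bin_duration: float = 0.25, hop_s: float = 0.125) -> int:
    """Index of the analysis window whose centre is nearest the event centre."""
    centre = onset_s + duration_s / 2.0
    return max(0, int(round((centre - bin_duration / 2.0) / hop_s)))


def verify_candidates(candidates: list[EventCandidate],
                      injections,
                      bin_duration: float = 0.25,
                      hop_s: float = 0.125,
                      tolerance_bins: int = 2) -> list[EventCandidate]:
    """Keep candidates whose detector label matches the synthetic injection
    log — the stand-in for the visual-verification step used with clinical
    recordings.

    A non-baseline candidate is kept if an injection of the same class lies
    on the same channel within ``tolerance_bins`` bins of the candidate bin.
    A baseline candidate is kept if no injection of any class is within
    ``tolerance_bins`` bins on its channel.
    """
    by_channel: dict[int, list] = {}
    for inj in injections:
        by_channel.setdefault(inj.channel, []).append(inj)
    kept = []
    for c in candidates:
        injs = by_channel.get(c.channel, [])
        near = [inj for inj in injs
                if abs(injection_bin(inj.onset_s, inj.duration_s,
                                     bin_duration, hop_s) - c.bin)
                <= tolerance_bins]
        if c.label is EventLabel.BASELINE:
            if not near:
                kept.append(c)
        else:
            if any(inj.label is c.label for inj in near):
                kept.append(c)
    return kept


@dataclass
class SplitSpec:
    """Randomized disjoint train/test split sizes per (subject, class)."""

    n_train: int = 500
    n_test: int = 500
    n_randomizations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 0 or self.n_test <= 0 or self.n_randomizations < 1:
            raise ValueError("invalid split sizes")


def make_splits(gt: GroundTruthSet, spec: SplitSpec
                ) -> list[tuple[list[EventFeature], list[EventFeature]]]:
    """``n_randomizations`` disjoint (train, test) pairs.

    Within each randomization and each non-empty (subject, class) cell,
    ``n_train`` events are drawn for training and ``n_test`` disjoint events
    for testing.  Empty cells are skipped (a subject may lack a class).
    """
    rng = np.random.default_rng(spec.seed)
    splits = []
    for _ in range(spec.n_randomizations):
        train: list[EventFeature] = []
        test: list[EventFeature] = []
        for s in gt.subjects:
            for lab in CLASS_ORDER:
                cell = gt.events(s, lab)
                if not cell:
                    continue
                need = spec.n_train + spec.n_test
                if len(cell) < need:
                    raise ValueError(
                        f"cell ({s}, {lab.value}) has {len(cell)} events; "
                        f"{need} required for the split"
                    )
                perm = rng.permutation(len(cell))
                train.extend(cell[i] for i in perm[: spec.n_train])
                test.extend(cell[i] for i in perm[spec.n_train: need])
        splits.append((train, test))
    return splits


def features_to_csv(events: list[EventFeature], path,
                    manifest: dict | None = None) -> None:
    """Serialize events (one row per event, 24 feature columns) with an
    optional ``# key=value`` manifest header recording seed and counts."""
    with open(path, "w", newline="") as fh:
        if manifest:
            for k, v in manifest.items():
                fh.write(f"# {k}={v}\n")
        w = csv.writer(fh)
        cols = [f"f{b}_{t}" for t in range(3) for b in range(8)]
        w.writerow(["subject", "channel", "bin", "label"] + cols)
        for e in events:
            w.writerow([e.subject_id, e.channel, e.bin, e.label.value]
                       + [f"{v:.6g}" for v in e.features.T.ravel()])


def features_from_csv(path) -> list[EventFeature]:
    events = []
    with open(path) as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.reader(rows)
    next(reader)  # header
    for row in reader:
        subj, ch, b, lab = row[0], int(row[1]), int(row[2]), EventLabel(row[3])
        feats = np.array([float(v) for v in row[4:]]).reshape(3, 8).T
        events.append(EventFeature(features=feats, label=lab, subject_id=subj,
                                   channel=ch, bin=b))
    return events
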