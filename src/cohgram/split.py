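"""Subject-wise fold assignment and non-overlapping segmentation.

Leakage avoidance is structural: folds are assigned at the *subject*
level first, and recordings are segmented afterwards, so no segment of
any subject can ever appear on both sides of a train/test split.
Segments are fixed-length (10/20/30 s typically) with zero overlap;
within a segment, sliding analysis windows (0.4 s, 50% overlap by
default) feed the coherence transform.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .io import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SplitPlan",
    "WindowSpec",
    "seconds_to_samples",
    "assign_folds",
    "segment_recording",
    "slide_windows",
    "n_windows",
]


def seconds_to_samples(seconds: float, sfreq: float) -> int:
    """Convert a duration to samples with round-half-up.

    Exact at 500 Hz for the standard values (0.4 s -> 200, 0.2 s -> 100)
    and well defined at any other rate.
    """
    return int(math.floor(seconds * sfreq + 0.5))


@dataclasses.dataclass
class Segment:
    """A fixed-length, zero-overlap slice of a Recording; inherits the
    recording's subject_id and label verbatim."""

    subject_id: str
    label: str | None
    segment_index: int
    sfreq: float
    data: np.ndarray
    segment_length_s: float

    def __post_init__(self) -> None:
        expected = seconds_to_samples(self.segment_length_s, self.sfreq)
        if self.data.shape[1] != expected:
            raise InputError(
                f"segment has {self.data.shape[1]} samples, expected {expected}"
            )


@dataclasses.dataclass
class SplitPlan:
    """Subject -> fold assignment for k-fold cross-validation."""

    k: int
    assignment: dict[str, int]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        bad = {s: f for s, f in self.assignment.items() if not 0 <= f < self.k}
        if bad:
            raise ConfigurationError(f"fold indices out of [0, {self.k}): {bad}")

    def fold_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.assignment.items() if f == fold}

    def train_test_subjects(self, fold: int) -> tuple[set[str], set[str]]:
        test = self.fold_subjects(fold)
        train = set(self.assignment) - test
        return train, test


@dataclasses.dataclass
class WindowSpec:
    """Sliding analysis window: 0.4 s advanced in 0.2 s steps (50%
    overlap) by default."""

    window_s: float = 0.4
    step_s: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.window_s:
            raise ConfigurationError(
                f"need 0 < step_s <= window_s, got {self.step_s}, {self.window_s}"
            )


def assign_folds(
    subjects: Sequence[tuple[str, str | None]],
    k: int,
    seed: int = 0,
) -> SplitPlan:
    """Stratified, seeded random partition of subjects into k folds.

    Within each class label, subjects are shuffled and dealt round-robin
    across folds, so folds stay class-balanced to within one subject.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    ids = [s for s, _ in subjects]
    if len(ids) != len(set(ids)):
        raise ConfigurationError("duplicate subject_ids")
    by_label: dict[str | None, list[str]] = {}
    for sid, label in subjects:
        by_label.setdefault(label, []).append(sid)
    for label, members in by_label.items():
        if len(members) < k:
            raise ConfigurationError(
                f"class {label!r} has {len(members)} subjects but k={k}"
            )
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for label in sorted(by_label, key=str):
        members = sorted(by_label[label])
        order = rng.permutation(len(members))
        for pos, idx in enumerate(order):
            assignment[members[idx]] = pos % k
    return SplitPlan(k=k, assignment=assignment)


def segment_recording(rec: Recording, segment_length_s: float) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping fixed-length
    segments; the trailing remainder is dropped.

    A recording shorter than one segment yields an empty list with a
    logged warning (not an error).
    """
    if not segment_length_s > 0:
        raise ConfigurationError("segment_length_s must be positive")
    seg_samples = seconds_to_samples(segment_length_s, rec.sfreq)
    n_segments = rec.n_samples // seg_samples
    if n_segments == 0:
        logger.warning(
            "recording %s (%.1f s) shorter than one %g s segment; skipped",
            rec.subject_id, rec.duration_s, segment_length_s,
        )
        return []
    return [
        Segment(
            subject_id=rec.subject_id,
            label=rec.label,
            segment_index=i,
            sfreq=rec.sfreq,
            data=rec.data[:, i * seg_samples:(i + 1) * seg_samples].copy(),
            segment_length_s=segment_length_s,
        )
        for i in range(n_segments)
    ]


def n_windows(n_samples: int, sfreq: float, spec: WindowSpec) -> int:
    """Number of sliding windows that fit: floor((L - w)/s) + 1."""
    w = seconds_to_samples(spec.window_s, sfreq)
    s = seconds_to_samples(spec.step_s, sfreq)
    if w > n_samples:
        raise InputError(
            f"window of {w} samples longer than segment of {n_samples}"
        )
    return (n_samples - w) // s + 1


def slide_windows(seg: Segment, spec: WindowSpec) -> list[np.ndarray]:
    """Sliding windows of a segment, ordered by start time.

    Window starts form an arithmetic sequence with common difference
    step_s in samples; at the defaults consecutive windows overlap by
    exactly half a window.  A trailing partial window is dropped.
    """
    w = seconds_to_samples(spec.window_s, seg.sfreq)
    s = seconds_to_samples(spec.step_s, seg.sfreq)
    count = n_windows(seg.data.shape[1], seg.sfreq, spec)
    return [seg.data[:, i * s:i * s + w] for i in range(count)]
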