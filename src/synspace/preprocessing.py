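"""Segmentation, averaging, filtering and normalization of reaching sessions.

Turns a continuous five-channel recording into (a) the averaged,
filtered, normalized source matrix fed to the synergy decomposition and
(b) individual filtered, normalized trials used to train the decoder.
Processing order for the source matrix: segment -> time-normalize ->
average -> zero-phase Butterworth low-pass -> min-max normalize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._common import CHANNELS, SHOULDER_IDX
from .synthetic_motion import Session

__all__ = [
    "MotionTrial",
    "NormalizationRecord",
    "SourceMatrix",
    "SegmentationError",
    "segment_trials",
    "time_normalize",
    "average_trials",
    "lowpass",
    "fit_normalization",
    "assemble_source_matrix",
    "angular_velocities",
]


class SegmentationError(RuntimeError):
    """No movements (or the wrong number) detected in a session."""


@dataclass
class MotionTrial:
    """One segmented reaching movement: 5 angle channels x time, degrees.

    ``start``/``end`` optionally record the half-open sample range the
    trial occupied in its source session."""

    trial_id: str
    target_id: int
    angles: np.ndarray  # (5, T)
    rate: float
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.angles.shape[1] < 2:
            raise ValueError("a trial needs at least 2 samples")
        if not np.isfinite(self.angles).all():
            raise ValueError("trial contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[1]


@dataclass(frozen=True)
class NormalizationRecord:
    """Per-channel affine map sending the training min/max to -1/+1.

    ``role`` tags what the record was fitted on ("angles" or
    "velocities") so a record is never applied to the wrong signal kind.
    """

    mins: np.ndarray
    maxs: np.ndarray
    role: str = "angles"
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "mins", np.asarray(self.mins, dtype=float))
        object.__setattr__(self, "maxs", np.asarray(self.maxs, dtype=float))
        if np.any(self.maxs <= self.mins):
            bad = [
                self.channel_names[i]
                for i in np.flatnonzero(self.maxs <= self.mins)
            ]
            raise ValueError(f"constant channel(s) cannot be normalized: {bad}")

    def apply(self, values: np.ndarray, rows: slice | None = None) -> np.ndarray:
        """Map degrees to [-1, 1] (no clipping; out-of-range stays outside)."""
        mins, maxs = self._rows(rows)
        return 2.0 * (values - mins[:, None]) / (maxs - mins)[:, None] - 1.0

    def invert(self, values: np.ndarray, rows: slice | None = None) -> np.ndarray:
        """Map normalized values back to degrees."""
        mins, maxs = self._rows(rows)
        return (values + 1.0) / 2.0 * (maxs - mins)[:, None] + mins[:, None]

    def _rows(self, rows: slice | None) -> tuple[np.ndarray, np.ndarray]:
        if rows is None:
            return self.mins, self.maxs
        return self.mins[rows], self.maxs[rows]

    def coverage(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of samples falling outside the fitted range."""
        mapped = self.apply(values)
        return np.abs(mapped) > 1.0


@dataclass
class SourceMatrix:
    """The normalized j x (m * tmax) matrix of averaged movements.

    Columns are the per-target averaged movements concatenated in target
    order; ``segment_boundaries`` (m + 1 indices) delimit the blocks.
    """

    values: np.ndarray
    normalization: NormalizationRecord
    segment_boundaries: np.ndarray
    target_order: tuple[int, ...]
    channel_means: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.segment_boundaries = np.asarray(self.segment_boundaries, dtype=int)
        if np.max(np.abs(self.values)) > 1.0 + 1e-9:
            raise ValueError("source matrix entries must lie in [-1, 1]")
        if np.any(np.diff(self.segment_boundaries) <= 0):
            raise ValueError("segment boundaries must be strictly increasing")
        if self.segment_boundaries[0] != 0 or self.segment_boundaries[-1] != self.values.shape[1]:
            raise ValueError("segment boundaries must span the full column range")
        self.channel_means = self.values.mean(axis=1)

    def block(self, k: int) -> np.ndarray:
        a, b = self.segment_boundaries[k], self.segment_boundaries[k + 1]
        return self.values[:, a:b]


def _speed_trace(session: Session, smooth_cutoff: float) -> np.ndarray:
    """Smoothed aggregate angular speed: Euclidean norm of the
    per-channel finite-difference velocities of the low-passed angles.

    Smoothing is applied to the angles before differentiating; for the
    zero-phase filter the two orders are equivalent in the interior but
    filtering first avoids the large edge transients that differencing
    raw measurement noise produces."""
    angles = session.angles
    nyq = session.rate / 2.0
    if 0 < smooth_cutoff < nyq:
        sos = signal.butter(4, smooth_cutoff / nyq, output="sos")
        angles = signal.sosfiltfilt(sos, angles, axis=1)
    vel = np.gradient(angles, axis=1) * session.rate
    return np.linalg.norm(vel, axis=0)


def segment_trials(
    session: Session,
    speed_threshold_fraction: float = 0.05,
    smooth_cutoff: float = 2.0,
    sustain_s: float = 0.1,
    close_sustain_s: float = 0.15,
    min_duration_s: float = 0.3,
) -> list[MotionTrial]:
    """Cut a continuous session into individual reaching movements.

    Movement onset is the first sample where the smoothed aggregate
    speed exceeds a threshold for at least ``sustain_s``; the offset is
    the condition on the return to rest, sustained for
    ``close_sustain_s``.  The close condition is longer than the open
    one because an out-and-back reach pauses briefly at its reversal
    point, whereas a genuine rest lasts on the order of half a second.
    The threshold is set a fraction of the way from the rest-speed
    floor (10th percentile of the trace) to the session peak, so
    detection is robust to measurement noise at rest; with a clean
    signal it reduces to a fraction of the peak speed.  Candidate
    movements shorter than ``min_duration_s`` are discarded as noise
    blips.

    When the session carries target labels, the detected count must
    match the labeled count; otherwise a ``SegmentationError`` is raised
    with the speed-trace diagnostics attached.
    """
    T = session.angles.shape[1]
    if speed_threshold_fraction == 0:
        return [
            MotionTrial(
                trial_id=f"{session.subject_id}-{session.kind}-000",
                target_id=session.target_ids[0] if session.target_ids else -1,
                angles=session.angles.copy(),
                rate=session.rate,
            )
        ]
    speed = _speed_trace(session, smooth_cutoff)
    peak = float(speed.max())
    floor = float(np.percentile(speed, 10.0))
    if peak <= 0 or peak - floor < 1e-12:
        raise SegmentationError(
            f"no motion detected: peak speed {peak:.3g} deg/s, floor {floor:.3g}"
        )
    thr = floor + speed_threshold_fraction * (peak - floor)
    sustain = max(1, int(round(sustain_s * session.rate)))
    close_sustain = max(1, int(round(close_sustain_s * session.rate)))
    min_len = max(2, int(round(min_duration_s * session.rate)))

    above = speed > thr
    # run-length encode the boolean trace
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] + (edges + 1).tolist()
    runs = [(s, e, bool(above[s])) for s, e in zip(starts, starts[1:] + [T])]

    segments: list[tuple[int, int]] = []
    open_start: int | None = None
    for s, e, is_above in runs:
        if is_above and e - s >= sustain and open_start is None:
            open_start = s
        elif not is_above and e - s >= close_sustain and open_start is not None:
            segments.append((open_start, s))
            open_start = None
    if open_start is not None:
        segments.append((open_start, T))
    segments = [(a, b) for a, b in segments if b - a >= min_len]

    if not segments:
        raise SegmentationError(
            "no movements detected "
            f"(threshold {thr:.3g} deg/s, peak {peak:.3g}, floor {floor:.3g})"
        )
    if session.target_ids and len(segments) != len(session.target_ids):
        raise SegmentationError(
            f"detected {len(segments)} movements but the session labels "
            f"{len(session.target_ids)} (threshold {thr:.3g} deg/s)"
        )
    labels = session.target_ids or [-1] * len(segments)
    return [
        MotionTrial(
            trial_id=f"{session.subject_id}-{session.kind}-{k:03d}",
            target_id=labels[k],
            angles=session.angles[:, a:b].copy(),
            rate=session.rate,
            start=a,
            end=b,
        )
        for k, (a, b) in enumerate(segments)
    ]


def time_normalize(trial: MotionTrial, target_length: int) -> MotionTrial:
    """Resample every channel to ``target_length`` samples by linear
    interpolation on the normalized time axis [0, 1]; endpoints are
    preserved exactly."""
    if target_length < 2:
        raise ValueError("target_length must be at least 2")
    T = trial.n_samples
    if target_length == T:
        return MotionTrial(trial.trial_id, trial.target_id, trial.angles.copy(), trial.rate)
    u_old = np.linspace(0.0, 1.0, T)
    u_new = np.linspace(0.0, 1.0, target_length)
    resampled = np.vstack([np.interp(u_new, u_old, ch) for ch in trial.angles])
    return MotionTrial(trial.trial_id, trial.target_id, resampled, trial.rate)


def average_trials(trials: list[MotionTrial]) -> MotionTrial:
    """Element-wise mean of time-aligned trials sharing one target."""
    if not trials:
        raise ValueError("need at least one trial")
    targets = {t.target_id for t in trials}
    if len(targets) > 1:
        raise ValueError(f"cannot average trials with mixed targets: {sorted(targets)}")
    lengths = {t.n_samples for t in trials}
    if len(lengths) > 1:
        raise ValueError("trials must be time-normalized to a common length first")
    mean = np.mean([t.angles for t in trials], axis=0)
    return MotionTrial(
        trial_id=f"avg-target{trials[0].target_id}",
        target_id=trials[0].target_id,
        angles=mean,
        rate=trials[0].rate,
    )


def lowpass(trial: MotionTrial, order: int = 6, cutoff: float = 10.0) -> MotionTrial:
    """Zero-phase Butterworth low-pass (forward-backward) per channel.

    The stated order is the design order of the one-pass filter; the
    forward-backward application doubles the effective order and cancels
    the phase.  DC is preserved (unit passband gain at 0 Hz).
    """
    nyq = trial.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    sos = signal.butter(order, cutoff / nyq, output="sos")
    filtered = signal.sosfiltfilt(sos, trial.angles, axis=1)
    return MotionTrial(trial.trial_id, trial.target_id, filtered, trial.rate)


def fit_normalization(
    trials: list[MotionTrial] | list[np.ndarray],
    role: str = "angles",
    channel_names: tuple[str, ...] = CHANNELS,
) -> NormalizationRecord:
    """Fit per-channel min/max over all supplied (training) samples."""
    if not trials:
        raise ValueError("need at least one trial")
    arrays = [t.angles if isinstance(t, MotionTrial) else np.asarray(t) for t in trials]
    stacked = np.concatenate(arrays, axis=1)
    return NormalizationRecord(
        mins=stacked.min(axis=1),
        maxs=stacked.max(axis=1),
        role=role,
        channel_names=channel_names,
    )


def assemble_source_matrix(
    averaged: list[MotionTrial], normalization: NormalizationRecord
) -> SourceMatrix:
    """Concatenate the per-target averaged movements into the source matrix."""
    if not averaged:
        raise ValueError("need at least one averaged trial")
    lengths = {t.n_samples for t in averaged}
    if len(lengths) > 1:
        raise ValueError(f"averaged trials differ in length: {sorted(lengths)}")
    ordered = sorted(averaged, key=lambda t: t.target_id)
    tmax = ordered[0].n_samples
    values = np.concatenate([normalization.apply(t.angles) for t in ordered], axis=1)
    boundaries = np.arange(len(ordered) + 1) * tmax
    return SourceMatrix(
        values=values,
        normalization=normalization,
        segment_boundaries=boundaries,
        target_order=tuple(t.target_id for t in ordered),
    )


def angular_velocities(trial: MotionTrial) -> np.ndarray:
    """Shoulder angular velocities (3 x T, degrees/second).

    Central finite differences scaled by the sampling rate, with
    one-sided differences at the endpoints.  Expects an already
    low-pass-filtered trial.
    """
    if trial.n_samples < 3:
        raise ValueError("need at least 3 samples for central differences")
    return np.gradient(trial.angles[SHOULDER_IDX], axis=1) * trial.rate
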