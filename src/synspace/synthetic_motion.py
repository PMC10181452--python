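"""Synthetic reaching-motion generator with planted kinematic synergies.

Emulates the study design the decoding pipeline expects: per subject, a
training session of repeated reaching movements toward each point of an
8-target grid and a validation session of random-target movements, all
recorded as five joint-angle channels (three shoulder, two forearm) at
120 Hz.  Every movement is driven by a small number of latent activation
signals through a subject-specific spatial synergy basis, so the
low-dimensional structure the pipeline is meant to recover is present by
construction, and the ground truth is kept alongside each session for
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._common import CHANNELS, N_CHANNELS, derive_seed

__all__ = [
    "CohortConfig",
    "GroundTruthSubject",
    "Session",
    "activation_pulse",
    "generate_basis",
    "generate_activation_profile",
    "generate_subject_session",
    "generate_cohort",
    "write_subject_dir",
    "read_subject_dir",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the experimental protocol being emulated: 8 reaching
    targets, 15 training repetitions per target, 35 random-target
    validation movements, 120 Hz sampling.  ``noise_sd`` is i.i.d.
    Gaussian measurement noise per channel sample, in degrees;
    joint-angle streams from an IMU motion-capture skeletal model are
    smooth, so the default is sub-degree.
    """

    n_subjects: int = 14
    n_targets: int = 8
    n_train_trials_per_target: int = 15
    n_validation_movements: int = 35
    sampling_rate: float = 120.0
    movement_duration: float = 1.5
    rest_duration: float = 0.5
    n_latent: int = 2
    noise_sd: float = 0.5
    inter_subject_basis_sd: float = 0.08
    amplitude_scale: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_targets": self.n_targets,
            "n_train_trials_per_target": self.n_train_trials_per_target,
            "n_validation_movements": self.n_validation_movements,
            "n_latent": self.n_latent,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.inter_subject_basis_sd < 0:
            raise ValueError("inter_subject_basis_sd must be non-negative")
        if self.n_latent > N_CHANNELS:
            raise ValueError(
                f"n_latent={self.n_latent} cannot exceed the {N_CHANNELS} channels"
            )


@dataclass
class GroundTruthSubject:
    """Simulation ground truth for one subject.

    ``true_basis`` plays the role of the spatial synergy loadings the
    pipeline estimates; ``target_amplitudes`` holds the peak activation
    of each latent component for each reaching target.
    """

    subject_id: str
    true_basis: np.ndarray          # (5, n_latent), orthonormal columns
    baseline_posture: np.ndarray    # (5,) resting angles, degrees
    target_amplitudes: np.ndarray   # (n_targets, n_latent), degrees

    def __post_init__(self) -> None:
        self.true_basis = np.asarray(self.true_basis, dtype=float)
        if np.linalg.matrix_rank(self.true_basis) < self.true_basis.shape[1]:
            raise ValueError("true_basis columns must be linearly independent")


@dataclass
class Session:
    """One continuous recording: angles (5 x T, degrees) plus ground truth.

    ``boundaries`` holds half-open [start, end) sample ranges of the true
    movements, ``target_ids`` the matching target label per movement.
    """

    subject_id: str
    kind: str                       # "training" | "validation"
    angles: np.ndarray              # (5, T)
    rate: float
    boundaries: list[tuple[int, int]] = field(default_factory=list)
    target_ids: list[int] = field(default_factory=list)

    @property
    def n_movements(self) -> int:
        return len(self.boundaries)


def activation_pulse(u) -> np.ndarray:
    """Raised-cosine out-and-back pulse on normalized time u in [0, 1].

    Zero (with zero slope) at both endpoints, unit peak at u = 0.5,
    infinitely differentiable in the interior.
    """
    u = np.asarray(u, dtype=float)
    return np.sin(np.pi * u) ** 2


def generate_basis(n_channels: int, n_latent: int, seed: int) -> np.ndarray:
    """Draw an orthonormal spatial basis (n_channels x n_latent).

    Columns are orthonormalized seeded Gaussian draws, sign-fixed so the
    largest-magnitude entry of each column is positive.
    """
    if not 1 <= n_latent <= n_channels:
        raise ValueError(
            f"need 1 <= n_latent <= n_channels, got {n_latent} > {n_channels}"
        )
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_channels, n_latent))
    q, _ = np.linalg.qr(raw)
    return _fix_signs(q[:, :n_latent])


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Flip columns to a deterministic sign: loading sum positive.

    The sum of loadings is a smooth functional of the column, so the
    convention is stable under small perturbations of the basis (a
    largest-entry rule is not, once several channels carry near-equal
    weight).  Columns whose loadings sum to nearly zero fall back to
    the largest-magnitude entry.
    """
    basis = basis.copy()
    for k in range(basis.shape[1]):
        col = basis[:, k]
        total = col.sum()
        anchor = total if abs(total) > 1e-8 else col[np.argmax(np.abs(col))]
        if anchor < 0:
            basis[:, k] = -col
    return basis


def generate_activation_profile(
    target_id: int, duration: float, rate: float, amplitudes
) -> np.ndarray:
    """Latent activation time courses for one movement (n_latent x T).

    Each latent channel rises smoothly to its target-specific amplitude
    and returns to zero.  Channel n is the raised-cosine pulse
    s = sin^2(pi u) sharpened by a factor ((0.7 + 0.6 s) / 1.3)^n, so
    the latents have linearly independent time courses (a movement
    genuinely spans ``n_latent`` temporal dimensions) while every
    channel keeps the unit peak at mid-movement, the exact-zero
    endpoints and the quadratic onset/offset tails the segmenter
    expects.
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    n_samples = int(round(duration * rate))
    if n_samples < 4:
        raise ValueError("duration * rate must yield at least 4 samples")
    u = np.linspace(0.0, 1.0, n_samples)
    s = activation_pulse(u)
    profile = np.empty((amplitudes.size, n_samples))
    for n, amp in enumerate(amplitudes):
        profile[n] = amp * s * ((0.7 + 0.6 * s) / 1.3) ** n
    profile[:, 0] = 0.0
    profile[:, -1] = 0.0
    return profile


def _movement_block(
    subject: GroundTruthSubject,
    target: int,
    duration: float,
    rate: float,
) -> np.ndarray:
    """Noise-free angle block (5 x T) for one movement toward ``target``."""
    profile = generate_activation_profile(
        target, duration, rate, subject.target_amplitudes[target]
    )
    return subject.baseline_posture[:, None] + subject.true_basis @ profile


def _assemble_session(
    subject: GroundTruthSubject,
    targets: list[int],
    durations: list[float],
    config: CohortConfig,
    rng: np.random.Generator,
    kind: str,
) -> Session:
    rate = config.sampling_rate
    n_rest = int(round(config.rest_duration * rate))
    rest = np.repeat(subject.baseline_posture[:, None], n_rest, axis=1)

    blocks = [rest]
    boundaries: list[tuple[int, int]] = []
    cursor = n_rest
    for target, duration in zip(targets, durations):
        move = _movement_block(subject, target, duration, rate)
        blocks.append(move)
        boundaries.append((cursor, cursor + move.shape[1]))
        cursor += move.shape[1]
        blocks.append(rest)
        cursor += n_rest
    angles = np.concatenate(blocks, axis=1)
    if config.noise_sd > 0:
        angles = angles + rng.normal(0.0, config.noise_sd, size=angles.shape)
    return Session(
        subject_id=subject.subject_id,
        kind=kind,
        angles=angles,
        rate=rate,
        boundaries=boundaries,
        target_ids=list(targets),
    )


def generate_subject_session(
    subject: GroundTruthSubject, config: CohortConfig, seed: int
) -> tuple[Session, Session]:
    """Generate the (training, validation) session pair for one subject.

    The training session holds ``n_targets * n_train_trials_per_target``
    movements in target-blocked order; the validation session holds
    ``n_validation_movements`` toward uniformly drawn targets.  Each
    movement's duration is jittered by a seeded uniform factor in
    [0.9, 1.1].  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(seed)

    train_targets = [
        t
        for t in range(config.n_targets)
        for _ in range(config.n_train_trials_per_target)
    ]
    train_durations = [
        config.movement_duration * rng.uniform(0.9, 1.1) for _ in train_targets
    ]
    training = _assemble_session(
        subject, train_targets, train_durations, config, rng, "training"
    )

    val_targets = list(
        rng.integers(0, config.n_targets, size=config.n_validation_movements)
    )
    val_durations = [
        config.movement_duration * rng.uniform(0.9, 1.1) for _ in val_targets
    ]
    validation = _assemble_session(
        subject, [int(t) for t in val_targets], val_durations, config, rng, "validation"
    )
    return training, validation


def _target_amplitudes(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Peak latent activations per target (n_targets x n_latent), degrees.

    For two latents the targets sit at equally spaced directions of an
    eccentric ring: the first synergy carries most of the movement and
    the second modulates it target by target, reproducing the dominant
    first-component variance spectrum characteristic of planar reaching
    (first component well above half the variance, first two nearly
    all of it).  For other latent counts the amplitudes are seeded
    uniform draws with random signs.
    """
    if config.n_latent == 2:
        theta = 2.0 * np.pi * np.arange(config.n_targets) / config.n_targets
        # The reach synergy is engaged strongly for every target (no
        # reach is close to zero-effort); the second synergy modulates
        # with a quarter of its spread, giving the dominant-first
        # variance spectrum while keeping all movements detectable.
        amps = config.amplitude_scale * np.column_stack(
            [1.0 + 0.4 * np.cos(theta), 0.35 * np.sin(theta) + 0.03]
        )
        return amps
    mags = rng.uniform(0.4, 1.0, size=(config.n_targets, config.n_latent))
    signs = rng.choice([-1.0, 1.0], size=mags.shape)
    return config.amplitude_scale * mags * signs


def _reference_basis(n_channels: int, n_latent: int, seed: int) -> np.ndarray:
    """Shared cohort basis with a dominant whole-arm first synergy.

    The first column loads substantially on every channel (magnitudes
    drawn in [0.6, 1.0] with random signs before normalization), the way
    the primary inter-joint coordination pattern of planar reaching
    couples all degrees of freedom; the remaining columns are random
    directions orthogonalized against it.  Together with the eccentric
    target-amplitude ring this yields the characteristic variance
    spectrum (first component dominant, first two nearly exhaustive)
    even after per-channel min-max normalization.
    """
    rng = np.random.default_rng(seed)
    first = rng.uniform(0.4, 0.5, size=n_channels) * rng.choice([-1.0, 1.0], n_channels)
    first[4] = 0.8   # elbow flexion-extension dominates the reach synergy
    first[3] = rng.uniform(0.15, 0.25) * rng.choice([-1.0, 1.0])
    cols = [first / np.linalg.norm(first)]
    if n_latent > 1:
        # The second synergy is led by forearm pronation-supination,
        # loads appreciably on the shoulder, and is absent from elbow
        # flexion; one shoulder entry is solved for so the column is
        # orthogonal to the first without Gram-Schmidt bleed into FA_y.
        second = rng.uniform(0.45, 0.65, size=n_channels) * rng.choice([-1.0, 1.0], n_channels)
        second[4] = 0.0
        second[3] = 0.8
        second[0] = -(second[1:] @ first[1:]) / first[0]
        second /= np.linalg.norm(second)
        cols.append(second)
    if n_latent > 2:
        extra = rng.standard_normal((n_channels, n_latent - 2))
        cols.append(extra)
    q, _ = np.linalg.qr(np.column_stack(cols))
    return _fix_signs(q[:, :n_latent])


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[GroundTruthSubject, Session, Session]]:
    """Generate a full cohort: per subject, ground truth plus sessions.

    Subject bases are a shared reference basis plus per-subject Gaussian
    perturbations of scale ``inter_subject_basis_sd``, re-orthonormalized;
    a perturbation scale of zero yields identical bases.  Target
    amplitudes are shared across subjects (the same physical target grid);
    baseline postures are per-subject draws within anatomically plausible
    ranges.
    """
    ref_basis = _reference_basis(N_CHANNELS, config.n_latent, derive_seed(config.seed, "basis"))
    amp_rng = np.random.default_rng(derive_seed(config.seed, "amplitudes"))
    amplitudes = _target_amplitudes(config, amp_rng)

    cohort = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        rng = np.random.default_rng(derive_seed(config.seed, "subject", i))
        if config.inter_subject_basis_sd > 0:
            perturbed = ref_basis + config.inter_subject_basis_sd * rng.standard_normal(
                ref_basis.shape
            )
            q, _ = np.linalg.qr(perturbed)
            basis = _fix_signs(q[:, : config.n_latent])
        else:
            rng.standard_normal(ref_basis.shape)  # keep stream position fixed
            basis = ref_basis.copy()
        baseline = np.array(
            [
                rng.uniform(-40.0, 40.0),   # SH_x
                rng.uniform(-40.0, 40.0),   # SH_y
                rng.uniform(-40.0, 40.0),   # SH_z
                rng.uniform(-30.0, 30.0),   # FA_x
                rng.uniform(40.0, 110.0),   # FA_y (elbow stays flexed)
            ]
        )
        subject = GroundTruthSubject(
            subject_id=sid,
            true_basis=basis,
            baseline_posture=baseline,
            target_amplitudes=amplitudes,
        )
        training, validation = generate_subject_session(
            subject, config, derive_seed(config.seed, "session", i)
        )
        cohort.append((subject, training, validation))
    return cohort


# ---------------------------------------------------------------------------
# On-disk layout: one directory per subject with a long-format trials.csv per
# session, a manifest.yaml, and the ground truth in a separate JSON archive so
# the pipeline can be run blind.
# ---------------------------------------------------------------------------

def _session_frame(session: Session) -> pd.DataFrame:
    T = session.angles.shape[1]
    trial_id = np.full(T, -1, dtype=int)
    target_id = np.full(T, -1, dtype=int)
    for k, ((a, b), tgt) in enumerate(zip(session.boundaries, session.target_ids)):
        trial_id[a:b] = k
        target_id[a:b] = tgt
    frame = pd.DataFrame(
        {
            "trial_id": trial_id,
            "target_id": target_id,
            "sample_index": np.arange(T),
            "time_s": np.arange(T) / session.rate,
        }
    )
    for j, name in enumerate(CHANNELS):
        frame[name] = session.angles[j]
    return frame


def write_subject_dir(
    directory: str | Path,
    subject: GroundTruthSubject,
    training: Session,
    validation: Session,
    config: CohortConfig,
) -> Path:
    """Serialize one subject's sessions and ground truth under ``directory``."""
    directory = Path(directory) / subject.subject_id
    directory.mkdir(parents=True, exist_ok=True)
    _session_frame(training).to_csv(directory / "training_trials.csv", index=False)
    _session_frame(validation).to_csv(directory / "validation_trials.csv", index=False)
    manifest = {
        "subject_id": subject.subject_id,
        "channels": list(CHANNELS),
        "sampling_rate": float(config.sampling_rate),
        "seed": int(config.seed),
        "sessions": {
            "training": "training_trials.csv",
            "validation": "validation_trials.csv",
        },
        "ground_truth": "ground_truth.json",
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    truth = {
        "true_basis": subject.true_basis.tolist(),
        "baseline_posture": subject.baseline_posture.tolist(),
        "target_amplitudes": subject.target_amplitudes.tolist(),
        "training_boundaries": [list(b) for b in training.boundaries],
        "training_targets": list(map(int, training.target_ids)),
        "validation_boundaries": [list(b) for b in validation.boundaries],
        "validation_targets": list(map(int, validation.target_ids)),
    }
    (directory / "ground_truth.json").write_text(json.dumps(truth))
    return directory


def read_subject_dir(
    directory: str | Path, blind: bool = False
) -> tuple[GroundTruthSubject | None, Session, Session]:
    """Load a serialized subject.  ``blind=True`` skips the ground truth."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    rate = float(manifest["sampling_rate"])
    sid = manifest["subject_id"]

    sessions = {}
    for kind, fname in manifest["sessions"].items():
        frame = pd.read_csv(directory / fname)
        angles = frame[list(CHANNELS)].to_numpy().T
        # trial/target annotations are part of the experiment log (the
        # protocol knows which target was displayed), so they are always
        # available; only the latent ground truth can be withheld.
        boundaries, targets = [], []
        tid = frame["trial_id"].to_numpy()
        tgt = frame["target_id"].to_numpy()
        for k in range(tid.max() + 1):
            idx = np.flatnonzero(tid == k)
            boundaries.append((int(idx[0]), int(idx[-1]) + 1))
            targets.append(int(tgt[idx[0]]))
        sessions[kind] = Session(
            subject_id=sid,
            kind=kind,
            angles=angles,
            rate=rate,
            boundaries=boundaries,
            target_ids=targets,
        )

    subject = None
    if not blind:
        truth = json.loads((directory / manifest["ground_truth"]).read_text())
        subject = GroundTruthSubject(
            subject_id=sid,
            true_basis=np.array(truth["true_basis"]),
            baseline_posture=np.array(truth["baseline_posture"]),
            target_amplitudes=np.array(truth["target_amplitudes"]),
        )
    return subject, sessions["training"], sessions["validation"]
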