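"""Scoring and statistics for forearm-motion decoding experiments.

Covers the per-scenario accuracy metrics (pooled RMSE in degrees,
Pearson correlation with its qualitative interpretation bands), the
cross-subject transfer protocol (every target x source subject pair,
with the target subject's normalization records and synergy matrix
substituted at reconstruction), and the group statistics: one-way ANOVA
computable directly from printed group summaries (count/mean/variance)
and the Tukey HSD post hoc test based on the studentized-range
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._common import FOREARM_IDX
from .preprocessing import MotionTrial, NormalizationRecord
from .synergy import SynergyDecomposition
from .decoder import TrainedDecoder, estimate_forearm, make_feature_sequences

__all__ = [
    "EvaluationReport",
    "GroupSummary",
    "AnovaResult",
    "TukeyResult",
    "SubjectData",
    "rmse",
    "pearson",
    "interpret_r",
    "summarize",
    "anova_from_summaries",
    "f_critical",
    "tukey_hsd",
    "evaluate_decoder",
    "cross_subject_evaluate",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared error pooled over outputs and time points.

    With multiple outputs the per-output mean squared errors are
    averaged before the square root, i.e. the square root of the grand
    mean of squared errors.
    """
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    if actual.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {actual.shape} vs {predicted.shape}")
    if actual.size == 0:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def pearson(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Sample Pearson correlation coefficient of two series."""
    actual = np.asarray(actual, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if actual.shape != predicted.shape or actual.size < 2:
        raise ValueError("need two equally sized series of length >= 2")
    if np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        raise ValueError("correlation is undefined for a constant series")
    return float(np.corrcoef(actual, predicted)[0, 1])


_BANDS = (
    (0.7, 1.0, "strong"),
    (0.3, 0.7, "distinct"),
    (0.1, 0.3, "weak"),
)


def interpret_r(r: float) -> str:
    """Qualitative interpretation band for a Pearson coefficient.

    The published band edges overlap (e.g. both the weak and the
    distinct band contain |r| = 0.3); boundary values are assigned to
    the band of larger |r|.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    magnitude = abs(r)
    sign = "positive" if r > 0 else "negative"
    for lo, _hi, word in _BANDS:
        if magnitude >= lo:
            return f"{word} {sign} linear relationship"
    return "not a linear relationship"


@dataclass
class EvaluationReport:
    """Accuracy of one decoder on one subject's validation movements."""

    subject_id: str
    source_subject_id: str
    methodology: str
    per_output_rmse: dict[str, float]
    pooled_rmse: float
    per_output_r: dict[str, float]
    r_interpretation: dict[str, str]


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """Count / sum / mean / sample-variance summary of one RMSE group,
    matching the descriptive-statistics rows of the published tables."""

    label: str
    n: int
    mean: float
    variance: float
    total: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a group needs n >= 2")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.total is None:
            object.__setattr__(self, "total", self.n * self.mean)


def summarize(values, label: str = "") -> GroupSummary:
    """Count, sum, mean and sample variance (n - 1 denominator)."""
    values = np.asarray(values, float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values")
    return GroupSummary(
        label=label,
        n=int(values.size),
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)),
        total=float(values.sum()),
    )


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    F: float
    p: float
    F_critical: float
    alpha: float = 0.05


def f_critical(df1: int, df2: int, alpha: float = 0.05) -> float:
    """Upper-alpha quantile of the F distribution."""
    if df1 < 1 or df2 < 1 or not 0 < alpha < 1:
        raise ValueError("need df >= 1 and 0 < alpha < 1")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def anova_from_summaries(
    groups: list[GroupSummary], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA computed from group summaries alone.

    The between-group sum of squares is Sum n_i (m_i - grand)^2 with the
    grand mean weighted by group size; the within-group sum of squares
    is Sum (n_i - 1) s_i^2.  Identical to the raw-data ANOVA when the
    summaries are exact.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_total = sum(g.n for g in groups)
    grand = sum(g.n * g.mean for g in groups) / n_total
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ss_within = sum((g.n - 1) * g.variance for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f_stat = ms_between / ms_within
    return AnovaResult(
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_between + ss_within,
        df_between=df_between,
        df_within=df_within,
        ms_between=ms_between,
        ms_within=ms_within,
        F=f_stat,
        p=float(stats.f.sf(f_stat, df_between, df_within)),
        F_critical=f_critical(df_between, df_within, alpha),
        alpha=alpha,
    )


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise studentized-range statistics at equal group sizes."""

    pairs: tuple[tuple[str, str], ...]
    q: tuple[float, ...]
    p: tuple[float, ...]
    q_critical: float
    alpha: float = 0.05

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [a for a, _ in self.pairs],
                "group_b": [b for _, b in self.pairs],
                "q": self.q,
                "p": self.p,
                "q_critical": self.q_critical,
            }
        )


def tukey_hsd(
    groups: list[GroupSummary],
    ms_within: float | None = None,
    df_within: int | None = None,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey honest-significant-difference test from group summaries.

    Requires equal group sizes (the balanced design of the protocol;
    the Tukey-Kramer unequal-n extension is deliberately unsupported).
    Q = |m_i - m_j| / sqrt(ms_within / n); p-values and the critical
    value come from the studentized-range distribution with k groups
    and ``df_within`` degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g.n for g in groups}
    if len(sizes) > 1:
        raise ValueError(f"unequal group sizes unsupported: {sorted(sizes)}")
    n = groups[0].n
    k = len(groups)
    if ms_within is None or df_within is None:
        anova = anova_from_summaries(groups, alpha)
        ms_within = anova.ms_within
        df_within = anova.df_within
    if ms_within <= 0:
        raise ValueError("ms_within must be positive")
    se = np.sqrt(ms_within / n)
    pairs, qs, ps = [], [], []
    for a, b in combinations(groups, 2):
        q = abs(a.mean - b.mean) / se
        pairs.append((a.label, b.label))
        qs.append(float(q))
        ps.append(float(stats.studentized_range.sf(q, k, df_within)))
    return TukeyResult(
        pairs=tuple(pairs),
        q=tuple(qs),
        p=tuple(ps),
        q_critical=float(stats.studentized_range.ppf(1.0 - alpha, k, df_within)),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Decoder evaluation and cross-subject transfer
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Everything needed to evaluate any decoder on one subject:
    filtered validation trials plus the subject's own preprocessing and
    synergy artifacts."""

    subject_id: str
    validation_trials: list[MotionTrial]
    angle_record: NormalizationRecord
    velocity_record: NormalizationRecord | None = None
    decomp_full: SynergyDecomposition | None = None
    decomp_forearm: SynergyDecomposition | None = None

    def decomposition_for(self, methodology: str) -> SynergyDecomposition | None:
        if methodology == "two_synergy":
            return self.decomp_full
        if methodology == "one_synergy":
            return self.decomp_forearm
        return None


def evaluate_decoder(
    decoder: TrainedDecoder,
    subject: SubjectData,
    source_subject_id: str | None = None,
) -> EvaluationReport:
    """Score a decoder on a subject's validation movements.

    Inputs are normalized with the evaluated subject's records; for
    synergy methodologies the subject's own synergy decomposition is
    used at reconstruction (this is what makes the cross-subject
    protocol a transfer of the network, not of the synergy matrix).
    The first window - 1 samples of each movement yield no prediction
    and are dropped from the reference signal accordingly.
    """
    scenario = decoder.scenario
    features = make_feature_sequences(
        subject.validation_trials,
        scenario.input_combo,
        subject.angle_record,
        subject.velocity_record,
    )
    decomp = subject.decomposition_for(scenario.methodology)
    estimates = estimate_forearm(
        decoder, features, decomposition=decomp, angle_record=subject.angle_record
    )
    window = scenario.window
    actual_parts, est_parts = [], []
    for trial, est in zip(subject.validation_trials, estimates):
        if est.shape[0] == 0:
            continue
        actual_parts.append(trial.angles[FOREARM_IDX, window - 1 :].T)
        est_parts.append(est)
    actual = np.concatenate(actual_parts, axis=0)
    estimated = np.concatenate(est_parts, axis=0)

    output_names = ("FA_x", "FA_y")
    per_rmse = {
        name: rmse(actual[:, i], estimated[:, i]) for i, name in enumerate(output_names)
    }
    per_r = {
        name: pearson(actual[:, i], estimated[:, i])
        for i, name in enumerate(output_names)
    }
    return EvaluationReport(
        subject_id=subject.subject_id,
        source_subject_id=source_subject_id or subject.subject_id,
        methodology=scenario.methodology,
        per_output_rmse=per_rmse,
        pooled_rmse=rmse(actual, estimated),
        per_output_r=per_r,
        r_interpretation={name: interpret_r(r) for name, r in per_r.items()},
    )


def cross_subject_evaluate(
    decoders: dict[str, TrainedDecoder],
    subjects: dict[str, SubjectData],
    include_diagonal: bool = True,
) -> pd.DataFrame:
    """Pooled RMSE for every (target subject, source model) pair.

    Entry (A, B) feeds subject A's validation inputs (normalized with
    A's records) through the decoder trained on subject B, substituting
    A's synergy decomposition at reconstruction for the synergy
    methodologies.  Self-pairs (A = A) are included by default, matching
    the n-squared group counts of the published design.
    """
    if set(decoders) != set(subjects):
        missing = set(decoders) ^ set(subjects)
        raise ValueError(f"decoders and subject data must cover the same ids: {missing}")
    cells = {
        (d.scenario.methodology, d.scenario.n_hidden_layers, d.scenario.input_combo,
         d.scenario.window)
        for d in decoders.values()
    }
    if len(cells) > 1:
        raise ValueError("all decoders must share one scenario cell")
    ids = sorted(subjects)
    matrix = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for target_id in ids:
        for source_id in ids:
            if not include_diagonal and target_id == source_id:
                continue
            report = evaluate_decoder(
                decoders[source_id], subjects[target_id], source_subject_id=source_id
            )
            matrix.loc[target_id, source_id] = report.pooled_rmse
    matrix.index.name = "target_subject"
    matrix.columns.name = "source_model"
    return matrix
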