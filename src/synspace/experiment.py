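"""End-to-end orchestration of the decoding study on synthetic cohorts.

One configuration drives everything: cohort generation, per-subject
preprocessing and synergy extraction, decoder training over the
methodology x depth x input grid, personalized and cross-subject
evaluation, and the group statistics.  All stage seeds are derived
deterministically from a single master seed, so a rerun with the same
configuration reproduces every non-training output byte-identically and
every training loss exactly (the NumPy training loop is deterministic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._common import FOREARM_IDX, VELOCITY_CHANNELS, derive_seed
from .synthetic_motion import CohortConfig, GroundTruthSubject, Session, generate_cohort
from .preprocessing import (
    MotionTrial,
    SourceMatrix,
    angular_velocities,
    assemble_source_matrix,
    average_trials,
    fit_normalization,
    lowpass,
    segment_trials,
    time_normalize,
)
from .synergy import SynergyDecomposition, extract, select_components
from .decoder import (
    METHODOLOGIES,
    ScenarioSpec,
    TrainedDecoder,
    build_windows,
    make_feature_sequences,
    make_target_sequences,
    train,
)
from .evaluation import (
    AnovaResult,
    EvaluationReport,
    GroupSummary,
    SubjectData,
    TukeyResult,
    anova_from_summaries,
    cross_subject_evaluate,
    evaluate_decoder,
    summarize,
    tukey_hsd,
)

logger = logging.getLogger("synspace")

__all__ = [
    "ExperimentConfig",
    "SubjectArtifacts",
    "PersonalizedResults",
    "CrossSubjectResults",
    "build_subject_artifacts",
    "train_scenario",
    "run_personalized",
    "run_cross_subject",
    "run_all",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full study configuration with deterministic seed derivation."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    methodologies: tuple[str, ...] = METHODOLOGIES
    layer_counts: tuple[int, ...] = (1, 2, 3)
    input_combos: tuple[int, ...] = (2, 3, 4, 6)
    window: int = 10
    hidden_units: int = 64
    dropout: float = 0.10
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.005
    early_stopping_patience: int = 10
    speed_threshold_fraction: float = 0.05
    filter_order: int = 6
    filter_cutoff: float = 10.0
    variance_threshold: float = 0.85
    averaged_only: bool = False
    chosen_layers: int = 2
    chosen_combo: int = 6
    master_seed: int = 0

    @property
    def grid_size(self) -> int:
        return len(self.methodologies) * len(self.layer_counts) * len(self.input_combos)

    def scenario(self, methodology: str, layers: int, combo: int, seed: int) -> ScenarioSpec:
        return ScenarioSpec(
            methodology=methodology,
            n_hidden_layers=layers,
            input_combo=combo,
            window=self.window,
            hidden_units=self.hidden_units,
            dropout=self.dropout,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            early_stopping_patience=self.early_stopping_patience,
            seed=seed,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        for key in ("methodologies", "layer_counts", "input_combos"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)


@dataclass
class SubjectArtifacts:
    """All per-subject pipeline products needed downstream."""

    subject_id: str
    truth: GroundTruthSubject | None
    training_trials: list[MotionTrial]       # filtered individual trials
    source: SourceMatrix
    decomp_full: SynergyDecomposition
    decomp_forearm: SynergyDecomposition
    data: SubjectData                        # validation side + records

    @property
    def angle_record(self):
        return self.data.angle_record

    @property
    def velocity_record(self):
        return self.data.velocity_record


def build_subject_artifacts(
    truth: GroundTruthSubject | None,
    training: Session,
    validation: Session,
    config: ExperimentConfig,
) -> SubjectArtifacts:
    """Run the preprocessing and synergy stages for one subject.

    Source-matrix path: segment -> time-normalize (to the global median
    trial length) -> average per target -> zero-phase low-pass ->
    min-max normalize.  Decoder path: the same segmented trials are
    filtered individually; one angle normalization record fitted on all
    of them serves both paths, and shoulder velocities get their own
    record.
    """
    sid = training.subject_id
    raw_trials = segment_trials(training, config.speed_threshold_fraction)
    tmax = int(np.median([t.n_samples for t in raw_trials]))
    aligned = [time_normalize(t, tmax) for t in raw_trials]
    averaged = []
    for target in sorted({t.target_id for t in aligned}):
        group = [t for t in aligned if t.target_id == target]
        averaged.append(
            lowpass(average_trials(group), config.filter_order, config.filter_cutoff)
        )
    filtered = [
        lowpass(t, config.filter_order, config.filter_cutoff) for t in raw_trials
    ]
    # one record covers both uses: decoder sequences (individual trials)
    # and the source matrix (averaged trials, whose filter transients can
    # poke marginally outside the individual-trial range)
    angle_record = fit_normalization(filtered + averaged, role="angles")
    velocity_record = fit_normalization(
        [angular_velocities(t) for t in filtered],
        role="velocities",
        channel_names=VELOCITY_CHANNELS,
    )
    source = assemble_source_matrix(averaged, angle_record)
    decomp_full = extract(source)
    decomp_full.n_retained = select_components(decomp_full, config.variance_threshold)
    decomp_forearm = extract(
        source.values[FOREARM_IDX], channel_names=("FA_x", "FA_y")
    )
    decomp_forearm.n_retained = 1

    val_trials = [
        lowpass(t, config.filter_order, config.filter_cutoff)
        for t in segment_trials(validation, config.speed_threshold_fraction)
    ]
    data = SubjectData(
        subject_id=sid,
        validation_trials=val_trials,
        angle_record=angle_record,
        velocity_record=velocity_record,
        decomp_full=decomp_full,
        decomp_forearm=decomp_forearm,
    )
    return SubjectArtifacts(
        subject_id=sid,
        truth=truth,
        training_trials=averaged if config.averaged_only else filtered,
        source=source,
        decomp_full=decomp_full,
        decomp_forearm=decomp_forearm,
        data=data,
    )


def train_scenario(
    artifacts: SubjectArtifacts, scenario: ScenarioSpec
) -> TrainedDecoder:
    """Train one grid cell on a subject's individual training trials."""
    decomp = (
        artifacts.decomp_forearm
        if scenario.methodology == "one_synergy"
        else artifacts.decomp_full
    )
    features = make_feature_sequences(
        artifacts.training_trials,
        scenario.input_combo,
        artifacts.angle_record,
        artifacts.velocity_record,
    )
    targets = make_target_sequences(
        artifacts.training_trials,
        scenario.methodology,
        artifacts.angle_record,
        decomp,
    )
    dataset = build_windows(features, targets, scenario.window)
    return train(
        dataset,
        scenario,
        angle_record=artifacts.angle_record,
        velocity_record=artifacts.velocity_record,
        decomposition=None if scenario.methodology == "direct" else decomp,
    )


def _reports_frame(reports: list[EvaluationReport], extra: dict | None = None) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "subject_id": r.subject_id,
            "source_subject_id": r.source_subject_id,
            "methodology": r.methodology,
            "pooled_rmse": r.pooled_rmse,
        }
        for name, value in r.per_output_rmse.items():
            row[f"rmse_{name}"] = value
        for name, value in r.per_output_r.items():
            row[f"r_{name}"] = value
        if extra:
            row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PersonalizedResults:
    reports: pd.DataFrame
    summaries: list[GroupSummary]
    anova: AnovaResult | None
    config_hash: str


def run_personalized(config: ExperimentConfig) -> PersonalizedResults:
    """Train and evaluate every grid scenario per subject; then compare
    the methodologies across subjects for the chosen model (by default
    two hidden layers and six inputs) with a one-way ANOVA."""
    cohort = generate_cohort(config.cohort)
    all_reports: list[EvaluationReport] = []
    rows = []
    chosen: dict[str, list[float]] = {m: [] for m in config.methodologies}
    for truth, training, validation in cohort:
        artifacts = build_subject_artifacts(truth, training, validation, config)
        for methodology in config.methodologies:
            for layers in config.layer_counts:
                for combo in config.input_combos:
                    seed = derive_seed(
                        config.master_seed, "train", artifacts.subject_id,
                        methodology, layers, combo,
                    )
                    scenario = config.scenario(methodology, layers, combo, seed)
                    decoder = train_scenario(artifacts, scenario)
                    report = evaluate_decoder(decoder, artifacts.data)
                    all_reports.append(report)
                    rows.append(
                        {"n_hidden_layers": layers, "input_combo": combo}
                    )
                    logger.info(
                        "personalized %s %s L%d I%d rmse=%.3f",
                        artifacts.subject_id, methodology, layers, combo,
                        report.pooled_rmse,
                    )
                    if layers == config.chosen_layers and combo == config.chosen_combo:
                        chosen[methodology].append(report.pooled_rmse)
    frame = _reports_frame(all_reports)
    frame = pd.concat([frame, pd.DataFrame(rows)], axis=1)

    summaries, anova = [], None
    if all(len(v) >= 2 for v in chosen.values()) and len(chosen) >= 2:
        summaries = [summarize(v, label=m) for m, v in chosen.items()]
        anova = anova_from_summaries(summaries)
    return PersonalizedResults(
        reports=frame, summaries=summaries, anova=anova,
        config_hash=config.config_hash(),
    )


@dataclass
class CrossSubjectResults:
    matrices: dict[str, pd.DataFrame]
    summaries: list[GroupSummary]
    anova: AnovaResult
    tukey: TukeyResult | None
    config_hash: str


def run_cross_subject(
    config: ExperimentConfig,
    layers: int | None = None,
    combo: int | None = None,
    include_diagonal: bool = True,
) -> CrossSubjectResults:
    """Cross-subject transfer for one scenario cell.

    Per methodology, one decoder is trained per subject, then every
    (target, source) pair is scored with the target subject's records
    and synergy matrix, yielding n-squared RMSE values per methodology.
    ANOVA (and Tukey HSD when it is significant at the chosen alpha)
    compares the methodologies over those groups.
    """
    layers = config.chosen_layers if layers is None else layers
    combo = config.chosen_combo if combo is None else combo
    cohort = generate_cohort(config.cohort)
    artifacts = {
        training.subject_id: build_subject_artifacts(truth, training, validation, config)
        for truth, training, validation in cohort
    }
    subjects = {sid: a.data for sid, a in artifacts.items()}

    matrices: dict[str, pd.DataFrame] = {}
    summaries: list[GroupSummary] = []
    for methodology in config.methodologies:
        decoders = {}
        for sid, art in artifacts.items():
            seed = derive_seed(
                config.master_seed, "train", sid, methodology, layers, combo
            )
            decoders[sid] = train_scenario(
                art, config.scenario(methodology, layers, combo, seed)
            )
        matrix = cross_subject_evaluate(decoders, subjects, include_diagonal)
        matrices[methodology] = matrix
        values = matrix.to_numpy(dtype=float)
        if not include_diagonal:
            values = values[~np.eye(len(matrix), dtype=bool)]
        summaries.append(summarize(np.asarray(values).ravel(), label=methodology))
        logger.info(
            "cross-subject %s L%d I%d mean=%.3f var=%.3f",
            methodology, layers, combo, summaries[-1].mean, summaries[-1].variance,
        )
    anova = anova_from_summaries(summaries)
    tukey = (
        tukey_hsd(summaries, anova.ms_within, anova.df_within)
        if anova.p < anova.alpha
        else None
    )
    return CrossSubjectResults(
        matrices=matrices, summaries=summaries, anova=anova, tukey=tukey,
        config_hash=config.config_hash(),
    )


def _summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [s.label for s in summaries],
            "count": [s.n for s in summaries],
            "sum": [s.total for s in summaries],
            "mean": [s.mean for s in summaries],
            "variance": [s.variance for s in summaries],
        }
    )


def run_all(config: ExperimentConfig, output_dir: str | Path) -> dict:
    """Full study: personalized grid plus cross-subject transfer for the
    best-case (six-input) and worst-case (two-input) chosen-depth
    scenarios.  Writes tidy CSV reports and a JSON statistics bundle,
    each stamped with the configuration hash."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "master_seed": config.master_seed}

    personalized = run_personalized(config)
    personalized.reports.to_csv(output_dir / "personalized_reports.csv", index=False)
    bundle: dict = {**stamp, "personalized": {}}
    if personalized.anova is not None:
        _summaries_frame(personalized.summaries).to_csv(
            output_dir / "personalized_summaries.csv", index=False
        )
        bundle["personalized"]["anova"] = dataclasses.asdict(personalized.anova)

    bundle["cross_subject"] = {}
    for combo in sorted({config.chosen_combo, 2}):
        cross = run_cross_subject(config, combo=combo)
        tag = f"{config.chosen_layers}layers_{combo}inputs"
        for methodology, matrix in cross.matrices.items():
            matrix.to_csv(output_dir / f"cross_subject_{tag}_{methodology}.csv")
        _summaries_frame(cross.summaries).to_csv(
            output_dir / f"cross_subject_{tag}_summaries.csv", index=False
        )
        entry = {"anova": dataclasses.asdict(cross.anova)}
        if cross.tukey is not None:
            entry["tukey"] = {
                "pairs": list(map(list, cross.tukey.pairs)),
                "q": list(cross.tukey.q),
                "p": list(cross.tukey.p),
                "q_critical": cross.tukey.q_critical,
            }
        bundle["cross_subject"][tag] = entry
    (output_dir / "stats_bundle.json").write_text(json.dumps(bundle, indent=2))
    return bundle
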