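"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
graph features -> statistics/classification.

`run_study` reproduces the whole synthetic experiment from one seed and a
config; the CLI's `run-all` subcommand and the reproduction script are
thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis, cohort, connectivity, network, preprocess


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline with study defaults."""

    # cohort
    n_per_group: int = 10
    n_channels: int = 8
    duration_s: float = 300.0
    sampling_rate: float = 1000.0
    var_order: int = 3
    # preprocessing
    cutoff: float = 50.0
    target_rate: float = 128.0
    epoch_samples: int = 1280
    # connectivity
    p_min: int = 1
    p_max: int = 20
    criterion: str = "bic"
    fixed_order: int | None = None
    freq_step: float = connectivity.DEFAULT_FREQ_STEP
    # network
    tau: float = network.DEFAULT_TAU
    unreachable_policy: str = "exclude"
    # analysis
    undefined_policy: str = "impute"
    k_folds: int = 10
    cv: str = "epoch"
    presets: list[str] | None = None

    @property
    def l_ceiling(self) -> float:
        """Imputation value for undefined L: path-length upper bound."""
        return (self.n_channels - 1) / self.tau


def subject_feature_rows(
    subject: cohort.SyntheticSubject, config: PipelineConfig
) -> pd.DataFrame:
    """Preprocess one subject and extract the per-epoch 36-feature rows."""
    epochs = preprocess.preprocess_recording(
        subject.recording,
        cutoff=config.cutoff,
        target_rate=config.target_rate,
        channels=subject.recording.channel_labels,
        samples_per_epoch=config.epoch_samples,
        source_subject=subject.subject_id,
        group=subject.group,
    )
    return epochs_to_features(epochs, config)


def epochs_to_features(
    epochs: preprocess.EpochedEEG, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-epoch connectivity + graph features for an epoched recording."""
    config = config or PipelineConfig()
    rows = []
    for e in range(epochs.n_epochs):
        pdc_bands, dtf_bands = connectivity.epoch_connectivity(
            epochs.data[e],
            sampling_rate=epochs.sampling_rate,
            channel_labels=epochs.channel_labels,
            p_min=config.p_min,
            p_max=config.p_max,
            criterion=config.criterion,
            order=config.fixed_order,
            freq_step=config.freq_step,
        )
        feats = network.feature_vector(
            pdc_bands, dtf_bands, tau=config.tau,
            unreachable_policy=config.unreachable_policy,
        )
        row = {
            analysis.SUBJECT_COL: epochs.source_subject,
            analysis.GROUP_COL: epochs.group,
        }
        row.update(feats.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def build_feature_table(
    subjects: Sequence[cohort.SyntheticSubject], config: PipelineConfig
) -> pd.DataFrame:
    """Feature table (one row per epoch) for a whole cohort."""
    return pd.concat(
        [subject_feature_rows(s, config) for s in subjects], ignore_index=True
    )


@dataclass
class StudyResult:
    """Everything the end-to-end synthetic study produces."""

    table: pd.DataFrame
    correlations: pd.DataFrame
    ttests: pd.DataFrame
    report: analysis.ClassificationReport
    config: PipelineConfig
    seed: int


def run_study(
    seed: int = 0,
    config: PipelineConfig | None = None,
    hp_coupling: cohort.CouplingSpec = cohort.HP_COUPLING,
    lp_coupling: cohort.CouplingSpec = cohort.LP_COUPLING,
) -> StudyResult:
    """Run the full synthetic study from one seed.

    Generates the two-group cohort, preprocesses every recording, computes
    per-epoch PDC/DTF band graphs and the 36-feature vectors, then the
    group statistics and the cross-validated classifier report.
    """
    config = config or PipelineConfig()
    subjects = cohort.make_cohort(
        n_per_group=config.n_per_group,
        hp_coupling=hp_coupling,
        lp_coupling=lp_coupling,
        duration_s=config.duration_s,
        sampling_rate=config.sampling_rate,
        seed=seed,
        n_channels=config.n_channels,
        order=config.var_order,
    )
    table = build_feature_table(subjects, config)
    clean = analysis.clean_feature_table(
        table, policy=config.undefined_policy, ceiling=config.l_ceiling
    )
    correlations = analysis.feature_target_correlation(clean)
    ttests = analysis.group_ttest(clean)
    report = analysis.run_classifiers(
        clean,
        presets=config.presets,
        k_folds=config.k_folds,
        seed=seed,
        cv=config.cv,
    )
    return StudyResult(table, correlations, ttests, report, config, seed)
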