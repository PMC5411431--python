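"""End-to-end conveniences tying the stages together.

These helpers are what the command-line interface, the test-bench and
the reproduction script call: featurize whole subjects, train the
transferable decoder on one group and evaluate it on held-out subjects.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import DecoderConfig
from .ensemble import (
    EnsembleModel,
    LabeledFeatureSet,
    build_resamples,
    ensemble_posterior,
    fit_ensemble,
)
from .features import FeatureTable, featurize_trials
from .metrics import MetricsReport, score
from .preprocess import apply_bandpass, design_bandpass, remove_eog
from .simulate import SubjectData

logger = logging.getLogger(__name__)


def featurize_subject(subject: SubjectData,
                      config: DecoderConfig = DecoderConfig()
                      ) -> FeatureTable:
    """Band-pass (and optionally ocular-clean) every session, then
    featurize all trials, concatenated across the five sessions."""
    sos = design_bandpass(config.bandpass)
    table: FeatureTable | None = None
    for plan, rec in zip(subject.plans, subject.recordings):
        filtered = apply_bandpass(rec, sos)
        if config.eog_removal:
            filtered, report = remove_eog(filtered, config.ica)
            if report.removed:
                logger.info("subject %s: removed %d ocular component(s)",
                            subject.profile.subject_id, len(report.removed))
        part = featurize_trials(filtered, plan, kernel=config.sg)
        table = part if table is None else table.concat(part)
    return table


def featurize_corpus(subjects: list[SubjectData],
                     config: DecoderConfig = DecoderConfig()
                     ) -> FeatureTable:
    table: FeatureTable | None = None
    for sub in subjects:
        part = featurize_subject(sub, config)
        table = part if table is None else table.concat(part)
    if table is None:
        raise ValueError("no subjects supplied")
    return table


def train_decoder(table: FeatureTable,
                  channels: tuple[str, ...] | None = None,
                  config: DecoderConfig = DecoderConfig(),
                  seed: int = 0) -> EnsembleModel:
    """Fit the resampled ensemble on an assembled feature table."""
    chans = tuple(channels) if channels is not None else table.channel_names
    data = LabeledFeatureSet(table.matrix(chans), table.labels)
    # clamp folds so desk-scale fixtures with few minority trials still train
    k = max(2, min(config.k_folds, int(np.bincount(data.y).min())))
    if k < config.k_folds:
        logger.warning("reduced resample folds from %d to %d (minority class)",
                       config.k_folds, k)
    plan = build_resamples(data.y, k=k, M=config.resamples,
                           seed=seed, with_replacement=config.with_replacement)
    return fit_ensemble(data, plan=plan, threshold=config.threshold,
                        seed=seed, selected_channels=chans)


@dataclass
class TransferResult:
    """Held-out-subject evaluation of a trained decoder."""

    report: MetricsReport
    posterior: np.ndarray
    labels: np.ndarray


def evaluate_transfer(model: EnsembleModel, table: FeatureTable
                      ) -> TransferResult:
    """Score a trained decoder on the feature table of unseen subjects."""
    X = table.matrix(model.selected_channels)
    p = ensemble_posterior(model, X)
    y = table.labels
    report = score(y, p, threshold=model.threshold,
                   subject_ids=[m.subject_id for m in table.metas])
    return TransferResult(report=report, posterior=p, labels=y)
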