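"""Backward elimination of electrodes by cross-validated ensemble AUC.

Starting from the full montage, electrodes are visited once in montage
order; removing an electrode is accepted permanently whenever the
cross-validated AUC of the remaining set does not drop below the current
reference (ties favour the smaller model), in which case the reference
is updated.  The experiment features are always retained.  Selection
uses the same ensemble decoder that will be deployed, scored by
stratified k-fold validation AUC (k = 10 by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .ensemble import (
    LabeledFeatureSet,
    build_resamples,
    ensemble_posterior,
    fit_ensemble,
)
from .features import FeatureTable
from .metrics import auc_score

logger = logging.getLogger(__name__)


def crossval_auc(data: LabeledFeatureSet, k: int = 10, seed: int = 0) -> float:
    """Mean validation AUC of the ensemble decoder over stratified folds."""
    counts = np.bincount(data.y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot stratify "
            f"into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for train, val in skf.split(data.X, data.y):
        sub = LabeledFeatureSet(data.X[train], data.y[train])
        plan = build_resamples(sub.y, k=min(k, int(np.bincount(sub.y).min())),
                               seed=seed)
        model = fit_ensemble(sub, plan=plan, seed=seed)
        aucs.append(auc_score(data.y[val], ensemble_posterior(model, data.X[val])))
    return float(np.mean(aucs))


@dataclass
class SelectionStep:
    channel: str
    auc_with: float
    auc_without: float
    decision: str  # "kept" | "rejected"


@dataclass
class SelectionTrace:
    """Per-channel record of the greedy elimination pass."""

    steps: list[SelectionStep] = field(default_factory=list)
    initial_auc: float = 0.0
    final_auc: float = 0.0
    final_subset: tuple[str, ...] = ()

    def to_rows(self) -> list[dict]:
        return [{"channel": s.channel, "auc_with": s.auc_with,
                 "auc_without": s.auc_without, "decision": s.decision}
                for s in self.steps]


def backward_eliminate(table: FeatureTable, k: int = 10, seed: int = 0
                       ) -> tuple[tuple[str, ...], SelectionTrace]:
    """Single greedy pass of electrode elimination on a feature table.

    Returns the selected channel subset (never empty: if every channel
    were rejected the single best channel is restored with a warning)
    and the full decision trace.
    """
    channels = list(table.channel_names)
    if len(channels) < 2:
        raise ValueError("need at least two channels to select from")
    y = table.labels

    def cv(chans: list[str]) -> float:
        data = LabeledFeatureSet(table.matrix(tuple(chans)), y)
        return crossval_auc(data, k=k, seed=seed)

    current = list(channels)
    ref_auc = cv(current)
    trace = SelectionTrace(initial_auc=ref_auc)
    for ch in channels:
        candidate = [c for c in current if c != ch]
        if not candidate:
            trace.steps.append(SelectionStep(ch, ref_auc, float("nan"), "kept"))
            continue
        auc_without = cv(candidate)
        if auc_without >= ref_auc:  # ties prefer the smaller model
            current = candidate
            trace.steps.append(
                SelectionStep(ch, ref_auc, auc_without, "rejected"))
            ref_auc = auc_without
        else:
            trace.steps.append(
                SelectionStep(ch, ref_auc, auc_without, "kept"))
    if not current:
        logger.warning("all channels rejected; falling back to the best "
                       "single channel")
        best = max(channels, key=lambda c: cv([c]))
        current = [best]
        ref_auc = cv(current)
    trace.final_subset = tuple(current)
    trace.final_auc = ref_auc
    return tuple(current), trace
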