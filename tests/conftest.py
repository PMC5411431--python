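"""Shared fixtures: small synthetic recordings and feature tables.

Everything is generated at test time from fixed seeds; expensive
artefacts are session-scoped so the suite builds them once.
"""
from __future__ import annotations

import numpy as np
import pytest

import errpdecode as ed
from errpdecode.features import N_BINS, FeatureTable
from errpdecode.simulate import TrialMeta


@pytest.fixture(scope="session")
def profile() -> ed.SubjectProfile:
    return ed.SubjectProfile()


@pytest.fixture(scope="session")
def sos() -> np.ndarray:
    return ed.design_bandpass()


@pytest.fixture(scope="session")
def small_plan(profile) -> list[TrialMeta]:
    return ed.make_session_plan(profile, 1, seed=0)[:20]


@pytest.fixture(scope="session")
def small_rec(profile, small_plan) -> ed.ContinuousRecording:
    return ed.synthesize_recording(small_plan, profile, seed=3)


@pytest.fixture(scope="session")
def filtered_rec(small_rec, sos) -> ed.ContinuousRecording:
    return ed.apply_bandpass(small_rec, sos)


@pytest.fixture(scope="session")
def small_table(filtered_rec, small_plan) -> FeatureTable:
    return ed.featurize_trials(filtered_rec, small_plan)


@pytest.fixture(scope="session")
def small_model(small_table) -> ed.EnsembleModel:
    return ed.train_decoder(small_table, seed=0)


def dummy_meta(i: int, is_error: bool, subject: str = "01") -> TrialMeta:
    """Minimal trial metadata for feature-table fixtures."""
    return TrialMeta(
        subject_id=subject, session=1, word_index=i // 5 + 1,
        letter_position=i % 5 + 1, feedback_index=i + 1,
        total_feedback=i + 1, total_word=i // 5 + 1,
        sequence_type=i % 2, is_error=is_error,
        onset_time=5.0 + 4.5 * i)


def make_feature_table(rng: np.random.Generator, n: int,
                       channels: tuple[str, ...],
                       informative: tuple[str, ...] = (),
                       effect: float = 2.0) -> FeatureTable:
    """Gaussian feature table where only ``informative`` channels carry
    a label-dependent shift of ``effect`` standard deviations."""
    y = rng.integers(0, 2, size=n)
    sig = rng.standard_normal((n, len(channels), N_BINS))
    for ch in informative:
        sig[:, channels.index(ch), :] += effect * y[:, None]
    cmean = rng.standard_normal((n, len(channels)))
    csq = cmean ** 2 + 1.0 + rng.random((n, len(channels)))
    metas = [dummy_meta(i, bool(y[i])) for i in range(n)]
    static = np.array([(m.session, m.feedback_index, m.letter_position,
                        m.word_index, m.total_feedback, m.total_word,
                        m.sequence_type) for m in metas], dtype=float)
    return FeatureTable(signal=sig, chan_mean=cmean, chan_sqmean=csq,
                        static_meta=static, channel_names=tuple(channels),
                        metas=metas)
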