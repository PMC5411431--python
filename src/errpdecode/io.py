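"""File dialects: recordings, trial metadata, labels and predictions.

Recordings travel as CSV with the header
``Time,<56 scalp channels>,EOG,FeedBackEvent`` — one row per 5 ms sample,
amplitudes in µV, ``FeedBackEvent`` 1 at feedback onsets.  Trial metadata
is a TSV with one row per feedback period.  Predictions are two-column
CSV ``IdFeedBack,Prediction`` carrying the error posterior so that
threshold-free metrics (AUC) remain computable downstream.

Readers validate rather than repair: a malformed file raises
:class:`FormatError` naming the offending column or row.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import EOG_CHANNEL, SCALP_CHANNELS
from .simulate import SAMPLING_RATE, ContinuousRecording, TrialMeta

ERROR_LABEL = "Error"
NOERROR_LABEL = "NoError"


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


@dataclass(frozen=True, order=True)
class FeedbackId:
    """Identifier of one feedback period: subject, session, index.

    Rendered as ``S<subject>_Sess<NN>_FB<NNN>`` with zero-padded session
    (2 digits) and feedback index (3 digits); render/parse round-trips.
    """

    subject_id: str
    session: int
    feedback_index: int

    _PATTERN = re.compile(r"^S(?P<subj>[^_]+)_Sess(?P<sess>\d{2})_FB(?P<fb>\d{3})$")

    def render(self) -> str:
        return (f"S{self.subject_id}_Sess{self.session:02d}"
                f"_FB{self.feedback_index:03d}")

    @classmethod
    def parse(cls, text: str) -> "FeedbackId":
        m = cls._PATTERN.match(text)
        if m is None:
            raise FormatError(f"malformed feedback id {text!r}")
        return cls(m["subj"], int(m["sess"]), int(m["fb"]))

    @classmethod
    def of_trial(cls, meta: TrialMeta) -> "FeedbackId":
        return cls(meta.subject_id, meta.session, meta.feedback_index)


@dataclass(frozen=True)
class PredictionRecord:
    """One decoded feedback period: id, error posterior and hard label."""

    id: FeedbackId
    posterior_error: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior_error <= 1.0:
            raise FormatError(
                f"posterior {self.posterior_error} outside [0, 1] "
                f"for {self.id.render()}")
        if self.label not in (ERROR_LABEL, NOERROR_LABEL):
            raise FormatError(f"unknown label {self.label!r}")


_EXPECTED_HEADER = ("Time", *SCALP_CHANNELS, EOG_CHANNEL, "FeedBackEvent")


def write_recording(rec: ContinuousRecording, path) -> None:
    """Write a recording in the CSV dialect (µV, 6 decimal places)."""
    n = rec.n_samples
    df = pd.DataFrame({"Time": np.arange(n) / rec.sampling_rate})
    for i, name in enumerate(rec.channel_names):
        df[name] = rec.samples[i]
    df["FeedBackEvent"] = rec.feedback_marker.astype(int)
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording(path) -> ContinuousRecording:
    """Read a recording, validating header, time base and marker values.

    Channels are reordered to montage order by header name, so column
    permutations are tolerated; missing or duplicated columns, a
    non-uniform time base (beyond one sample period) and marker values
    outside {0, 1} are rejected.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    dupes = {c for c in cols if cols.count(c) > 1}
    if dupes:
        raise FormatError(f"duplicated column(s) {sorted(dupes)} in {path}")
    missing = set(_EXPECTED_HEADER) - set(cols)
    if missing:
        raise FormatError(f"missing column(s) {sorted(missing)} in {path}")
    extra = set(cols) - set(_EXPECTED_HEADER)
    if extra:
        raise FormatError(f"unexpected column(s) {sorted(extra)} in {path}")

    time = df["Time"].to_numpy(float)
    step = 1.0 / SAMPLING_RATE
    dt = np.diff(time)
    if dt.size and (np.any(dt <= 0) or np.any(np.abs(dt - step) > step)):
        bad = int(np.argmax((dt <= 0) | (np.abs(dt - step) > step))) + 1
        raise FormatError(
            f"column 'Time' is not a uniform {step * 1e3:.0f} ms grid "
            f"(row {bad})")

    marker = df["FeedBackEvent"].to_numpy()
    if not np.isin(marker, (0, 1)).all():
        bad = int(np.argmax(~np.isin(marker, (0, 1))))
        raise FormatError(
            f"column 'FeedBackEvent' has value {marker[bad]!r} at row {bad}; "
            "expected 0 or 1")

    order = (*SCALP_CHANNELS, EOG_CHANNEL)
    samples = df[list(order)].to_numpy(float).T
    return ContinuousRecording(
        samples=samples, feedback_marker=marker.astype(np.int8),
        channel_names=order)


_META_COLUMNS = ("IdFeedBack", "subject_id", "session", "word_index",
                 "letter_position", "feedback_index", "total_feedback",
                 "total_word", "sequence_type", "is_error", "onset_time")


def write_plan(plan: list[TrialMeta], path) -> None:
    """Write trial metadata as TSV, one row per feedback period."""
    rows = [(FeedbackId.of_trial(t).render(), t.subject_id, t.session,
             t.word_index, t.letter_position, t.feedback_index,
             t.total_feedback, t.total_word, t.sequence_type,
             int(t.is_error), t.onset_time) for t in plan]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_plan(path) -> list[TrialMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing metadata column(s) {sorted(missing)}")
    return [TrialMeta(
        subject_id=str(r.subject_id), session=int(r.session),
        word_index=int(r.word_index), letter_position=int(r.letter_position),
        feedback_index=int(r.feedback_index),
        total_feedback=int(r.total_feedback), total_word=int(r.total_word),
        sequence_type=int(r.sequence_type), is_error=bool(r.is_error),
        onset_time=float(r.onset_time)) for r in df.itertuples()]


def write_labels(labels: dict[FeedbackId, str], path) -> None:
    rows = sorted((fid.render(), lab) for fid, lab in labels.items())
    pd.DataFrame(rows, columns=["IdFeedBack", "Label"]).to_csv(path, index=False)


def read_labels(path) -> dict[FeedbackId, str]:
    """Read a label file mapping feedback ids to Error/NoError."""
    df = pd.read_csv(path)
    for col in ("IdFeedBack", "Label"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    out: dict[FeedbackId, str] = {}
    for row in df.itertuples():
        fid = FeedbackId.parse(row.IdFeedBack)
        if fid in out:
            raise FormatError(f"duplicate feedback id {row.IdFeedBack}")
        if row.Label not in (ERROR_LABEL, NOERROR_LABEL):
            raise FormatError(
                f"label {row.Label!r} for {row.IdFeedBack}; expected "
                f"{ERROR_LABEL!r} or {NOERROR_LABEL!r}")
        out[fid] = row.Label
    return out


def write_predictions(records: list[PredictionRecord], path) -> None:
    """Write predictions sorted by id as ``IdFeedBack,Prediction`` CSV."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate feedback ids in prediction records")
    rows = sorted((r.id.render(), r.posterior_error) for r in records)
    pd.DataFrame(rows, columns=["IdFeedBack", "Prediction"]).to_csv(
        path, index=False, float_format="%.9f")


def read_predictions(path) -> dict[FeedbackId, float]:
    df = pd.read_csv(path)
    for col in ("IdFeedBack", "Prediction"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    out: dict[FeedbackId, float] = {}
    for row in df.itertuples():
        fid = FeedbackId.parse(row.IdFeedBack)
        if fid in out:
            raise FormatError(f"duplicate feedback id {row.IdFeedBack}")
        p = float(row.Prediction)
        if not 0.0 <= p <= 1.0:
            raise FormatError(
                f"prediction {p} outside [0, 1] for {row.IdFeedBack}")
        out[fid] = p
    return out
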