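"""Pseudo-online streaming decoder.

Samples arrive in chunks; a stateful causal band-pass runs continuously
over the selected channels, a bounded ring buffer keeps the recent
filtered past, and a feedback switch watches the marker track.  When a
marker fires at sample t the decoder waits for t + 1000 ms of data, cuts
the [-200, +1000) ms block, prepends the trailing 100 ms of the
previously processed block as smoothing context (mirror padding on a
cold start), then smooths, baseline-corrects, downsamples, merges the
experiment features, standardizes and averages the ensemble posteriors.
One prediction is emitted per marker; state size is independent of
stream length, so the decoder runs unmodified on an endless stream.

Decoding a recording through this path is numerically identical to the
batch featurizer (same block pipeline, same filter state evolution).
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from scipy import signal as sps

from .ensemble import EnsembleModel, classify, ensemble_posterior
from .features import (
    CARRY_SAMPLES,
    POST_SAMPLES,
    PRE_SAMPLES,
    block_feature_vector,
)
from .io import ERROR_LABEL, NOERROR_LABEL, FeedbackId
from .preprocess import SGKernel
from .simulate import ContinuousRecording, TrialMeta

logger = logging.getLogger(__name__)

#: Ring-buffer capacity: must cover one block plus its smoothing context
#: (1.3 s) with headroom for chunked arrival.
BUFFER_SAMPLES = 400


@dataclass
class TrialPrediction:
    """One decoded feedback period with its decode latency."""

    id: FeedbackId
    p_error: float
    label: str
    computation_time_us: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_error <= 1.0:
            raise ValueError("posterior outside [0, 1]")
        if self.computation_time_us <= 0:
            raise ValueError("computation time must be positive")


@dataclass
class StreamState:
    """Mutable decoder state: filter memory, ring buffer, carry-over."""

    zi: np.ndarray                      # sosfilt state per channel
    buffer: np.ndarray                  # (channels, BUFFER_SAMPLES)
    buffer_start: int = 0               # absolute index of buffer[:, 0]
    n_seen: int = 0                     # samples consumed so far
    pending: list[int] = field(default_factory=list)   # marker positions
    carry: np.ndarray | None = None     # (channels, 20) previous block tail
    cold_starts: int = 0

    @property
    def buffer_fill(self) -> int:
        return self.n_seen - self.buffer_start


def _chunks(rec: ContinuousRecording, rows: np.ndarray, chunk: int
            ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    for i in range(0, rec.n_samples, chunk):
        sl = slice(i, min(i + chunk, rec.n_samples))
        yield rec.samples[rows, sl], rec.feedback_marker[sl]


def stream_decode(source: ContinuousRecording | Iterable,
                  model: EnsembleModel,
                  metas: list[TrialMeta],
                  sos: np.ndarray,
                  kernel: SGKernel = SGKernel(),
                  chunk_size: int = 20) -> list[TrialPrediction]:
    """Decode a sample stream, one prediction per feedback marker.

    ``source`` is either a recording (streamed internally in
    ``chunk_size``-sample chunks over the model's selected channels) or
    an iterable of ``(samples_chunk, marker_chunk)`` pairs already
    restricted to those channels.  ``metas`` supplies the experiment
    features of the k-th marker in order.
    """
    channels = model.selected_channels
    if channels is None:
        raise ValueError("model carries no selected-channel list")
    if isinstance(source, ContinuousRecording):
        rows = source.channel_index(channels)
        stream = _chunks(source, rows, chunk_size)
    else:
        stream = iter(source)

    n_chan = len(channels)
    zi = np.zeros((sos.shape[0], n_chan, 2))
    state = StreamState(zi=zi, buffer=np.zeros((n_chan, BUFFER_SAMPLES)))
    predictions: list[TrialPrediction] = []
    meta_iter = iter(metas)

    for raw, marker in stream:
        filtered, state.zi = sps.sosfilt(sos, raw, axis=1, zi=state.zi)
        _append(state, filtered)
        onset_base = state.n_seen - raw.shape[1]
        state.pending.extend(onset_base + int(i)
                             for i in np.flatnonzero(marker == 1))
        _drain(state, model, meta_iter, predictions, kernel)
    _drain(state, model, meta_iter, predictions, kernel)

    if len(predictions) != len(metas):
        logger.warning("stream ended with %d of %d markers decodable",
                       len(predictions), len(metas))
    return predictions


def _append(state: StreamState, filtered: np.ndarray) -> None:
    n_new = filtered.shape[1]
    fill = state.buffer_fill
    if fill + n_new > BUFFER_SAMPLES:
        shift = fill + n_new - BUFFER_SAMPLES
        state.buffer[:, : fill - shift] = state.buffer[:, shift:fill]
        state.buffer_start += shift
        fill -= shift
    state.buffer[:, fill:fill + n_new] = filtered
    state.n_seen += n_new


def _drain(state: StreamState, model: EnsembleModel, meta_iter,
           predictions: list[TrialPrediction], kernel: SGKernel) -> None:
    while state.pending and state.pending[0] + POST_SAMPLES <= state.n_seen:
        onset = state.pending.pop(0)
        meta = next(meta_iter)
        t0 = time.perf_counter_ns()
        block = _cut_block(state, onset)
        sig, meta_vec = block_feature_vector(
            block, state.carry, meta, model.selected_channels, kernel)
        x = np.concatenate([sig.ravel(), meta_vec])
        p = float(ensemble_posterior(model, x)[0])
        label = (ERROR_LABEL if classify(p, model.threshold) == 1
                 else NOERROR_LABEL)
        elapsed_us = max((time.perf_counter_ns() - t0) / 1e3, 1e-3)
        state.carry = block[:, -CARRY_SAMPLES:].copy()
        predictions.append(TrialPrediction(
            id=FeedbackId.of_trial(meta), p_error=p, label=label,
            computation_time_us=elapsed_us))


def _cut_block(state: StreamState, onset: int) -> np.ndarray:
    """The [-200, +1000) ms filtered block, mirror-padded on cold start."""
    start = onset - PRE_SAMPLES
    stop = onset + POST_SAMPLES
    if start < state.buffer_start:
        avail_lo = max(start, state.buffer_start)
        i0 = avail_lo - state.buffer_start
        i1 = stop - state.buffer_start
        avail = state.buffer[:, i0:i1]
        state.cold_starts += 1
        logger.warning("marker at sample %d precedes available history; "
                       "mirror-padding %d samples", onset, avail_lo - start)
        return np.pad(avail, ((0, 0), (avail_lo - start, 0)), mode="reflect")
    i0 = start - state.buffer_start
    return state.buffer[:, i0:i0 + PRE_SAMPLES + POST_SAMPLES].copy()


def decode_batch(rec: ContinuousRecording, model: EnsembleModel,
                 metas: list[TrialMeta], sos: np.ndarray,
                 kernel: SGKernel = SGKernel()) -> list[TrialPrediction]:
    """Offline path: filter the whole recording, then run the identical
    per-block pipeline.  Matches :func:`stream_decode` to rounding."""
    channels = model.selected_channels
    if channels is None:
        raise ValueError("model carries no selected-channel list")
    rows = rec.channel_index(channels)
    filtered = sps.sosfilt(sos, rec.samples[rows], axis=1)
    onsets = rec.onset_samples()
    if len(onsets) != len(metas):
        raise ValueError("marker count differs from metadata length")
    carry: np.ndarray | None = None
    out: list[TrialPrediction] = []
    for onset, meta in zip(onsets, metas):
        if onset + POST_SAMPLES > filtered.shape[1]:
            raise ValueError(f"onset {onset} too close to end of recording")
        t0 = time.perf_counter_ns()
        start = onset - PRE_SAMPLES
        if start >= 0:
            block = filtered[:, start:onset + POST_SAMPLES]
        else:
            block = np.pad(filtered[:, :onset + POST_SAMPLES],
                           ((0, 0), (-start, 0)), mode="reflect")
        sig, meta_vec = block_feature_vector(block, carry, meta, channels,
                                             kernel)
        x = np.concatenate([sig.ravel(), meta_vec])
        p = float(ensemble_posterior(model, x)[0])
        label = (ERROR_LABEL if classify(p, model.threshold) == 1
                 else NOERROR_LABEL)
        elapsed_us = max((time.perf_counter_ns() - t0) / 1e3, 1e-3)
        carry = block[:, -CARRY_SAMPLES:].copy()
        out.append(TrialPrediction(id=FeedbackId.of_trial(meta), p_error=p,
                                   label=label,
                                   computation_time_us=elapsed_us))
    return out
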