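"""Feedback-locked epoching and feature-vector assembly.

Each feedback period yields a window from 200 ms before to 1000 ms after
onset (240 samples at 200 Hz).  After baseline correction (subtracting
the 200 ms pre-onset mean per channel) the 200 post-onset samples are
reduced to 8 bin means of 25 samples each, giving 8 values per channel —
448 signal features for the full 56-channel montage.  Nine experiment
features (grand mean, grand variance, session number, feedback number,
alphabet position, word number, total feedback, total word, sequence
type) complete the 457-dimensional vector.

Smoothing context: each trial block is prepended with the trailing
100 ms (20 samples) of the previously processed block before
Savitzky-Golay smoothing, mirroring the streaming decoder; the first
block of a stream mirror-pads instead.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SGKernel, sg_smooth
from .simulate import SAMPLING_RATE, ContinuousRecording, TrialMeta

PRE_SAMPLES = 40        # 200 ms before onset
POST_SAMPLES = 200      # 1000 ms after onset
EPOCH_SAMPLES = PRE_SAMPLES + POST_SAMPLES  # 240
N_BINS = 8
BIN_WIDTH = POST_SAMPLES // N_BINS          # 25
CARRY_SAMPLES = 20      # 100 ms of smoothing context from the previous block
N_META = 9

META_NAMES = ("mean", "variance", "session", "feedback_number",
              "alphabet_position", "word_number", "total_feedback",
              "total_word", "sequence_type")


@dataclass
class TrialEpoch:
    """One feedback-locked window: (channels, 240) samples at 200 Hz."""

    samples: np.ndarray
    channel_names: tuple[str, ...]
    meta: TrialMeta | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (len(self.channel_names), EPOCH_SAMPLES):
            raise ValueError(
                f"epoch must be (channels, {EPOCH_SAMPLES}), "
                f"got {self.samples.shape}")


def extract_epoch(rec: ContinuousRecording, onset_sample: int,
                  meta: TrialMeta | None = None,
                  channels: tuple[str, ...] | None = None) -> TrialEpoch:
    """Cut the [-200 ms, +1000 ms) window around one feedback onset.

    An onset within the first 200 ms mirror-pads the missing pre-onset
    samples (streaming cold start); an onset whose post-window exceeds
    the recording raises.
    """
    names = channels if channels is not None else rec.channel_names[:-1]
    rows = rec.channel_index(names)
    if onset_sample + POST_SAMPLES > rec.n_samples or onset_sample < 0:
        raise IndexError(
            f"onset sample {onset_sample} leaves no room for a "
            f"{POST_SAMPLES}-sample post-onset window")
    start = onset_sample - PRE_SAMPLES
    if start >= 0:
        window = rec.samples[np.ix_(rows, np.arange(start, onset_sample + POST_SAMPLES))]
    else:
        avail = rec.samples[rows, : onset_sample + POST_SAMPLES]
        window = np.pad(avail, ((0, 0), (-start, 0)), mode="reflect")
    return TrialEpoch(samples=window, channel_names=tuple(names), meta=meta)


def baseline_correct(epoch: TrialEpoch) -> TrialEpoch:
    """Subtract the per-channel mean of the 40 pre-onset samples."""
    base = epoch.samples[:, :PRE_SAMPLES].mean(axis=1, keepdims=True)
    return TrialEpoch(samples=epoch.samples - base,
                      channel_names=epoch.channel_names, meta=epoch.meta)


def downsample_epoch(epoch: TrialEpoch) -> np.ndarray:
    """Reduce the 200 post-onset samples to 8 bin means per channel."""
    post = epoch.samples[:, PRE_SAMPLES:]
    return post.reshape(post.shape[0], N_BINS, BIN_WIDTH).mean(axis=2)


def compute_meta(meta: TrialMeta, epoch: TrialEpoch) -> np.ndarray:
    """The 9 experiment features of one (baseline-corrected) epoch.

    Grand mean and population variance are taken over every sample of
    every channel present in the epoch; the remaining seven values come
    from the trial metadata (long sequence encoded 1, short 0).
    """
    flat = epoch.samples.ravel()
    return np.array([
        flat.mean(), flat.var(),
        meta.session, meta.feedback_index, meta.letter_position,
        meta.word_index, meta.total_feedback, meta.total_word,
        meta.sequence_type,
    ], dtype=np.float64)


def assemble(signal_features: dict[str, np.ndarray],
             meta_features: np.ndarray,
             selected_channels: tuple[str, ...]) -> np.ndarray:
    """Concatenate 8-value channel blocks (channel-major, montage order
    of ``selected_channels``) followed by the 9 experiment features."""
    blocks = []
    for ch in selected_channels:
        if ch not in signal_features:
            raise KeyError(f"missing signal block for channel {ch!r}")
        block = np.asarray(signal_features[ch], dtype=np.float64)
        if block.shape != (N_BINS,):
            raise ValueError(f"channel {ch!r} block must have {N_BINS} values")
        blocks.append(block)
    meta = np.asarray(meta_features, dtype=np.float64)
    if meta.shape != (N_META,):
        raise ValueError(f"meta block must have {N_META} values")
    return np.concatenate([*blocks, meta])


def feature_names(channels: tuple[str, ...]) -> list[str]:
    names = [f"{ch}_bin{b + 1}" for ch in channels for b in range(N_BINS)]
    return names + list(META_NAMES)


def smooth_block(block: np.ndarray, carry: np.ndarray | None,
                 kernel: SGKernel = SGKernel()) -> np.ndarray:
    """Savitzky-Golay smooth one (channels, 240) block.

    ``carry`` is the trailing 20-sample context from the previously
    processed block, prepended before smoothing and dropped afterwards;
    with no history the left context is mirror-padded from the block
    itself.  Remaining edge samples are mirror-padded inside
    :func:`~errpdecode.preprocess.sg_smooth`.
    """
    if carry is None:
        ext = np.pad(block, ((0, 0), (CARRY_SAMPLES, 0)), mode="reflect")
    else:
        if carry.shape != (block.shape[0], CARRY_SAMPLES):
            raise ValueError("carry-over must be (channels, 20)")
        ext = np.concatenate([carry, block], axis=1)
    return sg_smooth(ext, kernel)[:, CARRY_SAMPLES:]


def block_feature_vector(block: np.ndarray, carry: np.ndarray | None,
                         meta: TrialMeta, channels: tuple[str, ...],
                         kernel: SGKernel = SGKernel()
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Full per-block pipeline: smooth, baseline, downsample, meta.

    Returns ``(signal (n_channels, 8), meta (9,))`` — the shared core of
    the offline featurizer and the streaming decoder.
    """
    smoothed = smooth_block(block, carry, kernel)
    epoch = baseline_correct(TrialEpoch(smoothed, channels, meta))
    return downsample_epoch(epoch), compute_meta(meta, epoch)


@dataclass
class FeatureTable:
    """Per-trial features of a set of recordings, by channel.

    ``signal`` is (n_trials, n_channels, 8); ``chan_mean`` and
    ``chan_sqmean`` hold per-trial per-channel first and second moments
    of the baseline-corrected epoch so the grand mean/variance can be
    recomputed exactly for any channel subset; ``static_meta`` holds the
    seven metadata-derived features.
    """

    signal: np.ndarray
    chan_mean: np.ndarray
    chan_sqmean: np.ndarray
    static_meta: np.ndarray
    channel_names: tuple[str, ...]
    metas: list[TrialMeta]

    @property
    def n_trials(self) -> int:
        return self.signal.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return np.array([int(m.is_error) for m in self.metas])

    def channel_rows(self, channels: tuple[str, ...]) -> np.ndarray:
        return np.array([self.channel_names.index(c) for c in channels])

    def matrix(self, channels: tuple[str, ...] | None = None) -> np.ndarray:
        """Assemble (n_trials, 8*c + 9) vectors for a channel subset.

        Grand mean/variance are recomputed over the subset, matching
        what the streaming decoder sees when only selected channels are
        acquired.
        """
        chans = channels if channels is not None else self.channel_names
        rows = self.channel_rows(tuple(chans))
        sig = self.signal[:, rows, :].reshape(self.n_trials, -1)
        mean = self.chan_mean[:, rows].mean(axis=1)
        var = self.chan_sqmean[:, rows].mean(axis=1) - mean ** 2
        meta = np.column_stack([mean, var, self.static_meta])
        return np.concatenate([sig, meta], axis=1)

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if other.channel_names != self.channel_names:
            raise ValueError("cannot concatenate tables with different channels")
        return FeatureTable(
            signal=np.concatenate([self.signal, other.signal]),
            chan_mean=np.concatenate([self.chan_mean, other.chan_mean]),
            chan_sqmean=np.concatenate([self.chan_sqmean, other.chan_sqmean]),
            static_meta=np.concatenate([self.static_meta, other.static_meta]),
            channel_names=self.channel_names,
            metas=self.metas + other.metas)


def featurize_trials(rec: ContinuousRecording, plan: list[TrialMeta],
                     channels: tuple[str, ...] | None = None,
                     kernel: SGKernel = SGKernel()) -> FeatureTable:
    """Featurize every trial of one (already band-passed) recording.

    Trials are processed in onset order; each block's smoothing context
    is the trailing 100 ms of the previous block, exactly as in the
    streaming decoder.
    """
    names = tuple(channels) if channels is not None else rec.channel_names[:-1]
    rows = rec.channel_index(names)
    onsets = rec.onset_samples()
    if len(onsets) != len(plan):
        raise ValueError(
            f"marker count {len(onsets)} != plan length {len(plan)}")
    sig = np.empty((len(plan), len(names), N_BINS))
    cmean = np.empty((len(plan), len(names)))
    csq = np.empty((len(plan), len(names)))
    static = np.empty((len(plan), N_META - 2))
    carry: np.ndarray | None = None
    for i, (onset, meta) in enumerate(zip(onsets, plan)):
        start = onset - PRE_SAMPLES
        if start >= 0:
            block = rec.samples[np.ix_(rows, np.arange(start, onset + POST_SAMPLES))]
        else:
            avail = rec.samples[rows, : onset + POST_SAMPLES]
            block = np.pad(avail, ((0, 0), (-start, 0)), mode="reflect")
        smoothed = smooth_block(block, carry, kernel)
        epoch = baseline_correct(TrialEpoch(smoothed, names, meta))
        sig[i] = downsample_epoch(epoch)
        cmean[i] = epoch.samples.mean(axis=1)
        csq[i] = (epoch.samples ** 2).mean(axis=1)
        static[i] = (meta.session, meta.feedback_index, meta.letter_position,
                     meta.word_index, meta.total_feedback, meta.total_word,
                     meta.sequence_type)
        carry = block[:, -CARRY_SAMPLES:]
    return FeatureTable(signal=sig, chan_mean=cmean, chan_sqmean=csq,
                        static_meta=static, channel_names=names,
                        metas=list(plan))
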