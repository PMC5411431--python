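"""Synthetic P300-speller feedback sessions with error-related potentials.

The generator emulates the structure of a copy-spelling experiment: each
subject completes five sessions (four of 12 five-letter words, one of 20),
every letter ends in a feedback period, and on error trials a stereotyped
three-lobed error potential (positive ~200 ms, large negative ~250 ms,
positive ~320 ms after feedback onset, fronto-central maximum) is embedded
in ongoing background EEG.  Background activity is 1/f (pink) noise plus a
10 Hz alpha rhythm on posterior channels; ocular artifacts are biphasic
blink transients on the EOG lead that leak into anterior scalp channels.

Everything is deterministic given a seed, so the downstream decoder can be
exercised end to end without any recorded data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import (
    EOG_CHANNEL,
    FRONTAL_LEAK,
    N_SCALP,
    SCALP_CHANNELS,
    errp_topography,
    posterior_mask,
)

SAMPLING_RATE = 200  # Hz
WORDS_PER_SESSION = (12, 12, 12, 12, 20)
LETTERS_PER_WORD = 5
TRIALS_PER_SESSION = tuple(w * LETTERS_PER_WORD for w in WORDS_PER_SESSION)  # 60,...,100
N_SESSIONS = 5

#: Error-potential template: (latency ms, amplitude µV) of each
#: Gaussian-windowed lobe; all lobes share a 25 ms standard deviation.
#: Signs and latencies follow the canonical feedback-locked morphology;
#: the dominant middle lobe is the error-related negativity.
ERRP_LOBES = ((200.0, 2.0), (250.0, -5.0), (320.0, 3.0))
ERRP_LOBE_SD_MS = 25.0

#: Spacing between consecutive feedback onsets (covers the flashing
#: sequence, the 1.3 s feedback display and the inter-trial break).
ONSET_SPACING_S = 4.5
MIN_ONSET_SPACING_S = 2.8
SESSION_LEAD_IN_S = 5.0
SESSION_TAIL_S = 2.0


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one simulated subject.

    Parameters
    ----------
    errp_gain
        Multiplier on the error-potential template amplitude (>= 0).
        ``0`` produces label-independent signals.
    noise_rms
        RMS amplitude of the background pink noise per channel, in µV.
    error_rate_fast, error_rate_slow
        Probability of an erroneous feedback under the fast (4-flash,
        short) and slow (8-flash, long) spelling condition.
    latency_jitter_sd
        Standard deviation (ms) of the per-trial latency shift applied
        to the whole error-potential template.
    """

    subject_id: str = "01"
    errp_gain: float = 1.0
    noise_rms: float = 3.0
    error_rate_fast: float = 0.35
    error_rate_slow: float = 0.20
    latency_jitter_sd: float = 10.0
    alpha_amplitude: float = 1.5
    blink_rate: float = 0.2     # blinks per second (Poisson)
    blink_amplitude: float = 80.0  # µV on the EOG lead
    p_long_sequence: float = 0.5

    def __post_init__(self) -> None:
        for name in ("error_rate_fast", "error_rate_slow", "p_long_sequence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.errp_gain < 0:
            raise ValueError("errp_gain must be >= 0")
        if self.noise_rms <= 0:
            raise ValueError("noise_rms must be > 0")


@dataclass(frozen=True)
class TrialMeta:
    """Metadata of one feedback period (one letter of one word)."""

    subject_id: str
    session: int            # 1..5
    word_index: int         # 1-based within session
    letter_position: int    # 1..5 within word
    feedback_index: int     # 1-based within session
    total_feedback: int     # 1-based since session 1
    total_word: int         # 1-based since session 1
    sequence_type: int      # 1 = long (slow), 0 = short (fast)
    is_error: bool
    onset_time: float       # seconds from recording start


@dataclass
class ContinuousRecording:
    """A multichannel recording at 200 Hz with a feedback-marker track.

    ``samples`` is a (channels, time) matrix in µV whose rows follow
    ``channel_names`` (the 56 scalp channels in montage order, then EOG);
    ``feedback_marker`` is 1 at each feedback-onset sample, else 0.
    """

    samples: np.ndarray
    feedback_marker: np.ndarray
    channel_names: tuple[str, ...] = field(
        default=SCALP_CHANNELS + (EOG_CHANNEL,))
    sampling_rate: int = SAMPLING_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.feedback_marker = np.asarray(self.feedback_marker)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError("channel_names and samples row count differ")
        if self.feedback_marker.shape != (self.samples.shape[1],):
            raise ValueError("marker length must equal recording length")
        if not np.isin(self.feedback_marker, (0, 1)).all():
            raise ValueError("feedback_marker values must be 0 or 1")
        if self.sampling_rate != SAMPLING_RATE:
            raise ValueError("only 200 Hz recordings are supported")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def scalp(self) -> np.ndarray:
        """View of the 56 scalp rows (EOG excluded)."""
        return self.samples[:N_SCALP]

    @property
    def eog(self) -> np.ndarray:
        return self.samples[self.channel_names.index(EOG_CHANNEL)]

    def onset_samples(self) -> np.ndarray:
        """Sample indices of feedback onsets, in temporal order."""
        return np.flatnonzero(self.feedback_marker == 1)

    def channel_index(self, names) -> np.ndarray:
        return np.array([self.channel_names.index(n) for n in names])


def derive_seed(master: int, *parts: int) -> int:
    """Derive a reproducible child seed < 2**31 from a master seed."""
    ss = np.random.SeedSequence([int(master), *[int(p) for p in parts]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_session_plan(
    profile: SubjectProfile, session: int, seed: int
) -> list[TrialMeta]:
    """Draw the trial schedule of one session.

    Sessions 1-4 contain 12 five-letter words (60 feedback periods),
    session 5 contains 20 (100 feedback periods).  Each word is assigned
    a spelling condition (long/slow or short/fast sequence); error labels
    are Bernoulli with the condition-specific rate.
    """
    if session not in range(1, N_SESSIONS + 1):
        raise ValueError(f"session must be in 1..{N_SESSIONS}, got {session}")
    rng = np.random.default_rng(seed)
    n_words = WORDS_PER_SESSION[session - 1]
    prior_feedback = sum(TRIALS_PER_SESSION[: session - 1])
    prior_words = sum(WORDS_PER_SESSION[: session - 1])
    plan: list[TrialMeta] = []
    fb = 0
    for w in range(1, n_words + 1):
        long_seq = int(rng.random() < profile.p_long_sequence)
        p_err = profile.error_rate_slow if long_seq else profile.error_rate_fast
        for pos in range(1, LETTERS_PER_WORD + 1):
            fb += 1
            plan.append(TrialMeta(
                subject_id=profile.subject_id,
                session=session,
                word_index=w,
                letter_position=pos,
                feedback_index=fb,
                total_feedback=prior_feedback + fb,
                total_word=prior_words + w,
                sequence_type=long_seq,
                is_error=bool(rng.random() < p_err),
                onset_time=SESSION_LEAD_IN_S + (fb - 1) * ONSET_SPACING_S,
            ))
    return plan


def errp_waveform(
    time_ms: np.ndarray, gain: float = 1.0, jitter_ms: float = 0.0
) -> np.ndarray:
    """Error-potential template evaluated on ``time_ms`` (ms from onset).

    Sum of three Gaussian-windowed lobes at 200/250/320 ms (+ jitter);
    amplitude is linear in ``gain``; identically zero before onset.
    """
    t = np.asarray(time_ms, dtype=np.float64)
    y = np.zeros_like(t)
    for latency, amp in ERRP_LOBES:
        mu = latency + jitter_ms
        y += amp * np.exp(-0.5 * ((t - mu) / ERRP_LOBE_SD_MS) ** 2)
    y[t < 0] = 0.0
    return gain * y


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int,
                rms: float) -> np.ndarray:
    """Independent 1/f-amplitude noise per channel, normalised to ``rms``."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / SAMPLING_RATE)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n, axis=1)
    scale = rms / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x * scale


def _blink_transient(n_samples: int) -> np.ndarray:
    """Unit-amplitude biphasic blink, 300 ms long at 200 Hz."""
    t = np.arange(n_samples) / SAMPLING_RATE
    up = np.where(t < 0.2, np.sin(np.pi * t / 0.2), 0.0)
    down = np.where((t >= 0.2) & (t < 0.3),
                    -0.3 * np.sin(np.pi * (t - 0.2) / 0.1), 0.0)
    return up + down


def synthesize_recording(
    plan: list[TrialMeta], profile: SubjectProfile, seed: int
) -> ContinuousRecording:
    """Render one continuous recording realising ``plan``.

    Background pink noise on all channels, alpha on posterior sites,
    blinks on the EOG lead leaking into anterior channels, and — on error
    trials only — the error-potential template weighted by the
    fronto-central topography.  One marker sample per trial onset.
    """
    if not plan:
        raise ValueError("plan must contain at least one trial")
    onsets = np.array([t.onset_time for t in plan])
    if np.any(np.diff(onsets) < MIN_ONSET_SPACING_S):
        raise ValueError(
            f"feedback onsets must be >= {MIN_ONSET_SPACING_S} s apart")
    rng = np.random.default_rng(seed)
    n = int(round((onsets[-1] + SESSION_TAIL_S) * SAMPLING_RATE))
    n_chan = N_SCALP + 1

    samples = _pink_noise(rng, n_chan, n, profile.noise_rms)

    # posterior alpha rhythm, random phase per channel
    t_axis = np.arange(n) / SAMPLING_RATE
    post = np.flatnonzero(posterior_mask())
    phases = rng.uniform(0, 2 * np.pi, size=post.size)
    samples[post] += profile.alpha_amplitude * np.sin(
        2 * np.pi * 10.0 * t_axis[None, :] + phases[:, None])

    # blinks: Poisson arrivals on the EOG lead, anterior leakage
    n_blinks = rng.poisson(profile.blink_rate * t_axis[-1])
    blink_starts = np.sort(rng.uniform(0, t_axis[-1] - 0.3, size=n_blinks))
    kernel = _blink_transient(int(0.3 * SAMPLING_RATE))
    eog_row = n_chan - 1
    leak_rows = {SCALP_CHANNELS.index(ch): c for ch, c in FRONTAL_LEAK.items()}
    for start in blink_starts:
        i0 = int(round(start * SAMPLING_RATE))
        amp = profile.blink_amplitude * rng.uniform(0.7, 1.3)
        seg = slice(i0, i0 + kernel.size)
        samples[eog_row, seg] += amp * kernel[: n - i0]
        for row, coeff in leak_rows.items():
            samples[row, seg] += coeff * amp * kernel[: n - i0]

    # error-potential on error trials, fronto-central topography
    topo = errp_topography()
    tpl_len = int(0.7 * SAMPLING_RATE)  # template support: 0..700 ms
    tpl_ms = np.arange(tpl_len) * 1000.0 / SAMPLING_RATE
    marker = np.zeros(n, dtype=np.int8)
    for trial in plan:
        i0 = int(round(trial.onset_time * SAMPLING_RATE))
        marker[i0] = 1
        jitter = float(rng.normal(0.0, profile.latency_jitter_sd))
        if trial.is_error and profile.errp_gain > 0:
            wave = errp_waveform(tpl_ms, profile.errp_gain, jitter)
            seg = slice(i0, min(i0 + tpl_len, n))
            samples[:N_SCALP, seg] += topo[:, None] * wave[: seg.stop - i0]

    return ContinuousRecording(samples=samples, feedback_marker=marker)


@dataclass
class SubjectData:
    """All five sessions of one simulated subject."""

    profile: SubjectProfile
    plans: list[list[TrialMeta]]
    recordings: list[ContinuousRecording]

    @property
    def n_trials(self) -> int:
        return sum(len(p) for p in self.plans)


def plan_subject(profile: SubjectProfile, seed: int) -> list[list[TrialMeta]]:
    """Session plans (no signal synthesis) for one subject."""
    return [make_session_plan(profile, s, derive_seed(seed, 0, s))
            for s in range(1, N_SESSIONS + 1)]


def generate_subject(profile: SubjectProfile, seed: int) -> SubjectData:
    """Plans plus rendered recordings for one subject."""
    plans = plan_subject(profile, seed)
    recordings = [
        synthesize_recording(plan, profile, derive_seed(seed, 1, s + 1))
        for s, plan in enumerate(plans)
    ]
    return SubjectData(profile=profile, plans=plans, recordings=recordings)


def generate_corpus(
    n_subjects: int,
    seed: int,
    profile: SubjectProfile | None = None,
    plans_only: bool = False,
) -> list[SubjectData]:
    """Simulate ``n_subjects`` complete five-session datasets.

    Per-subject seeds are derived reproducibly from ``seed``; the supplied
    ``profile`` (default parameters if omitted) is reused for every
    subject with only the subject id replaced.  With ``plans_only`` the
    recordings are skipped, which is enough for trial-count accounting.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = profile or SubjectProfile()
    out = []
    for i in range(n_subjects):
        prof = replace(base, subject_id=f"{i + 1:02d}")
        sub_seed = derive_seed(seed, 100 + i)
        if plans_only:
            out.append(SubjectData(prof, plan_subject(prof, sub_seed), []))
        else:
            out.append(generate_subject(prof, sub_seed))
    return out
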