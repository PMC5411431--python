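"""Signal conditioning: band-pass filtering, ocular-artifact removal and
Savitzky-Golay smoothing.

The error potential lives in 0.1-10 Hz, so recordings are band-passed with
a recursive elliptic filter (design order 4, 1 dB passband ripple, 50 dB
stopband attenuation).  Filtering is causal forward-only so the offline
and streaming paths share one code path.  Ocular artifacts are removed by
independent component analysis: components whose correlation with the EOG
lead exceeds a threshold are subtracted before further processing.
Savitzky-Golay smoothing (cubic, 31-sample window) denoises each epoch
while preserving peak shape.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .montage import N_SCALP
from .simulate import SAMPLING_RATE, ContinuousRecording


class FilterDesignError(RuntimeError):
    """The requested recursive filter is unstable or infeasible."""


@dataclass(frozen=True)
class BandpassSpec:
    """Elliptic band-pass design parameters."""

    design_order: int = 4
    passband: tuple[float, float] = (0.1, 10.0)
    passband_ripple_db: float = 1.0
    stopband_attenuation_db: float = 50.0

    def __post_init__(self) -> None:
        lo, hi = self.passband
        if not 0.0 < lo < hi < SAMPLING_RATE / 2:
            raise ValueError(
                f"passband edges must satisfy 0 < {lo} < {hi} < Nyquist")


def design_bandpass(spec: BandpassSpec = BandpassSpec(),
                    fs: float = SAMPLING_RATE) -> np.ndarray:
    """Design the elliptic band-pass as second-order sections.

    Raises :class:`FilterDesignError` if any pole falls on or outside the
    unit circle.
    """
    sos = sps.ellip(spec.design_order, spec.passband_ripple_db,
                    spec.stopband_attenuation_db, spec.passband,
                    btype="bandpass", fs=fs, output="sos")
    _, poles, _ = sps.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise FilterDesignError("band-pass design has unstable poles")
    return sos


def apply_bandpass(rec: ContinuousRecording, sos: np.ndarray) -> ContinuousRecording:
    """Filter every channel causally (forward-only); marker untouched."""
    filtered = sps.sosfilt(sos, rec.samples, axis=1)
    return ContinuousRecording(
        samples=filtered, feedback_marker=rec.feedback_marker.copy(),
        channel_names=rec.channel_names, sampling_rate=rec.sampling_rate)


@dataclass(frozen=True)
class SGKernel:
    """Savitzky-Golay convolution kernel (local least-squares polynomial).

    Smoothing replaces each sample by the value at the window centre of
    the best-fitting polynomial of order ``poly_order`` over the
    surrounding ``2 * half_window + 1`` samples; this reduces to a fixed
    symmetric convolution whose coefficients sum to one.
    """

    half_window: int = 15
    poly_order: int = 3

    def __post_init__(self) -> None:
        if self.poly_order >= self.window:
            raise ValueError("poly_order must be smaller than the window")

    @property
    def window(self) -> int:
        return 2 * self.half_window + 1

    @property
    def coefficients(self) -> np.ndarray:
        # savgol_coeffs returns the kernel in convolution order; it is
        # symmetric for the smoothing (derivative-0) case, so the
        # orientation is immaterial.
        return sps.savgol_coeffs(self.window, self.poly_order)


def sg_smooth(series: np.ndarray, kernel: SGKernel = SGKernel()) -> np.ndarray:
    """Savitzky-Golay smoothing along the last axis, length preserved.

    Edges are handled by mirror padding (reflection about the end
    samples).  Input shorter than the window is rejected.
    """
    x = np.asarray(series, dtype=np.float64)
    n = kernel.half_window
    if x.shape[-1] < kernel.window:
        raise ValueError(
            f"series length {x.shape[-1]} shorter than window {kernel.window}")
    pad = [(0, 0)] * (x.ndim - 1) + [(n, n)]
    xp = np.pad(x, pad, mode="reflect")
    coeffs = kernel.coefficients
    out = np.apply_along_axis(
        lambda row: np.convolve(row, coeffs, mode="valid"), -1, xp)
    return out


class ICAError(RuntimeError):
    """Ocular-component decomposition failed."""


@dataclass(frozen=True)
class ICACleanSpec:
    """Configuration of ICA-based ocular-artifact removal."""

    n_components: int | None = None   # None -> full rank (56)
    eog_corr_threshold: float = 0.7
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-4
    min_duration_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eog_corr_threshold <= 1.0:
            raise ValueError("eog_corr_threshold must be in [0, 1]")


@dataclass
class ICAReport:
    """Which components were removed and why."""

    n_components: int
    removed: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = True

    def to_dict(self) -> dict:
        return {"n_components": self.n_components,
                "removed": [{"component": c, "eog_correlation": round(r, 4)}
                            for c, r in self.removed],
                "converged": self.converged}


def remove_eog(rec: ContinuousRecording,
               spec: ICACleanSpec = ICACleanSpec()
               ) -> tuple[ContinuousRecording, ICAReport]:
    """Subtract ICA components correlated with the EOG lead.

    The decomposition is fit on the scalp channels; every component whose
    absolute Pearson correlation with the recorded EOG exceeds the
    threshold is back-projected and subtracted, leaving the remaining
    subspace untouched (so a blink-free recording passes through almost
    unchanged).  Deterministic given the seed.
    """
    if rec.duration < spec.min_duration_s:
        raise ICAError(
            f"recording too short for ICA: {rec.duration:.1f} s "
            f"< {spec.min_duration_s:.0f} s")
    scalp = rec.scalp  # (56, T)
    eog = rec.eog

    ica = FastICA(n_components=spec.n_components, whiten="unit-variance",
                  max_iter=spec.max_iter, tol=spec.tol,
                  random_state=spec.seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(scalp.T)  # (T, k)
    converged = not any(issubclass(w.category, ConvergenceWarning)
                        for w in caught)
    if not np.isfinite(sources).all():
        raise ICAError("ICA produced non-finite sources")

    k = sources.shape[1]
    eog_c = eog - eog.mean()
    src_c = sources - sources.mean(axis=0)
    denom = np.sqrt((src_c ** 2).sum(axis=0) * (eog_c ** 2).sum())
    corr = np.where(denom > 0, (src_c * eog_c[:, None]).sum(axis=0) / denom, 0.0)

    rejected = np.flatnonzero(np.abs(corr) > spec.eog_corr_threshold)
    report = ICAReport(n_components=k,
                       removed=[(int(i), float(corr[i])) for i in rejected],
                       converged=converged)

    cleaned = scalp.copy()
    if rejected.size:
        artifact = sources[:, rejected] @ ica.mixing_[:, rejected].T  # (T, 56)
        cleaned = cleaned - artifact.T

    samples = rec.samples.copy()
    samples[:N_SCALP] = cleaned
    out = ContinuousRecording(
        samples=samples, feedback_marker=rec.feedback_marker.copy(),
        channel_names=rec.channel_names, sampling_rate=rec.sampling_rate)
    return out, report
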