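"""Preprocessing and quality control: triggered segmentation, event-related
averaging, amplitude-histogram QC with saturation detection, and EMG
(muscle) artifact detection.

Amplitude histograms support a histogram-based quality check: recording
equipment clips at its dynamic-range limits, and because file headers do
not always report the true saturation values, the histogram (with its
Shannon entropy as a summary) lets those thresholds be identified and
saturated samples flagged.

The EMG detector combines time-domain criteria (slope, max/min amplitude)
with frequency-domain criteria (absolute and relative "high beta" power
above 25 Hz, spectral edge frequency); thresholds are calibrated from the
parameter distributions over a reference period rather than fixed
empirically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .gdf_io import SignalRecording

__all__ = [
    "EpochSet",
    "AmplitudeHistogram",
    "EmgDetectorParams",
    "segment_by_trigger",
    "event_related_average",
    "amplitude_histogram",
    "histogram_entropy",
    "detect_saturation",
    "calibrate_emg_detector",
    "detect_emg_artifacts",
]

logger = logging.getLogger("biosigkit")

BETA_EDGE_HZ = 25.0  # lower edge of the "high beta" band used by the EMG detector
SEF_FRACTION = 0.95  # spectral-edge fraction used by the EMG detector


@dataclass
class EpochSet:
    """Segmented trials: (epoch, channel, time) in physical units.

    Epochs are half-open windows ``[trigger - pre, trigger + post)`` so every
    epoch has exactly ``round((pre + post) * sampling_rate)`` samples.
    """

    data: np.ndarray
    pre: float
    post: float
    sampling_rate: float
    trigger_codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epoch, channel, time)")
        self.trigger_codes = np.asarray(self.trigger_codes, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time axis relative to the trigger, in seconds."""
        n = self.data.shape[2]
        return np.arange(n) / self.sampling_rate - self.pre


@dataclass
class AmplitudeHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    channel: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")


def segment_by_trigger(
    recording: SignalRecording,
    codes: set[int] | frozenset[int],
    pre: float,
    post: float,
) -> EpochSet:
    """Cut one epoch around every event whose code is in ``codes``.

    Events whose window ``[pos - pre, pos + post)`` does not lie fully inside
    the recording are dropped (the count is logged).  No matching events
    yields an empty EpochSet, not an error.
    """
    if pre < 0 or post < 0 or pre + post <= 0:
        raise ValueError("need pre, post >= 0 and pre + post > 0")
    x = recording.to_array()
    fs = recording.sampling_rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    ev = recording.events
    mask = np.isin(ev.codes.astype(int), list(codes))
    epochs, kept_codes, dropped = [], [], 0
    for pos, code in zip(ev.positions[mask], ev.codes[mask]):
        lo, hi = int(pos) - n_pre, int(pos) + n_post
        if lo < 0 or hi > x.shape[1]:
            dropped += 1
            continue
        epochs.append(x[:, lo:hi])
        kept_codes.append(int(code))
    if dropped:
        logger.info("segment_by_trigger: dropped %d out-of-bounds event(s)", dropped)
    data = (
        np.stack(epochs)
        if epochs
        else np.empty((0, x.shape[0], n_pre + n_post))
    )
    return EpochSet(data=data, pre=pre, post=post, sampling_rate=fs,
                    trigger_codes=np.asarray(kept_codes, dtype=int))


def event_related_average(epochs: EpochSet) -> np.ndarray:
    """Arithmetic mean over epochs; shape (channel, time)."""
    if epochs.n_epochs == 0:
        raise ValueError("cannot average an empty EpochSet")
    return epochs.data.mean(axis=0)


def amplitude_histogram(
    x: np.ndarray,
    n_bins: int,
    value_range: tuple[float, float] | None = None,
    channel: int = 0,
) -> AmplitudeHistogram:
    """Equal-width amplitude histogram over ``value_range``.

    Pass the channel's (digital_min, digital_max) as ``value_range`` when a
    channel spec is available; otherwise the observed [min, max] is used.
    Clipped-amplitude recordings show up as mass piled at the extreme bins.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=np.float64).ravel()
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        raise ValueError("signal has no finite samples")
    if value_range is None:
        lo, hi = float(finite.min()), float(finite.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = value_range
    counts, edges = np.histogram(finite, bins=n_bins, range=(lo, hi))
    # keep out-of-range samples in the edge bins so counts stay conserved
    counts[0] += int(np.sum(finite < lo))
    counts[-1] += int(np.sum(finite > hi))
    return AmplitudeHistogram(bin_edges=edges, counts=counts, channel=channel)


def histogram_entropy(hist: AmplitudeHistogram) -> float:
    """Shannon entropy of the amplitude distribution, in bits (0·log 0 := 0)."""
    total = hist.counts.sum()
    if total <= 0:
        raise ValueError("histogram has no counts")
    p = hist.counts[hist.counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def detect_saturation(
    x: np.ndarray, lo: float, hi: float
) -> tuple[np.ndarray, float]:
    """Flag samples at or beyond the dynamic-range limits.

    Returns (mask, fraction): mask is True where ``x <= lo`` or ``x >= hi``.
    Use a channel's digital/physical min/max as defaults when known; the
    amplitude histogram supports choosing the thresholds when they are not.
    """
    if lo >= hi:
        raise ValueError("need lo < hi")
    x = np.asarray(x, dtype=np.float64)
    mask = (x <= lo) | (x >= hi)
    return mask, float(mask.mean()) if x.size else 0.0


# ---------------------------------------------------------------------------
# EMG (muscle) artifact detection


@dataclass
class EmgDetectorParams:
    """Detection thresholds calibrated from a reference period.

    A test window is flagged when ANY criterion fires: slope or maximum
    amplitude above threshold, minimum amplitude below threshold, absolute
    or relative power above 25 Hz, or spectral edge frequency above
    threshold.
    """

    slope_threshold: float
    amp_min: float
    amp_max: float
    abs_beta_threshold: float
    rel_beta_threshold: float
    sef_threshold: float

    def as_dict(self) -> dict[str, float]:
        return {
            "slope": self.slope_threshold,
            "amp_min": self.amp_min,
            "amp_max": self.amp_max,
            "abs_beta": self.abs_beta_threshold,
            "rel_beta": self.rel_beta_threshold,
            "sef": self.sef_threshold,
        }


def _window_params(w: np.ndarray, fs: float) -> dict[str, float]:
    """The six detection parameters for one analysis window."""
    w = w - w.mean()
    slope = float(np.max(np.abs(np.diff(w))) * fs) if len(w) > 1 else 0.0
    nper = min(len(w), int(fs))
    freqs, pxx = sps.welch(w, fs=fs, window="hann", nperseg=nper,
                           noverlap=nper // 2, detrend=False)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    total = float(pxx.sum() * df)
    beta = float(pxx[freqs >= BETA_EDGE_HZ].sum() * df)
    cum = np.cumsum(pxx) * df
    if total > 0:
        sef = float(np.interp(SEF_FRACTION * total, cum, freqs))
        rel_beta = beta / total
    else:
        sef, rel_beta = 0.0, 0.0
    return {
        "slope": slope,
        "amp_min": float(w.min()),
        "amp_max": float(w.max()),
        "abs_beta": beta,
        "rel_beta": rel_beta,
        "sef": sef,
    }


def _split_windows(x: np.ndarray, n: int) -> list[np.ndarray]:
    """Non-overlapping half-open windows of n samples; a short tail is dropped."""
    return [x[i : i + n] for i in range(0, len(x) - n + 1, n)]


def calibrate_emg_detector(reference: np.ndarray, fs: float) -> EmgDetectorParams:
    """Derive detection thresholds from a clean reference period.

    Each parameter is computed over 1-s reference windows; thresholds are
    mean + 3·SD of the parameter distribution (mean − 3·SD for the minimum
    amplitude).  For Gaussian data each one-sided criterion then flags
    ≈0.13% of windows drawn from the same distribution.
    """
    reference = np.asarray(reference, dtype=np.float64)
    if fs <= 50:
        raise ValueError("sampling rate must exceed 50 Hz (beta band undefined)")
    n = int(round(fs))
    if len(reference) < 10 * n:
        raise ValueError("reference period must be at least 10 s")
    rows = [_window_params(w, fs) for w in _split_windows(reference, n)]
    stats = {k: np.array([r[k] for r in rows]) for k in rows[0]}

    def hi(k: str) -> float:
        return float(stats[k].mean() + 3 * stats[k].std())

    return EmgDetectorParams(
        slope_threshold=hi("slope"),
        amp_min=float(stats["amp_min"].mean() - 3 * stats["amp_min"].std()),
        amp_max=hi("amp_max"),
        abs_beta_threshold=hi("abs_beta"),
        rel_beta_threshold=hi("rel_beta"),
        sef_threshold=hi("sef"),
    )


def detect_emg_artifacts(
    x: np.ndarray,
    fs: float,
    params: EmgDetectorParams,
    window: float = 1.0,
) -> np.ndarray:
    """Per-window muscle-artifact flags over non-overlapping windows.

    Returns a boolean array with one entry per complete window; a window is
    flagged when any single criterion exceeds its calibrated threshold.
    """
    if fs <= 50:
        raise ValueError("sampling rate must exceed 50 Hz (beta band undefined)")
    if window < 0.5:
        raise ValueError("detection window must be at least 0.5 s")
    x = np.asarray(x, dtype=np.float64)
    n = int(round(window * fs))
    flags = []
    for w in _split_windows(x, n):
        p = _window_params(w, fs)
        flags.append(
            p["slope"] > params.slope_threshold
            or p["amp_max"] > params.amp_max
            or p["amp_min"] < params.amp_min
            or p["abs_beta"] > params.abs_beta_threshold
            or p["rel_beta"] > params.rel_beta_threshold
            or p["sef"] > params.sef_threshold
        )
    return np.asarray(flags, dtype=bool)
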