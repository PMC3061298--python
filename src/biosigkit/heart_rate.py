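"""Heart-rate extraction from the ECG: Hilbert-envelope R-peak detection,
beat-to-beat rate series, and event-related heart-rate averages.

The detector computes the envelope of the (band-passed) ECG as the
magnitude of its analytic signal and finds R-peaks by thresholding the
envelope.  A refractory period enforces a physiological ceiling on the
detected rate.  Instantaneous heart rate is 60/RR beats per minute,
assigned to the time of the second peak of each RR pair; for event-related
averaging the irregularly sampled rate series is first interpolated onto a
uniform grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .gdf_io import EventTable
from .preprocessing import EpochSet, event_related_average

__all__ = [
    "RPeakList",
    "HeartRateSeries",
    "hilbert_envelope",
    "detect_r_peaks",
    "heart_rate_series",
    "event_related_heart_rate",
]

logger = logging.getLogger("biosigkit")

QRS_BAND_HZ = (8.0, 20.0)  # pass-band emphasizing QRS energy before the Hilbert transform
DEFAULT_THRESHOLD_FRACTION = 0.5  # of the 95th envelope percentile
DEFAULT_REFRACTORY_S = 0.25  # 240 bpm physiological cap
HR_GRID_HZ = 4.0  # uniform resampling rate for event-related averaging


@dataclass
class RPeakList:
    """Detected R-peak sample positions (0-based, strictly increasing)."""

    indices: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(self.indices) > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.sampling_rate

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class HeartRateSeries:
    """Beat-to-beat heart rate (beats/min) at the second peak of each RR pair."""

    times: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.rate = np.asarray(self.rate, dtype=np.float64)
        if self.times.shape != self.rate.shape:
            raise ValueError("times and rate must have equal length")


def hilbert_envelope(ecg: np.ndarray) -> np.ndarray:
    """Envelope of the signal: magnitude of the analytic signal."""
    ecg = np.asarray(ecg, dtype=np.float64)
    if len(ecg) < 16:
        raise ValueError("signal too short for envelope estimation (need >= 16 samples)")
    return np.abs(sps.hilbert(ecg))


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    refractory: float = DEFAULT_REFRACTORY_S,
    band: tuple[float, float] | None = QRS_BAND_HZ,
) -> RPeakList:
    """Detect R-peaks by thresholding the Hilbert envelope of the ECG.

    The signal is band-pass filtered (default 8–20 Hz, emphasizing QRS
    energy) before the envelope is taken.  Peaks are local envelope maxima
    above ``threshold_fraction`` times the 95th envelope percentile,
    separated by at least the refractory period.  A flat envelope yields an
    empty list.
    """
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz for R-peak detection")
    ecg = np.asarray(ecg, dtype=np.float64)
    x = ecg
    if band is not None:
        sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, ecg)
    env = hilbert_envelope(x)
    level = np.percentile(env, 95)
    if level <= 0:
        return RPeakList(indices=np.empty(0, dtype=np.int64), sampling_rate=fs)
    threshold = threshold_fraction * level
    distance = max(1, int(round(refractory * fs)))
    peaks, _ = sps.find_peaks(env, height=threshold, distance=distance)
    return RPeakList(indices=peaks, sampling_rate=fs)


def heart_rate_series(peaks: RPeakList) -> HeartRateSeries:
    """Instantaneous heart rate 60/RR for each successive peak pair."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to compute a heart rate")
    t = peaks.times
    rr = np.diff(t)
    return HeartRateSeries(times=t[1:], rate=60.0 / rr)


def event_related_heart_rate(
    hr: HeartRateSeries,
    events: EventTable,
    pre: float,
    post: float,
    event_sampling_rate: float,
    codes: set[int] | None = None,
    grid_rate: float = HR_GRID_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Average heart rate time-locked to events.

    The rate series is linearly interpolated onto a uniform ``grid_rate``
    grid first; epochs whose window falls outside the rate support are
    dropped and logged.  Returns (times relative to event, mean rate).
    """
    if len(hr.times) < 2:
        raise ValueError("heart-rate series too short")
    t0, t1 = hr.times[0], hr.times[-1]
    grid = np.arange(t0, t1, 1.0 / grid_rate)
    rate = np.interp(grid, hr.times, hr.rate)

    ev_times = events.positions / event_sampling_rate
    if codes is not None:
        ev_times = ev_times[np.isin(events.codes.astype(int), list(codes))]
    n_pre, n_post = int(round(pre * grid_rate)), int(round(post * grid_rate))
    epochs, dropped = [], 0
    for et in ev_times:
        center = int(round((et - t0) * grid_rate))
        lo, hi = center - n_pre, center + n_post
        if lo < 0 or hi > len(grid):
            dropped += 1
            continue
        epochs.append(rate[lo:hi])
    if dropped:
        logger.info("event_related_heart_rate: dropped %d out-of-support event(s)", dropped)
    eset = EpochSet(
        data=np.stack(epochs)[:, None, :] if epochs else np.empty((0, 1, n_pre + n_post)),
        pre=pre,
        post=post,
        sampling_rate=grid_rate,
    )
    avg = event_related_average(eset)[0]
    times = np.arange(n_pre + n_post) / grid_rate - pre
    return times, avg
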