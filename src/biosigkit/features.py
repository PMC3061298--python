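"""EEG feature extraction: band power, Hjorth parameters, spectral edge
frequency, and autoregressive coefficients.

Spectral estimates use Welch's method (Hann window, 1-s segments, 50%
overlap by default); all features are computed after mean removal so they
are invariant to the signal's DC offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import signal as sps

__all__ = [
    "PowerSpectrum",
    "HjorthTriple",
    "power_spectrum",
    "band_power",
    "hjorth",
    "spectral_edge_frequency",
    "ar_coefficients",
]


@dataclass
class PowerSpectrum:
    """One-sided power spectral density with the estimation settings used."""

    freqs: np.ndarray
    density: np.ndarray
    window: str = "hann"
    nperseg: int = 0
    noverlap: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.freqs.shape != self.density.shape:
            raise ValueError("freqs and density must have equal length")
        if np.any(self.density < 0):
            raise ValueError("spectral density must be nonnegative")

    @property
    def total_power(self) -> float:
        return float(integrate.trapezoid(self.density, self.freqs))


@dataclass
class HjorthTriple:
    """Hjorth activity (signal units²), mobility, complexity.

    Mobility is in rad/sample by default; multiply by fs/(2π) for Hz.
    For a pure sinusoid mobility approximates the oscillation frequency and
    complexity approaches 1 (minimal bandwidth).
    """

    activity: float
    mobility: float
    complexity: float

    def mobility_hz(self, fs: float) -> float:
        return self.mobility * fs / (2 * np.pi)


def power_spectrum(
    x: np.ndarray,
    fs: float,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> PowerSpectrum:
    """Welch power spectral density of a demeaned signal."""
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    nperseg = min(len(x), max(8, int(round(segment_s * fs))))
    noverlap = int(nperseg * overlap)
    freqs, pxx = sps.welch(x, fs=fs, window=window, nperseg=nperseg,
                           noverlap=noverlap, detrend=False)
    return PowerSpectrum(freqs=freqs, density=pxx, window=window,
                         nperseg=nperseg, noverlap=noverlap)


def band_power(
    x: np.ndarray, fs: float, band: tuple[float, float], segment_s: float = 1.0
) -> float:
    """Integrated spectral power over the half-open band [lo, hi) Hz.

    Band powers are additive over a disjoint partition of [0, fs/2], and
    their sum approximates the signal variance (Parseval).
    """
    lo, hi = band
    if not 0 <= lo < hi <= fs / 2:
        raise ValueError(f"band [{lo}, {hi}) must lie within [0, {fs / 2}] with lo < hi")
    spec = power_spectrum(x, fs, segment_s=segment_s)
    df = spec.freqs[1] - spec.freqs[0]
    mask = (spec.freqs >= lo) & (spec.freqs < hi)
    return float(spec.density[mask].sum() * df)


def hjorth(x: np.ndarray) -> HjorthTriple:
    """Hjorth parameters from first differences of the demeaned signal.

    activity = var(x); mobility = sqrt(var(Δx)/var(x));
    complexity = mobility(Δx)/mobility(x).
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    x = x - x.mean()
    v0 = float(np.var(x))
    if v0 == 0:
        raise ValueError("constant signal: mobility undefined")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v1, v2 = float(np.var(d1)), float(np.var(d2))
    mobility = np.sqrt(v1 / v0)
    complexity = np.sqrt(v2 / v1) / mobility if v1 > 0 else np.inf
    return HjorthTriple(activity=v0, mobility=float(mobility), complexity=float(complexity))


def spectral_edge_frequency(spectrum: PowerSpectrum, fraction: float = 0.95) -> float:
    """Smallest frequency below which ``fraction`` of the total power lies.

    Linear interpolation between frequency bins of the cumulative
    (trapezoid) power.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    cum = integrate.cumulative_trapezoid(spectrum.density, spectrum.freqs, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise ValueError("spectrum has zero total power")
    return float(np.interp(fraction * total, cum, spectrum.freqs))


def ar_coefficients(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Univariate AR(p) fit: x_t = Σ_k a_k x_{t−k} + e_t.

    Returns (a, residual variance).  Delegates to the multivariate AR
    estimator with a single channel; the coefficients describe the entire
    spectral density function compactly.
    """
    from .mvar import fit_mvar

    if order < 1:
        raise ValueError("AR order must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    model = fit_mvar(x[None, :] - x.mean(), order)
    a = np.array([A[0, 0] for A in model.A])
    return a, float(model.sigma[0, 0])
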