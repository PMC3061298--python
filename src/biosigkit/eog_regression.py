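"""Ocular-artifact removal from EEG by multichannel linear regression.

The observed EEG is modelled as a linear superposition of the true cortical
activity and the electro-oculogram propagated to the scalp by volume
conduction:

    Y(t) = E(t) + b · O(t)

with Y the observed N-channel EEG, O the observed M-channel (bipolar) EOG,
and b the N×M propagation matrix.  Volume conduction depends only on head
geometry and tissue conductivity, so b is assumed constant over the
recording and frequency-independent.  Because cortical EEG and ocular
activity are uncorrelated, right-multiplying by O(t)ᵀ and taking the time
average gives the least-squares solution

    b = ⟨Y·Oᵀ⟩ · ⟨O·Oᵀ⟩⁻¹

and the corrected EEG is E(t) = Y(t) − b·O(t).  b minimizes the mean square
of E, and the estimate is least biased when the EOG-to-other-noise ratio is
high — hence coefficients should be estimated on a segment with large
ocular activity, optionally after band-pass filtering away 1/f amplifier
drift and high-frequency noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "MultichannelSegment",
    "PropagationMatrix",
    "EstimationError",
    "estimate_propagation",
    "correct_eog",
    "eog_reduction_percentage",
]

CONDITION_CAP = 1e8  # default cap on cond(⟨O·Oᵀ⟩)


class EstimationError(RuntimeError):
    """Raised when the EOG covariance is singular or ill-conditioned."""


@dataclass
class MultichannelSegment:
    """Paired EEG (Y: N×T) and EOG (O: M×T) segments at a common rate."""

    Y: np.ndarray
    O: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=np.float64))
        self.O = np.atleast_2d(np.asarray(self.O, dtype=np.float64))
        if self.Y.shape[1] != self.O.shape[1]:
            raise ValueError(
                f"EEG and EOG must have equal length: {self.Y.shape[1]} != {self.O.shape[1]}"
            )
        if self.Y.shape[0] < 1 or self.O.shape[0] < 1:
            raise ValueError("need at least one EEG and one EOG channel")


@dataclass
class PropagationMatrix:
    """EOG→EEG propagation coefficients b (N×M, dimensionless gains)."""

    b: np.ndarray
    n_samples: int = 0
    bandpass: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.b = np.atleast_2d(np.asarray(self.b, dtype=np.float64))
        if not np.all(np.isfinite(self.b)):
            raise ValueError("propagation matrix must be finite")


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def estimate_propagation(
    segment: MultichannelSegment,
    demean: bool = True,
    bandpass: tuple[float, float] | None = None,
    condition_cap: float = CONDITION_CAP,
) -> PropagationMatrix:
    """Least-squares estimate b = ⟨Y·Oᵀ⟩·⟨O·Oᵀ⟩⁻¹ over the segment.

    ``demean`` removes each channel's time average first (the superposition
    model has no intercept term).  ``bandpass`` (lo, hi) in Hz filters both
    Y and O before estimation, which improves the estimate when broadband
    amplifier noise is present.  Raises :class:`EstimationError` when
    ⟨O·Oᵀ⟩ is ill-conditioned, naming the near-collinear EOG channels.
    """
    Y, O = segment.Y, segment.O
    if bandpass is not None:
        Y = _bandpass(Y, segment.sampling_rate, bandpass)
        O = _bandpass(O, segment.sampling_rate, bandpass)
    if demean:
        Y = Y - Y.mean(axis=1, keepdims=True)
        O = O - O.mean(axis=1, keepdims=True)
    T = Y.shape[1]
    cov_oo = O @ O.T / T
    cond = np.linalg.cond(cov_oo)
    if not np.isfinite(cond) or cond > condition_cap:
        raise EstimationError(
            f"EOG covariance is ill-conditioned (cond={cond:.3g} > {condition_cap:.1g}); "
            f"offending EOG channels: {_collinear_channels(O)}"
        )
    cov_yo = Y @ O.T / T
    # solve b·cov_oo = cov_yo without forming the inverse
    b = np.linalg.solve(cov_oo.T, cov_yo.T).T
    return PropagationMatrix(b=b, n_samples=T, bandpass=bandpass)


def _collinear_channels(O: np.ndarray) -> list[int]:
    """Indices of EOG channels involved in near-perfect pairwise correlation."""
    if O.shape[0] < 2:
        return [0]
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(O)
    bad: set[int] = set()
    for i in range(O.shape[0]):
        if O[i].std() == 0:
            bad.add(i)
        for j in range(i + 1, O.shape[0]):
            if abs(r[i, j]) > 0.999:
                bad.update((i, j))
    return sorted(bad) if bad else list(range(O.shape[0]))


def correct_eog(segment: MultichannelSegment, b: PropagationMatrix) -> np.ndarray:
    """Remove the propagated ocular activity: E(t) = Y(t) − b·O(t)."""
    if b.b.shape != (segment.Y.shape[0], segment.O.shape[0]):
        raise ValueError(
            f"propagation matrix shape {b.b.shape} does not match "
            f"({segment.Y.shape[0]} EEG, {segment.O.shape[0]} EOG) channels"
        )
    return segment.Y - b.b @ segment.O


def eog_reduction_percentage(
    raw: np.ndarray, corrected: np.ndarray, true_eeg: np.ndarray
) -> float:
    """Percent of artifact variance removed, averaged over EEG channels.

    Per channel: 100·(1 − var(corrected − true)/var(raw − true)).  100 means
    perfect removal; 0 means no change; negative values mean the correction
    added noise.  Requires a known artifact-free reference, so this is a
    simulation-only diagnostic.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=np.float64))
    corrected = np.atleast_2d(np.asarray(corrected, dtype=np.float64))
    true_eeg = np.atleast_2d(np.asarray(true_eeg, dtype=np.float64))
    if not raw.shape == corrected.shape == true_eeg.shape:
        raise ValueError("raw, corrected and reference must have equal shapes")
    var_before = np.var(raw - true_eeg, axis=1)
    if np.any(var_before == 0):
        raise ValueError("raw signal equals the reference on some channel; "
                         "reduction undefined")
    var_after = np.var(corrected - true_eeg, axis=1)
    return float(np.mean(100.0 * (1.0 - var_after / var_before)))
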