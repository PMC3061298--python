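"""Multivariate autoregressive (MVAR) modeling and frequency-domain coupling
measures: auto/cross spectra, coherency (magnitude, imaginary part, phase),
partial coherence, the directed transfer function (DTF), and partial
directed coherence (PDC).

An MVAR model of order p regresses each of K channels on p lags of all
channels:

    x(t) = Σ_{k=1..p} A_k · x(t−k) + e(t),    cov(e) = Σ

Its frequency-domain form uses Ā(f) = I − Σ_k A_k e^{−i2πfk/fs} and the
transfer matrix H(f) = Ā(f)⁻¹, from which the cross-spectral density is
S(f) = H(f)·Σ·H(f)ᴴ/fs.  All coupling measures here derive from the fitted
model, so the MVAR fit is the common basis for comparing them:

* coherency C_ij = S_ij/√(S_ii S_jj) — complex; |C| ∈ [0, 1].  Its
  imaginary part cannot be produced by instantaneous volume conduction
  alone, and its phase slope estimates the inter-channel time delay.
* partial coherence — coherence after partializing out all other channels,
  computed from the inverse spectral matrix G = S⁻¹ as |G_ij|²/(G_ii G_jj).
* DTF γ²_ij(f) = |H_ij|²/Σ_k |H_ik|² — row-normalized; directed and
  sensitive to cascade (indirect) flow.
* PDC π_ij(f) = |Ā_ij|/√(Σ_k |Ā_kj|²) — column-normalized; directed and
  sensitive only to direct influence.

Index convention throughout: element [i, j] quantifies the influence of
channel j on channel i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MvarModel",
    "SpectralMatrix",
    "Coherency",
    "fit_mvar",
    "spectral_matrices",
    "coherency",
    "partial_coherence",
    "dtf",
    "pdc",
]

MIN_SAMPLES_FACTOR = 10  # require T > factor · K · p for estimation


@dataclass
class MvarModel:
    """Fitted MVAR model: lag matrices A_1..A_p and innovation covariance."""

    A: list[np.ndarray]
    sigma: np.ndarray
    sampling_rate: float = 1.0

    def __post_init__(self) -> None:
        self.A = [np.atleast_2d(np.asarray(a, dtype=np.float64)) for a in self.A]
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=np.float64))
        K = self.sigma.shape[0]
        for a in self.A:
            if a.shape != (K, K):
                raise ValueError("all coefficient matrices must be K×K")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("innovation covariance must be symmetric")

    @property
    def order(self) -> int:
        return len(self.A)

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[0]

    def companion_spectral_radius(self) -> float:
        """Spectral radius of the companion matrix; < 1 means stable."""
        K, p = self.n_channels, self.order
        comp = np.zeros((K * p, K * p))
        comp[:K, :] = np.hstack(self.A)
        if p > 1:
            comp[K:, : K * (p - 1)] = np.eye(K * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def is_stable(self) -> bool:
        return self.companion_spectral_radius() < 1.0


@dataclass
class SpectralMatrix:
    """Per-frequency spectral quantities of an MVAR model.

    S[f] is the K×K cross-spectral density (Hermitian PSD), H[f] the
    transfer matrix, Abar[f] the frequency-domain coefficient matrix.
    """

    freqs: np.ndarray
    S: np.ndarray  # (F, K, K) complex
    H: np.ndarray
    Abar: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)


def fit_mvar(X: np.ndarray, order: int, min_samples_factor: int = MIN_SAMPLES_FACTOR) -> MvarModel:
    """Multichannel least-squares MVAR fit.

    ``X`` is (K, T).  Each x(t), t = p..T−1, is regressed on the stacked lag
    vector [x(t−1); …; x(t−p)]; sigma is the residual covariance.  Raises
    when the series is too short or the regressor matrix is rank-deficient
    (suggesting a lower order).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    K, T = X.shape
    p = int(order)
    if p < 1:
        raise ValueError("model order must be >= 1")
    if T <= min_samples_factor * K * p:
        raise ValueError(
            f"series too short: T={T} must exceed {min_samples_factor}·K·p="
            f"{min_samples_factor * K * p}; lower the order"
        )
    # regressor Z: (K·p, T−p); row block k holds lag k+1
    n = T - p
    Z = np.empty((K * p, n))
    for k in range(p):
        Z[k * K : (k + 1) * K, :] = X[:, p - 1 - k : T - 1 - k]
    Xf = X[:, p:]
    rank = np.linalg.matrix_rank(Z)
    if rank < K * p:
        raise ValueError(
            f"regressor matrix is rank-deficient (rank {rank} < {K * p}); "
            "try a lower model order"
        )
    coef, *_ = np.linalg.lstsq(Z.T, Xf.T, rcond=None)
    coef = coef.T  # (K, K·p)
    A = [coef[:, k * K : (k + 1) * K] for k in range(p)]
    resid = Xf - coef @ Z
    dof = max(n - K * p, 1)
    sigma = resid @ resid.T / dof
    sigma = (sigma + sigma.T) / 2
    return MvarModel(A=A, sigma=sigma)


def _abar(model: MvarModel, freqs: np.ndarray) -> np.ndarray:
    """Ā(f) = I − Σ_k A_k e^{−i2πfk/fs}, stacked over frequencies."""
    K, fs = model.n_channels, model.sampling_rate
    F = len(freqs)
    out = np.tile(np.eye(K, dtype=complex), (F, 1, 1))
    for k, Ak in enumerate(model.A, start=1):
        phase = np.exp(-2j * np.pi * freqs * k / fs)
        out -= phase[:, None, None] * Ak
    return out


def spectral_matrices(model: MvarModel, freqs: np.ndarray | None = None) -> SpectralMatrix:
    """Transfer matrices and cross-spectral densities on a frequency grid.

    Default grid: 128 points on [0, fs/2].  S(f) = H(f)·Σ·H(f)ᴴ/fs is
    Hermitian with real nonnegative diagonal at every frequency.
    """
    fs = model.sampling_rate
    if freqs is None:
        freqs = np.linspace(0, fs / 2, 128)
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any(freqs < 0) or np.any(freqs > fs / 2):
        raise ValueError("frequencies must lie in [0, fs/2]")
    Abar = _abar(model, freqs)
    H = np.empty_like(Abar)
    for fi in range(len(freqs)):
        try:
            H[fi] = np.linalg.inv(Abar[fi])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"coefficient matrix singular at f={freqs[fi]:.4g} Hz"
            ) from exc
    S = H @ model.sigma @ np.conj(np.swapaxes(H, 1, 2)) / fs
    # enforce exact Hermitian symmetry against rounding
    S = (S + np.conj(np.swapaxes(S, 1, 2))) / 2
    return SpectralMatrix(freqs=freqs, S=S, H=H, Abar=Abar)


@dataclass
class Coherency:
    """Complex coherency of one channel pair over frequency."""

    freqs: np.ndarray
    values: np.ndarray  # complex

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def msc(self) -> np.ndarray:
        """Magnitude-squared coherence."""
        return np.abs(self.values) ** 2

    @property
    def imaginary(self) -> np.ndarray:
        return np.imag(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def delay_estimate(self) -> float:
        """Inter-channel delay (s) from the slope of unwrapped phase vs 2πf."""
        phi = np.unwrap(self.phase)
        w = 2 * np.pi * self.freqs
        slope = np.polyfit(w, phi, 1)[0]
        return float(-slope)


def coherency(spec: SpectralMatrix, i: int, j: int) -> Coherency:
    """Coherency C_ij(f) = S_ij/√(S_ii·S_jj): the cross-spectrum normalized
    by the autospectra.  |C| lies in [0, 1]; a nonzero imaginary part
    indicates lagged coupling that volume conduction alone cannot explain.
    """
    Sii = np.real(spec.S[:, i, i])
    Sjj = np.real(spec.S[:, j, j])
    if np.any(Sii <= 0) or np.any(Sjj <= 0):
        raise ValueError("zero autospectrum: coherency undefined")
    return Coherency(freqs=spec.freqs, values=spec.S[:, i, j] / np.sqrt(Sii * Sjj))


def partial_coherence(spec: SpectralMatrix, i: int, j: int) -> np.ndarray:
    """Partial coherence |G_ij|²/(G_ii·G_jj), G = S⁻¹: coupling between
    channels i and j after partializing out all remaining channels.
    Values lie in [0, 1]; with K=2 it equals the magnitude-squared coherence.
    """
    out = np.empty(len(spec.freqs))
    for fi in range(len(spec.freqs)):
        try:
            G = np.linalg.inv(spec.S[fi])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"spectral matrix singular at f={spec.freqs[fi]:.4g} Hz"
            ) from exc
        out[fi] = np.abs(G[i, j]) ** 2 / (np.real(G[i, i]) * np.real(G[j, j]))
    return out


def dtf(model: MvarModel, freqs: np.ndarray | None = None, squared: bool = True) -> np.ndarray:
    """Directed transfer function, row-normalized: (K, K, F) array.

    γ²_ij(f) = |H_ij(f)|² / Σ_k |H_ik(f)|²; element [i, j] is the inflow
    from channel j to channel i, and each row of squared values sums to 1.
    Detects directed flow including cascades (indirect paths).
    """
    spec = spectral_matrices(model, freqs)
    H2 = np.abs(spec.H) ** 2  # (F, K, K)
    denom = H2.sum(axis=2, keepdims=True)
    g2 = H2 / denom
    out = g2 if squared else np.sqrt(g2)
    return np.transpose(out, (1, 2, 0))


def pdc(
    model: MvarModel,
    freqs: np.ndarray | None = None,
    squared: bool = True,
    generalized: bool = False,
) -> np.ndarray:
    """Partial directed coherence, column-normalized: (K, K, F) array.

    π_ij(f) = |Ā_ij(f)| / √(Σ_k |Ā_kj(f)|²); element [i, j] is the direct
    outflow from channel j to channel i, and each column of squared values
    sums to 1.  Unlike the DTF it does not respond to indirect (cascade)
    paths, so it indexes the direct causal structure.  ``generalized``
    weights entries by the inverse innovation standard deviations.
    """
    fs = model.sampling_rate
    if freqs is None:
        freqs = np.linspace(0, fs / 2, 128)
    freqs = np.asarray(freqs, dtype=np.float64)
    Abar = _abar(model, freqs)  # (F, K, K)
    if generalized:
        w = 1.0 / np.sqrt(np.diag(model.sigma))
        num2 = (np.abs(Abar) ** 2) * (w[None, :, None] ** 2)
    else:
        num2 = np.abs(Abar) ** 2
    denom = num2.sum(axis=1, keepdims=True)  # sum over rows k for each column j
    if np.any(denom == 0):
        raise ValueError("zero column norm in the frequency-domain coefficients")
    p2 = num2 / denom
    out = p2 if squared else np.sqrt(p2)
    return np.transpose(out, (1, 2, 0))
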