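"""Seeded synthetic-signal generators for every test scenario.

Each generator is a pure function of its parameters (the seed fully
determines the output) and returns the ground truth alongside the data:
the true EEG and mixing matrix for the EOG scenario, the true R-peak
positions for the ECG, the true coefficient matrices for MVAR processes,
the true saturation mask for clipped signals, and the class labels for BCI
epochs.  Default parameters live in :data:`SCENARIO_DEFAULTS` so every
test and script cites a single source.

Generator parameters are logged into the produced recording as a JSON TLV
block (tag 255), so a fixture file documents how it was made.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy import signal as sps

from .gdf_io import (
    ChannelSpec,
    EventTable,
    FixedHeader,
    SignalRecording,
    TlvBlock,
)
from .mvar import MvarModel
from .preprocessing import EpochSet

__all__ = [
    "SCENARIO_DEFAULTS",
    "FixtureSpec",
    "EegEogMixture",
    "EcgFixture",
    "MvarFixture",
    "make_eeg_eog_mixture",
    "make_synth_ecg",
    "make_mvar_process",
    "make_classed_epochs",
    "make_bci_recording",
    "make_clipped_signal",
    "write_minimal_edf",
    "make_recording",
]

PARAMS_TLV_TAG = 255

# Central scenario defaults: the conditions every test and script uses.
SCENARIO_DEFAULTS: dict[str, dict[str, Any]] = {
    "eeg_eog": {
        "seed": 2011,
        "n_samples": 100_000,
        "sampling_rate": 125.0,
        # EOG→EEG propagation: 2 EEG channels, 2 bipolar EOG regressors.
        # With unit-variance EOG in the active segment this puts the
        # artifact variance at ≈4.25× the (unit) EEG variance per channel.
        "b0": ((2.0, 0.5), (1.9, -0.8)),
        "quiet_gain": 0.1,  # EOG amplitude in the quiet half
    },
    "ecg": {
        "seed": 7,
        "bpm": 60.0,
        "duration": 60.0,
        "sampling_rate": 256.0,
        "qrs_width_s": 0.04,  # full width of the Gaussian QRS complex (±2σ)
    },
    "ecg_modulated": {
        # mirrors an alternating-task protocol: mean 63 bpm with a ±4 bpm
        # event-locked oscillation
        "bpm": 63.0,
        "amplitude_bpm": 4.0,
        "period_s": 30.0,
        "duration": 600.0,
    },
    "mvar": {
        "seed": 42,
        "n_samples": 10_000,
        "sampling_rate": 128.0,
    },
    "bci": {
        "seed": 9,
        "n_per_class": 30,
        "sampling_rate": 128.0,
        "epoch_s": 1.0,
        "amplitudes": (1.0, 2.0),  # 10 Hz amplitude per class
        "class_codes": (769, 770),
    },
}

# Named MVAR scenarios: element [i, j] of a lag matrix is the influence of
# channel j on channel i.  Each channel carries an oscillatory AR(2)
# (a1=0.5, a2=−0.6, pole radius √0.6 ≈ 0.77).
_AR2 = (0.5, -0.6)
MVAR_SCENARIOS: dict[str, list[np.ndarray]] = {
    "independent": [
        np.diag([_AR2[0]] * 3),
        np.diag([_AR2[1]] * 3),
    ],
    "unidirectional": [  # 1 drives 2, no feedback
        np.array([[0.5, 0.0], [0.6, 0.5]]),
        np.array([[-0.6, 0.0], [0.0, -0.6]]),
    ],
    "chain": [  # 1 → 2 → 3, coupling only through 2
        np.array([[0.5, 0.0, 0.0], [0.6, 0.5, 0.0], [0.0, 0.6, 0.5]]),
        np.diag([_AR2[1]] * 3),
    ],
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameter record of one generated fixture; the seed fully determines it."""

    seed: int
    duration: float
    sampling_rate: float
    params: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "duration": self.duration,
                "sampling_rate": self.sampling_rate,
                **{k: _jsonable(v) for k, v in self.params.items()},
            }
        )


def _jsonable(v: Any) -> Any:
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def make_recording(
    data: np.ndarray,
    fs: float,
    labels: list[str] | None = None,
    events: EventTable | None = None,
    spec: FixtureSpec | None = None,
    sample_type: str = "float32",
) -> SignalRecording:
    """Wrap a (channels, samples) array into a SignalRecording.

    Float32 channels use identity calibration (gain 1, offset 0) and the
    data is pre-rounded to float32 precision so a write/read cycle is
    bit-exact.  Record length is one second where possible.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n_ch, n_samp = data.shape
    spr = int(fs) if n_samp % int(fs) == 0 else 1
    channels = []
    for i in range(n_ch):
        if sample_type == "float32":
            ch = ChannelSpec(
                label=labels[i] if labels else f"ch{i}",
                physical_min=-32768.0, physical_max=32767.0,
                digital_min=-32768, digital_max=32767,
                sample_type="float32", samples_per_record=spr,
            )
        else:
            lo = float(np.min(data[i], initial=-1.0)) - 1e-9
            hi = float(np.max(data[i], initial=1.0)) + 1e-9
            ch = ChannelSpec(
                label=labels[i] if labels else f"ch{i}",
                physical_min=lo, physical_max=hi,
                digital_min=-32768, digital_max=32767,
                sample_type="int16", samples_per_record=spr,
            )
        channels.append(ch)
    if sample_type == "float32":
        data = data.astype(np.float32).astype(np.float64)
    fh = FixedHeader(
        n_channels=n_ch,
        n_records=n_samp // spr,
        samples_per_record=spr,
        sampling_rate=fs,
    )
    tlv = [TlvBlock(tag=PARAMS_TLV_TAG, value=spec.to_json().encode())] if spec else []
    rec = SignalRecording(
        fixed_header=fh,
        channels=channels,
        data=[data[i] for i in range(n_ch)],
        events=events if events is not None else EventTable(),
        tlv_blocks=tlv,
    )
    rec.validate()
    return rec


def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   band: tuple[float, float]) -> np.ndarray:
    """Band-limited unit-variance noise via a 2nd-order Butterworth band-pass."""
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


# ---------------------------------------------------------------------------
# EEG + EOG linear mixture


@dataclass
class EegEogMixture:
    recording: SignalRecording  # channels: EEG…, EOG…
    E: np.ndarray  # true EEG (N, T)
    O: np.ndarray  # observed EOG (M, T)
    Y: np.ndarray  # contaminated EEG (N, T)
    b0: np.ndarray  # true propagation matrix (N, M)
    active: slice  # sample range with large ocular activity
    sampling_rate: float


def make_eeg_eog_mixture(
    seed: int | None = None,
    n_samples: int | None = None,
    sampling_rate: float | None = None,
    b0: np.ndarray | None = None,
    quiet_gain: float | None = None,
) -> EegEogMixture:
    """Realize the linear superposition model Y = E + b0·O.

    E is band-limited (1–30 Hz) colored noise with unit variance; O holds
    low-frequency (<5 Hz) high-amplitude waveforms, statistically
    independent of E, quiet in the first half of the record and active
    (unit variance) in the second half.  The default propagation matrix
    puts ≈4× the EEG variance of artifact on each frontal channel during
    the active segment.
    """
    d = SCENARIO_DEFAULTS["eeg_eog"]
    seed = d["seed"] if seed is None else seed
    n_samples = d["n_samples"] if n_samples is None else n_samples
    fs = d["sampling_rate"] if sampling_rate is None else sampling_rate
    b0 = np.asarray(d["b0"] if b0 is None else b0, dtype=np.float64)
    quiet_gain = d["quiet_gain"] if quiet_gain is None else quiet_gain
    N, M = b0.shape

    rng = np.random.default_rng(seed)
    E = np.vstack([_colored_noise(rng, n_samples, fs, (1.0, 30.0)) for _ in range(N)])
    half = n_samples // 2
    O = np.empty((M, n_samples))
    sos = sps.butter(2, 5.0, btype="lowpass", fs=fs, output="sos")
    for m in range(M):
        raw = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
        raw = raw / raw[half:].std()  # unit variance in the active segment
        raw[:half] *= quiet_gain
        O[m] = raw
    Y = E + b0 @ O

    spec = FixtureSpec(seed=seed, duration=n_samples / fs, sampling_rate=fs,
                       params={"b0": b0, "quiet_gain": quiet_gain})
    labels = [f"EEG{i + 1}" for i in range(N)] + [f"EOG{m + 1}" for m in range(M)]
    rec = make_recording(np.vstack([Y, O]), fs, labels=labels, spec=spec)
    return EegEogMixture(
        recording=rec, E=E, O=O, Y=Y, b0=b0,
        active=slice(half, n_samples), sampling_rate=fs,
    )


# ---------------------------------------------------------------------------
# Synthetic ECG


@dataclass
class EcgFixture:
    recording: SignalRecording
    ecg: np.ndarray
    true_peaks: np.ndarray  # sample indices
    sampling_rate: float
    events: EventTable  # task onsets for the modulated scenario (may be empty)


def make_synth_ecg(
    seed: int | None = None,
    bpm: float | None = None,
    duration: float | None = None,
    sampling_rate: float | None = None,
    rr_jitter_s: float = 0.0,
    noise_snr_db: float | None = None,
    modulation: dict[str, float] | None = None,
) -> EcgFixture:
    """Impulse-train ECG: Gaussian QRS complexes (~40 ms wide) at scripted
    RR intervals, optional additive white noise at a given SNR, and an
    optional event-locked sinusoidal heart-rate modulation.

    ``modulation``: dict with amplitude_bpm and period_s; beat times then
    follow the instantaneous rate r(t) = bpm + A·sin(2πt/P), and task-onset
    events (code 1) are placed at t = 0, P, 2P, …  Noise changes the signal
    only — the true peak list is bookkeeping and stays exact.
    """
    d = SCENARIO_DEFAULTS["ecg"]
    seed = d["seed"] if seed is None else seed
    bpm = d["bpm"] if bpm is None else bpm
    duration = d["duration"] if duration is None else duration
    fs = d["sampling_rate"] if sampling_rate is None else sampling_rate
    if not 30 <= bpm <= 240:
        raise ValueError("bpm must lie in [30, 240]")
    rng = np.random.default_rng(seed)

    if modulation is None:
        rr = 60.0 / bpm
        # first beat at rr/2 so a whole-minute record at 60 bpm holds exactly 60 beats
        beats = np.arange(rr / 2, duration - 0.3, rr)
        if rr_jitter_s > 0:
            beats = beats + rng.normal(0, rr_jitter_s, size=len(beats))
            beats = np.sort(beats)
        event_positions = np.empty(0, dtype=np.int64)
    else:
        A, P = modulation["amplitude_bpm"], modulation["period_s"]
        t = np.arange(0, duration, 1.0 / fs)
        rate = bpm + A * np.sin(2 * np.pi * t / P)  # beats/min
        phase = np.cumsum(rate / 60.0) / fs  # beats elapsed
        n_beats = int(np.floor(phase[-1]))
        beats = np.interp(np.arange(1, n_beats + 1), phase, t)
        beats = beats[beats < duration - 0.5]
        event_positions = (np.arange(0, duration - P / 2, P) * fs).astype(np.int64)

    sigma = d["qrs_width_s"] / 4.0  # ±2σ spans the QRS width
    t = np.arange(0, duration, 1.0 / fs)
    ecg = np.zeros_like(t)
    for tb in beats:
        lo = max(0, int((tb - 5 * sigma) * fs))
        hi = min(len(t), int((tb + 5 * sigma) * fs) + 1)
        ecg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tb) / sigma) ** 2)
    if noise_snr_db is not None:
        snr = 10 ** (noise_snr_db / 10)
        noise_var = ecg.var() / snr
        ecg = ecg + rng.normal(0, np.sqrt(noise_var), size=len(ecg))

    events = EventTable(
        positions=event_positions, codes=np.ones(len(event_positions), dtype=np.uint16)
    )
    spec = FixtureSpec(
        seed=seed, duration=duration, sampling_rate=fs,
        params={"bpm": bpm, "rr_jitter_s": rr_jitter_s, "noise_snr_db": noise_snr_db,
                "modulation": modulation},
    )
    rec = make_recording(ecg[None, :], fs, labels=["ECG"], events=events, spec=spec)
    true_peaks = np.round(beats * fs).astype(np.int64)
    return EcgFixture(recording=rec, ecg=ecg, true_peaks=true_peaks,
                      sampling_rate=fs, events=events)


# ---------------------------------------------------------------------------
# MVAR processes


@dataclass
class MvarFixture:
    data: np.ndarray  # (K, T)
    model: MvarModel | None  # true generating model (None for mixed-source data)
    sampling_rate: float
    info: dict[str, Any] = field(default_factory=dict)


def simulate_mvar(
    model: MvarModel, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Iterate x(t) = Σ A_k x(t−k) + e(t) with standard-normal innovations
    shaped by the model's innovation covariance; a burn-in of 10·p·K
    samples is discarded.  Unstable models are rejected.
    """
    if not model.is_stable():
        raise ValueError(
            f"unstable model: companion spectral radius "
            f"{model.companion_spectral_radius():.3f} >= 1"
        )
    K, p = model.n_channels, model.order
    burn = 10 * p * K
    total = n_samples + burn
    chol = np.linalg.cholesky(model.sigma + 1e-15 * np.eye(K))
    e = rng.standard_normal((total, K)) @ chol.T
    x = np.zeros((total, K))
    for t in range(p, total):
        acc = e[t].copy()
        for k, Ak in enumerate(model.A, start=1):
            acc += Ak @ x[t - k]
        x[t] = acc
    return x[burn:].T


def make_mvar_process(
    seed: int | None = None,
    scenario: str = "chain",
    n_samples: int | None = None,
    sampling_rate: float | None = None,
    A: list[np.ndarray] | None = None,
    sigma: np.ndarray | None = None,
) -> MvarFixture:
    """Simulate a named MVAR scenario or user-supplied coefficients.

    Scenarios: 'independent' (3 uncoupled channels), 'unidirectional'
    (1 drives 2), 'chain' (1 → 2 → 3), 'zero_lag_mixed' (two observed
    channels formed by instantaneous mixing of two independent sources —
    a pure volume-conduction construction with no lagged coupling).
    """
    d = SCENARIO_DEFAULTS["mvar"]
    seed = d["seed"] if seed is None else seed
    n_samples = d["n_samples"] if n_samples is None else n_samples
    fs = d["sampling_rate"] if sampling_rate is None else sampling_rate
    rng = np.random.default_rng(seed)

    if scenario == "zero_lag_mixed" and A is None:
        src_model = MvarModel(
            A=MVAR_SCENARIOS["independent"][0:1] + MVAR_SCENARIOS["independent"][1:2],
            sigma=np.eye(3), sampling_rate=fs,
        )
        # use only two sources
        src_model = MvarModel(
            A=[a[:2, :2] for a in src_model.A], sigma=np.eye(2), sampling_rate=fs
        )
        sources = simulate_mvar(src_model, n_samples, rng)
        W = np.array([[1.0, 0.6], [0.6, 1.0]])
        return MvarFixture(
            data=W @ sources, model=None, sampling_rate=fs,
            info={"scenario": scenario, "mixing": W, "source_model": src_model},
        )

    if A is None:
        if scenario not in MVAR_SCENARIOS:
            raise ValueError(f"unknown scenario '{scenario}'")
        A = MVAR_SCENARIOS[scenario]
    K = A[0].shape[0]
    model = MvarModel(
        A=list(A),
        sigma=np.eye(K) if sigma is None else np.asarray(sigma, dtype=np.float64),
        sampling_rate=fs,
    )
    data = simulate_mvar(model, n_samples, rng)
    return MvarFixture(data=data, model=model, sampling_rate=fs,
                       info={"scenario": scenario})


# ---------------------------------------------------------------------------
# BCI epochs, clipped signals, minimal EDF


def make_classed_epochs(
    seed: int | None = None,
    n_per_class: int | None = None,
    sampling_rate: float | None = None,
    epoch_s: float | None = None,
    amplitudes: tuple[float, float] | None = None,
    n_channels: int = 2,
) -> tuple[EpochSet, np.ndarray]:
    """Class-structured epochs: unit background noise plus a 10 Hz sinusoid
    whose amplitude depends on the class.  Equal amplitudes give a null
    (label-independent) fixture.  Returns (EpochSet, labels)."""
    d = SCENARIO_DEFAULTS["bci"]
    seed = d["seed"] if seed is None else seed
    n_per_class = d["n_per_class"] if n_per_class is None else n_per_class
    fs = d["sampling_rate"] if sampling_rate is None else sampling_rate
    epoch_s = d["epoch_s"] if epoch_s is None else epoch_s
    amplitudes = d["amplitudes"] if amplitudes is None else amplitudes
    rng = np.random.default_rng(seed)
    n_t = int(round(epoch_s * fs))
    t = np.arange(n_t) / fs
    labels = np.repeat(np.arange(len(amplitudes)), n_per_class)
    labels = rng.permutation(labels)
    data = np.empty((len(labels), n_channels, n_t))
    for e, lab in enumerate(labels):
        phase = rng.uniform(0, 2 * np.pi)
        tone = amplitudes[lab] * np.sin(2 * np.pi * 10.0 * t + phase)
        data[e] = rng.standard_normal((n_channels, n_t)) + tone
    return (
        EpochSet(data=data, pre=0.0, post=epoch_s, sampling_rate=fs,
                 trigger_codes=labels),
        labels,
    )


def make_bci_recording(
    seed: int | None = None,
    n_per_class: int | None = None,
    sampling_rate: float | None = None,
    epoch_s: float | None = None,
    amplitudes: tuple[float, float] | None = None,
    class_codes: tuple[int, int] | None = None,
    n_channels: int = 2,
) -> SignalRecording:
    """Continuous recording with triggered class-dependent 10 Hz activity.

    Trials of ``epoch_s`` seconds alternate with equal rest gaps; each trial
    onset carries its class code in the event table.  Input for the
    benchmark metapipeline.
    """
    d = SCENARIO_DEFAULTS["bci"]
    seed = d["seed"] if seed is None else seed
    n_per_class = d["n_per_class"] if n_per_class is None else n_per_class
    fs = d["sampling_rate"] if sampling_rate is None else sampling_rate
    epoch_s = d["epoch_s"] if epoch_s is None else epoch_s
    amplitudes = d["amplitudes"] if amplitudes is None else amplitudes
    class_codes = d["class_codes"] if class_codes is None else class_codes
    rng = np.random.default_rng(seed)
    n_t = int(round(epoch_s * fs))
    gap = n_t
    labels = rng.permutation(np.repeat(np.arange(len(amplitudes)), n_per_class))
    total = (len(labels) + 1) * (n_t + gap)
    x = rng.standard_normal((n_channels, total))
    t_epoch = np.arange(n_t) / fs
    positions, codes = [], []
    for e, lab in enumerate(labels):
        start = gap + e * (n_t + gap)
        phase = rng.uniform(0, 2 * np.pi)
        x[:, start : start + n_t] += amplitudes[lab] * np.sin(
            2 * np.pi * 10.0 * t_epoch + phase
        )
        positions.append(start)
        codes.append(class_codes[lab])
    events = EventTable(positions=np.asarray(positions), codes=np.asarray(codes))
    spec = FixtureSpec(seed=seed, duration=total / fs, sampling_rate=fs,
                       params={"amplitudes": amplitudes, "class_codes": class_codes})
    return make_recording(x, fs, events=events, spec=spec)


def make_clipped_signal(
    seed: int = 0,
    duration: float = 10.0,
    sampling_rate: float = 128.0,
    amplitude: float = 1.0,
    clip_fraction: float = 0.8,
    frequency: float = 2.0,
    noise_std: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hard-clipped sinusoid and its true saturation mask.

    The raw signal is amplitude·sin(2πft) (+ optional noise); values beyond
    ±clip_fraction·amplitude are clipped to that level and marked True in
    the mask.  For a noiseless sine the saturated fraction is analytically
    2·arccos(clip_fraction)/π.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0, duration, 1.0 / sampling_rate)
    raw = amplitude * np.sin(2 * np.pi * frequency * t)
    if noise_std > 0:
        raw = raw + rng.normal(0, noise_std, size=len(t))
    level = clip_fraction * amplitude
    mask = np.abs(raw) >= level
    clipped = np.clip(raw, -level, level)
    return clipped, mask


def write_minimal_edf(
    path: str | Path,
    signals: list[np.ndarray],
    samples_per_record: list[int],
    record_duration: float = 1.0,
    physical_ranges: list[tuple[float, float]] | None = None,
    labels: list[str] | None = None,
) -> None:
    """Write a standard-conforming minimal EDF file (16-bit, little-endian).

    ``signals`` hold physical values; each channel i contributes
    ``samples_per_record[i]`` samples per record, so channels may have
    different rates.  Values are quantized onto the channel's digital range
    [-32768, 32767].
    """
    ns = len(signals)
    n_records_set = {len(s) // spr for s, spr in zip(signals, samples_per_record)}
    if len(n_records_set) != 1:
        raise ValueError("all channels must span the same number of records")
    n_records = n_records_set.pop()
    for s, spr in zip(signals, samples_per_record):
        if len(s) != n_records * spr:
            raise ValueError("signal length must equal n_records × samples_per_record")

    if physical_ranges is None:
        physical_ranges = []
        for s in signals:
            lo, hi = float(np.min(s)), float(np.max(s))
            if lo == hi:
                lo, hi = lo - 1.0, hi + 1.0
            physical_ranges.append((lo, hi))
    labels = labels or [f"ch{i}" for i in range(ns)]

    def f(text: str, width: int) -> bytes:
        raw = text.encode("ascii")
        if len(raw) > width:
            raise ValueError(f"EDF field too long: '{text}'")
        return raw.ljust(width)

    header_bytes = 256 + 256 * ns
    head = b"".join([
        f("0", 8),
        f("X X X X", 80),
        f("Startdate X synthetic fixture", 80),
        f("01.01.00", 8),
        f("00.00.00", 8),
        f(str(header_bytes), 8),
        f("", 44),
        f(str(n_records), 8),
        f(_fmt_num(record_duration), 8),
        f(str(ns), 4),
    ])
    cols = [
        b"".join(f(labels[i], 16) for i in range(ns)),
        b"".join(f("", 80) for _ in range(ns)),
        b"".join(f("uV", 8) for _ in range(ns)),
        b"".join(f(_fmt_num(physical_ranges[i][0]), 8) for i in range(ns)),
        b"".join(f(_fmt_num(physical_ranges[i][1]), 8) for i in range(ns)),
        b"".join(f("-32768", 8) for _ in range(ns)),
        b"".join(f("32767", 8) for _ in range(ns)),
        b"".join(f("", 80) for _ in range(ns)),
        b"".join(f(str(samples_per_record[i]), 8) for i in range(ns)),
        b"".join(f("", 32) for _ in range(ns)),
    ]
    digital = []
    for s, (lo, hi) in zip(signals, physical_ranges):
        gain = (hi - lo) / 65535.0
        dig = np.rint((np.asarray(s, dtype=np.float64) - lo) / gain) - 32768
        digital.append(np.clip(dig, -32768, 32767).astype("<i2"))

    with open(path, "wb") as out:
        out.write(head)
        out.write(b"".join(cols))
        for rec in range(n_records):
            for dig, spr in zip(digital, samples_per_record):
                out.write(dig[rec * spr : (rec + 1) * spr].tobytes())


def _fmt_num(v: float) -> str:
    """Format a number into <= 8 ASCII chars as EDF requires."""
    if v == int(v) and abs(v) < 1e7:
        return str(int(v))
    s = f"{v:.6g}"
    if len(s) > 8:
        s = f"{v:.2e}"
    return s[:8]
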