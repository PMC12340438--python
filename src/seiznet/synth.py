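"""Seedable synthetic EEG with a class-dependent spectral signature.

Non-seizure segments are pink (1/f^beta) noise plus weak background rhythms.
Seizure segments add two features the network is built to exploit: band-
limited oscillatory bursts (slow spike-wave-like activity in a configurable
band, 3-8 Hz by default) and sparse high-amplitude biphasic spike transients.
Burst amplitude is ``snr`` times the background standard deviation, so class
separability is a single dial.

The generator emulates the *statistical* structure of ictal vs interictal
EEG — class-dependent band power and transients over a 1/f background — not
physiologically forward-modelled EEG; see docs/methods.md for what that does
and does not validate.

Labels are allocated exactly (``round(prevalence * n)`` positives), and the
manifest (config + seed) regenerates a dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "SynthConfig",
    "LabeledDataset",
    "generate_background",
    "generate_seizure",
    "make_dataset",
    "band_power",
    "band_power_classifier",
    "save_dataset",
]


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the study geometry (1228-sample
    segments at 256 Hz, ~9.8% seizure prevalence)."""

    n_samples: int = 1000
    segment_length: int = 1228
    sampling_rate: float = 256.0
    prevalence: float = 711 / 7280
    spectral_exponent: float = 1.0                     # 1/f^beta background
    rhythms: list[tuple[float, float]] = field(
        default_factory=lambda: [(10.0, 0.3)])         # (centre Hz, amplitude)
    band_lo_hz: float = 3.0
    band_hi_hz: float = 8.0
    burst_rate: float = 3.0                            # expected bursts/segment
    spike_amplitude: float = 4.0                       # x background sd
    spike_rate: float = 4.0                            # expected spikes/segment
    snr: float = 4.0                                   # burst amp / background sd
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2")
        nyquist = self.sampling_rate / 2
        if not 0 < self.band_lo_hz < self.band_hi_hz <= nyquist:
            raise ValueError(
                f"seizure band ({self.band_lo_hz}, {self.band_hi_hz}) Hz must "
                f"sit inside (0, {nyquist}] Hz"
            )
        for freq, _amp in self.rhythms:
            if freq > nyquist:
                raise ValueError(f"rhythm at {freq} Hz is above Nyquist {nyquist} Hz")

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["rhythms"] = [list(r) for r in d["rhythms"]]
        return d

    @classmethod
    def from_manifest(cls, manifest: dict) -> "SynthConfig":
        d = dict(manifest)
        d["rhythms"] = [tuple(r) for r in d.get("rhythms", [])]
        return cls(**d)


@dataclass
class LabeledDataset:
    segments: np.ndarray   # (n, L)
    labels: np.ndarray     # (n,), 1 = seizure
    manifest: dict

    @property
    def n(self) -> int:
        return self.segments.shape[0]


def _rng(seed: int, stream: int) -> np.random.Generator:
    # separate deterministic streams so a null seizure signature reproduces
    # the background arrays exactly under the same seed
    return np.random.default_rng([int(seed), int(stream)])


def generate_background(n: int, cfg: SynthConfig, seed: int | None = None) -> np.ndarray:
    """Pink-noise segments with background rhythms, zero mean, unit-ish sd."""
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, 0)
    L, fs = cfg.segment_length, cfg.sampling_rate
    white = rng.standard_normal((n, L))
    spectrum = np.fft.rfft(white, axis=-1)
    k = np.arange(spectrum.shape[-1], dtype=float)
    k[0] = 1.0  # DC untouched; removed below anyway
    spectrum *= k ** (-cfg.spectral_exponent / 2.0)
    x = np.fft.irfft(spectrum, n=L, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    t = np.arange(L) / fs
    for freq, amp in cfg.rhythms:
        phase = rng.uniform(0, 2 * np.pi, size=(n, 1))
        jitter = rng.uniform(0.5, 1.5, size=(n, 1))
        x += amp * jitter * np.sin(2 * np.pi * freq * t[None, :] + phase)
    x -= x.mean(axis=-1, keepdims=True)
    return x


def _hann_burst(L: int, fs: float, centre: int, width: int, freq: float,
                phase: float) -> np.ndarray:
    lo = max(centre - width // 2, 0)
    hi = min(centre + width // 2, L)
    burst = np.zeros(L)
    t = np.arange(hi - lo) / fs
    burst[lo:hi] = np.hanning(hi - lo) * np.sin(2 * np.pi * freq * t + phase)
    return burst


def _biphasic_spike(L: int, fs: float, centre: int) -> np.ndarray:
    """Derivative-of-Gaussian transient, ~40 ms support."""
    sigma = 0.01 * fs  # 10 ms in samples
    idx = np.arange(L, dtype=float)
    z = (idx - centre) / sigma
    spike = -z * np.exp(-0.5 * z * z)
    peak = np.abs(spike).max()
    return spike / peak if peak > 0 else spike


def generate_seizure(n: int, cfg: SynthConfig, seed: int | None = None) -> np.ndarray:
    """Background plus in-band oscillatory bursts and sparse spike transients."""
    seed = cfg.seed if seed is None else seed
    x = generate_background(n, cfg, seed=seed)
    rng = _rng(seed, 1)
    L, fs = cfg.segment_length, cfg.sampling_rate
    sd = x.std(axis=-1)
    min_width = max(int(0.3 * fs / cfg.band_lo_hz), 4)     # >= ~1 cycles-ish
    max_width = max(int(2.0 * fs / cfg.band_lo_hz), min_width + 1)
    modified = False  # a null signature must reproduce the background bitwise
    for i in range(n):
        for _ in range(rng.poisson(cfg.burst_rate)):
            centre = rng.integers(0, L)
            width = int(rng.integers(min_width, max_width))
            freq = rng.uniform(cfg.band_lo_hz, cfg.band_hi_hz)
            phase = rng.uniform(0, 2 * np.pi)
            if cfg.snr != 0.0:
                x[i] += cfg.snr * sd[i] * _hann_burst(L, fs, centre, width, freq, phase)
                modified = True
        for _ in range(rng.poisson(cfg.spike_rate)):
            centre = int(rng.integers(0, L))
            polarity = 1.0 if rng.uniform() < 0.5 else -1.0
            if cfg.spike_amplitude != 0.0:
                x[i] += polarity * cfg.spike_amplitude * sd[i] * _biphasic_spike(L, fs, centre)
                modified = True
    if modified:
        x -= x.mean(axis=-1, keepdims=True)
    return x


def make_dataset(cfg: SynthConfig) -> LabeledDataset:
    """Shuffled labelled mix with exact positive-count allocation."""
    n = cfg.n_samples
    n_pos = int(round(cfg.prevalence * n))
    if n_pos < 1:
        raise ValueError(
            f"prevalence {cfg.prevalence} yields no positive samples at n={n}"
        )
    n_neg = n - n_pos
    pos = generate_seizure(n_pos, cfg, seed=cfg.seed)
    neg = generate_background(n_neg, cfg, seed=cfg.seed + 1)
    segments = np.concatenate([neg, pos], axis=0)
    labels = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    order = _rng(cfg.seed, 2).permutation(n)
    return LabeledDataset(segments=segments[order], labels=labels[order],
                          manifest=cfg.to_manifest())


# -- spectral utilities ------------------------------------------------------

def band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Per-segment Welch power inside [lo, hi] Hz."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    nperseg = min(x.shape[-1], 256)
    freqs, psd = sp_signal.welch(x, fs=fs, nperseg=nperseg, axis=-1)
    band = (freqs >= lo) & (freqs <= hi)
    return np.trapezoid(psd[..., band], freqs[band], axis=-1)


def band_power_classifier(train_x: np.ndarray, train_y: np.ndarray,
                          test_x: np.ndarray, fs: float,
                          lo: float, hi: float) -> np.ndarray:
    """Threshold on seizure-band power (midpoint of class log-power means).

    A deliberately trivial reference classifier: if it scores well, the
    generated benchmark is learnable and model failures are model bugs.
    """
    p_train = np.log(band_power(train_x, fs, lo, hi))
    mu_pos = p_train[train_y == 1].mean()
    mu_neg = p_train[train_y == 0].mean()
    threshold = 0.5 * (mu_pos + mu_neg)
    p_test = np.log(band_power(test_x, fs, lo, hi))
    above = p_test > threshold
    return (above if mu_pos > mu_neg else ~above).astype(int)


# -- persistence -------------------------------------------------------------

def save_dataset(ds: LabeledDataset, path, manifest_path=None) -> None:
    """NPZ with arrays ``segments`` and ``labels`` plus a JSON manifest."""
    np.savez(path, segments=ds.segments, labels=ds.labels,
             manifest_json=np.array(json.dumps(ds.manifest)))
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(ds.manifest, fh, indent=2)
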