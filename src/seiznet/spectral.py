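"""Dynamic frequency selection (DFS): learnable spectral masking of EEG.

Each fixed-length segment is taken to the frequency domain with a one-sided
real FFT, its amplitude spectrum is scored by a small two-layer perceptron,
the scores are turned into a probabilistic per-bin mask with the
Gumbel-SoftMax relaxation, the mask multiplies the complex coefficients, and
the inverse transform returns a filtered time-domain signal of the original
length.  Because every step is differentiable, training can discover which
frequency bands carry the seizure signature; the learned mask doubles as an
interpretability read-out (see :func:`export_mask_csv`).

Conventions
-----------
* one-sided spectrum, ``N = L // 2 + 1`` unique bins; bin ``k`` is
  ``k * fs / L`` Hz,
* the mask is a softmax over bins, so each row sums to 1 — with N bins this
  attenuates total energy roughly N-fold.  Downstream affine layers absorb
  the scale; ``mask_gain=True`` multiplies the mask by N for numerical
  comfort without changing its shape,
* Gumbel noise makes the selection stochastic during training; at inference
  the noise is dropped (plain softmax of the scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, irfft_pair, rfft_pair, softmax

__all__ = [
    "EEGBatch",
    "SpectralState",
    "DFSParams",
    "rfft_forward",
    "amplitude_spectrum",
    "score_frequencies",
    "sample_gumbel",
    "gumbel_softmax_weights",
    "spectral_filter",
    "dfs_forward",
    "export_mask_csv",
]

DEFAULT_SAMPLING_RATE = 256.0


@dataclass
class EEGBatch:
    """A batch of fixed-length single-channel EEG segments."""

    data: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 1:
            self.data = self.data[None, :]
        if self.data.ndim != 2:
            raise ValueError(f"expected (batch, length) data, got shape {self.data.shape}")
        if self.data.shape[1] < 2:
            raise ValueError("segment length must be >= 2")
        if not np.isfinite(self.data).all():
            raise ValueError("EEG data contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.data.shape[0],):
                raise ValueError("labels must be a vector of length batch")
            if not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be binary (0/1)")

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def segment_length(self) -> int:
        return self.data.shape[1]


@dataclass
class SpectralState:
    """Intermediate quantities of one DFS pass, kept for interpretability."""

    coefficients: np.ndarray  # complex (B, N)
    amplitude: np.ndarray     # (B, N)
    logits: np.ndarray        # (B, N)
    mask: np.ndarray          # (B, N), rows sum to 1
    n_bins: int


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


@dataclass
class DFSParams:
    """Parameters of the frequency scorer MLP plus the softmax temperature."""

    W1: Tensor  # (H_hidden, N)
    b1: Tensor  # (H_hidden,)
    W2: Tensor  # (N, H_hidden)
    b2: Tensor  # (N,)
    temperature: float = 1.0
    hidden_dim: int = 64

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @classmethod
    def init(cls, n_bins: int, hidden_dim: int = 64, temperature: float = 1.0,
             rng: np.random.Generator | None = None) -> "DFSParams":
        rng = rng or np.random.default_rng()
        # The scorer sees raw amplitude spectra, whose scale is data-dependent
        # and can be large; a near-zero output layer keeps the initial logits
        # close to 0 so the mask starts near-uniform instead of saturating
        # the softmax at an arbitrary bin (which would stall its gradients).
        return cls(
            W1=Tensor(_he_init(rng, n_bins, (hidden_dim, n_bins)), requires_grad=True, name="dfs.W1"),
            b1=Tensor(np.zeros(hidden_dim), requires_grad=True, name="dfs.b1"),
            W2=Tensor(1e-3 * _he_init(rng, hidden_dim, (n_bins, hidden_dim)), requires_grad=True, name="dfs.W2"),
            b2=Tensor(np.zeros(n_bins), requires_grad=True, name="dfs.b2"),
            temperature=temperature,
            hidden_dim=hidden_dim,
        )

    def tensors(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    @property
    def n_bins(self) -> int:
        return self.W2.shape[0]


# -- individual operations (array-level contracts) ---------------------------

def rfft_forward(x: EEGBatch | np.ndarray) -> np.ndarray:
    """One-sided spectrum of each segment: (B, L) -> complex (B, N)."""
    data = x.data if isinstance(x, EEGBatch) else np.asarray(x, dtype=np.float64)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[-1] < 2:
        raise ValueError("segment length must be >= 2")
    if not np.isfinite(data).all():
        raise ValueError("input contains non-finite values")
    return np.fft.rfft(data, axis=-1)


def amplitude_spectrum(F: np.ndarray) -> np.ndarray:
    """Elementwise modulus of the complex spectrum."""
    return np.abs(F)


def _score_t(A: Tensor, p: DFSParams) -> Tensor:
    """S = W2 . ReLU(W1 . A + b1) + b2, applied to each batch row."""
    hidden = (A @ p.W1.swapaxes(0, 1) + p.b1).relu()
    return hidden @ p.W2.swapaxes(0, 1) + p.b2


def score_frequencies(A: np.ndarray, p: DFSParams) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    if A.shape[-1] != p.W1.shape[1]:
        raise ValueError(
            f"amplitude has {A.shape[-1]} bins but scorer expects {p.W1.shape[1]}"
        )
    return _score_t(as_tensor(A), p).data


def sample_gumbel(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Gumbel(0,1) samples via -log(-log(U)), U ~ Uniform(0,1)."""
    u = rng.uniform(low=np.finfo(float).tiny, high=1.0, size=shape)
    return -np.log(-np.log(u))


def _gumbel_softmax_t(S: Tensor, tau: float, noise: np.ndarray | float) -> Tensor:
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    if isinstance(noise, np.ndarray):
        noise = noise.astype(S.data.dtype, copy=False)
    return softmax((S + noise) * (1.0 / tau), axis=-1)


def gumbel_softmax_weights(S: np.ndarray, tau: float,
                           rng_seed: int | None = None,
                           fixed_noise: np.ndarray | None = None,
                           shared_noise: bool = False) -> np.ndarray:
    """Probabilistic frequency weights w = softmax((S + g)/tau), rows sum to 1.

    ``fixed_noise`` overrides sampling (use 0 for the noise-free softmax);
    ``shared_noise`` draws one noise vector per frequency bin, shared across
    the batch, matching the reading in which the noise is indexed by
    frequency only.
    """
    S = np.asarray(S, dtype=np.float64)
    if fixed_noise is not None:
        g = np.asarray(fixed_noise, dtype=np.float64)
    elif rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        shape = S.shape[-1:] if shared_noise else S.shape
        g = sample_gumbel(shape, rng)
    else:
        g = 0.0
    return _gumbel_softmax_t(as_tensor(S), tau, g).data


def spectral_filter(F: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Elementwise spectral mask: real nonnegative W preserves phase."""
    F = np.asarray(F)
    W = np.asarray(W, dtype=np.float64)
    if F.shape != W.shape:
        raise ValueError(f"shape mismatch: spectrum {F.shape} vs mask {W.shape}")
    return F * W


# -- full differentiable pass ------------------------------------------------

_AMP_EPS = 1e-12  # keeps d|F|/dF finite at exact zeros


def dfs_forward_t(x: Tensor, p: DFSParams, noise: np.ndarray | float = 0.0,
                  mask_gain: bool = False, hard: bool = False
                  ) -> tuple[Tensor, SpectralState]:
    """Differentiable DFS pass on a tensor batch (B, L)."""
    L = x.shape[-1]
    spec = rfft_pair(x)              # (2, B, N)
    Fr, Fi = spec[0], spec[1]
    A = (Fr * Fr + Fi * Fi + _AMP_EPS).sqrt()
    S = _score_t(A, p)
    W = _gumbel_softmax_t(S, p.temperature, noise)
    if hard:
        onehot = np.zeros_like(W.data)
        onehot[np.arange(W.shape[0]), W.data.argmax(axis=-1)] = 1.0
        W = W + as_tensor(onehot - W.data)  # straight-through estimator
    W_used = W * float(p.n_bins) if mask_gain else W
    filtered = irfft_pair(Fr * W_used, Fi * W_used, n=L)
    state = SpectralState(
        coefficients=Fr.data + 1j * Fi.data,
        amplitude=A.data.copy(),
        logits=S.data.copy(),
        mask=W.data.copy(),
        n_bins=W.shape[-1],
    )
    return filtered, state


def dfs_forward(x: EEGBatch | np.ndarray, p: DFSParams,
                rng_seed: int | None = None,
                fixed_noise: np.ndarray | None = None,
                shared_noise: bool = False,
                mask_gain: bool = False,
                hard: bool = False) -> tuple[np.ndarray, SpectralState]:
    """Filter a batch through the DFS stage; returns (filtered B x L, state).

    With ``rng_seed=None`` and no ``fixed_noise`` the pass is deterministic
    (noise-free softmax), the inference-time convention.
    """
    data = x.data if isinstance(x, EEGBatch) else np.asarray(x, dtype=np.float64)
    if data.ndim == 1:
        data = data[None, :]
    if not np.isfinite(data).all():
        raise ValueError("input contains non-finite values")
    if fixed_noise is not None:
        g: np.ndarray | float = np.asarray(fixed_noise, dtype=np.float64)
    elif rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        n_bins = data.shape[-1] // 2 + 1
        shape = (n_bins,) if shared_noise else (data.shape[0], n_bins)
        g = sample_gumbel(shape, rng)
    else:
        g = 0.0
    filtered, state = dfs_forward_t(as_tensor(data), p, noise=g,
                                    mask_gain=mask_gain, hard=hard)
    return filtered.data, state


def export_mask_csv(masks: np.ndarray, sampling_rate: float, segment_length: int,
                    path) -> None:
    """Write the dataset-mean mask as (bin_index, frequency_hz, mean_weight)."""
    import pandas as pd

    masks = np.atleast_2d(np.asarray(masks, dtype=np.float64))
    mean_w = masks.mean(axis=0)
    bins = np.arange(mean_w.size)
    pd.DataFrame({
        "bin_index": bins,
        "frequency_hz": bins * sampling_rate / segment_length,
        "mean_weight": mean_w,
    }).to_csv(path, index=False)
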