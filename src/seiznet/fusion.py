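"""Key-waveform attention, phase-aware gating, and the classification head.

The filtered signal is scanned with a hybrid matched filter — a convex mix of
a learnable template and a fixed centre impulse, softmax-normalised to unit
mass — whose similarity profile, softmaxed over time, re-weights the signal
("key-waveform attention").  The enhanced signal is pooled and embedded to
each attention scale, a small tanh network estimates a signed phase offset
between the attended features and the aligned enhanced signal at every
timestep, and a sigmoid of that offset convexly blends the two streams.
Per-scale fused features are mean-pooled over time, concatenated, and mapped
to class probabilities.

The "phase" here is a learned scalar discrepancy, not an analytic
(Hilbert-transform) instantaneous phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, concat, correlate1d_replicate, softmax
from .multiscale import avg_pool_t, scale_embed_t

__all__ = [
    "WaveformKernel",
    "PhaseNetParams",
    "FusionState",
    "impulse_kernel",
    "hybrid_kernel",
    "waveform_similarity",
    "waveform_attention",
    "align_to_scale",
    "phase_difference",
    "phase_gate_fuse",
    "classify",
]


def impulse_kernel(k: int) -> np.ndarray:
    """Fixed impulse: 1 at the centre index k//2, 0 elsewhere."""
    K0 = np.zeros(k)
    K0[k // 2] = 1.0
    return K0


@dataclass
class WaveformKernel:
    """Hybrid matched-filter kernel: learnable base + fixed centre impulse."""

    base: Tensor          # (k,), trainable template
    alpha: Tensor         # scalar mix in [0,1] (stored unconstrained, clamped at use)
    impulse: np.ndarray   # (k,), fixed

    @classmethod
    def init(cls, k: int = 15, alpha_init: float = 0.5,
             rng: np.random.Generator | None = None) -> "WaveformKernel":
        if k % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {k}")
        rng = rng or np.random.default_rng()
        return cls(
            base=Tensor(rng.normal(0, 1.0, k), requires_grad=True, name="mcpa.W_b"),
            alpha=Tensor(float(alpha_init), requires_grad=True, name="mcpa.alpha"),
            impulse=impulse_kernel(k),
        )

    def tensors(self) -> list[Tensor]:
        return [self.base, self.alpha]

    @property
    def size(self) -> int:
        return self.base.shape[0]


@dataclass
class PhaseNetParams:
    """Two-layer tanh network estimating a signed per-timestep phase offset."""

    W1: Tensor  # (D, D/2)
    b1: Tensor  # (D/2,)
    W2: Tensor  # (D/2, 1)
    b2: Tensor  # scalar

    @classmethod
    def init(cls, embed_dim: int, rng: np.random.Generator | None = None
             ) -> "PhaseNetParams":
        rng = rng or np.random.default_rng()
        half = max(embed_dim // 2, 1)
        s = 1.0 / np.sqrt(embed_dim)
        return cls(
            W1=Tensor(rng.normal(0, s, (embed_dim, half)), requires_grad=True, name="mcpa.phase_W1"),
            b1=Tensor(np.zeros(half), requires_grad=True, name="mcpa.phase_b1"),
            W2=Tensor(rng.normal(0, 1.0 / np.sqrt(half), (half, 1)), requires_grad=True, name="mcpa.phase_W2"),
            b2=Tensor(0.0, requires_grad=True, name="mcpa.phase_b2"),
        )

    def tensors(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


@dataclass
class FusionState:
    """Intermediates of one fusion pass (numpy copies, for inspection)."""

    enhanced: np.ndarray                  # (B, L)
    aligned: list[np.ndarray]             # per scale (B, s_i, D)
    phase_offsets: list[np.ndarray]       # per scale (B, s_i, 1)
    gates: list[np.ndarray]               # per scale (B, s_i, 1), in (0,1)
    fused: list[np.ndarray]               # per scale (B, s_i, D)
    probabilities: np.ndarray             # (B, 2), rows sum to 1


# -- operations --------------------------------------------------------------

def hybrid_kernel_t(kernel: WaveformKernel) -> Tensor:
    alpha = kernel.alpha.clamp(0.0, 1.0)
    impulse = kernel.impulse.astype(kernel.base.data.dtype, copy=False)
    K_t = alpha * kernel.base.tanh() + (1.0 - alpha) * as_tensor(impulse)
    return softmax(K_t, axis=-1)


def hybrid_kernel(W_b, K_0, alpha) -> np.ndarray:
    """K_t = alpha*tanh(W_b) + (1-alpha)*K_0, softmax-normalised to unit mass."""
    W_b = np.asarray(W_b, dtype=np.float64)
    K_0 = np.asarray(K_0, dtype=np.float64)
    if W_b.shape != K_0.shape:
        raise ValueError("base and impulse kernels must share a length")
    kern = WaveformKernel(base=as_tensor(W_b), alpha=as_tensor(float(alpha)), impulse=K_0)
    return hybrid_kernel_t(kern).data


def waveform_similarity(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Replicate-padded sliding correlation; output length equals input."""
    x = np.asarray(x, dtype=np.float64)
    return correlate1d_replicate(as_tensor(x), as_tensor(kernel)).data


def waveform_attention_t(x: Tensor, S: Tensor, scale_preserving: bool = False) -> Tensor:
    A = softmax(S, axis=-1)
    if scale_preserving:
        A = A * float(x.shape[-1])
    return x * A


def waveform_attention(x: np.ndarray, S: np.ndarray,
                       scale_preserving: bool = False) -> np.ndarray:
    """X_enh = x * softmax(S over time); each attention row sums to 1."""
    x = np.asarray(x, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if x.shape != S.shape:
        raise ValueError(f"shape mismatch: signal {x.shape} vs scores {S.shape}")
    return waveform_attention_t(as_tensor(x), as_tensor(S), scale_preserving).data


def align_to_scale_t(x: Tensor, s_i: int, W: Tensor, b: Tensor,
                     allow_interpolation: bool = False) -> Tensor:
    """Pool (B, L) to length s_i then embed scalars to D dims."""
    return scale_embed_t(avg_pool_t(x, s_i, allow_interpolation), W, b)


def align_to_scale(x: np.ndarray, s_i: int, align_params: tuple) -> np.ndarray:
    W, b = align_params
    return align_to_scale_t(as_tensor(np.asarray(x, dtype=np.float64)), s_i,
                            as_tensor(W), as_tensor(b)).data


def phase_difference_t(A_i: Tensor, X_i: Tensor, p: PhaseNetParams) -> Tensor:
    hidden = ((A_i - X_i) @ p.W1 + p.b1).tanh()
    return hidden @ p.W2 + p.b2


def phase_difference(A_i: np.ndarray, X_i: np.ndarray, p: PhaseNetParams) -> np.ndarray:
    """Signed per-timestep offset: W2.tanh(W1.(A_i - X_i) + b1) + b2."""
    A_i = np.asarray(A_i, dtype=np.float64)
    X_i = np.asarray(X_i, dtype=np.float64)
    if A_i.shape != X_i.shape:
        raise ValueError("phase inputs must share a shape")
    return phase_difference_t(as_tensor(A_i), as_tensor(X_i), p).data


def phase_gate_fuse_t(A_i: Tensor, X_i: Tensor, dP: Tensor) -> tuple[Tensor, Tensor]:
    gate = dP.sigmoid()
    fused = gate * A_i + (1.0 - gate) * X_i
    return fused, gate


def phase_gate_fuse(A_i: np.ndarray, X_i: np.ndarray, dP: np.ndarray) -> np.ndarray:
    """Convex blend F = sigmoid(dP)*A_i + (1 - sigmoid(dP))*X_i."""
    fused, _ = phase_gate_fuse_t(as_tensor(np.asarray(A_i, dtype=np.float64)),
                                 as_tensor(np.asarray(X_i, dtype=np.float64)),
                                 as_tensor(np.asarray(dP, dtype=np.float64)))
    return fused.data


def classify_t(features: list[Tensor], W_y: Tensor, b_y: Tensor,
               head_reduction: str = "mean") -> tuple[Tensor, Tensor]:
    """Reduce per-scale features, concatenate, project; returns (logits, probs)."""
    if not features:
        raise ValueError("at least one feature tensor is required")
    if head_reduction == "mean":
        reduced = [f.mean(axis=1) for f in features]      # (B, D) each
    elif head_reduction == "flatten":
        reduced = [f.reshape(f.shape[0], f.shape[1] * f.shape[2]) for f in features]
    else:
        raise ValueError(f"unknown head_reduction {head_reduction!r}")
    logits = concat(reduced, axis=-1) @ W_y + b_y
    return logits, softmax(logits, axis=-1)


def classify(features: list[np.ndarray], head_params: tuple,
             head_reduction: str = "mean") -> np.ndarray:
    """Class probabilities (B, 2); rows sum to 1."""
    W_y, b_y = head_params
    feats = [as_tensor(np.asarray(f, dtype=np.float64)) for f in features]
    _, probs = classify_t(feats, as_tensor(W_y), as_tensor(b_y), head_reduction)
    return probs.data
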