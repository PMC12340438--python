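"""Multi-scale feature extraction with temperature-controlled attention.

The filtered signal is pooled to several temporal resolutions (non-overlapping
window means), each pooled sequence is lifted to a shared embedding width by
a per-scale affine map, and each scale is processed by multi-head
self-attention whose per-head score divisor is a *learnable* temperature
``tau_h = exp(lambda_h)``.  ``lambda_h`` is initialised to ``ln(D/H)`` so the
initial divisor equals the head width — playing the role of the conventional
``sqrt(d_k)`` scaling, which is otherwise absent.  The QKV projection is
shared across scales; the scale embeddings are not.

No positional encoding, residual path or normalisation layer is used: the
architecture is attention over embedded pooled amplitudes, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, concat, softmax

__all__ = [
    "ScaleConfig",
    "ScaleFeature",
    "AttentionParams",
    "multiscale_pool",
    "scale_embed",
    "tempered_attention",
    "mcfe_forward",
]


@dataclass
class ScaleConfig:
    """Target lengths and attention geometry for the multi-scale stage."""

    scales: list[int] = field(default_factory=lambda: [1228, 614, 307])
    embed_dim: int = 64
    n_heads: int = 4
    allow_interpolation: bool = False

    def __post_init__(self):
        if not self.scales:
            raise ValueError("at least one scale is required")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    def validate_length(self, L: int) -> None:
        if self.allow_interpolation:
            return
        for s in self.scales:
            if L % s != 0:
                raise ValueError(
                    f"segment length {L} is not divisible by scale {s}; "
                    "non-integral pooling ratios are rejected"
                )


@dataclass
class ScaleFeature:
    """Per-scale intermediates: pooled P, embedded H, attended A."""

    pooled: np.ndarray    # (B, s_i)
    embedded: np.ndarray  # (B, s_i, D)
    attended: np.ndarray  # (B, s_i, D)


@dataclass
class AttentionParams:
    """Shared QKV/output projections, per-head log-temperatures, and the
    per-scale scalar-to-D embeddings."""

    W_qkv: Tensor                     # (D, 3D)
    log_temps: Tensor                 # (H,), tau_h = exp(log_temps)
    W_o: Tensor                       # (D, D)
    b_o: Tensor                       # (D,)
    embed_weights: list[Tensor]       # each (1, D)
    embed_biases: list[Tensor]        # each (D,)

    @classmethod
    def init(cls, config: ScaleConfig, rng: np.random.Generator | None = None
             ) -> "AttentionParams":
        rng = rng or np.random.default_rng()
        D, H = config.embed_dim, config.n_heads
        scale = 1.0 / np.sqrt(D)
        return cls(
            W_qkv=Tensor(rng.normal(0, scale, (D, 3 * D)), requires_grad=True, name="mcfe.W_qkv"),
            log_temps=Tensor(np.full(H, np.log(D / H)), requires_grad=True, name="mcfe.log_temps"),
            W_o=Tensor(rng.normal(0, scale, (D, D)), requires_grad=True, name="mcfe.W_o"),
            b_o=Tensor(np.zeros(D), requires_grad=True, name="mcfe.b_o"),
            embed_weights=[
                Tensor(rng.normal(0, 1.0, (1, D)), requires_grad=True, name=f"mcfe.embed_W{i}")
                for i in range(len(config.scales))
            ],
            embed_biases=[
                Tensor(np.zeros(D), requires_grad=True, name=f"mcfe.embed_b{i}")
                for i in range(len(config.scales))
            ],
        )

    def tensors(self) -> list[Tensor]:
        return [self.W_qkv, self.log_temps, self.W_o, self.b_o,
                *self.embed_weights, *self.embed_biases]

    @property
    def temperatures(self) -> np.ndarray:
        return np.exp(self.log_temps.data)


# -- operations --------------------------------------------------------------

def _adaptive_pool_matrix(L: int, s: int) -> np.ndarray:
    """Row-stochastic (s, L) matrix averaging window [floor(tL/s), ceil((t+1)L/s))."""
    M = np.zeros((s, L))
    for t in range(s):
        lo = (t * L) // s
        hi = -(-((t + 1) * L) // s)  # ceil division
        M[t, lo:hi] = 1.0 / (hi - lo)
    return M


def avg_pool_t(x: Tensor, target_length: int, allow_interpolation: bool = False) -> Tensor:
    """Window means (..., L) -> (..., s).

    When L is divisible by s this is exact non-overlapping averaging with
    kernel k = L // s.  Otherwise the scale is rejected unless
    ``allow_interpolation`` is set, in which case adaptive (variable-window)
    average pooling is applied.
    """
    L = x.shape[-1]
    if L % target_length != 0:
        if not allow_interpolation:
            raise ValueError(
                f"length {L} is not divisible by target scale {target_length}"
            )
        M = _adaptive_pool_matrix(L, target_length).astype(x.data.dtype)
        return x @ as_tensor(M.T)
    k = L // target_length
    if k == 1:
        return x
    return x.reshape(*x.shape[:-1], target_length, k).mean(axis=-1)


def multiscale_pool(x: np.ndarray, scales: list[int],
                    allow_interpolation: bool = False) -> list[np.ndarray]:
    """Pool (B, L) to each target length with kernel k_i = L // s_i."""
    x = np.asarray(x, dtype=np.float64)
    return [avg_pool_t(as_tensor(x), s, allow_interpolation).data for s in scales]


def scale_embed_t(P: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Each scalar timestep to a D-vector: H[b,t,:] = P[b,t]*W + b."""
    return P.reshape(*P.shape, 1) @ W + b


def scale_embed(P: np.ndarray, W, b) -> np.ndarray:
    return scale_embed_t(as_tensor(np.asarray(P, dtype=np.float64)),
                         as_tensor(W), as_tensor(b)).data


def tempered_attention_t(H_i: Tensor, params: AttentionParams, n_heads: int,
                         return_weights: bool = False):
    """Multi-head self-attention with per-head learnable temperature."""
    B, s, D = H_i.shape
    if D % n_heads != 0:
        raise ValueError(f"embed dim {D} not divisible by {n_heads} heads")
    dh = D // n_heads
    qkv = H_i @ params.W_qkv                      # (B, s, 3D)
    heads = []
    weights = []
    taus = params.log_temps.exp()
    for h in range(n_heads):
        q = qkv[:, :, h * dh:(h + 1) * dh]
        k = qkv[:, :, D + h * dh:D + (h + 1) * dh]
        v = qkv[:, :, 2 * D + h * dh:2 * D + (h + 1) * dh]
        # temperature applied to Q before the (s x s) product: same scores,
        # one big temporary fewer on the tape
        scores = (q / taus[h]) @ k.swapaxes(-1, -2)
        alpha = softmax(scores, axis=-1)          # rows over keys sum to 1
        heads.append(alpha @ v)
        if return_weights:
            weights.append(alpha.data)
    out = concat(heads, axis=-1) @ params.W_o + params.b_o
    if not np.isfinite(out.data).all():
        raise FloatingPointError("non-finite activations in tempered attention output")
    if return_weights:
        return out, np.stack(weights, axis=1)     # (B, H, s, s)
    return out


def tempered_attention(H_i: np.ndarray, params: AttentionParams,
                       n_heads: int | None = None) -> np.ndarray:
    H_i = np.asarray(H_i, dtype=np.float64)
    n_heads = n_heads if n_heads is not None else params.log_temps.shape[0]
    return tempered_attention_t(as_tensor(H_i), params, n_heads).data


def mcfe_forward_t(x: Tensor, config: ScaleConfig, params: AttentionParams
                   ) -> list[tuple[Tensor, Tensor, Tensor]]:
    """Full multi-scale pass on a tensor batch; returns (P, H, A) per scale."""
    config.validate_length(x.shape[-1])
    out = []
    for i, s in enumerate(config.scales):
        P = avg_pool_t(x, s, config.allow_interpolation)
        H = scale_embed_t(P, params.embed_weights[i], params.embed_biases[i])
        A = tempered_attention_t(H, params, config.n_heads)
        out.append((P, H, A))
    return out


def mcfe_forward(x: np.ndarray, config: ScaleConfig, params: AttentionParams
                 ) -> list[ScaleFeature]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    feats = mcfe_forward_t(as_tensor(x), config, params)
    return [ScaleFeature(P.data, H.data, A.data) for P, H, A in feats]
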