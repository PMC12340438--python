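"""Full seizure-recognition network: spectral masking -> multi-scale
temperature-controlled attention -> phase-aware fusion -> softmax head.

The three stages are independently switchable, which yields the standard
ablation variants:

* ``AB1`` (``use_dfs=False``) — the raw signal feeds the multi-scale stage
  directly, no learnable spectral mask;
* ``AB2`` (``use_mcfe=False``) — a single attention branch at full
  resolution, no multi-scale decomposition;
* ``AB3`` (``use_mcpa=False``) — attended features go straight to the head,
  no waveform attention or phase gating.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .autograd import Tensor, as_tensor
from .fusion import (PhaseNetParams, WaveformKernel, align_to_scale_t,
                     classify_t, correlate1d_replicate, hybrid_kernel_t,
                     phase_difference_t, phase_gate_fuse_t,
                     waveform_attention_t)
from .multiscale import AttentionParams, ScaleConfig, mcfe_forward_t
from .spectral import DFSParams, dfs_forward_t, sample_gumbel

__all__ = ["ModelConfig", "SeizureNet", "build_model", "ablation_config",
           "config_hash", "save_model", "load_model"]

ABLATION_VARIANTS = ("ORI", "AB1", "AB2", "AB3")


@dataclass
class ModelConfig:
    """Every knob of the network and its training loop."""

    # geometry
    segment_length: int = 1228
    sampling_rate: float = 256.0
    # spectral-selection stage
    dfs_hidden_dim: int = 64
    dfs_temperature: float = 1.0
    mask_gain: bool = False          # multiply mask by N (shape-preserving rescale)
    shared_noise: bool = False       # one Gumbel draw per bin, shared across batch
    hard_mask: bool = False          # straight-through one-hot mask
    # multi-scale attention stage
    scales: list[int] = field(default_factory=lambda: [1228, 614, 307])
    embed_dim: int = 64
    n_heads: int = 4
    allow_interpolation: bool = False  # accept scales that do not divide L
    # waveform/phase fusion stage
    kernel_size: int = 15
    alpha_init: float = 0.5
    scale_preserving: bool = False   # multiply time-attention by L
    waveform_input: str = "dfs"      # "dfs" | "raw"
    head_reduction: str = "mean"     # "mean" | "flatten"
    # ablation switches
    use_dfs: bool = True
    use_mcfe: bool = True
    use_mcpa: bool = True
    # numerics
    dtype: str = "float32"           # parameter/activation precision
    # training
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    class_weight: bool = False
    positive_class: int = 1

    def __post_init__(self):
        if not self.scales:
            raise ValueError("at least one scale is required")
        if self.dfs_temperature <= 0:
            raise ValueError("dfs_temperature must be positive")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if not 0.0 <= self.alpha_init <= 1.0:
            raise ValueError("alpha_init must lie in [0, 1]")
        if self.waveform_input not in ("dfs", "raw"):
            raise ValueError("waveform_input must be 'dfs' or 'raw'")
        if self.head_reduction not in ("mean", "flatten"):
            raise ValueError("head_reduction must be 'mean' or 'flatten'")
        if self.positive_class not in (0, 1):
            raise ValueError("positive_class must be 0 or 1")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        off = [not self.use_dfs, not self.use_mcfe, not self.use_mcpa]
        if sum(off) > 1:
            raise ValueError(
                "at most one stage may be ablated at a time (AB1/AB2/AB3)"
            )
        if not self.allow_interpolation:
            for s in self.effective_scales:
                if self.segment_length % s != 0:
                    raise ValueError(
                        f"scale {s} does not divide segment length "
                        f"{self.segment_length} (set allow_interpolation to "
                        "accept interpolating pooling)"
                    )

    @property
    def effective_scales(self) -> list[int]:
        """Single full-resolution branch when the multi-scale stage is off."""
        return list(self.scales) if self.use_mcfe else [self.segment_length]

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: ModelConfig | dict) -> str:
    d = config.to_dict() if isinstance(config, ModelConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def ablation_config(base: ModelConfig, variant: str) -> ModelConfig:
    """Derive an ablation variant ('ORI', 'AB1', 'AB2', 'AB3') from a base."""
    variant = variant.upper()
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {ABLATION_VARIANTS}")
    flags = {"use_dfs": True, "use_mcfe": True, "use_mcpa": True}
    if variant != "ORI":
        flags[{"AB1": "use_dfs", "AB2": "use_mcfe", "AB3": "use_mcpa"}[variant]] = False
    return replace(base, **flags)


class SeizureNet:
    """The assembled network; parameters live as named autograd tensors."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        L = config.segment_length
        n_bins = L // 2 + 1
        scales = config.effective_scales
        self.scale_config = ScaleConfig(scales=scales, embed_dim=config.embed_dim,
                                        n_heads=config.n_heads,
                                        allow_interpolation=config.allow_interpolation)
        self.scale_config.validate_length(L)

        self.dfs: DFSParams | None = None
        if config.use_dfs:
            self.dfs = DFSParams.init(n_bins, hidden_dim=config.dfs_hidden_dim,
                                      temperature=config.dfs_temperature, rng=rng)
        self.attention = AttentionParams.init(self.scale_config, rng=rng)

        self.kernel: WaveformKernel | None = None
        self.phase: PhaseNetParams | None = None
        self.align_weights: list[Tensor] = []
        self.align_biases: list[Tensor] = []
        if config.use_mcpa:
            self.kernel = WaveformKernel.init(config.kernel_size, config.alpha_init, rng=rng)
            self.phase = PhaseNetParams.init(config.embed_dim, rng=rng)
            for i in range(len(scales)):
                self.align_weights.append(
                    Tensor(rng.normal(0, 1.0, (1, config.embed_dim)),
                           requires_grad=True, name=f"mcpa.align_W{i}"))
                self.align_biases.append(
                    Tensor(np.zeros(config.embed_dim),
                           requires_grad=True, name=f"mcpa.align_b{i}"))

        if config.head_reduction == "mean":
            head_in = len(scales) * config.embed_dim
        else:
            head_in = sum(scales) * config.embed_dim
        self.W_y = Tensor(rng.normal(0, 1.0 / np.sqrt(head_in), (head_in, 2)),
                          requires_grad=True, name="head.W_y")
        self.b_y = Tensor(np.zeros(2), requires_grad=True, name="head.b_y")

        self._np_dtype = np.float32 if config.dtype == "float32" else np.float64
        for p in self.parameters():
            p.data = p.data.astype(self._np_dtype)

    # -- parameter plumbing --------------------------------------------------
    def parameter_groups(self) -> dict[str, list[Tensor]]:
        groups: dict[str, list[Tensor]] = {}
        if self.dfs is not None:
            groups["dfs_scorer"] = self.dfs.tensors()
        groups["attention_qkv"] = [self.attention.W_qkv, self.attention.W_o,
                                   self.attention.b_o]
        groups["attention_temps"] = [self.attention.log_temps]
        groups["scale_embeddings"] = (self.attention.embed_weights
                                      + self.attention.embed_biases)
        if self.kernel is not None:
            groups["waveform_kernel"] = self.kernel.tensors()
            groups["phase_net"] = self.phase.tensors()
            groups["align_embeddings"] = self.align_weights + self.align_biases
        groups["head"] = [self.W_y, self.b_y]
        return groups

    def parameters(self) -> list[Tensor]:
        return [t for group in self.parameter_groups().values() for t in group]

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r} in state dict")
            arr = np.asarray(state[p.name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name!r}")
            p.data = arr.copy()

    # -- forward -------------------------------------------------------------
    def forward_t(self, x: np.ndarray, gumbel_noise: np.ndarray | float = 0.0,
                  return_state: bool = False):
        """Returns (logits Tensor, aux dict with numpy intermediates)."""
        cfg = self.config
        x_t = as_tensor(np.asarray(x, dtype=self._np_dtype))
        if isinstance(gumbel_noise, np.ndarray):
            gumbel_noise = gumbel_noise.astype(self._np_dtype)
        aux: dict = {}

        if self.dfs is not None:
            filtered, spec_state = dfs_forward_t(
                x_t, self.dfs, noise=gumbel_noise,
                mask_gain=cfg.mask_gain, hard=cfg.hard_mask)
            aux["mask"] = spec_state.mask
            if return_state:
                aux["spectral_state"] = spec_state
        else:
            filtered = x_t

        feats = mcfe_forward_t(filtered, self.scale_config, self.attention)
        attended = [A for _, _, A in feats]

        if self.kernel is not None:
            wave_in = filtered if cfg.waveform_input == "dfs" else x_t
            K = hybrid_kernel_t(self.kernel)
            sim = correlate1d_replicate(wave_in, K)
            enhanced = waveform_attention_t(wave_in, sim, cfg.scale_preserving)
            features = []
            gates = []
            for i, s in enumerate(self.scale_config.scales):
                X_i = align_to_scale_t(enhanced, s, self.align_weights[i],
                                       self.align_biases[i],
                                       cfg.allow_interpolation)
                dP = phase_difference_t(attended[i], X_i, self.phase)
                fused, gate = phase_gate_fuse_t(attended[i], X_i, dP)
                features.append(fused)
                gates.append(gate.data)
            if return_state:
                aux["enhanced"] = enhanced.data
                aux["gates"] = gates
        else:
            features = attended

        logits, probs = classify_t(features, self.W_y, self.b_y, cfg.head_reduction)
        aux["probabilities"] = probs.data
        return logits, aux

    def predict_proba(self, x: np.ndarray, chunk_size: int = 64) -> np.ndarray:
        """Deterministic (noise-free) class probabilities, chunked to keep the
        attention score arrays bounded."""
        x = np.atleast_2d(np.asarray(x))
        parts = []
        for lo in range(0, x.shape[0], chunk_size):
            _, aux = self.forward_t(x[lo:lo + chunk_size], gumbel_noise=0.0)
            parts.append(aux["probabilities"])
        return np.concatenate(parts, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=-1)

    def sample_noise(self, batch_size: int, rng: np.random.Generator):
        """Fresh Gumbel noise for one training step (0 when DFS is absent)."""
        if self.dfs is None:
            return 0.0
        n_bins = self.config.segment_length // 2 + 1
        shape = (n_bins,) if self.config.shared_noise else (batch_size, n_bins)
        return sample_gumbel(shape, rng)


def build_model(config: ModelConfig, rng: np.random.Generator | None = None) -> SeizureNet:
    return SeizureNet(config, rng=rng)


def save_model(model: SeizureNet, path) -> None:
    """Persist parameters + config to an NPZ archive."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["config_json"] = np.array(json.dumps(model.config.to_dict()))
    np.savez(path, **arrays)


def load_model(path) -> SeizureNet:
    with np.load(path, allow_pickle=False) as archive:
        cfg = ModelConfig(**json.loads(str(archive["config_json"])))
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    model = SeizureNet(cfg)
    model.load_state_dict(state)
    return model
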