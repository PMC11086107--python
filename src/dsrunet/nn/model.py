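"""The sparse-residual 1-D U-Net for PPG-to-ABP waveform translation.

The network maps a standardized 1024-sample PPG window to the corresponding
ABP window through a symmetric encoder–decoder: four downsampling levels
(block + 2:1 max-pool, channels doubling), a bottleneck block, and four
upsampling levels (2x transposed convolution + channel-attention-weighted
skip concatenation + block).  A 1-channel convolution after the last
decoder level produces the main output ("out"); additional 1-channel heads
at each decoder level ("level1"–"level4", shallow to deep) are linearly
upsampled to full length and supervised against the same target waveform
with weights [1, 0.9, 0.8, 0.7, 0.6] (deep supervision).

The ablation grid is expressed purely through ``block_type`` (plain /
residual / sparse_residual) and ``skip_type`` (plain / se / se_gru); see
:data:`ABLATION_VARIANTS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .layers import (
    BatchNorm1d, Conv1d, ConvTranspose1d, Module, ModuleList,
    make_block, make_skip,
)

__all__ = [
    "ModelConfig",
    "ModelOutputs",
    "DSRUnet",
    "build_dsrunet",
    "deep_supervision_loss",
    "mae_loss",
    "ABLATION_VARIANTS",
    "variant_config",
    "save_checkpoint",
    "load_checkpoint",
]

#: (block_type, skip_type) for the seven ablation variants; all use deep
#: supervision.  "model1" is the bare U-Net baseline, "dsrunet" the full model.
ABLATION_VARIANTS: dict[str, tuple[str, str]] = {
    "model1": ("plain", "plain"),
    "model2": ("plain", "se"),
    "model3": ("plain", "se_gru"),
    "model4": ("residual", "se"),
    "model5": ("sparse_residual", "se"),
    "model6": ("residual", "se_gru"),
    "dsrunet": ("sparse_residual", "se_gru"),
}


@dataclass
class ModelConfig:
    """Architecture description, including the ablation flags."""

    depth: int = 4
    base_channels: int = 32
    kernel_size: int = 3
    input_len: int = 1024
    block_type: str = "sparse_residual"
    skip_type: str = "se_gru"
    se_reduction: int = 8
    supervision_weights: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6)
    activation: str = "relu"

    def validate(self) -> None:
        if self.input_len % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_len {self.input_len} must be divisible by 2^depth={2**self.depth}"
            )
        if len(self.supervision_weights) != self.depth + 1:
            raise ValueError("need depth+1 supervision weights (main head + one per level)")
        if self.skip_type in ("se", "se_gru"):
            if self.base_channels % self.se_reduction != 0:
                raise ValueError(
                    f"se_reduction {self.se_reduction} must divide base_channels "
                    f"{self.base_channels}"
                )
        if self.activation != "relu":
            raise ValueError("only ReLU activation is supported")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["supervision_weights"] = tuple(d["supervision_weights"])
        return cls(**d)


def variant_config(name: str, **overrides) -> ModelConfig:
    """ModelConfig for one of the seven ablation variants by name."""
    block_type, skip_type = ABLATION_VARIANTS[name.lower()]
    return ModelConfig(block_type=block_type, skip_type=skip_type, **overrides)


@dataclass
class ModelOutputs:
    """Main prediction plus the four auxiliary (deep-supervision) outputs.

    All waveforms have shape [batch, input_len]; ``aux`` is ordered shallow
    (level1) to deep (level4).
    """

    main: Tensor
    aux: list[Tensor] = field(default_factory=list)


class DSRUnet(Module):
    """Encoder–decoder network; see the module docstring for the topology."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        C, d, k = cfg.base_channels, cfg.depth, cfg.kernel_size
        enc_ch = [C * 2 ** i for i in range(d)]          # per encoder level
        bott_ch = C * 2 ** d

        self.enc_blocks = ModuleList(
            make_block(cfg.block_type, 1 if i == 0 else enc_ch[i - 1], enc_ch[i],
                       k, "encoder", rng)
            for i in range(d)
        )
        self.bottleneck = make_block(cfg.block_type, enc_ch[-1], bott_ch, k,
                                     "encoder", rng)
        # decoder, deepest level first
        self.up_convs = ModuleList(
            ConvTranspose1d(bott_ch if i == d - 1 else enc_ch[i + 1], enc_ch[i], rng)
            for i in reversed(range(d))
        )
        self.skips = ModuleList(
            make_skip(cfg.skip_type, enc_ch[i], cfg.se_reduction, rng)
            for i in reversed(range(d))
        )
        self.dec_blocks = ModuleList(
            make_block(cfg.block_type, 2 * enc_ch[i], enc_ch[i], k, "decoder", rng)
            for i in reversed(range(d))
        )
        # prediction heads: "out" plus one per decoder level (shallow->deep)
        self.head_out = Conv1d(enc_ch[0], 1, kernel=1, rng=rng)
        self.head_levels = ModuleList(
            Conv1d(enc_ch[i], 1, kernel=1, rng=rng) for i in range(d)
        )

    def forward(self, x: Tensor | np.ndarray) -> ModelOutputs:
        """Map PPG windows [batch, 1, input_len] to :class:`ModelOutputs`."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim == 2:
            x = x.reshape((x.shape[0], 1, x.shape[1]))
        B, _, L = x.shape
        if L != self.cfg.input_len:
            raise ValueError(f"expected input length {self.cfg.input_len}, got {L}")
        d = self.cfg.depth

        enc_feats = []
        h = x
        for blk in self.enc_blocks:
            h = blk(h)
            enc_feats.append(h)
            h = h.maxpool2()
        h = self.bottleneck(h)

        dec_feats: dict[int, Tensor] = {}
        for j, level in enumerate(reversed(range(d))):  # deepest first
            h = self.up_convs[j](h)
            skip = self.skips[j](enc_feats[level])
            h = self.dec_blocks[j](concat([h, skip], axis=1))
            dec_feats[level] = h

        main = self.head_out(dec_feats[0]).reshape((B, L))
        aux = [
            self.head_levels[level](dec_feats[level])
            .interp_to(L)
            .reshape((B, L))
            for level in range(d)
        ]
        return ModelOutputs(main=main, aux=aux)

    __call__ = forward

    def predict_batch(self, x: np.ndarray) -> np.ndarray:
        """Inference-only forward pass; returns the main head as ndarray."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(x)
        finally:
            self.train(was_training)
        return out.main.data

    def describe(self) -> str:
        """Human-readable layer inventory."""
        cfg = self.cfg
        lines = [
            f"DSRUnet(block={cfg.block_type}, skip={cfg.skip_type}, "
            f"depth={cfg.depth}, base_channels={cfg.base_channels}, "
            f"input_len={cfg.input_len}, r={cfg.se_reduction})",
            f"  parameters: {self.n_parameters()}",
        ]
        for name, m in self._modules.items():
            lines.append(f"  {name}: {type(m).__name__}")
            if isinstance(m, ModuleList):
                for i, sub in enumerate(m):
                    lines.append(f"    [{i}] {type(sub).__name__}")
        return "\n".join(lines)


def build_dsrunet(cfg: ModelConfig, seed: int = 0) -> DSRUnet:
    """Build the network described by ``cfg`` with seeded initialization."""
    return DSRUnet(cfg, seed=seed)


def mae_loss(pred: Tensor, target: Tensor | np.ndarray) -> Tensor:
    """Mean absolute error."""
    if not isinstance(target, Tensor):
        target = Tensor(target)
    return (pred - target).abs().mean()


def deep_supervision_loss(
    outputs: ModelOutputs,
    target: Tensor | np.ndarray,
    weights: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6),
) -> tuple[Tensor, list[float]]:
    """Weighted sum of per-head MAE losses against the same target.

    ``weights[0]`` applies to the main head, the rest to the auxiliary heads
    in their stored (shallow to deep) order.  Returns the composite loss
    tensor and the unweighted per-head values for logging.
    """
    if len(weights) != 1 + len(outputs.aux):
        raise ValueError(
            f"got {len(weights)} weights for {1 + len(outputs.aux)} heads"
        )
    if not isinstance(target, Tensor):
        target = Tensor(target)
    heads = [outputs.main] + list(outputs.aux)
    per_head: list[float] = []
    total: Tensor | None = None
    for w, head in zip(weights, heads):
        l = mae_loss(head, target)
        per_head.append(float(l.data))
        term = w * l
        total = term if total is None else total + term
    return total, per_head


def save_checkpoint(model: DSRUnet, path: str, meta: dict | None = None) -> None:
    """Serialize parameters + buffers + embedded config JSON to one .npz."""
    arrays = {f"param:{n}": p.data for n, p in model.named_parameters()}
    arrays.update({f"buffer:{n}": b for n, b in model.named_buffers()})
    arrays["config_json"] = np.array(model.cfg.to_json())
    arrays["meta_json"] = np.array(json.dumps(meta or {}))
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> tuple[DSRUnet, dict]:
    """Rebuild a model from a checkpoint; returns (model, meta)."""
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig.from_json(str(z["config_json"]))
        meta = json.loads(str(z["meta_json"]))
        model = DSRUnet(cfg)
        params = dict(model.named_parameters())
        for key in z.files:
            if key.startswith("param:"):
                params[key[6:]].data[...] = z[key]
        buffers = dict(model.named_buffers())
        for key in z.files:
            if key.startswith("buffer:"):
                buffers[key[7:]][...] = z[key]
    return model, meta
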