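"""TriLightNet assembly, focal loss and checkpointing.

The full network encodes each volume with its own 3-D residual encoder
and the clinical vector with the KAN/PoolFormer tabular encoder; each
imaging feature map is refined by its own HBAM instance using the
shared clinical latent; the two refined streams are flattened to
tokens and fused by MMCA; the fused [B, L, 2C] representation is
mean-pooled over tokens and classified by a small head
(LayerNorm -> Linear -> GELU -> Linear) into a single pMCI logit.

Class imbalance (149 pMCI vs 363 sMCI) is handled by focal loss.  The
default form is the standard alpha-balanced focal loss

    L = -alpha_t (1 - p_t)^gamma log(p_t),
    p_t = p if y=1 else 1-p,   alpha_t = alpha if y=1 else 1-alpha,

with defaults alpha = 0.75 (up-weighting the minority converter class)
and gamma = 2.  A ``literal_form`` flag selects the variant in which a
single (1-p)^gamma factor multiplies the whole cross-entropy,
-alpha (1-p)^gamma [y log p + (1-y) log(1-p)]; it is kept for fidelity
but is not the default because it down-weights confident positives.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, clip, gelu, log, no_grad, power, sigmoid
from .hbam import Hbam
from .image_encoder import EncoderConfig, ResNet3d
from .mmca import Mmca, tokens_from_featuremap
from .nn import LayerNorm, Linear, Module
from .tabular import TabularConfig, TabularEncoder

__all__ = [
    "ModelConfig",
    "FocalLossConfig",
    "Prediction",
    "TriLightNet",
    "focal_loss",
    "save_checkpoint",
    "load_checkpoint",
]

_PROB_EPS = 1e-7


@dataclass(frozen=True)
class FocalLossConfig:
    alpha: float = 0.75
    gamma: float = 2.0
    literal_form: bool = False

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to build the network deterministically."""

    input_shape: tuple[int, int, int] = (24, 32, 24)
    image_preset: str = "test"
    tabular: TabularConfig = field(default_factory=TabularConfig)
    hbam_reduction: int = 8
    hbam_spatial_kernel: int = 7
    mmca_groups: int = 4
    mmca_bias_init: float = 0.0
    head_hidden: int = 64
    use_hbam: bool = True
    fusion: str = "mmca"  # "mmca" | "concat" (ablation variant)

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig.from_preset(self.image_preset)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["input_shape"] = tuple(d["input_shape"])
        tab = d.get("tabular", {})
        if isinstance(tab, dict):
            if "grid_range" in tab:
                tab["grid_range"] = tuple(tab["grid_range"])
            d["tabular"] = TabularConfig(**tab)
        return cls(**d)


@dataclass
class Prediction:
    """Single-subject output: p = sigmoid(logit), hard label at 0.5."""

    logit: float
    probability: float
    label: int

    @classmethod
    def from_logit(cls, logit: float) -> "Prediction":
        p = float(1.0 / (1.0 + np.exp(-logit)))
        return cls(logit=float(logit), probability=p, label=int(p >= 0.5))


class TriLightNet(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        enc_cfg = config.encoder_config()
        self.feature_spatial = enc_cfg.output_spatial(config.input_shape)
        self.c_img = enc_cfg.out_channels
        self.l_tokens = int(np.prod(self.feature_spatial))
        self.mri_encoder = ResNet3d(enc_cfg, rng)
        self.pet_encoder = ResNet3d(enc_cfg, rng)
        self.tabular = TabularEncoder(config.tabular, rng)
        if config.use_hbam:
            self.hbam_mri = Hbam(
                config.tabular.d_tab,
                self.c_img,
                config.hbam_reduction,
                config.hbam_spatial_kernel,
                rng,
            )
            self.hbam_pet = Hbam(
                config.tabular.d_tab,
                self.c_img,
                config.hbam_reduction,
                config.hbam_spatial_kernel,
                rng,
            )
        if config.fusion == "mmca":
            self.mmca = Mmca(
                self.c_img,
                self.l_tokens,
                config.mmca_groups,
                config.mmca_bias_init,
                rng,
            )
        elif config.fusion != "concat":
            raise ValueError(f"unknown fusion mode {config.fusion!r}")
        self.head_norm = LayerNorm(2 * self.c_img)
        self.head_fc1 = Linear(2 * self.c_img, config.head_hidden, rng=rng)
        self.head_fc2 = Linear(config.head_hidden, 1, rng=rng)

    def forward(self, mri: Tensor, pet: Tensor, clinical: Tensor) -> Tensor:
        """Batches of volumes [B, 1, D, H, W] x2 and clinical [B, 7]
        -> logits [B]."""
        f_cli = self.tabular(clinical)
        f_mri = self.mri_encoder(mri)
        f_pet = self.pet_encoder(pet)
        if self.config.use_hbam:
            f_mri = self.hbam_mri(f_mri, f_cli)
            f_pet = self.hbam_pet(f_pet, f_cli)
        tok_mri = tokens_from_featuremap(f_mri)
        tok_pet = tokens_from_featuremap(f_pet)
        if self.config.fusion == "mmca":
            fused = self.mmca(tok_mri, tok_pet)  # [B, L, 2C]
        else:
            from .autodiff import concatenate

            fused = concatenate([tok_mri, tok_pet], axis=-1)
        pooled = fused.mean(axis=1)  # [B, 2C]
        h = gelu(self.head_fc1(self.head_norm(pooled)))
        return self.head_fc2(h).reshape(pooled.shape[0])

    def predict(self, mri, pet, clinical) -> list[Prediction]:
        """Evaluation-mode predictions (no graph, running statistics)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(
                    _as_tensor(mri), _as_tensor(pet), _as_tensor(clinical)
                ).data
        finally:
            self.train(was_training)
        return [Prediction.from_logit(z) for z in np.atleast_1d(logits)]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def focal_loss(p, y, config: FocalLossConfig = FocalLossConfig(), reduction: str = "mean"):
    """Focal loss on probabilities ``p`` (clamped to [1e-7, 1-1e-7]).

    Accepts plain arrays (returns an ndarray/float) or autodiff tensors
    (returns a Tensor on the graph).
    """
    y_arr = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float64)
    if not np.isin(y_arr, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    is_tensor = isinstance(p, Tensor)
    pt_in = p if is_tensor else Tensor(np.asarray(p, dtype=np.float64))
    yv = Tensor(y_arr.astype(pt_in.data.dtype))
    pc = clip(pt_in, _PROB_EPS, 1.0 - _PROB_EPS)
    if config.literal_form:
        ce = -(yv * log(pc) + (1.0 - yv) * log(1.0 - pc))
        loss = config.alpha * power(1.0 - pc, config.gamma) * ce
    else:
        p_t = pc * yv + (1.0 - pc) * (1.0 - yv)
        alpha_t = config.alpha * yv + (1.0 - config.alpha) * (1.0 - yv)
        loss = -alpha_t * power(1.0 - p_t, config.gamma) * log(p_t)
    if reduction == "mean":
        loss = loss.mean()
    elif reduction != "none":
        raise ValueError("reduction must be 'mean' or 'none'")
    if is_tensor:
        return loss
    out = loss.data
    return float(out) if out.ndim == 0 else out


def focal_loss_from_logits(logits: Tensor, y, config: FocalLossConfig = FocalLossConfig()):
    """Convenience wrapper used by the training loop."""
    return focal_loss(sigmoid(logits), y, config)


# ---------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------

def save_checkpoint(model: TriLightNet, path, extra: dict | None = None) -> None:
    """Single archive of named parameter/buffer arrays plus a JSON
    snapshot of the model config."""
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    arrays = dict(model.state_dict())
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[TriLightNet, dict]:
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(arrays.pop("__meta__").tobytes().decode())
    model = TriLightNet(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(arrays)
    return model, meta["extra"]
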