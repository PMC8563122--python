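"""Multitask interactive-attention network for two-task palm classification.

The architecture is a shared residual backbone tapped at four levels,
feeding two task-specific branches of cascaded soft-attention modules (task
M: knuckle swelling, task P: thenar hypertrophy), cross-linked at every
level by an information-interaction module (IIM), and closed by per-task
1×1 class-map convolutions with global average pooling and softmax.

Per level i and branch b, the attention module splits in two parts.  Part 1
builds a bounded mask from the shared feature f(i), fused with the previous
module's output when one exists:

    f′(i) = T(G(f(i)))                       first module of the branch
    f′(i) = T(G(f(i) ⊕ down(f_m(i−1))))      otherwise

with G a 3×3 conv + BN + ReLU, T a 1×1 conv + BN + sigmoid, ⊕ channel
concatenation.  The IIM then mixes the two branches' masks, treating the
other task as weighted reference information:

    IIM_M(i) = T₁ₓ₁(f′_M(i) ⊕ λ₁·f′_P(i))
    IIM_P(i) = T₁ₓ₁(f′_P(i) ⊕ λ₂·f′_M(i))

each direction with its own 1×1 conv + BN halving the channel count back to
C_i.  Part 2 applies the mask with a residual identity that protects
against vanishing through repeated multiplication:

    f_m(i) = (1 + f′(i)) ⊙ f_IIM(i)

Ablation variants: ``osn`` (backbone + heads only), ``am_subset`` (any
non-empty subset of the four attention levels, non-adjacent levels aligned
by bilinear interpolation + 1×1 channel matching), ``no_iim`` (each branch
keeps a 1×1+BN on its own mask instead of the cross-link), and the two
single-task models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat
from .nn import Adam, BatchNorm2d, Conv2d, Module

VARIANTS = ("full", "osn", "am_subset", "no_iim", "single_task_m", "single_task_p")

PRESETS = {
    # channels per tap level, blocks per stage, stem width, default input side
    "small": {"channels": (8, 16, 32, 64), "blocks": 1, "stem": 8, "input_side": 64},
    "clinical": {"channels": (64, 128, 256, 512), "blocks": 2, "stem": 64, "input_side": 460},
}


class ModelConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    preset: str = "small"
    input_side: int | None = None
    variant: str = "full"
    am_levels: tuple[int, ...] = (1, 2, 3, 4)
    lambda1: float = 0.2
    lambda2: float = 0.4
    num_classes_per_task: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ModelConfigError(f"unknown preset {self.preset!r}")
        if self.variant not in VARIANTS:
            raise ModelConfigError(f"unknown variant {self.variant!r}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ModelConfigError("lambda weights must be >= 0")
        self.am_levels = tuple(sorted(set(int(i) for i in self.am_levels)))
        if self.variant == "am_subset" and not self.am_levels:
            raise ModelConfigError("am_subset needs a non-empty level set")
        if any(i < 1 or i > 4 for i in self.am_levels):
            raise ModelConfigError("am_levels must be within 1..4")
        if self.variant in ("full", "no_iim", "single_task_m", "single_task_p"):
            self.am_levels = (1, 2, 3, 4)
        if self.input_side is None:
            self.input_side = PRESETS[self.preset]["input_side"]

    @property
    def channels(self) -> tuple[int, ...]:
        return PRESETS[self.preset]["channels"]

    @property
    def tasks(self) -> tuple[str, ...]:
        if self.variant == "single_task_m":
            return ("m",)
        if self.variant == "single_task_p":
            return ("p",)
        return ("m", "p")

    @property
    def uses_iim(self) -> bool:
        return self.variant in ("full", "osn", "am_subset") and self.variant != "osn"

    def to_json(self) -> str:
        return json.dumps({"preset": self.preset, "input_side": self.input_side,
                           "variant": self.variant, "am_levels": list(self.am_levels),
                           "lambda1": self.lambda1, "lambda2": self.lambda2,
                           "num_classes_per_task": self.num_classes_per_task,
                           "seed": self.seed})

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["am_levels"] = tuple(d.get("am_levels", (1, 2, 3, 4)))
        return cls(**d)


@dataclass
class TaskPrediction:
    """Per-task class scores (post-GAP, pre-softmax) and probabilities."""
    scores: np.ndarray  # (N, 2)
    probs: np.ndarray   # (N, 2), rows sum to 1


# --------------------------------------------------------------------------
# backbone
# --------------------------------------------------------------------------

class BasicBlock(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, stride: int):
        super().__init__()
        self.conv1 = Conv2d(rng, in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(rng, out_ch, out_ch, 3, stride=1, padding=1, bias=False)
        self.bn2 = BatchNorm2d(out_ch)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(rng, in_ch, out_ch, 1, stride=stride, bias=False)
            self.proj_bn = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        sc = x if self.proj is None else self.proj_bn(self.proj(x))
        return (h + sc).relu()


class Backbone(Module):
    """Residual trunk tapped after each of its four stages."""

    def __init__(self, rng, preset: str):
        super().__init__()
        p = PRESETS[preset]
        ch = p["channels"]
        stem = p["stem"]
        if preset == "clinical":
            self.stem_conv = Conv2d(rng, 3, stem, 7, stride=2, padding=3, bias=False)
            self.stem_pool = 2  # avg-pool factor after the stem
            stage1_stride = 1
        else:
            self.stem_conv = Conv2d(rng, 3, stem, 3, stride=2, padding=1, bias=False)
            self.stem_pool = 1
            stage1_stride = 2
        self.stem_bn = BatchNorm2d(stem)
        in_ch = stem
        self.n_stages = 4
        for s in range(4):
            stride = stage1_stride if s == 0 else 2
            blocks = p["blocks"]
            for b in range(blocks):
                blk = BasicBlock(rng, in_ch, ch[s], stride if b == 0 else 1)
                self.register(f"stage{s + 1}_block{b}", blk)
                in_ch = ch[s]
        self.blocks_per_stage = p["blocks"]

    def __call__(self, x: Tensor) -> list[Tensor]:
        h = self.stem_bn(self.stem_conv(x)).relu()
        if self.stem_pool > 1:
            h = h.avg_pool2d(self.stem_pool)
        taps = []
        for s in range(4):
            for b in range(self.blocks_per_stage):
                h = getattr(self, f"stage{s + 1}_block{b}")(h)
            taps.append(h)
        return taps


# --------------------------------------------------------------------------
# attention branch pieces
# --------------------------------------------------------------------------

class AttentionStage(Module):
    """Part 1 of an attention module: mask f′(i) (and the pre-mask feature)."""

    def __init__(self, rng, level_ch: int, prev_ch: int | None, adjacent: bool):
        super().__init__()
        self.adjacent = adjacent
        in_ch = level_ch
        if prev_ch is not None:
            if adjacent:
                in_ch = level_ch + prev_ch
            else:
                # bilinear resize handles space; 1×1 conv matches channels
                self.match = Conv2d(rng, prev_ch, level_ch, 1, bias=False)
                self.match_bn = BatchNorm2d(level_ch)
                in_ch = 2 * level_ch
        self.g_conv = Conv2d(rng, in_ch, level_ch, 3, padding=1, bias=False)
        self.g_bn = BatchNorm2d(level_ch)
        self.t_conv = Conv2d(rng, level_ch, level_ch, 1, bias=False)
        self.t_bn = BatchNorm2d(level_ch)
        self.has_prev = prev_ch is not None

    def __call__(self, f_i: Tensor, f_m_prev: Tensor | None) -> Tensor:
        if self.has_prev:
            if f_m_prev is None:
                raise ValueError("attention stage expects a previous module output")
            h_i, w_i = f_i.shape[2], f_i.shape[3]
            if self.adjacent:
                prev = f_m_prev
                if prev.shape[2] != h_i:
                    prev = prev.avg_pool2d(prev.shape[2] // h_i)
            else:
                prev = f_m_prev.bilinear_resize(h_i, w_i)
                prev = self.match_bn(self.match(prev))
            x = concat([f_i, prev], axis=1)
        else:
            x = f_i
        g = self.g_bn(self.g_conv(x)).relu()
        return self.t_bn(self.t_conv(g)).sigmoid()

    @staticmethod
    def apply_mask(f_prime: Tensor, f_iim: Tensor) -> Tensor:
        """Part 2: f_m = (1 + f′) ⊙ f_IIM (residual identity on the mask)."""
        if f_prime.shape != f_iim.shape:
            raise ValueError(f"mask/feature shape mismatch: {f_prime.shape} vs {f_iim.shape}")
        return (f_prime + 1.0) * f_iim


class IIMBlock(Module):
    """Cross-branch fusion at one level: two directions, separate 1×1+BN."""

    def __init__(self, rng, ch: int, lambda1: float, lambda2: float):
        super().__init__()
        if lambda1 < 0 or lambda2 < 0:
            raise ModelConfigError("lambda weights must be >= 0")
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.reduce_m = Conv2d(rng, 2 * ch, ch, 1, bias=False)
        self.bn_m = BatchNorm2d(ch)
        self.reduce_p = Conv2d(rng, 2 * ch, ch, 1, bias=False)
        self.bn_p = BatchNorm2d(ch)

    def __call__(self, f_prime_m: Tensor, f_prime_p: Tensor) -> tuple[Tensor, Tensor]:
        if f_prime_m.shape != f_prime_p.shape:
            raise ValueError("IIM expects equal shapes across branches")
        f_iim_m = self.bn_m(self.reduce_m(concat([f_prime_m, f_prime_p * self.lambda1], axis=1)))
        f_iim_p = self.bn_p(self.reduce_p(concat([f_prime_p, f_prime_m * self.lambda2], axis=1)))
        return f_iim_m, f_iim_p


class OwnPath(Module):
    """IIM replacement without cross-talk: 1×1+BN on the branch's own mask."""

    def __init__(self, rng, ch: int):
        super().__init__()
        self.reduce = Conv2d(rng, ch, ch, 1, bias=False)
        self.bn = BatchNorm2d(ch)

    def __call__(self, f_prime: Tensor) -> Tensor:
        return self.bn(self.reduce(f_prime))


class Head(Module):
    """1×1 class-map convolution + GAP: one score map per class."""

    def __init__(self, rng, ch: int, n_classes: int):
        super().__init__()
        self.conv = Conv2d(rng, ch, n_classes, 1, bias=True)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x).global_avg_pool()  # (N, n_classes)


# --------------------------------------------------------------------------
# full model
# --------------------------------------------------------------------------

class MultitaskAttentionNet(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x0D31])
        self.backbone = Backbone(rng, cfg.preset)
        ch = cfg.channels
        levels = cfg.am_levels
        self.levels = levels
        self.tasks = cfg.tasks
        nc = cfg.num_classes_per_task

        if cfg.variant == "osn":
            for t in self.tasks:
                self.register(f"head_{t}", Head(rng, ch[-1], nc))
            return

        for t in self.tasks:
            prev_ch = None
            prev_level = None
            for lvl in levels:
                c = ch[lvl - 1]
                adjacent = prev_level is not None and lvl - prev_level == 1
                self.register(f"am_{t}_{lvl}",
                              AttentionStage(rng, c, prev_ch, adjacent))
                prev_ch, prev_level = c, lvl
            self.register(f"head_{t}", Head(rng, ch[levels[-1] - 1], nc))

        for lvl in levels:
            c = ch[lvl - 1]
            if cfg.variant in ("full", "am_subset"):
                self.register(f"iim_{lvl}", IIMBlock(rng, c, cfg.lambda1, cfg.lambda2))
            else:  # no_iim and single-task variants
                for t in self.tasks:
                    self.register(f"own_{t}_{lvl}", OwnPath(rng, c))

    # -- forward passes -----------------------------------------------------
    def forward_shared(self, x) -> list[Tensor]:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if t.ndim != 4 or t.shape[1] != 3:
            raise ValueError(f"expected NCHW input with 3 channels, got {t.shape}")
        if t.shape[2] != self.cfg.input_side or t.shape[3] != self.cfg.input_side:
            raise ValueError(
                f"input side {t.shape[2]}x{t.shape[3]} does not match configured "
                f"{self.cfg.input_side}")
        return self.backbone(t)

    def forward_tensors(self, x) -> dict[str, Tensor]:
        """Forward pass returning per-task logit tensors (graph retained).

        Also stashes the final attention output of each branch on
        ``self.last_branch_feature`` for Grad-CAM.
        """
        taps = self.forward_shared(x)
        self.last_branch_feature: dict[str, Tensor] = {}
        self.branch_features: dict[str, dict[int, Tensor]] = {t: {} for t in self.tasks}
        cfg = self.cfg
        if cfg.variant == "osn":
            out = {}
            for t in self.tasks:
                self.last_branch_feature[t] = taps[-1]
                out[t] = getattr(self, f"head_{t}")(taps[-1])
            return out

        f_m_prev: dict[str, Tensor | None] = {t: None for t in self.tasks}
        f_m_cur: dict[str, Tensor] = {}
        for lvl in self.levels:
            f_i = taps[lvl - 1]
            f_prime = {t: getattr(self, f"am_{t}_{lvl}")(f_i, f_m_prev[t])
                       for t in self.tasks}
            if cfg.variant in ("full", "am_subset"):
                f_iim_m, f_iim_p = getattr(self, f"iim_{lvl}")(f_prime["m"], f_prime["p"])
                f_iim = {"m": f_iim_m, "p": f_iim_p}
            else:
                f_iim = {t: getattr(self, f"own_{t}_{lvl}")(f_prime[t])
                         for t in self.tasks}
            for t in self.tasks:
                f_m_cur[t] = AttentionStage.apply_mask(f_prime[t], f_iim[t])
                self.branch_features[t][lvl] = f_m_cur[t]
            f_m_prev = dict(f_m_cur)

        out = {}
        for t in self.tasks:
            self.last_branch_feature[t] = f_m_cur[t]
            out[t] = getattr(self, f"head_{t}")(f_m_cur[t])
        return out

    def forward(self, x) -> dict[str, TaskPrediction]:
        """Inference-style forward: numpy scores and softmax probabilities."""
        logits = self.forward_tensors(x)
        preds = {}
        for t, z in logits.items():
            preds[t] = TaskPrediction(scores=z.data.copy(),
                                      probs=z.softmax(axis=1).data.copy())
        return preds

    # -- bookkeeping ---------------------------------------------------------
    def attention_module_count(self) -> int:
        return sum(1 for name, _ in self._modules.items() if name.startswith("am_"))

    def iim_block_count(self) -> int:
        return sum(1 for name, _ in self._modules.items() if name.startswith("iim_"))

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_model(cfg: ModelConfig) -> MultitaskAttentionNet:
    return MultitaskAttentionNet(cfg)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(model: MultitaskAttentionNet, path: str | Path,
                    extra: dict | None = None) -> Path:
    """Named-parameter archive (.npz) + sidecar JSON model config."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, **state)
    meta = {"model_config": json.loads(model.cfg.to_json())}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_checkpoint(path: str | Path) -> tuple[MultitaskAttentionNet, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**{**meta["model_config"],
                         "am_levels": tuple(meta["model_config"]["am_levels"])})
    model = MultitaskAttentionNet(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model, meta
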