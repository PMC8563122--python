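"""Grad-CAM per task branch, and a mask-based localization score.

The target layer is branch-specific, so the two tasks yield distinct maps.
By default it is the deepest attention-module output of the requested
branch whose feature grid still has spatial support of at least
``MIN_CAM_GRID`` (4) on a side; at full 460-pixel input this is the final
attention module (a 15×15 grid), while at reduced test scales — where the
final module collapses to 2×2 and a gradient-weighted map carries no usable
spatial information — it backs off to the deepest module that can still
resolve structure.  Pass ``level`` to override.  Channel weights are the
spatial means of the class score's gradient at that layer; the heatmap is
the rectified weighted channel sum, bilinearly upsampled to the input and
max-normalized to [0, 1].

Localization against a ground-truth lesion mask is scored as a soft
contrast ratio, mean(heatmap inside mask) / (mean inside + mean outside):
0.5 means no localization, 1.0 means all heat sits on the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, _bilinear_matrix
from .model import MultitaskAttentionNet

MIN_CAM_GRID = 4  # smallest feature-grid side on which a CAM is meaningful


@dataclass
class CamMap:
    heatmap: np.ndarray  # input-side H×W in [0, 1]
    task: str
    class_index: int
    level: int           # attention level the map was taken from (0 = shared trunk)
    raw: np.ndarray      # feature-resolution map before upsampling


def _default_level(model: MultitaskAttentionNet, task: str) -> int:
    """Deepest branch level whose grid side is >= MIN_CAM_GRID (else the last)."""
    feats = model.branch_features.get(task, {})
    if not feats:
        return 0  # osn variant: shared trunk output
    candidates = [lvl for lvl, f in feats.items() if min(f.shape[2:]) >= MIN_CAM_GRID]
    return max(candidates) if candidates else max(feats)


def grad_cam(model: MultitaskAttentionNet, image: np.ndarray, task: str, class_index: int = 1,
             level: int | None = None) -> CamMap:
    """Class-activation map of one image for one task branch.

    ``image`` is (3, S, S) or (1, 3, S, S) float32 in [0, 1].  ``level``
    picks the attention module whose output is inspected; default is the
    deepest one with adequate spatial support (see module docstring).
    """
    if task not in model.tasks:
        raise ValueError(f"task {task!r} not present in this model "
                         f"(variant {model.cfg.variant!r} has {model.tasks})")
    if class_index not in range(model.cfg.num_classes_per_task):
        raise ValueError(f"class_index must be in 0..{model.cfg.num_classes_per_task - 1}")
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    model.eval()
    logits = model.forward_tensors(x)
    if level is None:
        level = _default_level(model, task)
    if level == 0:
        target = model.last_branch_feature[task]
    else:
        if level not in model.branch_features.get(task, {}):
            raise ValueError(f"no attention module at level {level} for task {task!r}")
        target = model.branch_features[task][level]
    score = logits[task][:, class_index].sum()
    score.backward()
    grad = target.grad.reshape(target.shape)  # (1, C, h, w)
    act = target.data
    weights = grad.mean(axis=(2, 3), keepdims=True)  # spatial mean per channel
    raw = np.maximum((weights * act).sum(axis=1)[0], 0.0)  # rectified sum
    side = x.shape[2]
    a = _bilinear_matrix(side, raw.shape[0])
    b = _bilinear_matrix(side, raw.shape[1])
    heat = a @ raw @ b.T
    peak = heat.max()
    if peak > 0:
        heat = heat / peak
    return CamMap(heatmap=heat.astype(np.float32), task=task,
                  class_index=class_index, level=level, raw=raw.astype(np.float32))


def localization_score(cam: CamMap | np.ndarray, gt_mask: np.ndarray) -> float:
    """Mean-contrast overlap of a heatmap with a binary mask, in [0, 1]."""
    heat = cam.heatmap if isinstance(cam, CamMap) else np.asarray(cam, dtype=float)
    mask = np.asarray(gt_mask).astype(bool)
    if heat.shape != mask.shape:
        raise ValueError(f"shape mismatch: heatmap {heat.shape} vs mask {mask.shape}")
    if not mask.any():
        raise ValueError("localization_score: empty ground-truth mask")
    inside = float(heat[mask].mean())
    outside = float(heat[~mask].mean()) if (~mask).any() else 0.0
    if inside + outside == 0.0:
        return 0.5  # identically zero map carries no localization signal
    return inside / (inside + outside)


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Blend a heatmap over an H×W×3 uint8 image (red = hot) for export."""
    img = np.asarray(image, dtype=np.float32)
    h = np.clip(np.asarray(heatmap, dtype=np.float32), 0, 1)
    color = np.stack([255 * h, 64 * h, np.zeros_like(h)], axis=-1)
    out = (1 - alpha * h[..., None]) * img + alpha * h[..., None] * color
    return np.clip(out, 0, 255).astype(np.uint8)
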