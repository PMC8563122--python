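"""Training loop, evaluation metrics and the ablation harness.

Metrics follow the usual confusion-matrix definitions with decision
threshold 0.5 on the positive-class probability:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2·TP / (2·TP + FN + FP)

plus the AUC (Mann-Whitney statistic with ties counted one half).  Training
uses minibatch Adam under the step learning-rate schedule, and the saved
checkpoint is the epoch with the minimum total loss on the validation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import roc_auc_score

from .autograd import Tensor
from .losses import ScheduleConfig, UncertaintyWeights, lr_at, task_loss, total_loss
from .model import MultitaskAttentionNet, ModelConfig, build_model
from .nn import Adam
from .patches import dataset_psize_stats, extract_patch, resize_patch
from .records import RecordSet, SplitResult


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def confusion_counts(predictions, labels) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for binary predictions against binary labels."""
    pr = np.asarray(predictions).astype(int)
    la = np.asarray(labels).astype(int)
    if pr.shape != la.shape:
        raise ValueError(f"length mismatch: {pr.shape} vs {la.shape}")
    tp = int(np.sum((pr == 1) & (la == 1)))
    tn = int(np.sum((pr == 0) & (la == 0)))
    fp = int(np.sum((pr == 1) & (la == 0)))
    fn = int(np.sum((pr == 0) & (la == 1)))
    return tp, tn, fp, fn


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0.0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: tuple[int, int, int, int]) -> dict[str, float]:
    tp, tn, fp, fn = counts
    if tp + tn + fp + fn <= 0:
        raise ValueError("compute_metrics needs at least one evaluated record")
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": _safe_div(tp + tn, tp + fp + tn + fn, "accuracy"),
        "sensitivity": _safe_div(tp, tp + fn, "sensitivity"),
        "specificity": _safe_div(tn, tn + fp, "specificity"),
        "f1": _safe_div(2 * tp, 2 * tp + fn + fp, "f1"),
    }


def auc_score(scores, labels) -> float:
    """AUC of the positive-class probability (tie-corrected Mann-Whitney)."""
    la = np.asarray(labels).astype(int)
    if la.min() == la.max():
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(la, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    per_task: dict[str, dict[str, float]]  # task -> counts + derived metrics (incl. auc)
    losses: dict[str, float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------

def _transform_mask(mask: np.ndarray, landmarks, patch_size: int, side: int) -> np.ndarray:
    patch = extract_patch(mask.astype(np.uint8) * 255, landmarks, patch_size)
    if patch.shape[0] != side:
        patch = np.asarray(Image.fromarray(patch).resize((side, side), Image.NEAREST))
    return patch > 127


def prepare_arrays(rs: RecordSet, patch_size: int | None = None,
                   input_side: int = 64, with_masks: bool = False) -> dict:
    """Records -> network-ready arrays.

    Crops each image to the dataset patch size (chosen from the P_size
    distribution when not given), resizes to ``input_side``, and scales to
    [0, 1] float32 NCHW.  Ground-truth masks, when requested, follow the
    identical geometry with nearest-neighbour resizing.
    """
    if len(rs) == 0:
        raise ValueError("prepare_arrays: empty record set")
    if patch_size is None:
        patch_size = dataset_psize_stats(rs).chosen_global_size
    xs, ym, yp, mm, mp = [], [], [], [], []
    for r in rs:
        img = r.load_image()
        patch = extract_patch(img, r.landmarks, patch_size)
        patch = resize_patch(patch, input_side)
        xs.append(np.transpose(patch.astype(np.float32) / 255.0, (2, 0, 1)))
        ym.append(r.label_m)
        yp.append(r.label_p)
        if with_masks:
            mm.append(_transform_mask(r.gt_mask_m, r.landmarks, patch_size, input_side)
                      if r.gt_mask_m is not None else None)
            mp.append(_transform_mask(r.gt_mask_p, r.landmarks, patch_size, input_side)
                      if r.gt_mask_p is not None else None)
    out = {"x": np.stack(xs), "y_m": np.asarray(ym), "y_p": np.asarray(yp),
           "patch_size": patch_size, "record_ids": [r.record_id for r in rs]}
    if with_masks:
        out["mask_m"] = mm
        out["mask_p"] = mp
    return out


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 30
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    seed: int = 0
    input_side: int | None = None  # default: model's configured side


@dataclass
class TrainHistory:
    epochs: list[dict]  # per epoch: losses, lr, eta values, val metrics
    best_epoch: int     # 1-based epoch attaining the minimum val total loss

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def _forward_losses(model: MultitaskAttentionNet, x: np.ndarray, y_m: np.ndarray, y_p: np.ndarray,
                    weights: UncertaintyWeights | None):
    logits = model.forward_tensors(x)
    probs = {t: z.softmax(axis=1) for t, z in logits.items()}
    losses: dict[str, Tensor] = {}
    for t, ys in (("m", y_m), ("p", y_p)):
        if t in probs:
            losses[t] = task_loss(probs[t][:, 1], ys)
    if len(losses) == 2:
        if weights is None:  # evaluation without learned weights: σ² = 1
            weights = UncertaintyWeights()
        tot = total_loss(losses["p"], losses["m"], weights)  # L_h = task P, L_k = task M
    else:
        tot = next(iter(losses.values()))
    return tot, losses, probs


def evaluate_model(model: MultitaskAttentionNet, data: dict,
                   weights: UncertaintyWeights | None = None) -> MetricsReport:
    """Eval-mode metrics (and losses) on prepared arrays."""
    model.eval()
    tot, losses, probs = _forward_losses(model, data["x"], data["y_m"], data["y_p"], weights)
    report = MetricsReport(per_task={}, losses={"total": float(tot.data)})
    for t in probs:
        y = data[f"y_{t}"]
        p_pos = probs[t].data[:, 1]
        preds = (probs[t].data.argmax(axis=1)).astype(int)
        entry = compute_metrics(confusion_counts(preds, y))
        try:
            entry["auc"] = auc_score(p_pos, y)
        except ValueError:
            entry["auc"] = float("nan")
        report.per_task[t] = entry
        report.losses[f"task_{t}"] = float(losses[t].data)
    return report


def train(model: MultitaskAttentionNet, splits: SplitResult | dict, config: TrainConfig,
          verbose: bool = False) -> tuple[dict, TrainHistory]:
    """Train with minibatch Adam; return (best state_dict, history).

    ``splits`` is either a :class:`SplitResult` or a dict with prepared
    ``{"train": arrays, "val": arrays}`` (see :func:`prepare_arrays`).
    The checkpointed state is the epoch minimizing validation total loss.
    """
    side = config.input_side or model.cfg.input_side
    if isinstance(splits, SplitResult):
        tr = prepare_arrays(splits.train, input_side=side)
        va = prepare_arrays(splits.val, patch_size=tr["patch_size"], input_side=side)
    else:
        tr, va = splits["train"], splits["val"]
    if len(tr["y_m"]) == 0 or len(va["y_m"]) == 0:
        raise ValueError("train and validation sets must be non-empty")

    multitask = len(model.tasks) == 2
    weights = UncertaintyWeights() if multitask else None
    params = model.parameters() + (weights.parameters() if weights else [])
    sched = config.schedule
    opt = Adam(params, lr=sched.l0, beta1=sched.beta1, beta2=sched.beta2,
               weight_decay=sched.weight_decay)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x7124])

    n = tr["x"].shape[0]
    history: list[dict] = []
    best = {"epoch": -1, "loss": np.inf, "state": None, "eta": None}
    for epoch in range(1, config.epochs + 1):
        lr = lr_at(epoch, sched)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        ep_losses = []
        for start in range(0, n, sched.batch_size):
            idx = order[start:start + sched.batch_size]
            tot, _, _ = _forward_losses(model, tr["x"][idx], tr["y_m"][idx],
                                        tr["y_p"][idx], weights)
            if not np.isfinite(tot.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} (lr={lr}); aborting")
            opt.zero_grad()
            tot.backward()
            opt.step()
            ep_losses.append(float(tot.data))
        report = evaluate_model(model, va, weights)
        entry = {"epoch": epoch, "lr": lr,
                 "train_total_loss": float(np.mean(ep_losses)),
                 "val_total_loss": report.losses["total"]}
        for t in model.tasks:
            entry[f"val_loss_{t}"] = report.losses[f"task_{t}"]
            entry[f"val_accuracy_{t}"] = report.per_task[t]["accuracy"]
        if weights is not None:
            entry["eta_h"] = float(weights.eta_h.data)
            entry["eta_k"] = float(weights.eta_k.data)
        history.append(entry)
        if verbose:
            msg = " ".join(f"{k}={v:.4g}" for k, v in entry.items() if k != "epoch")
            print(f"[epoch {epoch:3d}] {msg}")
        if report.losses["total"] < best["loss"]:
            best = {"epoch": epoch, "loss": report.losses["total"],
                    "state": model.state_dict(),
                    "eta": (entry.get("eta_h"), entry.get("eta_k"))}
    model.load_state_dict(best["state"])
    return best["state"], TrainHistory(epochs=history, best_epoch=best["epoch"])


# --------------------------------------------------------------------------
# ablation harness
# --------------------------------------------------------------------------

def am_subset_grid() -> list[ModelConfig]:
    """The 15 attention-level combinations: 4 One-AM, 6 Two-AM, 4 Three-AM,
    and the full four-module cascade."""
    from itertools import combinations
    grid = []
    for k in (1, 2, 3):
        for combo in combinations((1, 2, 3, 4), k):
            grid.append(ModelConfig(variant="am_subset", am_levels=combo))
    grid.append(ModelConfig(variant="full"))
    return grid


def run_ablation(variants: list[ModelConfig], splits: SplitResult | dict,
                 config: TrainConfig, seeds: list[int],
                 verbose: bool = False) -> pd.DataFrame:
    """Train/evaluate every variant × seed; one result row each.

    Rows carry component indicator columns (am1..am4 — which attention
    levels the variant uses) followed by per-task metric columns
    (``accuracy_m``, ``auc_p``, ...); a task absent from a single-task
    variant reports NaN.
    """
    if not variants or not seeds:
        raise ValueError("need at least one variant and one seed")
    side = config.input_side or variants[0].input_side
    if isinstance(splits, SplitResult):
        tr = prepare_arrays(splits.train, input_side=side)
        va = prepare_arrays(splits.val, patch_size=tr["patch_size"], input_side=side)
        splits = {"train": tr, "val": va}
    rows = []
    for vc in variants:
        for seed in seeds:
            cfg = ModelConfig(preset=vc.preset, input_side=vc.input_side,
                              variant=vc.variant, am_levels=vc.am_levels,
                              lambda1=vc.lambda1, lambda2=vc.lambda2, seed=seed)
            model = build_model(cfg)
            tcfg = TrainConfig(epochs=config.epochs, schedule=config.schedule,
                               seed=seed, input_side=side)
            _, hist = train(model, splits, tcfg, verbose=verbose)
            report = evaluate_model(model, splits["val"])
            used = set(cfg.am_levels) if cfg.variant != "osn" else set()
            row = {"variant": cfg.variant, "seed": seed, "best_epoch": hist.best_epoch}
            for lvl in (1, 2, 3, 4):
                row[f"am{lvl}"] = int(lvl in used)
            for t in ("m", "p"):
                metrics = report.per_task.get(t, {})
                for k in ("accuracy", "sensitivity", "specificity", "f1", "auc"):
                    row[f"{k}_{t}"] = metrics.get(k, float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)
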