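"""Per-task losses, homoscedastic-uncertainty task weighting, and schedules.

Each task contributes a binary cross-entropy on its positive-class softmax
probability.  The two task losses are combined with learnable observation
noises σ_h (task P) and σ_k (task M):

    L_total = 1/(2σ_h²) L_h + 1/(2σ_k²) L_k + log σ_h² + log σ_k²

parameterized as η = log σ² so the optimization is unconstrained.  The
coefficient of the log terms is kept exactly as stated (no extra ½).

The learning rate is a five-plateau step schedule on the base rate l0:
l0 on epochs [0, 100], ×0.5 on (100, 150], ×0.1 on (150, 250], ×0.01 on
(250, 400], ×0.001 beyond 400.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor

EPS = 1e-7


class UncertaintyWeights:
    """Learnable η_h, η_k (= log σ²) scalars for the two-task loss."""

    def __init__(self, eta_h: float = 0.0, eta_k: float = 0.0):
        # float64: the log-variance scalars need finer granularity than the
        # float32 tensor default for the closed-form optimum to be resolvable
        self.eta_h = Tensor(np.asarray(eta_h, dtype=np.float64), requires_grad=True)
        self.eta_k = Tensor(np.asarray(eta_k, dtype=np.float64), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.eta_h, self.eta_k]

    @property
    def sigma2_h(self) -> float:
        return float(np.exp(self.eta_h.data))

    @property
    def sigma2_k(self) -> float:
        return float(np.exp(self.eta_k.data))


def task_loss(p_pos: Tensor | np.ndarray, y: np.ndarray) -> Tensor:
    """Batch-mean binary cross-entropy on the positive-class probability."""
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    p = p_pos if isinstance(p_pos, Tensor) else Tensor(np.asarray(p_pos))
    y = y.astype(np.float32).reshape(p.shape)
    pc = p.clip(EPS, 1.0 - EPS)
    ll = Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()
    return -ll.mean()


def total_loss(loss_h: Tensor | float, loss_k: Tensor | float,
               w: UncertaintyWeights) -> Tensor:
    """Uncertainty-weighted sum: ½e^(−η_h)L_h + ½e^(−η_k)L_k + η_h + η_k."""
    lh = loss_h if isinstance(loss_h, Tensor) else Tensor(np.asarray(loss_h, dtype=np.float64))
    lk = loss_k if isinstance(loss_k, Tensor) else Tensor(np.asarray(loss_k, dtype=np.float64))
    half = 0.5
    return ((-w.eta_h).exp() * lh * half + (-w.eta_k).exp() * lk * half
            + w.eta_h + w.eta_k)


@dataclass
class ScheduleConfig:
    l0: float = 0.01
    # (upper epoch bound inclusive, multiplier); last multiplier held beyond
    pieces: tuple[tuple[int, float], ...] = (
        (100, 1.0), (150, 0.5), (250, 0.1), (400, 0.01), (500, 0.001))
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0
    batch_size: int = 32
    max_epochs: int = 500

    def __post_init__(self):
        mults = [m for _, m in self.pieces]
        if any(m <= 0 for m in mults) or any(a < b for a, b in zip(mults, mults[1:])):
            raise ValueError("schedule multipliers must be positive and non-increasing")


def lr_at(s: int | float, cfg: ScheduleConfig | None = None) -> float:
    """Learning rate at schedule step (epoch) ``s``.

    The first plateau is boundary-inclusive on both sides; later pieces are
    (lo, hi].  Beyond the final breakpoint the last multiplier is held.
    """
    if cfg is None:
        cfg = ScheduleConfig()
    if s < 0:
        raise ValueError(f"schedule step must be >= 0, got {s}")
    for bound, mult in cfg.pieces:
        if s <= bound:
            return cfg.l0 * mult
    return cfg.l0 * cfg.pieces[-1][1]
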