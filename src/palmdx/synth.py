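"""Synthetic palm-image generator with planted, task-specific lesions.

Each record is a small RGB frame holding an elliptical "palm" whose
bounding landmarks (X1, X2, Y1, Y2) are returned alongside the image.  The
two binary labels plant soft-edged dark lesions in anatomically distinct
regions: knuckle-line swelling (task M) sits on the upper band of the palm,
thenar hypertrophy (task P) on the lower-lateral third near the thumb
boundary.  Ground-truth masks mark the planted pixels so attention
localization can be scored.  Landmark extents default to the clinical
statistics ΔX ~ N(423, 16.26²), ΔY ~ N(439, 27.15²) expressed as a fraction
of a 1200-pixel capture frame and rescaled to the configured image side.

Every record is generated from an independent substream derived from
(seed, record index), so datasets are reproducible regardless of the order
records are materialized in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import HandRecord, RecordSet

# Landmark-extent statistics of the clinical capture rig (1200 px frame).
_REF_FRAME = 1200.0
_REF_DELTA_MEAN = (423.0, 439.0)  # (ΔX, ΔY)
_REF_DELTA_SD = (16.26, 27.15)

# Exclusion-criterion frequencies used for contaminant flags.
_FLAG_WEIGHTS = {"peeling": 122, "scar": 98, "not_unfolded": 35}


class GeneratorConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    image_side: int = 64
    n_records: int = 400
    # proportions over (m, p) in the order (0,0), (0,1), (1,0), (1,1);
    # defaults follow the observed four-combination class balance.
    class_proportions: tuple[float, float, float, float] = (
        537 / 2159, 530 / 2159, 522 / 2159, 570 / 2159)
    delta_mean: tuple[float, float] | None = None  # pixels (ΔX, ΔY); None = scaled defaults
    delta_sd: tuple[float, float] | None = None
    lesion_contrast: float = 0.5
    lesion_radius: float | None = None  # pixels; None = 0.18 * min mean delta
    noise_sd: float = 0.1
    contaminant_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_side < 16:
            raise GeneratorConfigError("image_side must be >= 16")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (4,) or not np.isclose(props.sum(), 1.0, atol=1e-6):
            raise GeneratorConfigError("class_proportions must be 4 fractions summing to 1")
        if self.delta_mean is None:
            s = self.image_side / _REF_FRAME
            self.delta_mean = (_REF_DELTA_MEAN[0] * s, _REF_DELTA_MEAN[1] * s)
            if self.delta_sd is None:
                self.delta_sd = (_REF_DELTA_SD[0] * s, _REF_DELTA_SD[1] * s)
        if self.delta_sd is None:
            self.delta_sd = (0.03 * self.delta_mean[0], 0.06 * self.delta_mean[1])
        if self.lesion_radius is None:
            self.lesion_radius = 0.18 * min(self.delta_mean)
        if not (0 <= self.contaminant_rate < 1):
            raise GeneratorConfigError("contaminant_rate must be in [0, 1)")
        if self.lesion_contrast < 0 or self.noise_sd < 0:
            raise GeneratorConfigError("lesion_contrast and noise_sd must be >= 0")
        # M sits on the upper quarter band (rows 0.08..0.22 of palm height),
        # P on the lower-lateral third (0.72..0.90): keep the discs disjoint
        # under worst-case jitter.
        min_dy = self.delta_mean[1] - 3 * self.delta_sd[1]
        separation = 0.50 * min_dy
        if 2 * self.lesion_radius >= separation:
            raise GeneratorConfigError(
                f"lesion_radius {self.lesion_radius:.1f}px cannot keep the knuckle and "
                f"thenar regions disjoint (need < {separation / 2:.1f}px)")


def _lesion_profile(side: int, centre: tuple[float, float], radius: float) -> np.ndarray:
    """Soft-edged plateau disc: amplitude 1 at centre, 0.5 at ``radius``.

    A super-Gaussian (exponent 4) keeps the interior near full contrast —
    like a raised swelling — while the edge still rolls off smoothly.
    """
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    d = np.sqrt((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2)
    sigma = radius / (2.0 * np.log(2.0)) ** 0.25
    return np.exp(-0.5 * (d / sigma) ** 4)


def generate_record(cfg: GeneratorConfig, labels: tuple[int, int], seed: int,
                    record_id: str | None = None,
                    flags: frozenset = frozenset()) -> HandRecord:
    """Render one synthetic record; fully determined by ``seed``."""
    m, p = labels
    if m not in (0, 1) or p not in (0, 1):
        raise ValueError(f"labels must be binary, got {labels}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5A17])
    side = cfg.image_side

    dx = float(np.clip(rng.normal(cfg.delta_mean[0], cfg.delta_sd[0]),
                       6.0, side - 2.0))
    dy = float(np.clip(rng.normal(cfg.delta_mean[1], cfg.delta_sd[1]),
                       6.0, side - 2.0))
    # palm centre jittered around the frame centre
    cx = side / 2.0 + rng.uniform(-0.03, 0.03) * side
    cy = side / 2.0 + rng.uniform(-0.03, 0.03) * side
    cx = float(np.clip(cx, dx / 2 + 1, side - dx / 2 - 1))
    cy = float(np.clip(cy, dy / 2 + 1, side - dy / 2 - 1))
    x1, x2 = cx + dx / 2.0, cx - dx / 2.0
    y1, y2 = cy + dy / 2.0, cy - dy / 2.0

    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    r_ell = np.sqrt(((cc - cx) / (dx / 2.0)) ** 2 + ((rr - cy) / (dy / 2.0)) ** 2)
    palm = np.clip((1.0 - r_ell) / 0.08 + 0.5, 0.0, 1.0)  # soft-edged ellipse

    # Per-record global brightness is a nuisance: it varies more than the
    # image-wide mean shift a single lesion causes, so neither task is
    # solvable from global statistics — only from the lesion regions.
    bg = 0.10 + rng.uniform(-0.04, 0.04)
    skin = 0.42 + rng.uniform(-0.08, 0.08)
    v = bg + (skin - bg) * palm

    gt_m = np.zeros((side, side), dtype=bool)
    gt_p = np.zeros((side, side), dtype=bool)
    lesion = np.zeros((side, side), dtype=np.float64)
    if m:
        # knuckle line: anywhere on the upper quarter band of the palm
        lc_r = y2 + rng.uniform(0.08, 0.22) * dy
        lc_c = cx + rng.uniform(-0.28, 0.28) * dx
        prof = _lesion_profile(side, (lc_r, lc_c), cfg.lesion_radius)
        lesion += cfg.lesion_contrast * prof
        gt_m = prof >= 0.5
    if p:
        # thenar: lower-lateral third, toward the thumb boundary X1
        lc_r = y2 + rng.uniform(0.72, 0.90) * dy
        lc_c = x1 - rng.uniform(0.18, 0.32) * dx
        prof = _lesion_profile(side, (lc_r, lc_c), cfg.lesion_radius)
        lesion += cfg.lesion_contrast * prof
        gt_p = prof >= 0.5
    v = v + lesion * palm  # lesions brighten palm tissue only

    # mild channel tint so images are genuinely RGB
    img = np.stack([v * 1.08, v * 0.95, v * 0.88], axis=-1)
    img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img8 = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)

    return HandRecord(
        record_id=record_id or f"synth-{seed:08d}",
        image_ref=img8, x1=x1, x2=x2, y1=y1, y2=y2,
        label_m=m, label_p=p, flags=flags,
        gt_mask_m=gt_m if m else np.zeros((side, side), dtype=bool),
        gt_mask_p=gt_p if p else np.zeros((side, side), dtype=bool))


def _apportion(props: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` among ``props``."""
    exact = props * n
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(exact - np.floor(exact)), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_dataset(cfg: GeneratorConfig) -> RecordSet:
    """Generate ``cfg.n_records`` records with the configured class balance.

    Class counts follow largest-remainder apportionment of the proportions;
    a ``contaminant_rate`` fraction of records carries a random exclusion
    flag (frequencies matching the study's exclusion tally).
    """
    if cfg.n_records < 1:
        raise GeneratorConfigError("n_records must be >= 1")
    combos = [(0, 0), (0, 1), (1, 0), (1, 1)]
    counts = _apportion(np.asarray(cfg.class_proportions, dtype=float), cfg.n_records)
    labels: list[tuple[int, int]] = []
    for combo, k in zip(combos, counts):
        labels.extend([combo] * int(k))

    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xDA7A])
    order = rng.permutation(len(labels))
    n_flagged = int(round(cfg.contaminant_rate * cfg.n_records))
    flagged = set(rng.choice(cfg.n_records, size=n_flagged, replace=False).tolist()) \
        if n_flagged else set()
    flag_names = sorted(_FLAG_WEIGHTS)
    flag_p = np.asarray([_FLAG_WEIGHTS[f] for f in flag_names], dtype=float)
    flag_p /= flag_p.sum()

    records = []
    for idx in range(cfg.n_records):
        lab = labels[order[idx]]
        flags = frozenset()
        if idx in flagged:
            flags = frozenset({str(rng.choice(flag_names, p=flag_p))})
        rec = generate_record(cfg, lab, seed=(cfg.seed * 100003 + idx) & 0x7FFFFFFF,
                              record_id=f"synth-{idx:05d}", flags=flags)
        records.append(rec)
    return RecordSet(records, provenance="synthetic")
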