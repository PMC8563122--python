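"""Landmark-based palm-patch extraction.

From the four annotated landmarks the palm extent is ΔX = X1 − X2 (columns)
and ΔY = Y1 − Y2 (rows); the patch side P_size = max(ΔX, ΔY), rounded up.
A dataset-level patch size is then chosen as a coverage quantile of the
per-record P_size distribution (optionally capped), and each image is
cropped to a square of that side centred on the landmark bounding-box
midpoint, zero-padding anything outside the frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .records import RecordSet


class LandmarkConventionError(ValueError):
    pass


@dataclass
class PatchSpec:
    delta_x: float
    delta_y: float
    p_size: int
    crop_box: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open


@dataclass
class PsizeStats:
    p_sizes: list[int]
    histogram: tuple[list[int], list[float]]  # (counts, bin edges)
    chosen_global_size: int
    coverage: float


def compute_deltas(x1: float, x2: float, y1: float, y2: float) -> tuple[float, float]:
    dx = x1 - x2
    dy = y1 - y2
    if dx <= 0 or dy <= 0:
        raise LandmarkConventionError(
            f"landmark deltas must be positive (x1 > x2, y1 > y2); got ΔX={dx}, ΔY={dy}")
    return dx, dy


def compute_psize(delta_x: float, delta_y: float) -> int:
    """Patch side: the larger landmark delta, rounded up to an integer."""
    if delta_x <= 0 or delta_y <= 0:
        raise LandmarkConventionError("deltas must be positive")
    return int(math.ceil(max(delta_x, delta_y)))


def dataset_psize_stats(rs: RecordSet, coverage: float = 1.0,
                        hard_limit: int | None = None,
                        n_bins: int = 20) -> PsizeStats:
    """Choose a dataset-level patch side covering ``coverage`` of records.

    ``chosen_global_size`` is the smallest integer at or above the
    ``coverage``-quantile of per-record P_size values, optionally capped at
    ``hard_limit`` (mirroring a "most samples are below L" cut).
    """
    if len(rs) == 0:
        raise ValueError("dataset_psize_stats: empty record set")
    if not (0.0 < coverage <= 1.0):
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    p_sizes = [compute_psize(*compute_deltas(*r.landmarks)) for r in rs]
    arr = np.asarray(p_sizes, dtype=float)
    q = float(np.quantile(arr, coverage, method="inverted_cdf"))
    chosen = int(math.ceil(q))
    if hard_limit is not None:
        chosen = min(chosen, int(hard_limit))
    counts, edges = np.histogram(arr, bins=n_bins)
    return PsizeStats(p_sizes=p_sizes, histogram=(counts.tolist(), edges.tolist()),
                      chosen_global_size=chosen, coverage=coverage)


def patch_spec(landmarks: tuple[float, float, float, float],
               size: int | None = None) -> PatchSpec:
    """Crop geometry for one record: square of side ``size`` (default the
    record's own P_size) centred on the landmark bounding-box midpoint."""
    x1, x2, y1, y2 = landmarks
    dx, dy = compute_deltas(x1, x2, y1, y2)
    p = compute_psize(dx, dy)
    side = int(size) if size is not None else p
    cr = (y1 + y2) / 2.0  # row centre
    cc = (x1 + x2) / 2.0  # col centre
    row_min = int(math.floor(cr - side / 2.0))
    col_min = int(math.floor(cc - side / 2.0))
    return PatchSpec(delta_x=dx, delta_y=dy, p_size=p,
                     crop_box=(row_min, col_min, row_min + side, col_min + side))


def extract_patch(image: np.ndarray,
                  landmarks: tuple[float, float, float, float],
                  size: int) -> np.ndarray:
    """Crop a ``size``×``size`` patch centred on the palm; zero-pad outside.

    ``image`` is H×W×C (or H×W); the dtype is preserved.
    """
    if size < 1:
        raise ValueError(f"patch size must be >= 1, got {size}")
    h, w = image.shape[:2]
    x1, x2, y1, y2 = landmarks
    if x2 >= w or x1 < 0 or y2 >= h or y1 < 0:
        raise ValueError("landmarks lie entirely outside the image")
    spec = patch_spec(landmarks, size=size)
    r0, c0, r1, c1 = spec.crop_box
    out_shape = (size, size) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    sr0, sr1 = max(r0, 0), min(r1, h)
    sc0, sc1 = max(c0, 0), min(c1, w)
    if sr0 < sr1 and sc0 < sc1:
        out[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = image[sr0:sr1, sc0:sc1]
    return out


def resize_patch(patch: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize of an H×W×3 uint8 patch to ``side``×``side``."""
    if patch.shape[0] == side and patch.shape[1] == side:
        return patch
    im = Image.fromarray(patch)
    return np.asarray(im.resize((side, side), Image.BILINEAR))
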