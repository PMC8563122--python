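"""Dataset records, manifest I/O, exclusion rules and stratified splitting.

A record is one palm photograph with four hand-annotated landmark
coordinates bounding the palm (column coordinates ``x1 > x2``, row
coordinates ``y1 > y2``, origin top-left), two binary labels — ``label_m``
for metacarpophalangeal-joint (knuckle) swelling and ``label_p`` for
palmar-thenar hypertrophy — and optional quality flags that mark a record
for exclusion.  Synthetic records additionally carry ground-truth lesion
masks used to score attention localization.

Manifests are plain CSV (columns ``record_id, image_path, x1, x2, y1, y2,
label_m, label_p, flags``; flags semicolon-joined) with a JSON mirror.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

VALID_FLAGS = frozenset({"peeling", "scar", "not_unfolded"})

MANIFEST_COLUMNS = ["record_id", "image_path", "x1", "x2", "y1", "y2",
                    "label_m", "label_p", "flags"]


class ManifestSchemaError(ValueError):
    pass


class ManifestValidationError(ValueError):
    pass


@dataclass
class HandRecord:
    record_id: str
    image_ref: str | np.ndarray  # path or H×W×3 uint8 array
    x1: float
    x2: float
    y1: float
    y2: float
    label_m: int
    label_p: int
    flags: frozenset = field(default_factory=frozenset)
    gt_mask_m: np.ndarray | None = None
    gt_mask_p: np.ndarray | None = None

    def __post_init__(self):
        if self.label_m not in (0, 1):
            raise ManifestValidationError(
                f"record {self.record_id}: label_m must be 0 or 1, got {self.label_m}")
        if self.label_p not in (0, 1):
            raise ManifestValidationError(
                f"record {self.record_id}: label_p must be 0 or 1, got {self.label_p}")
        if not (self.x1 > self.x2 and self.y1 > self.y2):
            raise ManifestValidationError(
                f"record {self.record_id}: landmark convention requires x1 > x2 and "
                f"y1 > y2 (got x1={self.x1}, x2={self.x2}, y1={self.y1}, y2={self.y2})")
        unknown = set(self.flags) - VALID_FLAGS
        if unknown:
            raise ManifestValidationError(
                f"record {self.record_id}: unknown flags {sorted(unknown)}")
        self.flags = frozenset(self.flags)

    @property
    def landmarks(self) -> tuple[float, float, float, float]:
        return (self.x1, self.x2, self.y1, self.y2)

    def load_image(self) -> np.ndarray:
        """Return the H×W×3 uint8 image, reading from disk if needed."""
        if isinstance(self.image_ref, np.ndarray):
            return self.image_ref
        with Image.open(self.image_ref) as im:
            return np.asarray(im.convert("RGB"))

    @property
    def stratum(self) -> tuple[int, int]:
        return (self.label_m, self.label_p)


@dataclass
class RecordSet:
    records: list[HandRecord]
    provenance: str = "external"

    def __post_init__(self):
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestValidationError(f"duplicate record_ids: {dup}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ExclusionReport:
    counts: dict[str, int]
    n_input: int
    n_retained: int

    def to_json(self) -> str:
        return json.dumps({"counts": self.counts, "n_input": self.n_input,
                           "n_retained": self.n_retained}, indent=2)


@dataclass
class SplitResult:
    train: RecordSet
    val: RecordSet
    seed: int
    strata: list[tuple[int, int]]


def load_manifest(path: str | Path) -> RecordSet:
    """Load a CSV or JSON manifest into a :class:`RecordSet`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, dtype={"record_id": str, "flags": str},
                         keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(f"manifest {path} is missing columns: {missing}")
    base = path.parent
    records = []
    for row in df.itertuples(index=False):
        flags_raw = getattr(row, "flags") or ""
        if isinstance(flags_raw, float):  # JSON null
            flags_raw = ""
        flags = frozenset(f for f in str(flags_raw).split(";") if f)
        img = str(getattr(row, "image_path"))
        img_path = img if Path(img).is_absolute() else str(base / img)
        lm = int(getattr(row, "label_m"))
        lp = int(getattr(row, "label_p"))
        if float(getattr(row, "label_m")) != lm or float(getattr(row, "label_p")) != lp:
            raise ManifestValidationError(
                f"record {getattr(row, 'record_id')}: non-integer label")
        records.append(HandRecord(
            record_id=str(getattr(row, "record_id")),
            image_ref=img_path,
            x1=float(getattr(row, "x1")), x2=float(getattr(row, "x2")),
            y1=float(getattr(row, "y1")), y2=float(getattr(row, "y2")),
            label_m=lm, label_p=lp, flags=flags))
    return RecordSet(records, provenance="external")


def write_manifest(rs: RecordSet, path: str | Path, image_dir: str | Path | None = None) -> Path:
    """Write a manifest; in-memory images are saved as PNGs under ``image_dir``.

    Image paths are written relative to the manifest's directory when
    possible so the manifest directory is relocatable.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in rs:
        ref = r.image_ref
        if isinstance(ref, np.ndarray):
            if image_dir is None:
                image_dir = path.parent / "images"
            image_dir = Path(image_dir)
            image_dir.mkdir(parents=True, exist_ok=True)
            img_path = image_dir / f"{r.record_id}.png"
            Image.fromarray(ref).save(img_path)
            ref = str(img_path)
        try:
            ref_out = str(Path(ref).relative_to(path.parent))
        except ValueError:
            ref_out = str(ref)
        rows.append({"record_id": r.record_id, "image_path": ref_out,
                     "x1": r.x1, "x2": r.x2, "y1": r.y1, "y2": r.y2,
                     "label_m": r.label_m, "label_p": r.label_p,
                     "flags": ";".join(sorted(r.flags))})
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def apply_exclusions(rs: RecordSet) -> tuple[RecordSet, ExclusionReport]:
    """Drop records carrying any quality flag; report per-criterion counts.

    A record with several flags is counted once under each criterion but
    removed only once.  Order of retained records is preserved, so the
    operation is idempotent.
    """
    counts = {f: 0 for f in sorted(VALID_FLAGS)}
    retained = []
    for r in rs:
        for f in r.flags:
            counts[f] += 1
        if not r.flags:
            retained.append(r)
    report = ExclusionReport(counts=counts, n_input=len(rs), n_retained=len(retained))
    return RecordSet(retained, provenance=rs.provenance), report


def split_records(rs: RecordSet, train_fraction: float = 0.8, seed: int = 0) -> SplitResult:
    """Stratified train/validation split over the four (m, p) label combinations.

    Training quotas are apportioned to strata by the largest-remainder rule
    so that the total training count equals ``floor(n * train_fraction)``
    exactly while each stratum stays within one record of the global
    fraction.  A size-1 stratum always goes to training.  Shuffling within
    each stratum is driven by ``seed`` only.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    strata = [(m, p) for m in (0, 1) for p in (0, 1)]
    members = {s: [r for r in rs if r.stratum == s] for s in strata}
    sizes = np.array([len(members[s]) for s in strata])
    n = int(sizes.sum())
    eps = 1e-9
    target = int(np.floor(n * train_fraction + eps))
    exact = sizes * train_fraction
    quota = np.floor(exact + eps).astype(int)
    quota = np.where(sizes == 1, 1, quota)
    leftover = target - int(quota.sum())
    if leftover > 0:
        order = np.argsort(-(exact - np.floor(exact + eps)), kind="stable")
        for i in order:
            if leftover == 0:
                break
            if quota[i] < sizes[i]:
                quota[i] += 1
                leftover -= 1
    rng = np.random.default_rng(seed)
    train: list[HandRecord] = []
    val: list[HandRecord] = []
    for s, q in zip(strata, quota):
        group = members[s]
        if not group:
            continue
        order = rng.permutation(len(group))
        train.extend(group[i] for i in order[:q])
        val.extend(group[i] for i in order[q:])
    return SplitResult(train=RecordSet(train, provenance=rs.provenance),
                       val=RecordSet(val, provenance=rs.provenance),
                       seed=seed, strata=strata)
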