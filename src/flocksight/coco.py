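"""COCO-dialect annotation and results I/O, annotation QC, size histogram,
and keyframe sampling.

Annotation files are the standard COCO object-detection JSON: top-level
``images`` / ``annotations`` / ``categories`` lists; each annotation carries
``bbox`` as ``[x, y, w, h]`` and ``iscrowd``.  Results files are the COCO
results dialect: a JSON array of ``{image_id, category_id, bbox, score}``
objects, optionally extended with a ``provenance`` field.  Round trips are
lossless: unknown keys are preserved verbatim.

QC follows two curation rules for surveillance imagery: boxes too small for
a human to verify (strictly smaller than 5 px on either side) are removed,
and dense groups may be represented as one crowd-flagged box which is kept
regardless of size and excluded from per-individual recall accounting
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import BoundingBox, Detection, GroundTruth

__all__ = [
    "AnnotationSet",
    "QCReport",
    "SchemaError",
    "read_coco",
    "write_coco",
    "qc_filter",
    "size_histogram",
    "sample_keyframes",
    "read_results",
    "write_results",
]

DEFAULT_CATEGORIES = [{"id": 1, "name": "waterbird"}]


class SchemaError(ValueError):
    """Raised when a COCO file is missing a required key."""


@dataclass
class AnnotationSet:
    """In-memory COCO annotation file; raw dicts keep unknown fields."""

    images: list[dict] = field(default_factory=list)
    annotations: list[dict] = field(default_factory=list)
    categories: list[dict] = field(default_factory=lambda: [dict(c) for c in DEFAULT_CATEGORIES])
    extra: dict = field(default_factory=dict)

    def ground_truths(self, image_id: int | None = None) -> list[GroundTruth]:
        """Typed view of the annotations, optionally for one image."""
        out = []
        for a in self.annotations:
            if image_id is not None and a["image_id"] != image_id:
                continue
            x, y, w, h = a["bbox"]
            out.append(
                GroundTruth(
                    box=BoundingBox(x, y, w, h),
                    frame_id=a["image_id"],
                    crowd=bool(a.get("iscrowd", 0)),
                    id=a["id"],
                )
            )
        return out

    def image_ids(self) -> list[int]:
        return [im["id"] for im in self.images]

    def validate(self) -> None:
        ids = [a["id"] for a in self.annotations]
        if len(ids) != len(set(ids)):
            raise SchemaError("duplicate annotation ids")
        img_ids = set(self.image_ids())
        for a in self.annotations:
            if a["image_id"] not in img_ids:
                raise SchemaError(
                    f"annotation {a['id']} references unknown image_id "
                    f"{a['image_id']}"
                )


@dataclass
class QCReport:
    """Tallies of the annotation QC pass."""

    n_input: int
    n_removed_small: int
    n_crowd: int
    n_kept: int


def read_coco(path: str | Path) -> AnnotationSet:
    """Parse a COCO annotation JSON file into an :class:`AnnotationSet`."""
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("images", "annotations"):
        if key not in raw:
            raise SchemaError(f"missing required COCO key: {key!r}")
    for i, a in enumerate(raw["annotations"]):
        for key in ("id", "image_id", "bbox"):
            if key not in a:
                raise SchemaError(f"annotation index {i}: missing key {key!r}")
        if len(a["bbox"]) != 4:
            raise SchemaError(f"annotation index {i}: bbox must have 4 entries")
    cats = raw.get("categories", [dict(c) for c in DEFAULT_CATEGORIES])
    extra = {k: v for k, v in raw.items()
             if k not in ("images", "annotations", "categories")}
    aset = AnnotationSet(images=raw["images"], annotations=raw["annotations"],
                         categories=cats, extra=extra)
    aset.validate()
    return aset


def write_coco(aset: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` back to COCO JSON (lossless)."""
    doc = dict(aset.extra)
    doc["images"] = aset.images
    doc["annotations"] = aset.annotations
    doc["categories"] = aset.categories
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def qc_filter(
    aset: AnnotationSet, min_side: float = 5.0
) -> tuple[AnnotationSet, QCReport]:
    """Remove annotations strictly smaller than ``min_side`` on either side.

    Boxes of exactly ``min_side`` are kept.  Crowd-flagged annotations pass
    through regardless of size (they stand for whole groups, not single
    individuals) and are tallied separately.  Idempotent.
    """
    kept: list[dict] = []
    n_removed = 0
    n_crowd = 0
    for a in aset.annotations:
        crowd = bool(a.get("iscrowd", 0))
        _, _, w, h = a["bbox"]
        if crowd:
            n_crowd += 1
            kept.append(a)
        elif w < min_side or h < min_side:
            n_removed += 1
        else:
            kept.append(a)
    report = QCReport(
        n_input=len(aset.annotations),
        n_removed_small=n_removed,
        n_crowd=n_crowd,
        n_kept=len(kept),
    )
    out = AnnotationSet(
        images=list(aset.images),
        annotations=kept,
        categories=list(aset.categories),
        extra=dict(aset.extra),
    )
    return out, report


def size_histogram(
    aset: AnnotationSet, edges: Sequence[float] = (40.0,)
) -> tuple[np.ndarray, dict[float, float]]:
    """Histogram of annotation sizes against side-length edges.

    A box falls below edge ``e`` iff its area is below ``e**2`` (consistent
    with the small-object stratification).  Returns the per-bin counts
    (``len(edges) + 1`` bins) and the fraction of boxes below each edge.
    Raises on an empty annotation set (fractions undefined).
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or any(e <= 0 for e in edges):
        raise ValueError("edges must be positive and strictly increasing")
    if len(aset.annotations) == 0:
        raise ValueError("size_histogram of an empty annotation set")
    areas = np.array([a["bbox"][2] * a["bbox"][3] for a in aset.annotations])
    area_edges = np.array([e**2 for e in edges], dtype=float)
    counts = np.histogram(areas, bins=np.concatenate(([0.0], area_edges, [np.inf])))[0]
    fractions = {float(e): float(np.mean(areas < e**2)) for e in edges}
    return counts, fractions


def sample_keyframes(
    timestamps: Sequence[float], interval: float = 3.0
) -> list[int]:
    """Greedy fixed-interval keyframe selection.

    Keeps the first frame, then every next frame whose timestamp is at
    least ``interval`` seconds after the last kept one.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    ts = list(timestamps)
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("timestamps must be non-decreasing")
    if not ts:
        return []
    kept = [0]
    last = ts[0]
    for i, t in enumerate(ts[1:], start=1):
        if t >= last + interval:
            kept.append(i)
            last = t
    return kept


def read_results(path: str | Path) -> tuple[list[Detection], list[str | None]]:
    """Read a COCO results JSON array into detections plus provenance.

    Returns ``(detections, provenance)`` where provenance entries are the
    optional per-detection ``provenance`` strings (``None`` when absent).
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise SchemaError("results file must be a JSON array")
    dets: list[Detection] = []
    prov: list[str | None] = []
    for i, r in enumerate(raw):
        for key in ("image_id", "bbox", "score"):
            if key not in r:
                raise SchemaError(f"results entry {i}: missing key {key!r}")
        if len(r["bbox"]) != 4:
            raise SchemaError(f"results entry {i}: bbox must have 4 entries")
        x, y, w, h = r["bbox"]
        dets.append(
            Detection(
                box=BoundingBox(x, y, w, h),
                score=float(r["score"]),
                frame_id=int(r["image_id"]),
                category=str(r.get("category_id", 1)),
            )
        )
        prov.append(r.get("provenance"))
    return dets, prov


def write_results(
    detections: Sequence[Detection],
    path: str | Path,
    provenance: Sequence[str | None] | None = None,
) -> None:
    """Write detections as a COCO results JSON array (score kept verbatim)."""
    rows = []
    for i, d in enumerate(detections):
        row = {
            "image_id": d.frame_id,
            "category_id": 1,
            "bbox": [d.box.x, d.box.y, d.box.w, d.box.h],
            "score": d.score,
        }
        if provenance is not None and provenance[i] is not None:
            row["provenance"] = provenance[i]
        rows.append(row)
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1)
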