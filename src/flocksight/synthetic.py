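"""Synthetic surveillance-style sequences with COCO ground truth and a
configurable mock detector.

The generator emulates the statistics that matter to the pipeline, not
photorealism: many small moving targets on a textured static background
(about 43% of boxes below 40x40 px by default, matching wetland
surveillance footage), rigid per-object motion with occasional direction
changes and reflecting boundaries, and optional frame degradation (blur,
occlusion) of the kind temporal fusion is meant to repair.  Targets are
rendered as oriented ellipses carrying fixed speckle texture so that a
correlation tracker has something to lock onto; the texture translates
rigidly with the object.

The mock detector stands in for a per-frame neural detector: it drops each
ground-truth box independently with a miss rate, jitters surviving boxes,
draws scores from Beta distributions, and adds Poisson-distributed false
positives.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .coco import AnnotationSet, DEFAULT_CATEGORIES
from .metrics import BoundingBox, Detection

__all__ = [
    "SceneConfig",
    "DetectorConfig",
    "DegradationEvent",
    "generate_sequence",
    "mock_detect",
    "degrade",
    "occlusion_misses",
]


@dataclass(frozen=True)
class SceneConfig:
    """Scene layout, motion and rendering parameters.

    ``fraction_small`` controls the share of targets whose box area falls
    below 40x40 px (default 0.43, the small-object share typical of fixed
    wetland cameras).  ``fps`` is the analysed frame rate; at the default
    2 fps a 3-second look-back spans 6 frames.
    """

    n_frames: int = 30
    fps: float = 2.0
    frame_size: tuple[int, int] = (320, 320)  # (H, W)
    n_objects: int = 10
    fraction_small: float = 0.43
    small_side: tuple[int, int] = (8, 39)
    other_side: tuple[int, int] = (40, 120)
    speed: float = 3.0                  # px/frame
    direction_change_prob: float = 0.05
    background_noise: float = 0.08      # std of background texture
    background_smooth: float = 3.0      # Gaussian smoothing of the texture
    contrast: tuple[float, float] = (0.25, 0.6)  # object-background contrast
    speckle: float = 0.15               # object texture amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_small <= 1.0):
            raise ValueError("fraction_small must be in [0, 1]")
        H, W = self.frame_size
        if self.other_side[1] >= min(H, W):
            raise ValueError("objects must be smaller than the frame")


@dataclass(frozen=True)
class DetectorConfig:
    """Mock per-frame detector: dropout, false positives, noise, scores."""

    miss_rate: float = 0.1
    fp_rate: float = 0.5            # expected false positives per frame
    loc_noise_sigma: float = 1.0    # px jitter on center and size
    tp_score: tuple = ("beta", 8.0, 2.0)
    fp_score: tuple = ("beta", 2.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0, 1]")
        if self.fp_rate < 0 or self.loc_noise_sigma < 0:
            raise ValueError("fp_rate and loc_noise_sigma must be >= 0")


@dataclass(frozen=True)
class DegradationEvent:
    """Degradation applied to a half-open frame range.

    ``blur_sigma`` > 0 applies Gaussian blur; ``occlusions`` paints flat
    rectangles (x, y, w, h) over the frame.
    """

    frame_start: int
    frame_stop: int
    blur_sigma: float = 0.0
    occlusions: tuple[tuple[float, float, float, float], ...] = ()


def _sample_score(rng: np.random.Generator, spec: tuple) -> float:
    kind = spec[0]
    if kind == "beta":
        return float(np.clip(rng.beta(spec[1], spec[2]), 1e-6, 1.0))
    if kind == "const":
        return float(spec[1])
    raise ValueError(f"unknown score distribution: {spec!r}")


def _make_object(rng: np.random.Generator, cfg: SceneConfig):
    """Sample one target: size stratum, ellipse template, motion state."""
    if rng.random() < cfg.fraction_small:
        lo, hi = cfg.small_side
    else:
        lo, hi = cfg.other_side
    w = int(rng.integers(lo, hi + 1))
    h = int(rng.integers(lo, hi + 1))
    # oriented ellipse mask filling the w x h box
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    a = max(w, h) / 2.0
    b = max(min(w, h) / 2.0, 1.0)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        mask[int(cy), int(cx)] = True
    contrast = rng.uniform(*cfg.contrast) * rng.choice([-1.0, 1.0])
    texture = contrast + cfg.speckle * rng.standard_normal((h, w))
    template = np.where(mask, texture, 0.0)
    angle = rng.uniform(0, 2 * np.pi)
    vel = cfg.speed * np.array([np.cos(angle), np.sin(angle)])
    return {"w": w, "h": h, "mask": mask, "template": template,
            "pos": None, "vel": vel}


def _boxes_touch(pos_a, wa, ha, pos_b, wb, hb, margin: float = 2.0) -> bool:
    """True when two boxes overlap (with a safety margin)."""
    ax, ay = pos_a
    bx, by = pos_b
    return (
        ax < bx + wb + margin and bx < ax + wa + margin
        and ay < by + hb + margin and by < ay + ha + margin
    )


def _place_objects(rng: np.random.Generator, objects, cfg: SceneConfig) -> bool:
    """Find non-overlapping initial positions; False when unpackable.

    The scene is planar: solid targets exclude each other, so boxes never
    interpenetrate.  This keeps ground truth unambiguous under NMS-based
    evaluation (no two true boxes above the suppression threshold).
    """
    H, W = cfg.frame_size
    # largest first (same size distribution, better packing odds); per
    # object, scan a shuffled coarse grid of corners with random jitter so
    # tight layouts are still found; restart the whole layout if stuck
    order = sorted(objects, key=lambda o: -o["w"] * o["h"])
    for attempt in range(24):
        placed: list[dict] = []
        for obj in order:
            xs = np.arange(0, max(W - obj["w"], 1), 4, dtype=float)
            ys = np.arange(0, max(H - obj["h"], 1), 4, dtype=float)
            candidates = [(x, y) for y in ys for x in xs]
            if attempt < 12:
                rng.shuffle(candidates)
            # else: raster order -> tight corner packing for dense layouts
            for cx, cy in candidates:
                jx, jy = (rng.uniform(0, 4), rng.uniform(0, 4)) \
                    if attempt < 12 else (0.0, 0.0)
                pos = np.array([
                    min(cx + jx, W - obj["w"]),
                    min(cy + jy, H - obj["h"]),
                ])
                if all(
                    not _boxes_touch(pos, obj["w"], obj["h"],
                                     other["pos"], other["w"], other["h"])
                    for other in placed
                ):
                    obj["pos"] = pos
                    placed.append(obj)
                    break
            else:
                break  # no corner fits this object: restart the layout
        if len(placed) == len(objects):
            return True
    return False


def generate_sequence(cfg: SceneConfig) -> tuple[list[np.ndarray], AnnotationSet]:
    """Render a sequence of grayscale float frames plus COCO ground truth.

    Deterministic given ``cfg.seed``.  Frames are ``H x W`` float arrays in
    roughly [0, 1]; annotation ``image_id`` equals the 0-based frame index.
    Boxes are tight around each rendered ellipse and never leave the frame
    (velocities reflect at the borders).
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.frame_size
    background = 0.5 + cfg.background_noise * ndimage.gaussian_filter(
        rng.standard_normal((H, W)), cfg.background_smooth
    ) * cfg.background_smooth  # re-amplify after smoothing
    # a size draw that cannot be packed without overlap is rejected and
    # redrawn (rare at the defaults; see _place_objects)
    for _ in range(50):
        objects = [_make_object(rng, cfg) for _ in range(cfg.n_objects)]
        if _place_objects(rng, objects, cfg):
            break
    else:
        raise ValueError("objects cannot be packed into the frame; reduce "
                         "n_objects or object sizes")

    frames: list[np.ndarray] = []
    images = []
    annotations = []
    ann_id = 1
    for t in range(cfg.n_frames):
        canvas = background.copy()
        for k, obj in enumerate(objects):
            x = int(round(obj["pos"][0]))
            y = int(round(obj["pos"][1]))
            x = min(max(x, 0), W - obj["w"])
            y = min(max(y, 0), H - obj["h"])
            region = canvas[y : y + obj["h"], x : x + obj["w"]]
            region[obj["mask"]] = 0.5 + obj["template"][obj["mask"]]
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": t,
                    "category_id": 1,
                    "bbox": [float(x), float(y), float(obj["w"]), float(obj["h"])],
                    "area": float(obj["w"] * obj["h"]),
                    "iscrowd": 0,
                    "track_id": k,
                }
            )
            ann_id += 1
            # advance motion: reflecting frame borders, and solid targets
            # bounce off each other (planar scene, no interpenetration)
            if rng.random() < cfg.direction_change_prob:
                angle = rng.uniform(0, 2 * np.pi)
                obj["vel"] = cfg.speed * np.array([np.cos(angle), np.sin(angle)])
            proposed = obj["pos"] + obj["vel"]
            for d, limit, side in ((0, W, obj["w"]), (1, H, obj["h"])):
                if proposed[d] < 0:
                    proposed[d] = -proposed[d]
                    obj["vel"][d] = -obj["vel"][d]
                elif proposed[d] > limit - side:
                    proposed[d] = 2 * (limit - side) - proposed[d]
                    obj["vel"][d] = -obj["vel"][d]
            collision = any(
                other is not obj
                and _boxes_touch(proposed, obj["w"], obj["h"],
                                 other["pos"], other["w"], other["h"])
                for other in objects
            )
            if collision:
                obj["vel"] = -obj["vel"]  # bounce back, stay put this frame
            else:
                obj["pos"] = proposed
        frames.append(np.clip(canvas, 0.0, 1.0))
        images.append(
            {"id": t, "file_name": f"frame_{t:06d}.png", "width": W, "height": H}
        )

    aset = AnnotationSet(
        images=images,
        annotations=annotations,
        categories=[dict(c) for c in DEFAULT_CATEGORIES],
    )
    return frames, aset


def mock_detect(
    gt: AnnotationSet,
    cfg: DetectorConfig,
    forced_miss: Iterable[tuple[int, int]] = (),
) -> dict[int, list[Detection]]:
    """Simulate a per-frame detector on the ground truth.

    Each annotation is kept with probability ``1 - miss_rate`` (and never
    when ``(image_id, annotation_id)`` is in ``forced_miss``, e.g. for
    occluded objects), jittered by Gaussian noise on center and size, and
    scored from the TP score model.  Poisson false positives are placed
    uniformly per frame.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    forced = set(forced_miss)
    sizes = {im["id"]: (im["height"], im["width"]) for im in gt.images}
    out: dict[int, list[Detection]] = {im["id"]: [] for im in gt.images}

    for a in gt.annotations:
        fid = a["image_id"]
        # draw in a fixed order so forced misses don't shift the stream
        u = rng.random()
        jitter = rng.normal(0.0, cfg.loc_noise_sigma, size=4)
        score = _sample_score(rng, cfg.tp_score)
        if (fid, a["id"]) in forced or u < cfg.miss_rate:
            continue
        x, y, w, h = a["bbox"]
        H, W = sizes[fid]
        w2 = max(w + jitter[2], 2.0)
        h2 = max(h + jitter[3], 2.0)
        x2 = float(np.clip(x + jitter[0], 0, W - w2))
        y2 = float(np.clip(y + jitter[1], 0, H - h2))
        out[fid].append(
            Detection(BoundingBox(x2, y2, w2, h2), score=score, frame_id=fid)
        )

    for fid in sorted(out):
        H, W = sizes[fid]
        n_fp = rng.poisson(cfg.fp_rate)
        for _ in range(n_fp):
            w = float(rng.uniform(6, 60))
            h = float(rng.uniform(6, 60))
            x = float(rng.uniform(0, W - w))
            y = float(rng.uniform(0, H - h))
            score = _sample_score(rng, cfg.fp_score)
            out[fid].append(
                Detection(BoundingBox(x, y, w, h), score=score, frame_id=fid)
            )
    return out


def degrade(
    frames: Sequence[np.ndarray], schedule: Sequence[DegradationEvent]
) -> list[np.ndarray]:
    """Apply blur/occlusion events; frames outside all events are the same
    objects (bit-identical) as the input."""
    out = list(frames)
    for ev in schedule:
        if ev.frame_start < 0 or ev.frame_stop > len(frames):
            raise ValueError("degradation schedule outside frame range")
        for t in range(ev.frame_start, ev.frame_stop):
            img = out[t]
            if ev.blur_sigma > 0:
                img = ndimage.gaussian_filter(img, ev.blur_sigma)
            if ev.occlusions:
                img = img.copy() if img is out[t] else img
                for (x, y, w, h) in ev.occlusions:
                    img[int(y) : int(y + h), int(x) : int(x + w)] = 0.0
            out[t] = img
    return out


def occlusion_misses(
    schedule: Sequence[DegradationEvent],
    gt: AnnotationSet,
    min_cover: float = 0.5,
) -> set[tuple[int, int]]:
    """Forced-miss set for annotations covered by occlusion rectangles.

    An annotation is flagged when an occlusion rectangle covers at least
    ``min_cover`` of its box area on that frame.
    """
    flags: set[tuple[int, int]] = set()
    for a in gt.annotations:
        x, y, w, h = a["bbox"]
        for ev in schedule:
            if not (ev.frame_start <= a["image_id"] < ev.frame_stop):
                continue
            for (ox, oy, ow, oh) in ev.occlusions:
                iw = min(x + w, ox + ow) - max(x, ox)
                ih = min(y + h, oy + oh) - max(y, oy)
                if iw > 0 and ih > 0 and iw * ih >= min_cover * w * h:
                    flags.add((a["image_id"], a["id"]))
    return flags
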