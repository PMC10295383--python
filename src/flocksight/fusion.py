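"""Sequential-frame detection fusion: 3-second look-back, keyframe
selection, KCF propagation, and NMS fusion with current-frame detections.

Per-frame detectors degrade on frames where the target is blurred, occluded
or in an unusual pose.  This stage repairs such frames with temporal
context: for each current frame it looks back a fixed interval (3 s by
default), picks the window frame whose best detection score is highest (the
keyframe), propagates that frame's detections to the current frame with one
KCF tracker per box, and merges tracked and current detections by greedy
non-maximum suppression.  Tracked boxes carry an exponentially decayed
score so that, all else equal, a fresh detection outranks a propagated one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kcf import TrackerParams, init_track, track_step, update_model
from .metrics import BoundingBox, Detection, iou

__all__ = [
    "FrameBuffer",
    "FusedDetectionSet",
    "FusionConfig",
    "select_keyframe",
    "propagate",
    "nms",
    "fuse",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class FrameBuffer:
    """Look-back window: ordered (frame_id, image) pairs plus detections."""

    frames: list[tuple[int, np.ndarray]]
    detections: dict[int, list[Detection]]
    fps: float
    lookback_seconds: float = 3.0

    def __post_init__(self) -> None:
        ids = [fid for fid, _ in self.frames]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("frame ids must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def window_size(self) -> int:
        return int(round(self.lookback_seconds * self.fps))


@dataclass
class FusedDetectionSet:
    """NMS-fused detections with per-box provenance.

    ``provenance[i]`` is ``"current"`` or ``"tracked:<source frame_id>"``
    for ``detections[i]``.
    """

    detections: list[Detection] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FusionConfig:
    """Pipeline configuration; ``fps`` converts the look-back seconds into
    a frame count and must come from the video metadata."""

    fps: float
    lookback_seconds: float = 3.0
    nms_iou: float = 0.5
    decay: float = 0.95           # per-frame score decay for tracked boxes
    drop_response: float = 0.25   # discard tracks whose KCF peak falls below
    tracker: TrackerParams = field(default_factory=TrackerParams)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (0.0 < self.nms_iou < 1.0):
            raise ValueError("nms_iou must be in (0, 1)")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError("decay must be in (0, 1]")


def select_keyframe(buffer: FrameBuffer) -> int | None:
    """Window frame whose maximum detection score is highest.

    Ties go to the most recent frame.  Returns ``None`` when no window
    frame has any detections (fusion then degenerates to the current
    detections alone).
    """
    best_fid: int | None = None
    best_score = -np.inf
    for fid, _ in buffer.frames:
        dets = buffer.detections.get(fid, [])
        if not dets:
            continue
        s = max(d.score for d in dets)
        if s >= best_score:  # >= so later frames win ties
            best_score, best_fid = s, fid
    return best_fid


def propagate(
    keyframe_dets: Sequence[Detection],
    frames: Sequence[np.ndarray],
    params: TrackerParams | None = None,
    decay: float = 0.95,
    drop_response: float = 0.25,
    current_frame_id: int = 0,
    source_frame_id: int = 0,
) -> list[Detection]:
    """Track each keyframe detection to the last frame of ``frames``.

    ``frames`` runs from the keyframe (inclusive) to the current frame
    (inclusive).  One KCF tracker is initialised per box on the keyframe and
    stepped with online model updates; a track whose peak response drops
    below ``drop_response`` is discarded (drifted or lost).  Survivors are
    returned as detections at the current frame with score
    ``source_score * decay ** n_steps``.
    """
    if not keyframe_dets:
        return []
    if len(frames) == 0:
        raise ValueError("propagate requires at least the keyframe image")
    params = params or TrackerParams()
    n_steps = len(frames) - 1
    out: list[Detection] = []
    for det in keyframe_dets:
        state = init_track(frames[0], det.box, params)
        alive = True
        box = det.box
        for img in frames[1:]:
            box, resp = track_step(state, img)
            if resp < drop_response:
                alive = False
                logger.debug(
                    "dropped track from frame %d (response %.3f < %.3f)",
                    source_frame_id, resp, drop_response,
                )
                break
            state = update_model(state, img)
        if alive:
            out.append(
                Detection(
                    box=box,
                    score=det.score * decay**n_steps,
                    frame_id=current_frame_id,
                    category=det.category,
                )
            )
    return out


def nms(dets: Sequence[Detection], iou_thresh: float) -> list[Detection]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending score order (ties by input order); a box
    is kept iff its IoU with every previously kept box of the same category
    is below ``iou_thresh``.
    """
    if not (0.0 < iou_thresh < 1.0):
        raise ValueError("iou_thresh must be in (0, 1)")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    kept: list[int] = []
    for i in order:
        if all(
            dets[i].category != dets[j].category
            or iou(dets[i].box, dets[j].box) < iou_thresh
            for j in kept
        ):
            kept.append(i)
    kept.sort()
    return [dets[i] for i in kept]


def fuse(
    current_dets: Sequence[Detection],
    tracked_dets: Sequence[Detection],
    iou_thresh: float = 0.5,
    source_frame_id: int | None = None,
) -> FusedDetectionSet:
    """NMS-merge current-frame and tracked detections.

    Current detections precede tracked ones in the candidate list, so they
    win exact score ties under the stable NMS ordering.
    """
    pool = list(current_dets) + list(tracked_dets)
    tags = ["current"] * len(current_dets) + [
        f"tracked:{source_frame_id if source_frame_id is not None else '?'}"
    ] * len(tracked_dets)
    kept = nms(pool, iou_thresh)
    # recover provenance by identity within the pool
    out = FusedDetectionSet()
    used: set[int] = set()
    for d in kept:
        for i, p in enumerate(pool):
            if i not in used and p is d:
                out.detections.append(d)
                out.provenance.append(tags[i])
                used.add(i)
                break
    return out


def run_pipeline(
    frames: Sequence[tuple[int, np.ndarray]],
    detections: Mapping[int, Sequence[Detection]],
    config: FusionConfig,
    lookback_detections: Mapping[int, Sequence[Detection]] | None = None,
) -> dict[int, FusedDetectionSet]:
    """Run look-back fusion over an ordered frame sequence.

    For every frame with a full look-back window (``lookback_seconds *
    fps`` preceding frames) the keyframe is selected, its detections are
    propagated by KCF, and the result is NMS-fused with the current
    detections.  Frames without a full window pass their detections through
    unchanged.  ``lookback_detections`` optionally supplies a separate
    detection source for the window (e.g. a slower, higher-quality pass);
    by default the window reuses ``detections``.

    Frame ids must be consecutive integers; gaps raise an error listing the
    missing ids.
    """
    ids = [fid for fid, _ in frames]
    gaps = [
        missing
        for a, b in zip(ids, ids[1:])
        for missing in range(a + 1, b)
    ]
    if gaps:
        raise ValueError(f"missing frames in sequence: {gaps}")

    window_n = int(round(config.lookback_seconds * config.fps))
    look = lookback_detections if lookback_detections is not None else detections
    results: dict[int, FusedDetectionSet] = {}

    for t, (fid, img) in enumerate(frames):
        current = list(detections.get(fid, []))
        if t < window_n:
            results[fid] = FusedDetectionSet(
                detections=current, provenance=["current"] * len(current)
            )
            continue
        window_frames = frames[t - window_n : t]
        buffer = FrameBuffer(
            frames=list(window_frames),
            detections={f: list(look.get(f, [])) for f, _ in window_frames},
            fps=config.fps,
            lookback_seconds=config.lookback_seconds,
        )
        key = select_keyframe(buffer)
        if key is None:
            results[fid] = FusedDetectionSet(
                detections=current, provenance=["current"] * len(current)
            )
            continue
        logger.debug("frame %d: keyframe %d", fid, key)
        key_pos = ids.index(key)
        span = [img_ for _, img_ in frames[key_pos : t + 1]]
        tracked = propagate(
            buffer.detections[key],
            span,
            params=config.tracker,
            decay=config.decay,
            drop_response=config.drop_response,
            current_frame_id=fid,
            source_frame_id=key,
        )
        results[fid] = fuse(current, tracked, config.nms_iou, source_frame_id=key)
    return results
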