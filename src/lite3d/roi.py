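"""Cut-paste-warp preprocessing: bounding boxes -> fixed-size ROI-only clips.

Plain cropping-and-resizing of detector boxes destroys the very signal a
behavior classifier needs: how the animal's apparent size and position
change from frame to frame.  The cut-paste-warp scheme keeps it — the ROI
is cut out, pasted at its *original* position onto a black canvas the size
of the source frame, and then the whole canvas is resized to the network
input size.  Relative position and relative scale across consecutive
frames survive the warp by construction; everything outside the ROI is
exactly zero before interpolation.

Boxes are 0-based, half-open pixel rectangles [x, x+w) x [y, y+h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize


@dataclass(frozen=True)
class BoundingBox:
    """A per-frame detection or prediction box.

    ``source`` records whether the box came from the detector or from the
    tracker's linear motion predictor (a tracking-loss fill-in).
    """

    frame_index: int
    x: float
    y: float
    w: float
    h: float
    confidence: float = 1.0
    source: str = "detected"  # "detected" | "predicted"

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"degenerate box {self.w}x{self.h}")
        if self.source not in ("detected", "predicted"):
            raise ValueError(f"unknown box source {self.source!r}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_dict(self) -> dict:
        return {
            "frame": self.frame_index,
            "x": self.x, "y": self.y, "w": self.w, "h": self.h,
            "confidence": self.confidence, "source": self.source,
        }


@dataclass(frozen=True)
class ROISequence:
    """The classification unit: k ROI-only frames for one tracked target.

    ``clips`` is a ``(k, c, n, n)`` float32 array, oldest frame first;
    ``boxes`` are the k source boxes (detected or predicted).
    """

    clips: np.ndarray
    boxes: tuple[BoundingBox, ...]
    track_id: int = -1
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))
        if len(self.boxes) != self.clips.shape[0]:
            raise ValueError("one box per clip frame required")
        idx = [b.frame_index for b in self.boxes]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def k(self) -> int:
        return self.clips.shape[0]

    @property
    def last_frame(self) -> int:
        return self.boxes[-1].frame_index


def _as_float_rgb(frame: np.ndarray) -> np.ndarray:
    """Frame -> float32 HxWx3 in [0,1]; grayscale replicated to 3 channels."""
    f = np.asarray(frame)
    if f.dtype == np.uint8:
        f = f.astype(np.float32) / 255.0
    else:
        f = f.astype(np.float32)
    if f.ndim == 2:
        f = np.repeat(f[:, :, None], 3, axis=2)
    if f.ndim != 3 or f.shape[2] != 3:
        raise ValueError(f"expected HxW or HxWx3 frame, got {f.shape}")
    return f


def cut_paste_warp(frame: np.ndarray, box: BoundingBox, target_size: int) -> np.ndarray:
    """One ROI-only frame: cut the box, paste on a black frame-sized canvas
    at its original position, warp the canvas to target_size x target_size.

    Returns a ``(3, n, n)`` float32 image in [0, 1]; pixels outside the
    mapped ROI are zero up to bilinear interpolation at the ROI border.
    Boxes extending past the frame are clipped to it; a box entirely
    outside raises.
    """
    img = _as_float_rgb(frame)
    fh, fw = img.shape[:2]
    x0, y0 = int(np.floor(box.x)), int(np.floor(box.y))
    x1, y1 = int(np.ceil(box.x + box.w)), int(np.ceil(box.y + box.h))
    x0c, y0c = max(x0, 0), max(y0, 0)
    x1c, y1c = min(x1, fw), min(y1, fh)
    if x0c >= x1c or y0c >= y1c:
        raise ValueError(f"box {box} does not intersect the {fw}x{fh} frame")
    canvas = np.zeros_like(img)
    canvas[y0c:y1c, x0c:x1c] = img[y0c:y1c, x0c:x1c]
    warped = resize(
        canvas,
        (target_size, target_size),
        order=1,
        mode="constant",
        cval=0.0,
        anti_aliasing=False,
        preserve_range=True,
    ).astype(np.float32)
    return np.ascontiguousarray(warped.transpose(2, 0, 1))


def assemble_sequence(
    track_boxes: Sequence[BoundingBox],
    frames: Sequence[np.ndarray] | dict[int, np.ndarray],
    k: int = 10,
    n: int = 64,
    track_id: int = -1,
    label: str | None = None,
) -> ROISequence | None:
    """Build the training/prediction vector from a track's box history.

    Takes the ``k`` most recent boxes (oldest -> newest), runs each through
    :func:`cut_paste_warp` against its frame, and stacks the results.
    Returns ``None`` — not an exception — when fewer than ``k`` boxes are
    available; a track simply has no sequence to classify yet.

    ``frames`` may be a sequence indexed by frame number or a mapping
    ``frame_index -> image``.
    """
    if len(track_boxes) < k:
        return None
    recent = list(track_boxes)[-k:]
    clips = np.stack(
        [cut_paste_warp(frames[b.frame_index], b, n) for b in recent]
    )
    return ROISequence(clips=clips, boxes=tuple(recent),
                       track_id=track_id, label=label)
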