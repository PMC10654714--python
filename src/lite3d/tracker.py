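"""Detection-driven multi-target tracking.

Each live target is a *thread* holding a FIFO history of boxes.  Per frame:

1. every detection is gated against every thread — it may extend thread
   ``t`` only if IoU(last box of t, detection) > alpha AND the Euclidean
   distance between box centers is < beta pixels;
2. gated pairs are resolved greedily (detections in descending confidence,
   nearest-center thread wins), giving the update set **U**;
3. unmatched detections become new threads — the add set **A**;
4. every thread not updated (**P** = T − U) receives a linearly
   extrapolated box flagged ``source="predicted"`` and its consecutive-miss
   counter grows; a thread missing for ``r`` consecutive frames is aborted
   (default r = k/2 = 5 for k = 10);
5. any thread whose history holds at least ``k`` boxes is ready to emit a
   classification sequence of its most recent ``k``.

Both alpha and beta are species-tunable: fast movers need a looser IoU
gate and a wider distance gate.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

from .roi import BoundingBox


@dataclass(frozen=True)
class TrackerParams:
    """Matching gates and history geometry.

    alpha: IoU gate in [0, 1); beta: center-distance gate in pixels;
    k: sequence length; r: consecutive-miss tolerance (k // 2 when None).
    """

    alpha: float = 0.3
    beta: float = 40.0
    k: int = 10
    r: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.r is None:
            object.__setattr__(self, "r", self.k // 2)
        if self.r < 1:  # type: ignore[operator]
            raise ValueError("r must be >= 1")

    @classmethod
    def for_frame(cls, frame_shape: tuple[int, int], alpha: float = 0.3,
                  k: int = 10) -> "TrackerParams":
        """beta = 10% of the frame diagonal — a reasonable default gate."""
        h, w = frame_shape
        return cls(alpha=alpha, beta=0.1 * math.hypot(w, h), k=k)


@dataclass
class TrackThread:
    """One tracked target: id, FIFO box history, miss bookkeeping."""

    id: int
    boxes: deque = field(default_factory=deque)
    consecutive_misses: int = 0

    @property
    def last_box(self) -> BoundingBox:
        return self.boxes[-1]

    @property
    def last_seen(self) -> int:
        return self.last_box.frame_index

    def push(self, box: BoundingBox) -> None:
        self.boxes.append(box)


@dataclass
class StepResult:
    """Working sets and ready sequences produced by one tracker step."""

    added: list[int] = field(default_factory=list)      # A: new thread ids
    updated: list[int] = field(default_factory=list)    # U: matched thread ids
    predicted: list[int] = field(default_factory=list)  # P: extrapolated ids
    removed: list[int] = field(default_factory=list)    # aborted thread ids
    ready: list[tuple[int, list[BoundingBox]]] = field(default_factory=list)


class TrackerState:
    """The live thread set T plus a monotone id counter (ids never reused)."""

    def __init__(self, params: TrackerParams | None = None) -> None:
        self.params = params or TrackerParams()
        self.threads: dict[int, TrackThread] = {}
        self._next_id = 0

    def _new_thread(self, box: BoundingBox) -> TrackThread:
        t = TrackThread(id=self._next_id)
        self._next_id += 1
        t.push(box)
        self.threads[t.id] = t
        return t


def iou(b1: BoundingBox, b2: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ix = min(b1.x + b1.w, b2.x + b2.w) - max(b1.x, b2.x)
    iy = min(b1.y + b1.h, b2.y + b2.h) - max(b1.y, b2.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (b1.area + b2.area - inter)


def _center_dist(b1: BoundingBox, b2: BoundingBox) -> float:
    (x1, y1), (x2, y2) = b1.center, b2.center
    return math.hypot(x1 - x2, y1 - y2)


def match(
    detections: Sequence[BoundingBox],
    state: TrackerState,
    params: TrackerParams | None = None,
) -> dict[int, int]:
    """Greedy one-to-one assignment: detection index -> thread id.

    A detection can take a thread only if it passes *both* gates against
    the thread's most recent box (detected or predicted).  Detections are
    processed in descending confidence; among gated threads the nearest
    center wins.  Unassigned detections are new targets.
    """
    params = params or state.params
    order = sorted(range(len(detections)),
                   key=lambda i: -detections[i].confidence)
    taken: set[int] = set()
    assignment: dict[int, int] = {}
    for i in order:
        det = detections[i]
        best: tuple[float, int] | None = None
        for tid, thread in state.threads.items():
            if tid in taken:
                continue
            last = thread.last_box
            if iou(last, det) <= params.alpha:
                continue
            d = _center_dist(last, det)
            if d >= params.beta:
                continue
            if best is None or d < best[0]:
                best = (d, tid)
        if best is not None:
            assignment[i] = best[1]
            taken.add(best[1])
    return assignment


def predict_position(thread: TrackThread, frame_index: int | None = None) -> BoundingBox:
    """Linear motion fill-in for a tracking-loss frame.

    The center is extrapolated from the last two boxes (order-1 velocity),
    size copies the last box; with a single box the prediction is that box
    carried forward.  The returned box is flagged ``source="predicted"``.
    """
    last = thread.last_box
    if frame_index is None:
        frame_index = last.frame_index + 1
    if len(thread.boxes) < 2:
        cx, cy = last.center
    else:
        prev = thread.boxes[-2]
        (px, py), (lx, ly) = prev.center, last.center
        cx, cy = lx + (lx - px), ly + (ly - py)
    return BoundingBox(
        frame_index=frame_index,
        x=cx - last.w / 2.0,
        y=cy - last.h / 2.0,
        w=last.w,
        h=last.h,
        confidence=0.0,
        source="predicted",
    )


def step(
    state: TrackerState,
    detections: Sequence[BoundingBox],
    frame_index: int,
    params: TrackerParams | None = None,
) -> StepResult:
    """Advance the tracker one frame.

    Matched threads join U and push their detection; unmatched detections
    spawn threads (A); P = T − U threads push a predicted box and count a
    miss (a match resets the counter); threads reaching r misses are
    removed.  Threads whose history holds >= k boxes report their top-k
    window in ``ready`` for sequence assembly.
    """
    params = params or state.params
    res = StepResult()
    assignment = match(detections, state, params)

    for det_i, tid in assignment.items():
        thread = state.threads[tid]
        thread.push(detections[det_i])
        thread.consecutive_misses = 0
        res.updated.append(tid)

    updated = set(res.updated)
    for det_i, det in enumerate(detections):
        if det_i not in assignment:
            t = state._new_thread(det)
            res.added.append(t.id)

    # P = T - U - A: pre-existing threads with no match this frame
    added = set(res.added)
    for tid in list(state.threads):
        if tid in updated or tid in added:
            continue
        thread = state.threads[tid]
        thread.push(predict_position(thread, frame_index))
        thread.consecutive_misses += 1
        res.predicted.append(tid)
        if thread.consecutive_misses >= params.r:  # type: ignore[operator]
            del state.threads[tid]
            res.removed.append(tid)

    for tid, thread in state.threads.items():
        while len(thread.boxes) > 2 * params.k:  # bound memory
            thread.boxes.popleft()
        if len(thread.boxes) >= params.k:
            res.ready.append((tid, list(thread.boxes)[-params.k:]))
    return res
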