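"""End-to-end orchestration: training, evaluation and video inference.

``train`` fits a Lite3D model on labeled ROI sequences by mini-batch Adam
over focal or cross-entropy loss; ``evaluate`` produces a per-class
precision / overall precision-recall-F1 report (macro averaging);
``run_video`` chains detector -> tracker -> cut-paste-warp -> classifier
over a frame stream and emits per-frame, per-target annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .arch import ArchConfig
from .losses import FocalLossParams, class_weights, focal_loss, focal_loss_grad_logits
from .net import Lite3DModel, build_model, softmax
from .roi import BoundingBox, ROISequence, cut_paste_warp
from .synthetic import BEHAVIORS
from .tracker import TrackerParams, TrackerState, step

log = logging.getLogger("lite3d")

ANOMALOUS = tuple(b for b in BEHAVIORS if b != "normal")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults: batch 32, 50 epochs, Adam 1e-3)."""

    batch_size: int = 32
    epochs: int = 50
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "focal"          # "focal" | "cross_entropy"
    gamma: float = 2.0
    alpha: str | float = "auto"  # "auto" -> complement-frequency weights
    seed: int = 0
    val_fraction: float = 0.0    # optional held-out monitoring split

    def __post_init__(self) -> None:
        if self.loss not in ("focal", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is implemented")


@dataclass
class TrainingLog:
    epoch_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class MetricReport:
    """Per-class precision plus macro-averaged overall metrics."""

    classes: tuple[str, ...]
    per_class_precision: dict
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray

    def summary(self) -> str:
        lines = [f"{'class':>14s}  precision"]
        for c in self.classes:
            lines.append(f"{c:>14s}  {self.per_class_precision[c]:.3f}")
        lines.append(
            f"overall (macro): precision {self.precision:.3f}  "
            f"recall {self.recall:.3f}  F1 {self.f1:.3f}"
        )
        return "\n".join(lines)


def _stack_dataset(
    dataset: Sequence[ROISequence], classes: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if not dataset:
        raise ValueError("empty dataset")
    if any(s.label is None for s in dataset):
        raise ValueError("all sequences must carry labels")
    if classes is None:
        seen = {s.label for s in dataset}
        ordered = [b for b in BEHAVIORS if b in seen]
        ordered += sorted(seen - set(ordered))
        classes = ordered
    index = {c: i for i, c in enumerate(classes)}
    x = np.stack([s.clips for s in dataset]).astype(np.float32)
    y = np.array([index[s.label] for s in dataset], dtype=np.int64)
    return x, y, tuple(classes)


def split_dataset(
    dataset: Sequence[ROISequence], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[ROISequence], list[ROISequence]]:
    """Stratified train/test split by sequence label."""
    labels = [s.label for s in dataset]
    idx = np.arange(len(dataset))
    tr, te = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    return [dataset[i] for i in tr], [dataset[i] for i in te]


def _loss_params(cfg: TrainConfig, counts: np.ndarray) -> FocalLossParams:
    if cfg.loss == "cross_entropy":
        return FocalLossParams(gamma=0.0, alpha=1.0)
    if cfg.alpha == "auto":
        if len(counts) < 2:  # complement-frequency rule needs C >= 2
            return FocalLossParams(gamma=cfg.gamma, alpha=1.0)
        return FocalLossParams(gamma=cfg.gamma, alpha=class_weights(counts))
    return FocalLossParams(gamma=cfg.gamma, alpha=float(cfg.alpha))


def train(
    dataset: Sequence[ROISequence],
    arch: ArchConfig,
    cfg: TrainConfig | None = None,
) -> tuple[Lite3DModel, TrainingLog]:
    """Fit Lite3D on labeled sequences; deterministic under ``cfg.seed``.

    The class order of the prediction head follows the canonical behavior
    vocabulary; ``arch.n_categories`` must match the number of distinct
    labels.  Shape problems surface before any gradient step.
    """
    cfg = cfg or TrainConfig()
    x, y, classes = _stack_dataset(dataset)
    if len(classes) != arch.n_categories:
        raise ValueError(
            f"dataset has {len(classes)} classes but arch expects "
            f"{arch.n_categories}"
        )
    expect = (arch.input_depth, arch.input_channels,
              arch.input_height, arch.input_width)
    if x.shape[1:] != expect:
        raise ValueError(f"clip shape {x.shape[1:]} != arch input {expect}")

    rng = np.random.default_rng(cfg.seed)
    model = build_model(arch, seed=int(rng.integers(2**31 - 1)))
    model.classes = classes
    counts = np.bincount(y, minlength=len(classes))
    params = _loss_params(cfg, counts)
    eye = np.eye(len(classes), dtype=np.float32)

    x_val = y_val = None
    if cfg.val_fraction > 0:
        n_val = max(1, int(len(x) * cfg.val_fraction))
        order = rng.permutation(len(x))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        x_val, y_val = x[val_idx], y[val_idx]
        x, y = x[tr_idx], y[tr_idx]

    # Adam state
    mom = [(np.zeros_like(w), np.zeros_like(b)) for w, b in model.params]
    vel = [(np.zeros_like(w), np.zeros_like(b)) for w, b in model.params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t_step = 0
    logbook = TrainingLog()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb = model._to_internal(x[sel])
            yb = eye[y[sel]]
            logits, cache = model._forward(xb, keep_cache=True)
            probs = softmax(logits, axis=1)
            losses.append(focal_loss(probs, yb, params))
            dlogits = focal_loss_grad_logits(probs, yb, params)
            grads = model._backward(cache, dlogits)
            t_step += 1
            corr = np.sqrt(1 - b2**t_step) / (1 - b1**t_step)
            for (w, b), (gw, gb), m_wb, v_wb in zip(
                model.params, grads, mom, vel
            ):
                for p, g, m, v in ((w, gw, m_wb[0], v_wb[0]),
                                   (b, gb, m_wb[1], v_wb[1])):
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    p -= cfg.learning_rate * corr * m / (np.sqrt(v) + eps)
        logbook.epoch_loss.append(float(np.mean(losses)))
        msg = f"epoch {epoch + 1}/{cfg.epochs} loss {logbook.epoch_loss[-1]:.4f}"
        if x_val is not None:
            acc = float((predict_labels_idx(model, x_val) == y_val).mean())
            logbook.val_accuracy.append(acc)
            msg += f" val-acc {acc:.3f}"
        log.info(msg)
    return model, logbook


def predict_labels_idx(model: Lite3DModel, clips: np.ndarray,
                       batch_size: int = 64) -> np.ndarray:
    """Argmax class indices, batched to bound memory."""
    out = []
    for start in range(0, len(clips), batch_size):
        out.append(model.predict(clips[start:start + batch_size]))
    return np.concatenate(out)


def report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence[str]
) -> MetricReport:
    """MetricReport from index-coded truth and predictions (macro averages)."""
    labels = np.arange(len(classes))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    per_prec = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0
    )[0]
    return MetricReport(
        classes=tuple(classes),
        per_class_precision={c: float(p) for c, p in zip(classes, per_prec)},
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
    )


def evaluate(model: Lite3DModel, dataset: Sequence[ROISequence]) -> MetricReport:
    """Per-class precision and macro precision/recall/F1 on labeled data."""
    x, y, classes = _stack_dataset(dataset, classes=model.classes)
    pred = predict_labels_idx(model, x)
    return report_from_predictions(y, pred, classes)


Detector = Callable[[int, np.ndarray], Sequence[BoundingBox]]


def run_video(
    model: Lite3DModel,
    detector: Detector | Sequence[Sequence[BoundingBox]],
    frames: np.ndarray,
    params: TrackerParams | None = None,
) -> list[dict]:
    """Detect, track and classify every target over a frame stream.

    ``detector`` is either a callable ``(frame_index, frame) -> boxes`` or
    a precomputed per-frame box list.  Returns one record per (frame,
    live track): box geometry, box source, and — once the track's FIFO
    stack holds ``k`` boxes — the behavior label with its confidence and
    an anomaly flag.  A detector failure on a frame is logged and treated
    as zero detections.
    """
    if params is None:
        params = TrackerParams.for_frame(frames.shape[1:3], k=model.arch.input_depth)
    if params.k != model.arch.input_depth:
        raise ValueError("tracker k must equal the model input depth")
    n = model.arch.input_width
    classes = model.classes or tuple(
        f"class_{i}" for i in range(model.n_categories)
    )
    state = TrackerState(params)
    warp_cache: dict[tuple[int, int], np.ndarray] = {}
    annotations: list[dict] = []
    for t in range(len(frames)):
        if callable(detector):
            try:
                dets = list(detector(t, frames[t]))
            except Exception:  # noqa: BLE001 - detector is third-party
                log.exception("detector failed on frame %d; assuming none", t)
                dets = []
        else:
            dets = list(detector[t]) if t < len(detector) else []
        res = step(state, dets, t, params)

        # classify every thread whose stack is full, in one batch
        batch, meta = [], []
        for tid, boxes in res.ready:
            clips = np.stack([
                warp_cache.setdefault(
                    (tid, b.frame_index),
                    cut_paste_warp(frames[b.frame_index], b, n),
                )
                for b in boxes
            ])
            batch.append(clips)
            meta.append(tid)
        labels: dict[int, tuple[str, float]] = {}
        if batch:
            probs = model.forward_batch(np.stack(batch))
            for tid, p in zip(meta, probs):
                j = int(p.argmax())
                labels[tid] = (classes[j], float(p[j]))
        for tid, thread in state.threads.items():
            box = thread.last_box
            if box.frame_index != t:
                continue
            rec = {
                "frame": t,
                "track_id": tid,
                **box.as_dict(),
                "behavior": None,
                "behavior_confidence": None,
                "anomalous": None,
            }
            if tid in labels:
                name, conf = labels[tid]
                rec["behavior"] = name
                rec["behavior_confidence"] = conf
                rec["anomalous"] = name != "normal"
            annotations.append(rec)
    return annotations
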