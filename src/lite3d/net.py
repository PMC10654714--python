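"""The Lite3D network: valid 3D convolutions, ceiling max-pooling and a
flatten prediction head, with hand-rolled forward/backward passes.

The model is small enough (~0.08 M parameters for 7 categories) that plain
numpy with im2col-style windowing and BLAS matmuls trains it in minutes on
a CPU.  Tensors are ``float32`` throughout.

Internal layout: a batch is ``(B, C, D, H, W)`` — batch, channels, frames,
height, width.  A single :class:`Clip` as fed by callers is ``(k, c, n, n)``
(frames first, matching the ``k x c @ n x n`` notation used for shapes);
it is transposed on entry.

Convolution is implemented as cross-correlation, the universal practice in
deep-learning code; for learned kernels this is equivalent to true
convolution up to a kernel flip.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from ._kernels import pool_max_backward, pool_max_forward
from .arch import (
    ArchConfig,
    InvalidConfigError,
    LayerSpec,
    count_parameters,
    propagate_shapes,
)

_ACTIVATIONS = ("relu", "identity")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# core ops
# ---------------------------------------------------------------------------

def conv3d_valid(
    inp: np.ndarray,
    kernels: np.ndarray,
    biases: np.ndarray,
    activation: str = "identity",
) -> np.ndarray:
    """Valid (unpadded) 3D cross-correlation over one feature tensor.

    Parameters
    ----------
    inp:
        ``(C, D, H, W)`` input feature maps.
    kernels:
        ``(J, C, kd, kh, kw)`` kernel bank (J output maps).
    biases:
        ``(J,)`` one bias per output map.
    activation:
        ``"relu"`` or ``"identity"``, applied elementwise to the raw
        convolution result.

    Returns ``(J, D-kd+1, H-kh+1, W-kw+1)``; each axis shrinks by
    ``kernel - 1``.
    """
    if inp.ndim != 4 or kernels.ndim != 5:
        raise ValueError("expected (C,D,H,W) input and (J,C,kd,kh,kw) kernels")
    if kernels.shape[1] != inp.shape[0]:
        raise ValueError(
            f"channel mismatch: input has {inp.shape[0]}, kernels expect "
            f"{kernels.shape[1]}"
        )
    if any(kernels.shape[i + 2] > inp.shape[i + 1] for i in range(3)):
        raise ValueError(
            f"kernel {kernels.shape[2:]} larger than input {inp.shape[1:]}"
        )
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    out = _conv_forward(inp[None], kernels, biases)[0]
    return _relu(out) if activation == "relu" else out


def _offsets(kshape: tuple[int, int, int]):
    kd, kh, kw = kshape
    return [(p, q, r) for p in range(kd) for q in range(kh) for r in range(kw)]


def _im2col(x: np.ndarray, kshape: tuple[int, int, int]):
    """Unfold (B,C,D,H,W) into (B, C*K, M) columns, K = kernel volume,
    M = output volume.  One near-sequential slice copy per kernel offset,
    which is far cheaper than materializing the full sliding-window view."""
    b, c, d, h, w = x.shape
    kd, kh, kw = kshape
    do, ho, wo = d - kd + 1, h - kh + 1, w - kw + 1
    m = do * ho * wo
    col = np.empty((b, c, kd * kh * kw, m), dtype=x.dtype)
    for o, (p, q, r) in enumerate(_offsets(kshape)):
        col[:, :, o, :] = x[:, :, p:p + do, q:q + ho, r:r + wo].reshape(b, c, m)
    return col.reshape(b, c * kd * kh * kw, m), (do, ho, wo)


def _conv_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, return_col: bool = False
):
    """Batched valid cross-correlation: (B,C,D,H,W) x (J,C,kd,kh,kw) -> (B,J,...).

    With ``return_col`` the im2col matrix is also returned so the backward
    pass can reuse it for the weight gradient.
    """
    j = w.shape[0]
    col, (do, ho, wo) = _im2col(x, w.shape[2:])
    w2 = w.reshape(j, -1)
    out = np.matmul(w2, col)  # (B, J, M) via BLAS
    out += b[None, :, None]
    out = out.reshape(x.shape[0], j, do, ho, wo)
    return (out, col) if return_col else out


def _conv_backward(
    col: np.ndarray,
    w: np.ndarray,
    gout: np.ndarray,
    in_shape: tuple[int, ...],
    need_dx: bool = True,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of the valid cross-correlation.

    ``col`` is the forward im2col matrix, ``gout`` the upstream gradient
    (B,J,Do,Ho,Wo).  Returns ``(dx, dw, db)``; ``dx`` is None when
    ``need_dx`` is false (the first layer has no upstream input to update).
    """
    b, j = gout.shape[:2]
    do, ho, wo = gout.shape[2:]
    m = do * ho * wo
    g2 = np.ascontiguousarray(gout, dtype=np.float32).reshape(b, j, m)
    dw = np.matmul(g2, col.swapaxes(1, 2)).sum(axis=0).reshape(w.shape)
    db = g2.sum(axis=(0, 2))
    dx = None
    if need_dx:
        dx = np.zeros(in_shape, dtype=np.float32)
        for p, q, r in _offsets(w.shape[2:]):
            w_o = np.ascontiguousarray(w[:, :, p, q, r].T)  # (C, J)
            contrib = np.matmul(w_o, g2)  # (B, C, M)
            dx[:, :, p:p + do, q:q + ho, r:r + wo] += contrib.reshape(
                b, -1, do, ho, wo
            )
    return dx, dw.astype(np.float32), db.astype(np.float32)


def _pool_forward(
    x: np.ndarray, kernel: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Max-pooling with stride = kernel and ceiling division per axis.

    Partial windows at the far borders are padded with -inf so they still
    emit an element (this is what makes 62/3 -> 21 and 5/2 -> 3 in the
    reference stack).  Returns (output, padded input) — the padded input is
    kept for the backward pass.
    """
    b, c, d, h, w = x.shape
    kd, kh, kw = kernel
    pd, ph, pw = (-d) % kd, (-h) % kh, (-w) % kw
    xp = np.pad(
        x,
        ((0, 0), (0, 0), (0, pd), (0, ph), (0, pw)),
        constant_values=-np.inf,
    )
    out = pool_max_forward(xp, kd, kh, kw)
    return out, xp


def _pool_backward(
    gout: np.ndarray,
    xp: np.ndarray,
    out: np.ndarray,
    kernel: tuple[int, int, int],
    in_shape: tuple[int, ...],
) -> np.ndarray:
    """Route the gradient back to the max positions.

    Ties within a window split the gradient equally — a valid subgradient
    that avoids an argmax scatter and keeps every step a contiguous
    elementwise pass.
    """
    b, c, d, h, w = in_shape
    kd, kh, kw = kernel
    return pool_max_backward(
        xp, out, np.ascontiguousarray(gout, dtype=np.float32),
        kd, kh, kw, d, h, w,
    )


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class Lite3DModel:
    """A built Lite3D network.

    ``params`` holds one ``(weights, biases)`` pair per conv layer, in
    stack order; pooling layers are parameter-free.  The prediction head
    is the last conv layer, whose 1 x l @ 1 x 1 output map is flattened to
    the class scores — there are no fully connected layers.
    """

    arch: ArchConfig
    params: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    hidden_activation: str = "relu"
    classes: tuple[str, ...] | None = None  # category names, head order

    @property
    def n_categories(self) -> int:
        return self.arch.n_categories

    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in self.params)

    # -- inference ----------------------------------------------------------

    def forward_batch(self, clips: np.ndarray) -> np.ndarray:
        """Probabilities for a batch of clips ``(B, k, c, n, n)`` -> ``(B, l)``."""
        logits, _ = self._forward(self._to_internal(clips), keep_cache=False)
        return softmax(logits, axis=1)

    def forward(self, clip: np.ndarray) -> np.ndarray:
        """Class probabilities for one clip ``(k, c, n, n)``; sums to 1."""
        return self.forward_batch(clip[None])[0]

    def extract_features(self, clip: np.ndarray) -> np.ndarray:
        """Pre-softmax flatten-layer values for one clip (length l)."""
        logits, _ = self._forward(self._to_internal(clip[None]), keep_cache=False)
        return logits[0]

    def predict(self, clips: np.ndarray) -> np.ndarray:
        """Argmax category indices for a batch of clips."""
        return self.forward_batch(clips).argmax(axis=1)

    # -- internals ----------------------------------------------------------

    def _to_internal(self, clips: np.ndarray) -> np.ndarray:
        a = self.arch
        expect = (a.input_depth, a.input_channels, a.input_height, a.input_width)
        if clips.ndim != 5 or clips.shape[1:] != expect:
            raise ValueError(
                f"clip batch shape {clips.shape} does not match arch input "
                f"(B, {', '.join(map(str, expect))})"
            )
        # (B, D, C, H, W) -> (B, C, D, H, W)
        return np.ascontiguousarray(clips.swapaxes(1, 2), dtype=np.float32)

    def _forward(self, x: np.ndarray, keep_cache: bool):
        """Run the stack; returns (logits, cache-for-backward)."""
        cache: list[tuple] = []
        conv_i = 0
        for layer in self.arch.layers:
            if layer.kind == "conv":
                w, b = self.params[conv_i]
                conv_i += 1
                pre, col = _conv_forward(x, w, b, return_col=True)
                is_head = conv_i == len(self.params)
                out = pre if is_head else _relu(pre)
                if keep_cache:
                    cache.append(
                        ("conv", col, x.shape, w, pre if not is_head else None)
                    )
                x = out
            else:
                kern = (layer.temporal_kernel, layer.spatial_kernel,
                        layer.spatial_kernel)
                out, xp = _pool_forward(x, kern)
                if keep_cache:
                    cache.append(("pool", kern, x.shape, xp, out))
                x = out
        logits = x.reshape(x.shape[0], -1)
        if logits.shape[1] != self.n_categories:
            raise ValueError(
                f"head produced {logits.shape[1]} values, expected "
                f"{self.n_categories}; arch/input mismatch"
            )
        return logits, cache

    def _backward(self, cache: list[tuple], dlogits: np.ndarray):
        """Gradients for every conv layer given d(loss)/d(logits)."""
        grads: list[tuple[np.ndarray, np.ndarray] | None] = [None] * len(self.params)
        g = dlogits.reshape(dlogits.shape[0], self.n_categories, 1, 1, 1)
        g = np.ascontiguousarray(g, dtype=np.float32)
        conv_i = len(self.params)
        for entry in reversed(cache):
            if entry[0] == "conv":
                _, col, in_shape, w, pre = entry
                conv_i -= 1
                if pre is not None:  # hidden layer: ReLU gate
                    g = g * (pre > 0)
                dx, dw, db = _conv_backward(
                    col, w, g, in_shape, need_dx=conv_i > 0
                )
                grads[conv_i] = (dw, db)
                g = dx
            else:
                _, kern, in_shape, xp, out = entry
                g = _pool_backward(g, xp, out, kern, in_shape)
        return grads  # type: ignore[return-value]

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        """Serialize to one .npz file with the arch config embedded."""
        meta = {
            "layers": [
                {
                    "kind": l.kind,
                    "spatial_kernel": l.spatial_kernel,
                    "temporal_kernel": l.temporal_kernel,
                    "n_kernels": l.n_kernels,
                }
                for l in self.arch.layers
            ],
            "input_width": self.arch.input_width,
            "input_height": self.arch.input_height,
            "input_depth": self.arch.input_depth,
            "input_channels": self.arch.input_channels,
            "n_categories": self.arch.n_categories,
            "hidden_activation": self.hidden_activation,
            "classes": list(self.classes) if self.classes else None,
        }
        arrays = {}
        for i, (w, b) in enumerate(self.params):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        with open(path, "wb") as fh:
            np.savez(fh, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "Lite3DModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            params = []
            i = 0
            while f"w{i}" in data:
                params.append((data[f"w{i}"], data[f"b{i}"]))
                i += 1
        layers = tuple(
            LayerSpec(d["kind"], d["spatial_kernel"], d["temporal_kernel"],
                      d["n_kernels"])
            for d in meta["layers"]
        )
        arch = ArchConfig(
            layers=layers,
            input_width=meta["input_width"],
            input_height=meta["input_height"],
            input_depth=meta["input_depth"],
            input_channels=meta["input_channels"],
            n_categories=meta["n_categories"],
        )
        classes = meta.get("classes")
        return cls(arch=arch, params=params,
                   hidden_activation=meta["hidden_activation"],
                   classes=tuple(classes) if classes else None)


def build_model(arch: ArchConfig, seed: int = 0,
                hidden_activation: str = "relu") -> Lite3DModel:
    """Build a randomly initialized Lite3D model.

    Weights are fan-in-scaled Gaussian (std = sqrt(2 / fan_in), the usual
    choice for rectified-linear stacks), biases zero, fully determined by
    ``seed``.  Raises :class:`InvalidConfigError` if the arch does not
    propagate to a valid final shape.
    """
    trace = propagate_shapes(arch)  # raises InvalidConfigError on bad arch
    final = trace.final
    if (final.width, final.height, final.depth) != (
        arch.target_final_shape[0],
        arch.target_final_shape[1],
        arch.target_final_shape[2],
    ):
        raise InvalidConfigError(
            f"stack ends at {final.depth}x{final.channels}@{final.height}"
            f"x{final.width}, not the target {arch.target_final_shape}"
        )
    if hidden_activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {hidden_activation!r}")
    rng = np.random.default_rng(seed)
    params: list[tuple[np.ndarray, np.ndarray]] = []
    c_in = arch.input_channels
    for layer in arch.layers:
        if layer.kind != "conv":
            continue
        j = layer.n_kernels  # type: ignore[assignment]
        shape = (j, c_in, layer.temporal_kernel, layer.spatial_kernel,
                 layer.spatial_kernel)
        fan_in = c_in * layer.temporal_kernel * layer.spatial_kernel ** 2
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)
        b = np.zeros(j, dtype=np.float32)
        params.append((w, b))
        c_in = j
    model = Lite3DModel(arch=arch, params=params,
                        hidden_activation=hidden_activation)
    expected = count_parameters(arch).total
    assert model.n_parameters() == expected, "parameter count mismatch"
    return model
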