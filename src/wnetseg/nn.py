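"""Numpy executor for :class:`~wnetseg.architecture.NetworkGraph`.

Walks the layer graph in topological order and implements exact
reverse-mode gradients for every layer role, plus the Adam optimiser.
Convolutions use "same" zero padding (asymmetric for even kernels: pad
``(k-1)//2`` before, ``k//2`` after) via an im2col/matmul kernel; pooling is
the 2x2/stride-2 max with tie-splitting gradients; upsampling is
nearest-neighbour; dropout is the inverted form, active only during
training.  Weight initialisation is fan-in-scaled (He) from a seeded
generator.

The public interface is NCHW (batch, channel, height, width) to match the
shape annotations on the graph; internally activations are kept NHWC so the
im2col gather/scatter runs over contiguous channel vectors, which is what
keeps CPU training tractable.  Correctness of the backward pass is pinned
by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

from .architecture import NetworkGraph

__all__ = ["init_params", "forward", "backward", "num_params", "Adam"]

_CONV_ROLES = {"conv3x3": 3, "upconv2x2": 2, "conv1x1_out": 1}


def init_params(graph: NetworkGraph, rng: np.random.Generator,
                dtype=np.float32) -> dict:
    """He-initialised kernels/biases for every convolution node.

    Kernels are stored as (out_channels, in_channels, kh, kw).
    """
    params: dict = {}
    for nid in graph.topological_order():
        node = graph.nodes[nid]
        if node.role in _CONV_ROLES:
            k = node.attrs["kernel"]
            cin = node.attrs["in_channels"]
            cout = node.attrs["filters"]
            std = np.sqrt(2.0 / (k * k * cin))
            params[nid] = {
                "W": (rng.standard_normal((cout, cin, k, k)) * std).astype(dtype),
                "b": np.zeros(cout, dtype=dtype),
            }
    return params


def num_params(params: dict) -> int:
    return sum(int(a.size) for p in params.values() for a in p.values())


def _pad_amounts(k: int) -> tuple:
    return (k - 1) // 2, k // 2


def _im2col(x, kh, kw):
    """x is NHWC; returns the (n*h*w, kh*kw*c) patch matrix."""
    n, h, w, c = x.shape
    p0h, p1h = _pad_amounts(kh)
    p0w, p1w = _pad_amounts(kw)
    xp = np.pad(x, ((0, 0), (p0h, p1h), (p0w, p1w), (0, 0)))
    cols = np.empty((n, h, w, kh, kw, c), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = xp[:, i:i + h, j:j + w, :]
    return cols.reshape(n * h * w, kh * kw * c)


def _conv_forward(x, W, b):
    n, h, w, c = x.shape
    f, _, kh, kw = W.shape
    if kh == 1 and kw == 1:
        cols = x.reshape(-1, c)
    else:
        cols = _im2col(x, kh, kw)
    wmat = W.transpose(2, 3, 1, 0).reshape(kh * kw * c, f)
    out = cols @ wmat + b
    return out.reshape(n, h, w, f), cols


def _conv_backward(cols, x_shape, W, dout):
    n, h, w, c = x_shape
    f, _, kh, kw = W.shape
    wmat = W.transpose(2, 3, 1, 0).reshape(kh * kw * c, f)
    dout2 = dout.reshape(-1, f)
    dwmat = cols.T @ dout2
    dW = dwmat.reshape(kh, kw, c, f).transpose(3, 2, 0, 1)
    db = dout2.sum(axis=0)
    dcols = dout2 @ wmat.T
    if kh == 1 and kw == 1:
        dx = dcols.reshape(n, h, w, c)
    else:
        p0h, p1h = _pad_amounts(kh)
        p0w, p1w = _pad_amounts(kw)
        dcols = dcols.reshape(n, h, w, kh, kw, c)
        dxp = np.zeros((n, h + p0h + p1h, w + p0w + p1w, c), dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        dx = dxp[:, p0h:p0h + h, p0w:p0w + w, :]
    return dx, np.ascontiguousarray(dW).astype(W.dtype), db.astype(W.dtype)


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x, y, dy):
    return np.where(x > 0, dy, dy * (y + 1.0))


def forward(
    graph: NetworkGraph,
    params: dict,
    x: np.ndarray,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
    order: list | None = None,
) -> tuple:
    """Run the graph on a batch ``x`` of shape (n, c, h, w).

    Returns ``(probabilities, cache)`` with probabilities again (n, 1, h, w);
    the cache holds everything :func:`backward` needs.  Dropout masks are
    drawn from ``rng`` only when ``training`` is set (``rng`` is then
    required).
    """
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError(f"expected (n, c, h, w) input, got shape {x.shape}")
    s = graph.input_shape
    if x.shape[1:] != (s.channels, s.height, s.width):
        raise ValueError(
            f"input shape {x.shape[1:]} does not match graph input "
            f"({s.channels}, {s.height}, {s.width})"
        )
    if training and rng is None:
        raise ValueError("training-mode forward requires an rng for dropout")
    order = order if order is not None else graph.topological_order()
    acts: dict = {}
    cache: dict = {"order": order, "acts": acts, "training": training}
    for nid in order:
        node = graph.nodes[nid]
        preds = graph.predecessors(nid)
        role = node.role
        if role == "input":
            out = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # to NHWC
        elif role in _CONV_ROLES:
            out, cols = _conv_forward(
                acts[preds[0]], params[nid]["W"], params[nid]["b"]
            )
            cache[(nid, "cols")] = cols
            if node.attrs.get("activation") == "sigmoid":
                with np.errstate(over="ignore"):
                    out = 1.0 / (1.0 + np.exp(-out))
                cache[(nid, "probs")] = out
        elif role == "activation":
            z = acts[preds[0]]
            out = _elu(z) if node.attrs["kind"] == "elu" else np.maximum(z, 0.0)
        elif role == "maxpool2x2":
            z = acts[preds[0]]
            n, h, w, c = z.shape
            win = z.reshape(n, h // 2, 2, w // 2, 2, c)
            out = win.max(axis=(2, 4))
        elif role == "dropout":
            z = acts[preds[0]]
            rate = float(node.attrs.get("rate", 0.0))
            if training and rate > 0.0:
                mask = (rng.random(z.shape) >= rate).astype(z.dtype)
                out = z * mask / (1.0 - rate)
                cache[(nid, "mask")] = mask
            else:
                out = z
        elif role == "upsample":
            z = acts[preds[0]]
            out = np.repeat(np.repeat(z, 2, axis=1), 2, axis=2)
        elif role == "concat":
            out = np.concatenate([acts[p] for p in preds], axis=3)
        else:  # pragma: no cover - graph validation precludes this
            raise ValueError(f"unknown role {role!r}")
        acts[nid] = out
    probs = acts[graph.output_id]
    if not np.isfinite(probs).all():
        raise FloatingPointError("non-finite values in network output")
    return np.ascontiguousarray(probs.transpose(0, 3, 1, 2)), cache


def backward(graph: NetworkGraph, params: dict, cache: dict,
             dprobs: np.ndarray) -> dict:
    """Gradients of a scalar loss w.r.t. every parameter, given dL/dprobs
    (NCHW, matching :func:`forward`'s returned probabilities)."""
    acts = cache["acts"]
    order = cache["order"]
    grads: dict = {}
    dprobs = np.asarray(dprobs).transpose(0, 2, 3, 1)  # to NHWC
    d: dict = {graph.output_id: dprobs}

    def _send(pid, grad):
        if pid in d:
            d[pid] = d[pid] + grad
        else:
            d[pid] = grad

    for nid in reversed(order):
        if nid not in d:
            continue
        node = graph.nodes[nid]
        preds = graph.predecessors(nid)
        dy = d.pop(nid)
        role = node.role
        if role == "input":
            continue
        if role in _CONV_ROLES:
            if node.attrs.get("activation") == "sigmoid":
                probs = cache[(nid, "probs")]
                dy = dy * probs * (1.0 - probs)
            dx, dW, db = _conv_backward(
                cache[(nid, "cols")], acts[preds[0]].shape,
                params[nid]["W"], dy,
            )
            grads[nid] = {"W": dW, "b": db}
            _send(preds[0], dx)
        elif role == "activation":
            z = acts[preds[0]]
            if node.attrs["kind"] == "elu":
                _send(preds[0], _elu_grad(z, acts[nid], dy))
            else:
                _send(preds[0], dy * (z > 0))
        elif role == "maxpool2x2":
            z = acts[preds[0]]
            n, h, w, c = z.shape
            win = z.reshape(n, h // 2, 2, w // 2, 2, c)
            maxed = acts[nid][:, :, None, :, None, :]
            mask = (win == maxed).astype(dy.dtype)
            # split the gradient evenly across ties to keep gradcheck exact
            counts = mask.sum(axis=(2, 4), keepdims=True)
            dz = mask * (dy[:, :, None, :, None, :] / counts)
            _send(preds[0], dz.reshape(n, h, w, c))
        elif role == "dropout":
            if cache["training"] and (nid, "mask") in cache:
                rate = float(node.attrs["rate"])
                _send(preds[0], dy * cache[(nid, "mask")] / (1.0 - rate))
            else:
                _send(preds[0], dy)
        elif role == "upsample":
            n, h2, w2, c = dy.shape
            dz = dy.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
            _send(preds[0], dz)
        elif role == "concat":
            offset = 0
            for pid in preds:
                ch = acts[pid].shape[3]
                _send(pid, dy[:, :, :, offset:offset + ch])
                offset += ch
    return grads


class Adam:
    """Standard Adam (β1=0.9, β2=0.999, ε=1e-8) over the nested param dict."""

    def __init__(self, learning_rate: float = 1e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        if learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for nid, pg in grads.items():
            for key, g in pg.items():
                slot = (nid, key)
                m = self._m.get(slot)
                if m is None:
                    m = np.zeros_like(params[nid][key])
                    self._v[slot] = np.zeros_like(m)
                v = self._v[slot]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self._m[slot], self._v[slot] = m, v
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                params[nid][key] -= (
                    self.lr * mhat / (np.sqrt(vhat) + self.eps)
                ).astype(params[nid][key].dtype)
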