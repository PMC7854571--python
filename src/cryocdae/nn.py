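"""Minimal CPU neural-network engine for the convolutional autoencoders.

Everything is float32 and channels-last ``(N, H, W, C)``. Convolutions are
evaluated via im2col, one BLAS matmul per pass. Each layer owns persistent
workspace buffers (re-allocated only when the batch shape changes): on a
single core the arithmetic is cheap relative to repeated large allocations,
so buffer reuse is what keeps training fast. Layers cache what their
backward pass needs; a :class:`Sequential` chains them and an
:class:`RMSProp` optimizer updates parameters in place.

Weight initialization is a seeded uniform fan-in scheme:
``U(-sqrt(1/fan_in), +sqrt(1/fan_in))``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "TransposedConv2x2",
    "Dropout",
    "Sequential",
    "RMSProp",
    "ShapeError",
]

F32 = np.float32

# Workspace arrays shared across networks of identical architecture: keys are
# (layer slot signature, buffer name, shape, dtype). A training step
# (forward + backward + update) is atomic in this engine, so two networks
# never need the same slot's scratch space at the same time.
_WORKSPACES: dict = {}


def clear_workspaces() -> None:
    """Drop all shared scratch arrays (frees memory; they re-warm on use)."""
    _WORKSPACES.clear()


class ShapeError(ValueError):
    """Raised when an image side is incompatible with the pooling pyramid."""


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(1.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(F32)


class Layer:
    """Base layer: ``params()`` yields (name, array) pairs; grads in ``grads``."""

    grads: dict
    slot: str | None = None  # workspace signature, assigned by Sequential

    def params(self):
        return ()

    def __getstate__(self):
        state = self.__dict__.copy()
        for transient in ("_bufs", "_last", "_x"):
            state.pop(transient, None)
        return state

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # ---------------------------------------------------------- workspaces
    def _buf(self, name: str, shape, dtype=F32) -> np.ndarray:
        """A persistent scratch array, keyed by layer slot + shape.

        Keying by shape lets alternating batch sizes (full batches vs the
        final partial one) keep separate workspaces instead of reallocating
        every epoch; keying by slot lets identically built networks share.
        """
        if self.slot is not None:
            bufs = _WORKSPACES
            key = (self.slot, name, shape, np.dtype(dtype).str)
        else:
            bufs = self.__dict__.setdefault("_bufs", {})
            key = (name, shape, np.dtype(dtype).str)
        arr = bufs.get(key)
        if arr is None:
            arr = np.zeros(shape, dtype)
            bufs[key] = arr
        self.__dict__.setdefault("_last", {})[name] = arr
        return arr

    def _last_buf(self, name: str) -> np.ndarray:
        return self._last[name]

    def release_buffers(self) -> None:
        self.__dict__.pop("_bufs", None)
        self.__dict__.pop("_last", None)


class Conv2D(Layer):
    """Stride-1 same-padded 2D convolution with a square odd kernel.

    Two evaluation strategies: a single im2col GEMM for wide outputs, and a
    per-offset shift accumulation for narrow outputs (the channel-collapsing
    final convolution), where building the full column matrix would dwarf
    the arithmetic.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel_side: int,
        rng: np.random.Generator,
        relu: bool = False,
    ):
        if kernel_side % 2 != 1:
            raise ValueError("kernel_side must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_side
        self.relu = relu  # fused activation: saves full-size tensor passes
        fan_in = kernel_side * kernel_side * c_in
        self.W = _uniform_init(rng, (fan_in, c_out), fan_in)
        self.b = np.zeros(c_out, dtype=F32)
        self.grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}

    def params(self):
        yield "W", self.W
        yield "b", self.b

    @property
    def _narrow(self) -> bool:
        return self.c_out <= 4 and self.c_in > 1

    def forward(self, x, train=False, rng=None):
        k, p = self.k, self.k // 2
        n, h, w, ci = x.shape
        if ci != self.c_in:
            raise ShapeError(f"expected {self.c_in} input channels, got {ci}")
        xp = self._buf("xp", (n, h + 2 * p, w + 2 * p, ci))  # zero edges persist
        xp[:, p : p + h, p : p + w, :] = x
        y = self._buf("y", (n, h, w, self.c_out))
        yf = y.reshape(-1, self.c_out)
        if self._narrow:
            w3 = self.W.reshape(k * k, ci, self.c_out)
            xs = self._buf("xs", (n * h * w, ci))
            tmp = self._buf("ytmp", (n * h * w, self.c_out))
            for off in range(k * k):
                di, dj = divmod(off, k)
                np.copyto(xs.reshape(n, h, w, ci), xp[:, di : di + h, dj : dj + w, :])
                if off == 0:
                    np.matmul(xs, w3[off], out=yf)
                else:
                    np.matmul(xs, w3[off], out=tmp)
                    yf += tmp
        else:
            cols = self._buf("cols", (n * h * w, k * k * ci))
            cols3 = cols.reshape(n * h * w, k * k, ci)
            for di in range(k):
                for dj in range(k):
                    np.copyto(
                        cols3[:, di * k + dj, :].reshape(n, h, w, ci),
                        xp[:, di : di + h, dj : dj + w, :],
                    )
            np.matmul(cols, self.W, out=yf)
        y += self.b
        if self.relu:
            np.maximum(y, 0, out=y)
        self._hw = (n, h, w)
        return y

    def backward(self, dy, need_dx: bool = True):
        k, p = self.k, self.k // 2
        n, h, w = self._hw
        ci = self.c_in
        if self.relu:
            y = self._last_buf("y")
            mask = self._buf("relu_mask", y.shape, bool)
            np.greater(y, 0, out=mask)
            dy = dy.reshape(y.shape)
            if dy.flags.c_contiguous:  # gate in place: dy is upstream scratch
                np.multiply(dy, mask, out=dy)
            else:
                gated = self._buf("relu_dy", y.shape)
                np.multiply(dy, mask, out=gated)
                dy = gated
        dyf = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        np.sum(dyf, axis=0, out=self.grads["b"])
        dxp = self._buf("dxp", (n, h + 2 * p, w + 2 * p, ci)) if need_dx else None
        if need_dx:
            dxp.fill(0)
        if self._narrow:
            xp = self._last_buf("xp")
            w3 = self.W.reshape(k * k, ci, self.c_out)
            gw3 = self.grads["W"].reshape(k * k, ci, self.c_out)
            xs = self._last_buf("xs")
            tmp = self._buf("dxtmp", (n * h * w, ci))
            for off in range(k * k):
                di, dj = divmod(off, k)
                np.copyto(xs.reshape(n, h, w, ci), xp[:, di : di + h, dj : dj + w, :])
                np.matmul(xs.T, dyf, out=gw3[off])
                if need_dx:
                    np.matmul(dyf, w3[off].T, out=tmp)
                    dxp[:, di : di + h, dj : dj + w, :] += tmp.reshape(n, h, w, ci)
        else:
            cols = self._last_buf("cols")
            gwt = self._buf("gwt", (self.c_out, k * k * ci))
            np.matmul(dyf.T, cols, out=gwt)  # this layout is the faster GEMM
            self.grads["W"][...] = gwt.T
            if need_dx:
                dcols = self._buf("dcols", (n * h * w, k * k * ci))
                np.matmul(dyf, self.W.T, out=dcols)
                dcols5 = dcols.reshape(n, h, w, k * k, ci)
                for di in range(k):
                    for dj in range(k):
                        dxp[:, di : di + h, dj : dj + w, :] += dcols5[:, :, :, di * k + dj, :]
        if not need_dx:
            return dy
        return dxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    """The gradient mask is recovered from the cached output (y > 0 iff x > 0)."""

    def forward(self, x, train=False, rng=None):
        y = self._buf("y", x.shape)
        np.maximum(x, 0, out=y)
        return y

    def backward(self, dy):
        mask = self._buf("mask", dy.shape, bool)
        np.greater(self._last_buf("y"), 0, out=mask)
        dx = self._buf("dx", dy.shape)
        np.multiply(dy, mask, out=dx)
        return dx


class MaxPool2D(Layer):
    """2x2 max pooling via pairwise maxima over the four window corners.

    Backward routes each gradient to the first corner (row-major order)
    attaining the maximum, matching the usual argmax tie-break.
    """

    def __init__(self, factor: int = 2):
        if factor != 2:
            raise ValueError("only 2x2 pooling is supported")
        self.factor = factor

    @staticmethod
    def _corners(a):
        return (a[:, ::2, ::2, :], a[:, ::2, 1::2, :], a[:, 1::2, ::2, :], a[:, 1::2, 1::2, :])

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"image sides must be divisible by 2 at each pooling; got {h}x{w}")
        q = self._corners(x)
        y = self._buf("y", (n, h // 2, w // 2, c))
        tmp = self._buf("tmp", y.shape)
        np.maximum(q[0], q[1], out=y)
        np.maximum(q[2], q[3], out=tmp)
        np.maximum(y, tmp, out=y)
        self._x = x
        self._shape = (n, h, w, c)
        return y

    def backward(self, dy):
        n, h, w, c = self._shape
        y = self._last_buf("y")
        dx = self._buf("dx", (n, h, w, c))
        dx.fill(0)
        unclaimed = self._buf("unclaimed", y.shape, bool)
        unclaimed.fill(True)
        hit = self._buf("hit", y.shape, bool)
        routed = self._buf("routed", y.shape)
        for qx, qdx in zip(self._corners(self._x), self._corners(dx)):
            np.equal(qx, y, out=hit)
            hit &= unclaimed
            unclaimed &= ~hit
            np.multiply(dy, hit, out=routed)
            qdx += routed
        self._x = None
        return dx


class TransposedConv2x2(Layer):
    """Stride-2 transposed convolution with a 2x2 kernel (exact 2x upsampling).

    Each input pixel maps linearly to a 2x2 output block, so the whole layer
    is one matmul followed by a pixel shuffle — no overlap, no checkerboard.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = False):
        self.c_in, self.c_out = c_in, c_out
        self.relu = relu
        self.W = _uniform_init(rng, (c_in, 4 * c_out), c_in)
        self.b = np.zeros(c_out, dtype=F32)
        self.grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}

    def params(self):
        yield "W", self.W
        yield "b", self.b

    def forward(self, x, train=False, rng=None):
        n, h, w, _ = x.shape
        xf = self._buf("xf", (n * h * w, self.c_in))
        np.copyto(xf.reshape(x.shape), x)
        y4 = self._buf("y4", (n * h * w, 4 * self.c_out))
        np.matmul(xf, self.W, out=y4)
        y = self._buf("y", (n, 2 * h, 2 * w, self.c_out))
        np.copyto(
            y.reshape(n, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5),
            y4.reshape(n, h, w, 2, 2, self.c_out),
        )
        y += self.b
        if self.relu:
            np.maximum(y, 0, out=y)
        self._shape = (n, h, w)
        return y

    def backward(self, dy):
        n, h, w = self._shape
        if self.relu:
            y = self._last_buf("y")
            mask = self._buf("relu_mask", y.shape, bool)
            np.greater(y, 0, out=mask)
            if dy.flags.c_contiguous:
                np.multiply(dy, mask, out=dy)
            else:
                gated = self._buf("relu_dy", y.shape)
                np.multiply(dy, mask, out=gated)
                dy = gated
        dy4 = self._buf("dy4", (n * h * w, 4 * self.c_out))
        np.copyto(
            dy4.reshape(n, h, w, 2, 2, self.c_out),
            dy.reshape(n, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5),
        )
        np.matmul(self._last_buf("xf").T, dy4, out=self.grads["W"])
        np.sum(dy.reshape(-1, self.c_out), axis=0, out=self.grads["b"])
        dx = self._buf("dx", (n, h, w, self.c_in))
        np.matmul(dy4, self.W.T, out=dx.reshape(-1, self.c_in))
        return dx


class Dropout(Layer):
    """Inverted dropout: active only when ``train`` is True; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._active = False

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._active = False
            return x
        keep = 1.0 - self.rate
        mask = self._buf("mask", x.shape)
        kept = self._buf("kept", x.shape, bool)
        rng.random(dtype=np.float32, out=mask)
        np.less(mask, keep, out=kept)
        np.multiply(kept, F32(1.0 / keep), out=mask)
        y = self._buf("y", x.shape)
        np.multiply(x, mask, out=y)
        self._active = True
        return y

    def backward(self, dy):
        if not self._active:
            return dy
        dx = self._buf("dx", dy.shape)
        np.multiply(dy, self._last_buf("mask"), out=dx)
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers
        for i, layer in enumerate(layers):
            shape_sig = getattr(layer, "c_in", ""), getattr(layer, "c_out", "")
            layer.slot = f"{i}:{type(layer).__name__}:{shape_sig[0]}x{shape_sig[1]}"

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for i, layer in zip(range(len(self.layers) - 1, -1, -1), reversed(self.layers)):
            if i == 0 and isinstance(layer, Conv2D):
                dy = layer.backward(dy, need_dx=False)  # no gradient needed below the input
            else:
                dy = layer.backward(dy)
        return dy

    def release_buffers(self) -> None:
        for layer in self.layers:
            layer.release_buffers()
        clear_workspaces()

    def parameters(self):
        """Yield (layer, name, array) triples over all trainable parameters."""
        for layer in self.layers:
            for name, arr in layer.params():
                yield layer, name, arr

    @property
    def n_params(self) -> int:
        return sum(arr.size for _, _, arr in self.parameters())

    def state(self) -> list[np.ndarray]:
        return [arr.copy() for _, _, arr in self.parameters()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = list(self.parameters())
        if len(own) != len(arrays):
            raise ValueError("state length mismatch")
        for (layer, name, arr), new in zip(own, arrays):
            if arr.shape != new.shape:
                raise ValueError(f"shape mismatch for {type(layer).__name__}.{name}")
            arr[...] = new.astype(F32)


class RMSProp:
    """RMSProp with the conventional decay 0.9 and epsilon 1e-8."""

    def __init__(self, net: Sequential, learning_rate: float, rho: float = 0.9, eps: float = 1e-8):
        self.net = net
        self.lr = F32(learning_rate)
        self.rho = F32(rho)
        self.eps = F32(eps)
        self._cache = [np.zeros_like(arr) for _, _, arr in net.parameters()]

    def step(self) -> None:
        for cache, (layer, name, arr) in zip(self._cache, self.net.parameters()):
            g = layer.grads[name]
            cache *= self.rho
            cache += (1 - self.rho) * g * g
            arr -= self.lr * g / (np.sqrt(cache) + self.eps)
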