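"""Minimal 3D convolution primitives with explicit gradients (NumPy).

All convolutions use odd kernels with 'same' zero padding; downsampling is
strided convolution, upsampling is its adjoint (transposed convolution).
Layers operate on single samples shaped (channels, D, H, W); minibatch
gradients are accumulated by the trainer.

Patch matrices are assembled per kernel offset with block copies (one
contiguous copy per offset) rather than a window-view transpose, which is
the difference between memcpy speed and a 7-axis gather.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["Conv3", "ConvT3", "Conv1", "relu", "relu_grad"]


def _out_size(n: int, k: int, stride: int) -> int:
    p = (k - 1) // 2
    return (n + 2 * p - k) // stride + 1


def _offset_slices(k: int, stride: int, out_spatial):
    """Per kernel offset, the slices into the padded array that align the
    offset with every output position."""
    for off in itertools.product(range(k), repeat=3):
        yield off, tuple(
            slice(a, a + stride * (n - 1) + 1, stride) for a, n in zip(off, out_spatial)
        )


def _gather_cols(xp: np.ndarray, k: int, stride: int, out_spatial) -> np.ndarray:
    """Padded (C, ...) image -> (k^3 * C, L) patch matrix, offset-major."""
    c = xp.shape[0]
    L = int(np.prod(out_spatial))
    cols = np.empty((k**3, c, L), dtype=np.float32)
    for i, (_, sl) in enumerate(_offset_slices(k, stride, out_spatial)):
        cols[i] = xp[(slice(None),) + sl].reshape(c, L)
    return cols.reshape(k**3 * c, L)


def _scatter_cols(cols: np.ndarray, c: int, k: int, stride: int, out_spatial, padded_shape):
    """Adjoint of _gather_cols: accumulate (k^3 * C, L) back into a padded image."""
    out = np.zeros((c,) + tuple(padded_shape), dtype=np.float32)
    cols = cols.reshape(k**3, c, *out_spatial)
    for i, (_, sl) in enumerate(_offset_slices(k, stride, out_spatial)):
        out[(slice(None),) + sl] += cols[i]
    return out


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))


class Conv3:
    """k^3 convolution, stride 1 or 2, weights (Cout, Cin, k, k, k)."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, rng=None):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        scale = np.sqrt(2.0 / (cin * k**3))
        rng = rng if rng is not None else np.random.default_rng()
        self.W = (rng.normal(0.0, scale, (cout, cin, k, k, k))).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride = k, stride
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _wmat(self) -> np.ndarray:
        # (Cout, k^3 * Cin), offset-major to match _gather_cols
        return np.ascontiguousarray(
            self.W.transpose(2, 3, 4, 1, 0).reshape(-1, self.W.shape[0]).T
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        out_spatial = tuple(_out_size(n, k, s) for n in x.shape[1:])
        xp = _pad(x.astype(np.float32, copy=False), (k - 1) // 2)
        cols = _gather_cols(xp, k, s, out_spatial)
        y = self._wmat() @ cols + self.b[:, None]
        self._cache = (cols, x.shape[1:], out_spatial, xp.shape[1:])
        return y.reshape((-1,) + out_spatial)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        cols, in_spatial, out_spatial, padded = self._cache
        k, s, p = self.k, self.stride, (self.k - 1) // 2
        cout = dy.shape[0]
        dymat = dy.reshape(cout, -1).astype(np.float32, copy=False)
        dwmat = dymat @ cols.T  # (Cout, k^3*Cin)
        cin = self.W.shape[1]
        self.dW += dwmat.T.reshape(k, k, k, cin, cout).transpose(4, 3, 0, 1, 2)
        self.db += dymat.sum(axis=1)
        self._cache = None
        if not need_dx:
            return None
        g = self._wmat().T @ dymat  # (k^3*Cin, L)
        dxp = _scatter_cols(g, cin, k, s, out_spatial, padded)
        sl = tuple(slice(p, p + n) for n in in_spatial)
        return dxp[(slice(None),) + sl]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ConvT3:
    """Transposed k^3 convolution, stride 2, weights (Cin, Cout, k, k, k);
    doubles each spatial dimension (adjoint of the stride-2 Conv3)."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2, rng=None):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        scale = np.sqrt(2.0 / (cin * k**3))
        rng = rng if rng is not None else np.random.default_rng()
        self.W = (rng.normal(0.0, scale, (cin, cout, k, k, k))).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride = k, stride
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _wmat(self) -> np.ndarray:
        # (Cin, k^3 * Cout), offset-major
        return np.ascontiguousarray(
            self.W.transpose(2, 3, 4, 1, 0).reshape(-1, self.W.shape[0]).T
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, (self.k - 1) // 2
        cin, cout = self.W.shape[:2]
        in_spatial = x.shape[1:]
        out_spatial = tuple(s * n for n in in_spatial)
        xmat = x.reshape(cin, -1).astype(np.float32, copy=False)
        g = self._wmat().T @ xmat  # (k^3*Cout, L_in)
        padded = tuple(n + 2 * p for n in out_spatial)
        ypad = _scatter_cols(g, cout, k, s, in_spatial, padded)
        sl = tuple(slice(p, p + n) for n in out_spatial)
        y = ypad[(slice(None),) + sl] + self.b[:, None, None, None]
        self._cache = (xmat, in_spatial, out_spatial)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xmat, in_spatial, out_spatial = self._cache
        k, s, p = self.k, self.stride, (self.k - 1) // 2
        cin, cout = self.W.shape[:2]
        dyp = _pad(dy.astype(np.float32, copy=False), p)
        cols_dy = _gather_cols(dyp, k, s, in_spatial)  # (k^3*Cout, L_in)
        dwmat = xmat @ cols_dy.T  # (Cin, k^3*Cout)
        self.dW += dwmat.reshape(cin, k, k, k, cout).transpose(0, 4, 1, 2, 3)
        self.db += dy.reshape(cout, -1).sum(axis=1)
        dx = self._wmat() @ cols_dy  # (Cin, L_in)
        self._cache = None
        return dx.reshape((cin,) + tuple(in_spatial))

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Conv1:
    """1x1x1 projection, weights (Cout, Cin)."""

    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng if rng is not None else np.random.default_rng()
        self.W = (rng.normal(0.0, np.sqrt(2.0 / cin), (cout, cin))).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[1:]
        xmat = x.reshape(x.shape[0], -1).astype(np.float32, copy=False)
        self._cache = xmat
        y = self.W @ xmat + self.b[:, None]
        return y.reshape((-1,) + self._spatial)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dymat = dy.reshape(dy.shape[0], -1).astype(np.float32, copy=False)
        self.dW += dymat @ self._cache.T
        self.db += dymat.sum(axis=1)
        dx = self.W.T @ dymat
        self._cache = None
        return dx.reshape((-1,) + self._spatial)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return dy * (y > 0)
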