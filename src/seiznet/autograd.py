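"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a float64
numpy array, operations build a DAG of closures, and :meth:`Tensor.backward`
walks the graph in reverse topological order.  Only the operations the
network needs are implemented — elementwise arithmetic, (batched) matmul,
reductions, shape ops, the usual activations, a one-sided real FFT pair, and
a replicate-padded sliding correlation.

Real FFT convention
-------------------
``rfft_pair(x)`` returns the one-sided spectrum of a real signal of length
``L`` as a stacked real tensor of shape ``(2, ..., N)`` (real part, imaginary
part) with ``N = L//2 + 1``.  The adjoint of the transform is expressed with
the inverse transform itself, using the multiplicity ``w_k`` of each bin in
the two-sided spectrum (1 for DC and, for even ``L``, the Nyquist bin; 2
otherwise):  ``d x = L * irfft(g / w)`` and, for the inverse transform,
``d F = rfft(g) * w / L``.  Both adjoints are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack_rows",
    "rfft_pair",
    "irfft_pair",
    "correlate1d_replicate",
    "softmax",
    "log_softmax",
    "Adam",
    "gradcheck",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading dims
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over broadcast (size-1) dims
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self.name = name
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad}{tag})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph construction --------------------------------------------------
    @staticmethod
    def _op(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (per-epoch chains)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    # python-number operands take a fast path (no wrapping into a 0-d array,
    # which would silently promote float32 data to float64)
    def __add__(self, other):
        if isinstance(other, (int, float)):
            def backward(g):
                self._accum(g)

            return Tensor._op(self.data + other, (self,), backward)
        o = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            o._accum(_unbroadcast(g, o.shape))

        return Tensor._op(self.data + o.data, (self, o), backward)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def backward(g):
                self._accum(g * other)

            return Tensor._op(self.data * other, (self,), backward)
        o = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g * o.data, self.shape))
            o._accum(_unbroadcast(g * self.data, o.shape))

        return Tensor._op(self.data * o.data, (self, o), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return (-self) + other if isinstance(other, (int, float)) \
            else as_tensor(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        o = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g / o.data, self.shape))
            o._accum(_unbroadcast(-g * self.data / o.data**2, o.shape))

        return Tensor._op(self.data / o.data, (self, o), backward)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            def backward(g):
                self._accum(-g * other / self.data**2)

            return Tensor._op(other / self.data, (self,), backward)
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            self._accum(g * e * self.data ** (e - 1.0))

        return Tensor._op(self.data**e, (self,), backward)

    def __matmul__(self, other):
        o = as_tensor(other)

        def backward(g):
            ga = g @ np.swapaxes(o.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.shape))
            o._accum(_unbroadcast(gb, o.shape))

        return Tensor._op(self.data @ o.data, (self, o), backward)

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._op(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._op(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._op(out_data, (self,), backward)

    def clamp(self, lo: float, hi: float):
        """Clip to [lo, hi]; gradient is 1 strictly inside, 0 outside."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accum(g * mask)

        return Tensor._op(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._op(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._op(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._op(self.data[idx], (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack same-shape tensors along a new leading axis."""
    tensors = [as_tensor(t) for t in tensors]

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(g[i])

    return Tensor._op(np.stack([t.data for t in tensors]), tuple(tensors), backward)


# -- real FFT pair -----------------------------------------------------------

def _bin_multiplicity(L: int) -> np.ndarray:
    """Multiplicity of each one-sided bin in the full two-sided spectrum."""
    N = L // 2 + 1
    w = np.full(N, 2.0)
    w[0] = 1.0
    if L % 2 == 0:
        w[-1] = 1.0
    return w


def rfft_pair(x: Tensor) -> Tensor:
    """One-sided real FFT.  Input (..., L) -> output (2, ..., N): [Re, Im]."""
    x = as_tensor(x)
    L = x.shape[-1]
    dtype = x.data.dtype
    w = _bin_multiplicity(L)
    F = np.fft.rfft(x.data, axis=-1)  # numpy FFT computes in double

    def backward(g):
        gc = (g[0] + 1j * g[1]) / w
        x._accum((L * np.fft.irfft(gc, n=L, axis=-1)).astype(dtype, copy=False))

    return Tensor._op(np.stack([F.real, F.imag]).astype(dtype, copy=False), (x,), backward)


def irfft_pair(f_real: Tensor, f_imag: Tensor, n: int) -> Tensor:
    """Inverse of :func:`rfft_pair`: (..., N) real/imag parts -> (..., n)."""
    fr, fi = as_tensor(f_real), as_tensor(f_imag)
    w = _bin_multiplicity(n)
    # zero the structurally-imaginary-free bins so the adjoint matches the
    # map actually computed (irfft ignores Im at DC/Nyquist)
    dtype = fr.data.dtype
    fi_eff = fi.data.copy()
    fi_eff[..., 0] = 0.0
    if n % 2 == 0:
        fi_eff[..., -1] = 0.0
    out = np.fft.irfft(fr.data + 1j * fi_eff, n=n, axis=-1)

    def backward(g):
        G = np.fft.rfft(g, axis=-1) * (w / n)
        fr._accum(G.real.astype(dtype, copy=False))
        gi = G.imag
        gi[..., 0] = 0.0
        if n % 2 == 0:
            gi[..., -1] = 0.0
        fi._accum(gi.astype(dtype, copy=False))

    return Tensor._op(out.astype(dtype, copy=False), (fr, fi), backward)


# -- sliding correlation -----------------------------------------------------

def correlate1d_replicate(x: Tensor, kernel: Tensor) -> Tensor:
    """Replicate-pad ``x`` (..., L) by p=k//2 each side and slide ``kernel``.

    Output length equals input length; requires odd kernel length.
    """
    x, kernel = as_tensor(x), as_tensor(kernel)
    k = kernel.shape[-1]
    if k % 2 == 0:
        raise ValueError(f"kernel length must be odd, got {k}")
    p = k // 2
    L = x.shape[-1]
    xp = np.concatenate(
        [np.repeat(x.data[..., :1], p, axis=-1), x.data, np.repeat(x.data[..., -1:], p, axis=-1)],
        axis=-1,
    )
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=-1)  # (..., L, k)
    out = windows @ kernel.data

    def backward(g):
        # kernel grad: correlate grad with input windows
        kernel._accum((g[..., None] * windows).sum(axis=tuple(range(windows.ndim - 1))))
        # input grad: scatter g*K over the padded axis, fold pads onto edges
        gxp = np.zeros_like(xp)
        for j in range(k):
            gxp[..., j : j + L] += g * kernel.data[j]
        gx = gxp[..., p : p + L].copy()
        gx[..., 0] += gxp[..., :p].sum(axis=-1)
        gx[..., -1] += gxp[..., p + L :].sum(axis=-1)
        x._accum(gx)

    return Tensor._op(out, (x, kernel), backward)


# -- composed helpers --------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused, max-shifted softmax with the closed-form Jacobian product
    (a single op keeps the tape small on large attention score arrays)."""
    x = as_tensor(x)
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accum(out_data * (g - dot))

    return Tensor._op(out_data, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = x.data - x.data.max(axis=axis, keepdims=True)
    out_data = shift - np.log(np.exp(shift).sum(axis=axis, keepdims=True))

    def backward(g):
        x._accum(g - np.exp(out_data) * g.sum(axis=axis, keepdims=True))

    return Tensor._op(out_data, (x,), backward)


# -- optimisation ------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# -- verification ------------------------------------------------------------

def gradcheck(fn, inputs: list[Tensor], eps: float = 1e-6,
              rtol: float = 1e-5, atol: float = 1e-8) -> bool:
    """Compare analytic gradients of scalar ``fn(*inputs)`` with central
    finite differences; raises AssertionError on mismatch."""
    for t in inputs:
        t.grad = None
    out = fn(*inputs)
    if out.data.size != 1:
        raise ValueError("gradcheck requires a scalar output")
    out.backward()
    for t in inputs:
        if not t.requires_grad:
            continue
        analytic = np.zeros_like(t.data) if t.grad is None else t.grad
        numeric = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        num_flat = numeric.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(*inputs).data.item()
            flat[i] = orig - eps
            lo = fn(*inputs).data.item()
            flat[i] = orig
            num_flat[i] = (hi - lo) / (2 * eps)
        if not np.allclose(analytic, numeric, rtol=rtol, atol=atol):
            err = np.abs(analytic - numeric).max()
            raise AssertionError(
                f"gradient mismatch for {t!r}: max abs err {err:.3e}"
            )
    return True
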