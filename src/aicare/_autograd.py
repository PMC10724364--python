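"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for small recurrent attention networks trained on a
CPU: broadcasting elementwise arithmetic, batched matmul, tanh/sigmoid,
axis reductions, concatenation/stacking/slicing, a softmax primitive and a
numerically stable binary-cross-entropy-with-logits primitive. Gradients
are accumulated by topological-order backward passes; correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax", "bce_with_logits",
           "gru_sequence", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative postorder DFS (graphs are thousands of nodes deep in time)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad and self._backward is None:
            return
        if self.grad is None:
            # store by reference: backward fns always hand over fresh arrays
            # (or views nobody mutates afterwards), and accumulation below
            # allocates anew rather than writing in place
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- ops ---------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        if isinstance(other, (int, float)):  # keep weak dtype promotion
            out = Tensor(self.data + other, parents=(self,))
            out._backward = lambda g: self._accumulate(g)
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):  # keep weak dtype promotion
            out = Tensor(self.data * other, parents=(self,))
            out._backward = lambda g: self._accumulate(g * other)
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        plain = all(
            isinstance(i, (int, slice, type(Ellipsis), type(None)))
            for i in (idx if isinstance(idx, tuple) else (idx,))
        )
        def backward(g):
            full = np.zeros_like(self.data)
            if plain:  # basic indexing cannot alias, += is safe and fast
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accumulate(g.transpose(*inv))
        return out

    def broadcast_to(self, shape):
        out = Tensor(np.broadcast_to(self.data, shape), parents=(self,))
        out._backward = lambda g: self._accumulate(_unbroadcast(g, self.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = np.empty_like(self.data)
        pos = self.data >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ez = np.exp(self.data[~pos])
        y[~pos] = ez / (1.0 + ez)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accumulate(g[tuple(idx)])
    out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    def backward(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))
    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along `axis` (max-shifted for stability)."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))
    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))
    out._backward = backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray) -> Tensor:
    """Weighted mean binary cross-entropy from logits.

    ``loss = sum_i w_i * [softplus(z_i) - y_i * z_i] / sum_i w_i``; positions
    with weight 0 (uncertain or padded visits) contribute nothing, to either
    the value or the gradient.
    """
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype)
    w = np.asarray(weights, dtype=z.dtype)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("no labeled positions: all loss weights are zero")
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    val = ((softplus - y * z) * w).sum() / wsum
    out = Tensor(np.asarray(val, dtype=z.dtype), parents=(logits,))
    def backward(g):
        p = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate((g * w * (p - y) / wsum).astype(z.dtype, copy=False))
    out._backward = backward
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def gru_sequence(x: np.ndarray, Wx: Tensor, Wh: Tensor, b: Tensor) -> Tensor:
    """Run a batch of GRUs over a whole sequence as one graph node.

    ``x`` is a constant input of shape (T, F, N, in_dim) — T time steps,
    F independent parameter groups (feature channels; use F=1 for a single
    shared GRU), N batch items. ``Wx`` (F, in_dim, 3H), ``Wh`` (F, H, 3H)
    and ``b`` (F, 1, 3H) hold the update/reset/candidate gates side by side.
    Returns the hidden states (T, F, N, H), h starting from zeros:

        z_t = sigm(x_t Wx[:, :H]  + h_{t-1} Wh[:, :H]  + b[:H])
        r_t = sigm(x_t Wx[:, H:2H] + h_{t-1} Wh[:, H:2H] + b[H:2H])
        n_t = tanh(x_t Wx[:, 2H:] + (r_t * h_{t-1}) Wh[:, 2H:] + b[2H:])
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}

    The time loop and its backward pass (backpropagation through time) run
    in plain numpy, so graph overhead is one node regardless of T.
    """
    T, F, N, _ = x.shape
    H = Wh.shape[-2]
    Wx_d, Wh_d, b_d = Wx.data, Wh.data, b.data
    Wh_zr, Wh_n = Wh_d[..., : 2 * H], Wh_d[..., 2 * H:]
    gx = x @ Wx_d + b_d  # (T, F, N, 3H)

    dt = gx.dtype
    h_prev = np.zeros((F, N, H), dtype=dt)
    hs = np.empty((T, F, N, H), dtype=dt)
    zs = np.empty((T, F, N, H), dtype=dt)
    rs = np.empty((T, F, N, H), dtype=dt)
    ns = np.empty((T, F, N, H), dtype=dt)
    for t in range(T):
        zr = _sigmoid(gx[t, ..., : 2 * H] + h_prev @ Wh_zr)
        z, r = zr[..., :H], zr[..., H:]
        n = np.tanh(gx[t, ..., 2 * H:] + (r * h_prev) @ Wh_n)
        h_prev = (1.0 - z) * n + z * h_prev
        hs[t], zs[t], rs[t], ns[t] = h_prev, z, r, n

    out = Tensor(hs, parents=(Wx, Wh, b))

    def backward(g: np.ndarray) -> None:
        dWx = np.zeros_like(Wx_d)
        dWh = np.zeros_like(Wh_d)
        db = np.zeros_like(b_d)
        dgx = np.empty_like(gx)
        dh = np.zeros((F, N, H), dtype=dt)
        for t in range(T - 1, -1, -1):
            h_tm1 = hs[t - 1] if t > 0 else np.zeros((F, N, H), dtype=dt)
            z, r, n = zs[t], rs[t], ns[t]
            dh_t = g[t] + dh
            dz = dh_t * (h_tm1 - n)
            dn = dh_t * (1.0 - z)
            dh = dh_t * z
            da_n = dn * (1.0 - n * n)
            rh = r * h_tm1
            dWh[..., 2 * H:] += np.swapaxes(rh, -1, -2) @ da_n
            drh = da_n @ np.swapaxes(Wh_n, -1, -2)
            dr = drh * h_tm1
            dh += drh * r
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            da_zr = np.concatenate([da_z, da_r], axis=-1)
            dWh[..., : 2 * H] += np.swapaxes(h_tm1, -1, -2) @ da_zr
            dh += da_zr @ np.swapaxes(Wh_zr, -1, -2)
            dgx[t, ..., : 2 * H] = da_zr
            dgx[t, ..., 2 * H:] = da_n
        db += dgx.sum(axis=(0, 2))[:, None, :]
        dWx += np.einsum("tfni,tfnh->fih", x, dgx)
        Wx._accumulate(dWx)
        Wh._accumulate(dWh)
        b._accumulate(db)

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
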