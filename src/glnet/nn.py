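"""Minimal reverse-mode layers used by the GLNet classifier.

Everything is dense float64 numpy with explicit, hand-derived backward
passes (checked against central finite differences in the test suite).
Layers cache what their backward pass needs on ``forward`` and accumulate
parameter gradients into ``self.grads``.

The selective state-space layer (:class:`SSMScan`) treats the D deep
features of a sample as a length-D sequence of scalar inputs and runs the
diagonal recurrence

    h_t = exp(dt_t * A) * h_{t-1} + dt_t * B_t * u_t
    y_t = C_t . h_t + D_skip * u_t

with input-dependent step size dt_t = softplus(w_dt*u_t + b_dt) and mixing
vectors B_t, C_t given by affine maps of u_t (zero-order-hold
discretization).  A is stored as -exp(A_log) so its entries stay strictly
negative and the discrete-time factors exp(dt*A) stay inside the unit
interval: states cannot blow up for bounded inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class Layer:
    """Base: subclasses define .params (name -> array) and fill .grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_out, d_in)),
            "b": np.zeros(d_out),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class Conv1dSame(Layer):
    """Single-channel 1-D convolution along the feature axis, zero-padded so
    the sequence length is preserved; kernel size must be odd."""

    def __init__(self, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("conv kernel must be odd for same padding")
        self.k = kernel
        self.params = {
            "w": rng.normal(0.0, 1.0 / np.sqrt(kernel), size=kernel),
            "b": np.zeros(1),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        w = self.params["w"]
        half = self.k // 2
        y = np.full_like(x, self.params["b"][0])
        L = x.shape[1]
        for j, off in enumerate(range(-half, half + 1)):
            if off < 0:
                y[:, -off:] += w[j] * x[:, :L + off]
            elif off > 0:
                y[:, :L - off] += w[j] * x[:, off:]
            else:
                y += w[j] * x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, w = self._x, self.params["w"]
        half = self.k // 2
        L = x.shape[1]
        dx = np.zeros_like(x)
        for j, off in enumerate(range(-half, half + 1)):
            if off < 0:
                self.grads["w"][j] += float(np.sum(dy[:, -off:] * x[:, :L + off]))
                dx[:, :L + off] += w[j] * dy[:, -off:]
            elif off > 0:
                self.grads["w"][j] += float(np.sum(dy[:, :L - off] * x[:, off:]))
                dx[:, off:] += w[j] * dy[:, :L - off]
            else:
                self.grads["w"][j] += float(np.sum(dy * x))
                dx += w[j] * dy
        self.grads["b"][0] += float(dy.sum())
        return dx


class BatchNorm(Layer):
    """Batch normalization over features; eval mode uses running moments so a
    sample's output is independent of whatever batch it arrives in."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.buffers = {"running_mean": np.zeros(dim), "running_var": np.ones(dim)}
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.buffers["running_mean"] = (1 - m) * self.buffers["running_mean"] + m * mean
            self.buffers["running_var"] = (1 - m) * self.buffers["running_var"] + m * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (dy * xhat).sum(axis=0)
        self.grads["beta"] += dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        if not self._train:
            return dxhat * inv
        n = dy.shape[0]
        return (inv / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


@njit(cache=True)
def _ssm_forward_kernel(u, A, w_dt, b_dt, w_B, b_B, w_C, b_C, D, store_h):
    n, L = u.shape
    N = A.shape[0]
    y = np.empty((n, L))
    h_out = np.empty((n, L, N)) if store_h else np.empty((1, 1, N))
    for i in range(n):
        h = np.zeros(N)
        for t in range(L):
            ut = u[i, t]
            pre = w_dt * ut + b_dt
            dt = pre if pre > 30.0 else np.log1p(np.exp(pre))
            acc = D * ut
            for k in range(N):
                a = np.exp(dt * A[k])
                h[k] = a * h[k] + dt * (w_B[k] * ut + b_B[k]) * ut
                acc += (w_C[k] * ut + b_C[k]) * h[k]
            y[i, t] = acc
            if store_h:
                for k in range(N):
                    h_out[i, t, k] = h[k]
    return y, h_out


@njit(cache=True)
def _ssm_backward_kernel(u, h, dy, A, w_dt, b_dt, w_B, b_B, w_C, b_C, D):
    n, L = u.shape
    N = A.shape[0]
    du = np.empty((n, L))
    dA = np.zeros(N)
    dw_B = np.zeros(N)
    db_B = np.zeros(N)
    dw_C = np.zeros(N)
    db_C = np.zeros(N)
    dw_dt = 0.0
    db_dt = 0.0
    dD = 0.0
    for i in range(n):
        carry = np.zeros(N)  # a_{t+1} * gbar_{t+1}
        for t in range(L - 1, -1, -1):
            ut = u[i, t]
            dyt = dy[i, t]
            pre = w_dt * ut + b_dt
            dt = pre if pre > 30.0 else np.log1p(np.exp(pre))
            sig = 1.0 / (1.0 + np.exp(-pre))
            dD += dyt * ut
            dui = dyt * D
            ddt = 0.0
            for k in range(N):
                hk = h[i, t, k]
                # y_t = sum_k C_k h_k + D u ;  C_k = w_C u + b_C
                dw_C[k] += dyt * ut * hk
                db_C[k] += dyt * hk
                dui += dyt * (w_C[k] * hk)
                gbar = carry[k] + dyt * (w_C[k] * ut + b_C[k])
                hprev = h[i, t - 1, k] if t > 0 else 0.0
                a = np.exp(dt * A[k])
                # a-path: h_t = a h_{t-1} + inp
                da = gbar * hprev
                ddt += da * a * A[k]
                dA[k] += da * a * dt
                # inp = dt (w_B u + b_B) u
                Bt = w_B[k] * ut + b_B[k]
                ddt += gbar * Bt * ut
                dw_B[k] += gbar * dt * ut * ut
                db_B[k] += gbar * dt * ut
                dui += gbar * dt * (w_B[k] * ut + Bt)
                carry[k] = a * gbar
            dpre = ddt * sig
            dw_dt += dpre * ut
            db_dt += dpre
            dui += dpre * w_dt
            du[i, t] = dui
    return du, dA, dw_B, db_B, dw_C, db_C, dw_dt, db_dt, dD


class SSMScan(Layer):
    """Selective (input-dependent) diagonal state-space scan; see module doc."""

    def __init__(self, state_dim: int, rng: np.random.Generator,
                 mean_dt: float = 0.01) -> None:
        super().__init__()
        n = state_dim
        self.n = n
        self.params = {
            # A = -exp(A_log): initialized to -(1..N)
            "A_log": np.log(np.arange(1, n + 1, dtype=np.float64)),
            "w_dt": rng.normal(0.0, 0.05, size=1),
            "b_dt": np.array([np.log(np.expm1(mean_dt))]),
            "w_B": rng.normal(0.0, 1.0 / np.sqrt(n), size=n),
            "b_B": rng.normal(0.0, 1.0 / np.sqrt(n), size=n),
            "w_C": rng.normal(0.0, 1.0 / np.sqrt(n), size=n),
            "b_C": rng.normal(0.0, 1.0 / np.sqrt(n), size=n),
            "D_skip": np.ones(1),
        }
        self.zero_grad()

    def _param_tuple(self):
        p = self.params
        A = -np.exp(p["A_log"])
        return (A, float(p["w_dt"][0]), float(p["b_dt"][0]), p["w_B"], p["b_B"],
                p["w_C"], p["b_C"], float(p["D_skip"][0]))

    def forward(self, u: np.ndarray, train: bool, cache: bool = True) -> np.ndarray:
        if u.ndim != 2 or u.shape[1] < 1:
            raise ValueError("SSMScan expects a non-empty (batch, length) array")
        u = np.ascontiguousarray(u, dtype=np.float64)
        y, h = _ssm_forward_kernel(u, *self._param_tuple(), cache)
        self._cache = (u, h) if cache else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("forward was run with cache=False")
        u, h = self._cache
        A_args = self._param_tuple()
        A = A_args[0]
        (du, dA, dw_B, db_B, dw_C, db_C, dw_dt, db_dt, dD) = \
            _ssm_backward_kernel(u, h, np.ascontiguousarray(dy, dtype=np.float64),
                                 *A_args)
        g = self.grads
        g["A_log"] += dA * A  # dA/dA_log = -exp(A_log) = A
        g["w_B"] += dw_B
        g["b_B"] += db_B
        g["w_C"] += dw_C
        g["b_C"] += db_C
        g["w_dt"][0] += dw_dt
        g["b_dt"][0] += db_dt
        g["D_skip"][0] += dD
        return du
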