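"""Compact NumPy neural-network engine for the CNN+IndRNN classifier.

Implements exactly the layers the interaction model needs — embedding,
1-D convolution, max pooling, batch normalization, the IndRNN
recurrence, dropout and a dense sigmoid head — with analytic backward
passes and SGD/momentum/Adam updates.  Everything is seeded through one
numpy Generator, so training is bit-reproducible single-threaded.

The IndRNN recurrence is element-wise per neuron:

    h_t = act(W x_t + u * h_{t-1} + b)

with a *vector* recurrent weight ``u`` (no cross-neuron recurrent
mixing), which keeps per-neuron gradient magnitudes controllable by
clipping |u|.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def indrnn_forward(
    inputs: np.ndarray,
    W: np.ndarray,
    u: np.ndarray,
    b: np.ndarray,
    activation=relu,
    h0: np.ndarray | None = None,
) -> np.ndarray:
    """Reference IndRNN forward on time-major inputs (T, B, C) -> (T, B, H).

    Kept as a small standalone function so the vectorized layer can be
    cross-checked against a per-neuron scalar loop.
    """
    T, B, _ = inputs.shape
    H = W.shape[1]
    h = np.zeros((B, H)) if h0 is None else h0.astype(float)
    out = np.empty((T, B, H))
    for t in range(T):
        h = activation(inputs[t] @ W + u * h + b)
        out[t] = h
    return out


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Embedding(Layer):
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.params["E"] = rng.normal(0.0, 0.1, size=(vocab, dim)).astype(dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return self.params["E"][x]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dE = np.zeros_like(self.params["E"])
        flat_tok = self._x.ravel()
        flat_d = dout.reshape(-1, dout.shape[-1])
        for v in range(dE.shape[0]):  # small vocab: masked sums beat add.at
            sel = flat_tok == v
            if sel.any():
                dE[v] = flat_d[sel].sum(axis=0)
        self.grads["E"] = dE
        return np.zeros(self._x.shape)  # tokens carry no gradient


class Conv1D(Layer):
    """Valid 1-D convolution on (B, L, C_in) -> (B, Lout, C_out).

    Computed shift-and-add: y = sum_k x[:, k::stride][window] @ W_k, which
    avoids materializing im2col copies of the input.  ``stride`` subsamples
    output positions (Lout = (L - K) // stride + 1).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, dtype=np.float64):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.kernel = kernel
        self.stride = stride
        # weights stored as (K * C_in, C_out); W_k = W[k*C_in:(k+1)*C_in]
        self.params["W"] = (rng.normal(0.0, scale, size=(kernel * c_in, c_out))).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        K, s = self.kernel, self.stride
        Lout = (L - K) // s + 1
        W = self.params["W"]
        self._x = x
        self._cols = None
        if s == 1:
            # one big GEMM beats K small ones at small channel counts
            win = sliding_window_view(x, K, axis=1)  # (B, Lout, C, K)
            cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, Lout, K * C)
            self._cols = cols
            return cols @ W + self.params["b"]
        y = np.empty((B, Lout, W.shape[1]), dtype=x.dtype)
        y[:] = self.params["b"]
        for k in range(K):
            xs = x[:, k : k + (Lout - 1) * s + 1 : s, :]
            y += xs @ W[k * C : (k + 1) * C]
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, L, C = x.shape
        K, s = self.kernel, self.stride
        Lout = dout.shape[1]
        F = dout.shape[2]
        W = self.params["W"]
        dx = np.zeros_like(x)
        d2 = dout.reshape(-1, F)
        if self._cols is not None:
            self.grads["W"] = self._cols.reshape(-1, K * C).T @ d2
            dcols = (dout @ W.T).reshape(B, Lout, K, C)
            for k in range(K):
                dx[:, k : k + Lout, :] += dcols[:, :, k, :]
        else:
            dW = np.empty_like(W)
            for k in range(K):
                sl = slice(k, k + (Lout - 1) * s + 1, s)
                xs = np.ascontiguousarray(x[:, sl, :]).reshape(-1, C)
                dW[k * C : (k + 1) * C] = xs.T @ d2
                dx[:, sl, :] += dout @ W[k * C : (k + 1) * C].T
            self.grads["W"] = dW
        self.grads["b"] = d2.sum(axis=0)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; remainder positions dropped."""

    def __init__(self, width: int):
        super().__init__()
        self.width = width

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        P = self.width
        Lp = L // P
        xr = x[:, : Lp * P].reshape(B, Lp, P, C)
        self._arg = xr.argmax(axis=2)
        self._xshape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, Lp, C = dout.shape
        P = self.width
        dxr = np.zeros((B, Lp, P, C), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dx[:, : Lp * P] = dxr.reshape(B, Lp * P, C)
        return dx


class BatchNorm(Layer):
    """Batch normalization over the channel axis of (B, T, C) or (B, C).

    Besides the usual momentum-averaged running statistics, supports an
    explicit calibration pass (:meth:`begin_calibration` /
    :meth:`end_calibration`) that replaces the running statistics with exact
    moments accumulated over the pass — running averages lag badly when the
    upstream weights move fast, which flips eval-mode predictions.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float64):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._calibrating = False

    def begin_calibration(self) -> None:
        self._calibrating = True
        self._acc_n = 0
        self._acc_sum = np.zeros_like(self.running_mean)
        self._acc_sq = np.zeros_like(self.running_var)

    def end_calibration(self) -> None:
        if self._acc_n > 0:
            mean = self._acc_sum / self._acc_n
            self.running_mean = mean
            self.running_var = self._acc_sq / self._acc_n - mean ** 2
        self._calibrating = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        shape = x.shape
        x2 = x.reshape(-1, shape[-1])
        if self._calibrating:
            mean = x2.mean(axis=0)
            var = x2.var(axis=0)
            self._acc_n += x2.shape[0]
            self._acc_sum += x2.sum(axis=0)
            self._acc_sq += (x2 ** 2).sum(axis=0)
        elif train:
            mean = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x2 - mean) * inv
        self._xhat, self._inv, self._train_n = xhat, inv, x2.shape[0]
        return (self.params["gamma"] * xhat + self.params["beta"]).reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape = dout.shape
        d2 = dout.reshape(-1, shape[-1])
        n = self._train_n
        self.grads["gamma"] = (d2 * self._xhat).sum(axis=0)
        self.grads["beta"] = d2.sum(axis=0)
        dxhat = d2 * self.params["gamma"]
        dx = (self._inv / n) * (
            n * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0)
        )
        return dx.reshape(shape)


class IndRNN(Layer):
    """IndRNN over (B, T, C) -> (B, T, H), optional BN on the input projection."""

    def __init__(
        self,
        c_in: int,
        units: int,
        rng: np.random.Generator,
        recurrent_clip: float = 1.0,
        use_bn: bool = True,
        dtype=np.float64,
    ):
        super().__init__()
        scale = np.sqrt(2.0 / c_in)
        self.params["W"] = rng.normal(0.0, scale, size=(c_in, units)).astype(dtype)
        self.params["u"] = rng.uniform(0.0, recurrent_clip, size=units).astype(dtype)
        self.params["b"] = np.zeros(units, dtype=dtype)
        self.recurrent_clip = recurrent_clip
        self.bn = BatchNorm(units, dtype=dtype) if use_bn else None
        if self.bn is not None:
            # expose the BN affine parameters to the optimizer (shared arrays)
            self.params["gamma"] = self.bn.params["gamma"]
            self.params["beta"] = self.bn.params["beta"]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, T, C = x.shape
        z = x @ self.params["W"] + self.params["b"]
        if self.bn is not None:
            z = self.bn.forward(z, train)
        u = self.params["u"]
        H = u.shape[0]
        h = np.zeros((B, H), dtype=z.dtype)
        hs = np.empty((B, T, H), dtype=z.dtype)
        acts = np.empty((B, T, H), dtype=bool)
        for t in range(T):
            a = z[:, t] + u * h
            mask = a > 0
            h = np.where(mask, a, 0.0)
            hs[:, t] = h
            acts[:, t] = mask
        self._x, self._hs, self._acts = x, hs, acts
        return hs

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, hs, acts = self._x, self._hs, self._acts
        B, T, C = x.shape
        u = self.params["u"]
        dz = np.empty_like(dout)
        du = np.zeros_like(u)
        carry = np.zeros((B, u.shape[0]), dtype=dout.dtype)
        for t in range(T - 1, -1, -1):
            g = (dout[:, t] + carry) * acts[:, t]
            dz[:, t] = g
            h_prev = hs[:, t - 1] if t > 0 else 0.0
            du += (g * h_prev).sum(axis=0) if t > 0 else 0.0
            carry = g * u
        self.grads["u"] = du
        if self.bn is not None:
            dz = self.bn.backward(dz)
            self.grads["gamma"] = self.bn.grads["gamma"]
            self.grads["beta"] = self.bn.grads["beta"]
        self.grads["W"] = x.reshape(-1, C).T @ dz.reshape(-1, u.shape[0])
        self.grads["b"] = dz.sum(axis=(0, 1))
        return dz @ self.params["W"].T

    def clip_recurrent(self) -> None:
        np.clip(self.params["u"], -self.recurrent_clip, self.recurrent_clip, out=self.params["u"])


class MeanOverTime(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, None, :], self._T, axis=1) / self._T


class LastStep(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x[:, -1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, -1] = dout
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        scale = np.sqrt(1.0 / c_in)
        self.params["W"] = rng.normal(0.0, scale, size=(c_in, c_out)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self):
        for layer in self.layers:
            for name, p in layer.params.items():
                yield layer, name, p

    def batchnorms(self) -> list[BatchNorm]:
        out = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out.append(layer)
            elif isinstance(layer, IndRNN) and layer.bn is not None:
                out.append(layer.bn)
        return out

    def calibrate(self, x: np.ndarray, chunk_size: int = 128) -> np.ndarray:
        """Recompute BN statistics over ``x`` (chunked) and return outputs.

        Dropout is off; each BN layer normalizes with its chunk statistics
        while accumulating exact moments, then stores the aggregate as its
        inference statistics.
        """
        bns = self.batchnorms()
        for bn in bns:
            bn.begin_calibration()
        outs = [self.forward(x[i : i + chunk_size], train=False) for i in range(0, x.shape[0], chunk_size)]
        for bn in bns:
            bn.end_calibration()
        return np.concatenate(outs, axis=0)

    def n_parameters(self) -> int:
        return sum(p.size for _, _, p in self.parameters())


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and d(loss)/d(logit) for a sigmoid head."""
    p = np.clip(probs, 1e-12, 1.0 - 1e-12)
    y = labels.astype(p.dtype)
    loss = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
    dlogit = (p - y) / p.shape[0]
    return loss, dlogit


class SGD:
    def __init__(self, lr: float, momentum: float = 0.0):
        self.lr = lr
        self.momentum = momentum
        self._vel: dict[int, np.ndarray] = {}

    def step(self, net: Sequential) -> None:
        for layer, name, p in net.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            key = id(p)
            if self.momentum:
                v = self._vel.setdefault(key, np.zeros_like(p))
                v *= self.momentum
                v -= self.lr * g
                p += v
            else:
                p -= self.lr * g


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, net: Sequential) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name, p in net.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            key = id(p)
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
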