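"""The lightweight ECG-PPG cross-attention fusion network.

Architecture (single scalar regression head, CI or CO target):

* Two parallel temporal tokenizers (one per modality), each of two identical
  blocks: standard 1D conv (32 filters, kernel 7 ~ 28 ms at 250 Hz) -> ReLU
  -> depthwise-separable conv (depthwise k=7 + pointwise 1x1, 32 channels)
  -> ReLU -> squeeze-and-excitation (reduction 8) -> average pool (5).
  15,000 input samples -> 3000 tokens -> 600 tokens.
* Single-head scaled dot-product cross-attention: queries from ECG tokens,
  keys/values from PPG tokens, all projections dimension 32 and bias-free,
  plus a bias-free output projection.
* Global average pooling of ECG tokens, PPG tokens and attention output into
  three 32-vectors, concatenated to a 96-dim fused feature, then
  Dense(64)-ReLU-Dropout(0.3) -> Dense(32)-ReLU-Dropout(0.3) -> linear unit.

Total trainable parameters: 33,745.

Everything is implemented directly in numpy (float32 forward/backward with
im2col/BLAS matmuls) — the network IS the contribution here, and a
hand-derived backward pass keeps it dependency-free and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # jit kernels for the memory-bound depthwise convolution
    import numba as _nb
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _nb = None

__all__ = ["ModelConfig", "FusionNetwork", "count_parameters", "Param"]

_DT = np.float32


if _nb is not None:

    @_nb.njit(fastmath=True)
    def _dw_forward_kernel(xp, W, b, L):  # pragma: no cover - jitted
        B, Lp, C = xp.shape
        k = W.shape[0]
        y = np.empty((B, L, C), dtype=np.float32)
        for bi in range(B):
            for l in range(L):
                for c in range(C):
                    acc = b[c]
                    for j in range(k):
                        acc += xp[bi, l + j, c] * W[j, c]
                    y[bi, l, c] = acc
        return y

    @_nb.njit(fastmath=True)
    def _dw_backward_kernel(dy, xp, W, L):  # pragma: no cover - jitted
        B, Lp, C = xp.shape
        k = W.shape[0]
        dW = np.zeros((k, C), dtype=np.float32)
        db = np.zeros(C, dtype=np.float32)
        dxp = np.zeros((B, Lp, C), dtype=np.float32)
        for bi in range(B):
            for l in range(L):
                for c in range(C):
                    g = dy[bi, l, c]
                    db[c] += g
                    for j in range(k):
                        dW[j, c] += g * xp[bi, l + j, c]
                        dxp[bi, l + j, c] += g * W[j, c]
        return dW, db, dxp
else:  # pragma: no cover
    _dw_forward_kernel = None
    _dw_backward_kernel = None


@dataclass(frozen=True)
class ModelConfig:
    """Every architecture hyperparameter of the fusion network."""

    conv_filters: int = 32
    kernel: int = 7
    pool: int = 5
    se_reduction: int = 8
    attn_dim: int = 32           # d_k of the scaled dot-product attention
    dense_units: tuple = (64, 32)
    dropout: float = 0.3
    input_len: int = 15_000
    tokenizer_blocks: int = 2

    def __post_init__(self) -> None:
        if self.input_len % self.pool ** self.tokenizer_blocks != 0:
            raise ValueError(
                f"input_len {self.input_len} not divisible by "
                f"pool^blocks = {self.pool ** self.tokenizer_blocks}"
            )
        if self.conv_filters % self.se_reduction != 0:
            raise ValueError("se_reduction must divide conv_filters")

    @property
    def token_len(self) -> int:
        return self.input_len // self.pool ** self.tokenizer_blocks


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=_DT)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def _glorot(rng, shape, fan_in, fan_out) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(_DT)


class _Dense:
    """y = x @ W (+ b), applied along the last axis."""

    def __init__(self, rng, d_in, d_out, bias=True, name="dense"):
        self.W = Param(_glorot(rng, (d_in, d_out), d_in, d_out), f"{name}.W")
        self.b = Param(np.zeros(d_out), f"{name}.b") if bias else None
        self._x = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        df = dy.reshape(-1, dy.shape[-1])
        self.W.grad += xf.T @ df
        if self.b is not None:
            self.b.grad += df.sum(axis=0)
        return dy @ self.W.value.T


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _Conv1dSame:
    """Standard 1D convolution, 'same' padding, via im2col + matmul."""

    def __init__(self, rng, c_in, c_out, k, name="conv"):
        self.k, self.c_in = k, c_in
        fan_in, fan_out = k * c_in, c_out
        self.W = Param(_glorot(rng, (k * c_in, c_out), fan_in, fan_out),
                       f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._xcol = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        B, L, C = x.shape
        p = self.k // 2
        xp = np.zeros((B, L + self.k - 1, C), dtype=_DT)
        xp[:, p: p + L, :] = x
        v = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # v: (B, L, C, k) -> (B, L, k*C)
        return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(B, L, -1)

    def forward(self, x):
        self._shape = x.shape
        self._xcol = self._im2col(x)
        B, L, _ = x.shape
        y = self._xcol.reshape(B * L, -1) @ self.W.value + self.b.value
        return y.reshape(B, L, -1)

    def backward(self, dy):
        B, L, C = self._shape
        df = dy.reshape(B * L, -1)
        self.W.grad += self._xcol.reshape(B * L, -1).T @ df
        self.b.grad += df.sum(axis=0)
        dcol = (df @ self.W.value.T).reshape(B, L, self.k, C)
        p = self.k // 2
        dxp = np.zeros((B, L + self.k - 1, C), dtype=_DT)
        for j in range(self.k):
            dxp[:, j: j + L, :] += dcol[:, :, j, :]
        return dxp[:, p: p + L, :]


class _DepthwiseConv1d:
    """Per-channel temporal convolution, 'same' padding."""

    def __init__(self, rng, c, k, name="dwconv"):
        self.k, self.c = k, c
        self.W = Param(_glorot(rng, (k, c), k, 1), f"{name}.W")
        self.b = Param(np.zeros(c), f"{name}.b")
        self._xp = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        B, L, C = x.shape
        p = self.k // 2
        xp = np.zeros((B, L + self.k - 1, C), dtype=_DT)
        xp[:, p: p + L, :] = x
        self._xp, self._L = xp, L
        if _dw_forward_kernel is not None:
            return _dw_forward_kernel(xp, self.W.value, self.b.value, L)
        y = np.zeros((B, L, C), dtype=_DT)
        tmp = np.empty_like(y)
        for j in range(self.k):
            np.multiply(xp[:, j: j + L, :], self.W.value[j], out=tmp)
            y += tmp
        return y + self.b.value

    def backward(self, dy):
        L, xp = self._L, self._xp
        p = self.k // 2
        if _dw_backward_kernel is not None:
            dW, db, dxp = _dw_backward_kernel(
                np.ascontiguousarray(dy, dtype=_DT), xp, self.W.value, L
            )
            self.W.grad += dW
            self.b.grad += db
            return dxp[:, p: p + L, :]
        dxp = np.zeros_like(xp)
        tmp = np.empty_like(dy)
        for j in range(self.k):
            np.multiply(dy, xp[:, j: j + L, :], out=tmp)
            self.W.grad[j] += tmp.sum(axis=(0, 1))
            np.multiply(dy, self.W.value[j], out=tmp)
            dxp[:, j: j + L, :] += tmp
        self.b.grad += dy.sum(axis=(0, 1))
        return dxp[:, p: p + L, :]


class _SEBlock:
    """Squeeze-and-excitation channel gating (C -> C/r -> C, sigmoid)."""

    def __init__(self, rng, c, reduction, name="se"):
        self.fc1 = _Dense(rng, c, c // reduction, bias=True, name=f"{name}.fc1")
        self.fc2 = _Dense(rng, c // reduction, c, bias=True, name=f"{name}.fc2")
        self.relu = _ReLU()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def gates(self, x):
        z = x.mean(axis=1)                      # squeeze: (B, C)
        h = self.relu.forward(self.fc1.forward(z))
        a = np.clip(self.fc2.forward(h), -30.0, 30.0)
        return 1.0 / (1.0 + np.exp(-a))

    def forward(self, x):
        self._x = x
        self._g = self.gates(x)
        return x * self._g[:, None, :]

    def backward(self, dy):
        x, g = self._x, self._g
        L = x.shape[1]
        dx = dy * g[:, None, :]
        tmp = np.multiply(dy, x)
        dg = tmp.sum(axis=1)
        ds = dg * g * (1.0 - g)                 # through sigmoid
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(ds)))
        dx += dz[:, None, :] / L                # through the mean squeeze
        return dx


class _AvgPool:
    def __init__(self, p):
        self.p = p

    def forward(self, x):
        B, L, C = x.shape
        if L % self.p:
            raise ValueError(f"length {L} not divisible by pool {self.p}")
        self._L = L
        return x.reshape(B, L // self.p, self.p, C).mean(axis=2)

    def backward(self, dy):
        B, Lp, C = dy.shape
        return np.repeat(dy / self.p, self.p, axis=1)


class _Dropout:
    def __init__(self, rate):
        self.rate = rate
        self._mask = None

    def forward(self, x, training, rng):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _CrossAttention:
    """softmax(Q K^T / sqrt(d_k)) V with bias-free Q/K/V/output projections.

    Queries come from ECG tokens, keys and values from PPG tokens; each
    output row is a convex combination of projected PPG value rows.
    """

    def __init__(self, rng, d, name="attn"):
        self.d = d
        self.Wq = Param(_glorot(rng, (d, d), d, d), f"{name}.Wq")
        self.Wk = Param(_glorot(rng, (d, d), d, d), f"{name}.Wk")
        self.Wv = Param(_glorot(rng, (d, d), d, d), f"{name}.Wv")
        self.Wo = Param(_glorot(rng, (d, d), d, d), f"{name}.Wo")

    def params(self):
        return [self.Wq, self.Wk, self.Wv, self.Wo]

    def attention_weights(self, ecg_tokens, ppg_tokens):
        Q = ecg_tokens @ self.Wq.value
        K = ppg_tokens @ self.Wk.value
        S = (Q @ K.transpose(0, 2, 1)) * _DT(1.0 / np.sqrt(self.d))
        S = S - S.max(axis=-1, keepdims=True)
        # clamp to keep exp() away from subnormals (they are ~10x slower)
        A = np.exp(np.maximum(S, -60.0))
        return A / A.sum(axis=-1, keepdims=True)

    def forward(self, E, P):
        self._E, self._P = E, P
        self._Q = E @ self.Wq.value
        self._K = P @ self.Wk.value
        self._V = P @ self.Wv.value
        S = (self._Q @ self._K.transpose(0, 2, 1)) * _DT(1.0 / np.sqrt(self.d))
        S = S - S.max(axis=-1, keepdims=True)
        A = np.exp(np.maximum(S, -60.0))  # avoid subnormal-float stalls
        self._A = A / A.sum(axis=-1, keepdims=True)
        self._H = self._A @ self._V
        return self._H @ self.Wo.value

    @staticmethod
    def _contract(x, dy):
        # sum_b x_b^T dy_b via one flattened sgemm
        d = x.shape[-1]
        return x.reshape(-1, d).T @ dy.reshape(-1, dy.shape[-1])

    def backward(self, dy):
        E, P, A, V, H = self._E, self._P, self._A, self._V, self._H
        self.Wo.grad += self._contract(H, dy)
        dH = dy @ self.Wo.value.T
        dA = dH @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dH
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True)) * _DT(1.0 / np.sqrt(self.d))
        dQ = dS @ self._K
        dK = dS.transpose(0, 2, 1) @ self._Q
        self.Wq.grad += self._contract(E, dQ)
        self.Wk.grad += self._contract(P, dK)
        self.Wv.grad += self._contract(P, dV)
        dE = dQ @ self.Wq.value.T
        dP = dK @ self.Wk.value.T + dV @ self.Wv.value.T
        return dE, dP


class _TokenizerBlock:
    """conv -> ReLU -> depthwise -> pointwise -> ReLU -> SE -> avgpool."""

    def __init__(self, rng, c_in, cfg: ModelConfig, name):
        f = cfg.conv_filters
        self.conv = _Conv1dSame(rng, c_in, f, cfg.kernel, f"{name}.conv")
        self.relu1 = _ReLU()
        self.dw = _DepthwiseConv1d(rng, f, cfg.kernel, f"{name}.dw")
        self.pw = _Dense(rng, f, f, bias=True, name=f"{name}.pw")
        self.relu2 = _ReLU()
        self.se = _SEBlock(rng, f, cfg.se_reduction, f"{name}.se")
        self.pool = _AvgPool(cfg.pool)

    def params(self):
        return (self.conv.params() + self.dw.params() + self.pw.params()
                + self.se.params())

    def forward(self, x):
        x = self.relu1.forward(self.conv.forward(x))
        x = self.relu2.forward(self.pw.forward(self.dw.forward(x)))
        x = self.se.forward(x)
        return self.pool.forward(x)

    def backward(self, dy):
        dx = self.se.backward(self.pool.backward(dy))
        dx = self.dw.backward(self.pw.backward(self.relu2.backward(dx)))
        return self.conv.backward(self.relu1.backward(dx))


class FusionNetwork:
    """The full two-branch cross-attention regression network."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = cfg = config or ModelConfig()
        rng = np.random.default_rng(seed)
        f = cfg.conv_filters
        self.ecg_blocks = [
            _TokenizerBlock(rng, 1 if i == 0 else f, cfg, f"ecg{i}")
            for i in range(cfg.tokenizer_blocks)
        ]
        self.ppg_blocks = [
            _TokenizerBlock(rng, 1 if i == 0 else f, cfg, f"ppg{i}")
            for i in range(cfg.tokenizer_blocks)
        ]
        self.attn = _CrossAttention(rng, cfg.attn_dim, "attn")
        d1, d2 = cfg.dense_units
        self.fc1 = _Dense(rng, 3 * f, d1, bias=True, name="fc1")
        self.fc2 = _Dense(rng, d1, d2, bias=True, name="fc2")
        self.head = _Dense(rng, d2, 1, bias=True, name="head")
        self.relu1, self.relu2 = _ReLU(), _ReLU()
        self.drop1, self.drop2 = _Dropout(cfg.dropout), _Dropout(cfg.dropout)

    # ------------------------------------------------------------------ api
    def parameters(self) -> list[Param]:
        ps = []
        for blk in self.ecg_blocks + self.ppg_blocks:
            ps += blk.params()
        ps += self.attn.params()
        ps += self.fc1.params() + self.fc2.params() + self.head.params()
        return ps

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.parameters(), weights):
            p.value[...] = w

    def tokenize(self, x, branch: str):
        """Run one modality through its tokenizer; x is (B, L)."""
        h = np.ascontiguousarray(x, dtype=_DT)[..., None]
        blocks = self.ecg_blocks if branch == "ecg" else self.ppg_blocks
        for blk in blocks:
            h = blk.forward(h)
        return h

    def forward(self, x_ecg, x_ppg, training: bool = False, rng=None):
        """Scalar prediction per segment; inputs are (B, input_len) arrays."""
        if x_ecg.shape != x_ppg.shape or x_ecg.shape[-1] != self.config.input_len:
            raise ValueError(
                f"expected (B, {self.config.input_len}) inputs, got "
                f"{x_ecg.shape} / {x_ppg.shape}"
            )
        if training and rng is None:
            rng = np.random.default_rng(0)
        E = self.tokenize(x_ecg, "ecg")       # (B, Lt, C)
        P = self.tokenize(x_ppg, "ppg")
        O = self.attn.forward(E, P)
        self._Lt = E.shape[1]
        fused = np.concatenate(
            [E.mean(axis=1), P.mean(axis=1), O.mean(axis=1)], axis=1
        )                                     # (B, 3C) = (B, 96)
        self._fused_dim = fused.shape[1]
        h = self.drop1.forward(self.relu1.forward(self.fc1.forward(fused)),
                               training, rng)
        h = self.drop2.forward(self.relu2.forward(self.fc2.forward(h)),
                               training, rng)
        return self.head.forward(h)[:, 0]

    def backward(self, dy) -> None:
        """Accumulate parameter gradients given d(loss)/d(prediction)."""
        d = np.asarray(dy, dtype=_DT)[:, None]
        d = self.fc1.backward(
            self.relu1.backward(self.drop1.backward(
                self.fc2.backward(self.relu2.backward(self.drop2.backward(
                    self.head.backward(d)
                )))
            ))
        )
        C = self.config.conv_filters
        Lt = self._Lt
        dE_gap = np.repeat(d[:, None, 0:C], Lt, axis=1) / Lt
        dP_gap = np.repeat(d[:, None, C:2 * C], Lt, axis=1) / Lt
        dO = np.repeat(d[:, None, 2 * C:], Lt, axis=1) / Lt
        dE_att, dP_att = self.attn.backward(dO)
        dE, dP = dE_gap + dE_att, dP_gap + dP_att
        for blocks, g in ((self.ecg_blocks, dE), (self.ppg_blocks, dP)):
            for blk in reversed(blocks):
                g = blk.backward(g)

    def predict(self, x_ecg, x_ppg, batch_size: int = 32) -> np.ndarray:
        """Deterministic inference (dropout off), batched."""
        out = []
        for i in range(0, x_ecg.shape[0], batch_size):
            out.append(self.forward(x_ecg[i: i + batch_size],
                                    x_ppg[i: i + batch_size], training=False))
        return np.concatenate(out) if out else np.empty(0)


def count_parameters(model: FusionNetwork) -> int:
    """Exact number of trainable scalars."""
    return int(sum(p.size for p in model.parameters()))
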