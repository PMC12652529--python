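"""Gated recurrent unit primitives: single step, directional pass, BiGRU layer.

The GRU convention used throughout (reset gate applied inside the candidate's
recurrent term, update gate weighting the candidate):

    z   = sigmoid(W_z x + U_z h_prev + b_z)
    r   = sigmoid(W_r x + U_r h_prev + b_r)
    h~  = tanh(W_h x + U_h (r * h_prev) + b_h)
    h   = (1 - z) * h_prev + z * h~

Everything is NumPy float64, with hand-derived backpropagation through time —
which keeps training bit-deterministic for a fixed seed on one device, a
property the test suite leans on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_GATE_FIELDS = ("w_z", "u_z", "b_z", "w_r", "u_r", "b_r", "w_h", "u_h", "b_h")


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    e = np.exp(a[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class GRUParams:
    """Weights of one GRU direction: per gate, input W (in_dim x units as
    ``(in_dim, units)``), recurrent U ``(units, units)`` and bias ``(units,)``."""

    w_z: np.ndarray
    u_z: np.ndarray
    b_z: np.ndarray
    w_r: np.ndarray
    u_r: np.ndarray
    b_r: np.ndarray
    w_h: np.ndarray
    u_h: np.ndarray
    b_h: np.ndarray

    @property
    def in_dim(self) -> int:
        return self.w_z.shape[0]

    @property
    def units(self) -> int:
        return self.w_z.shape[1]

    def arrays(self) -> list[np.ndarray]:
        return [getattr(self, f) for f in _GATE_FIELDS]

    def zeros_like(self) -> "GRUParams":
        return GRUParams(*[np.zeros_like(a) for a in self.arrays()])

    def copy(self) -> "GRUParams":
        return GRUParams(*[a.copy() for a in self.arrays()])

    def __post_init__(self) -> None:
        d, u = self.w_z.shape
        for f in _GATE_FIELDS:
            a = getattr(self, f)
            expect = (d, u) if f.startswith("w") else (u, u) if f.startswith("u") else (u,)
            if a.shape != expect:
                raise ValueError(f"{f} has shape {a.shape}, expected {expect}")

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, units: int) -> "GRUParams":
        """Glorot-uniform weights, zero biases."""

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        kw = {}
        for g in ("z", "r", "h"):
            kw[f"w_{g}"] = glorot(in_dim, units)
            kw[f"u_{g}"] = glorot(units, units)
            kw[f"b_{g}"] = np.zeros(units)
        return cls(**kw)


def _step(x: np.ndarray, h_prev: np.ndarray, p: GRUParams):
    z = _sigmoid(x @ p.w_z + h_prev @ p.u_z + p.b_z)
    r = _sigmoid(x @ p.w_r + h_prev @ p.u_r + p.b_r)
    hh = np.tanh(x @ p.w_h + (r * h_prev) @ p.u_h + p.b_h)
    h = (1.0 - z) * h_prev + z * hh
    return h, z, r, hh


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, p: GRUParams) -> np.ndarray:
    """One GRU update; accepts a single vector or a batch (leading axis)."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x_t.shape[-1] != p.in_dim or h_prev.shape[-1] != p.units:
        raise ValueError(
            f"shape mismatch: x {x_t.shape} vs in_dim {p.in_dim}, "
            f"h {h_prev.shape} vs units {p.units}"
        )
    return _step(x_t, h_prev, p)[0]


class GRUDirection:
    """One direction of a GRU layer over a fixed-length sequence."""

    def __init__(self, params: GRUParams):
        self.params = params

    def forward(self, X: np.ndarray):
        """X: (batch, T, in_dim) in processing order.  Returns (H, cache)."""
        B, T, _ = X.shape
        p = self.params
        h = np.zeros((B, p.units))
        H = np.empty((B, T, p.units))
        cache = []
        for t in range(T):
            x = X[:, t]
            h_new, z, r, hh = _step(x, h, p)
            cache.append((x, h, z, r, hh))
            h = h_new
            H[:, t] = h
        return H, cache

    def backward(self, dH: np.ndarray, cache):
        """dH: per-step output gradients (batch, T, units).  Returns (dX, grads)."""
        p = self.params
        g = p.zeros_like()
        B, T, _ = dH.shape
        dX = np.empty((B, T, p.in_dim))
        dh_next = np.zeros((B, p.units))
        for t in range(T - 1, -1, -1):
            x, h_prev, z, r, hh = cache[t]
            dh = dH[:, t] + dh_next
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dh_prev = dh * (1.0 - z)

            da_h = dhh * (1.0 - hh * hh)
            g.w_h += x.T @ da_h
            g.u_h += (r * h_prev).T @ da_h
            g.b_h += da_h.sum(axis=0)
            drh = da_h @ p.u_h.T
            dr = drh * h_prev
            dh_prev += drh * r

            da_z = dz * z * (1.0 - z)
            g.w_z += x.T @ da_z
            g.u_z += h_prev.T @ da_z
            g.b_z += da_z.sum(axis=0)
            dh_prev += da_z @ p.u_z.T

            da_r = dr * r * (1.0 - r)
            g.w_r += x.T @ da_r
            g.u_r += h_prev.T @ da_r
            g.b_r += da_r.sum(axis=0)
            dh_prev += da_r @ p.u_r.T

            dX[:, t] = da_z @ p.w_z.T + da_r @ p.w_r.T + da_h @ p.w_h.T
            dh_next = dh_prev
        return dX, g


class BiGRULayer:
    """Forward + backward GRU over the same sequence, states concatenated.

    With ``return_sequences`` the output at each step is
    ``[h_fw(t), h_bw(t)]`` (dim 2*units); otherwise the layer returns the
    concatenation of each direction's *final* state (the forward state after
    the last step and the backward state after consuming the first step).
    """

    def __init__(self, fw: GRUParams, bw: GRUParams, return_sequences: bool = True):
        if fw.in_dim != bw.in_dim or fw.units != bw.units:
            raise ValueError("forward/backward parameter shapes differ")
        self.fw = GRUDirection(fw)
        self.bw = GRUDirection(bw)
        self.return_sequences = return_sequences

    @property
    def units(self) -> int:
        return self.fw.params.units

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, units: int,
             return_sequences: bool = True) -> "BiGRULayer":
        return cls(GRUParams.init(rng, in_dim, units), GRUParams.init(rng, in_dim, units),
                   return_sequences)

    def forward(self, X: np.ndarray):
        Hf, cf = self.fw.forward(X)
        Hb_rev, cb = self.bw.forward(np.ascontiguousarray(X[:, ::-1]))
        if self.return_sequences:
            out = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
        else:
            out = np.concatenate([Hf[:, -1], Hb_rev[:, -1]], axis=1)
        return out, (cf, cb, X.shape)

    def backward(self, d_out: np.ndarray, cache):
        cf, cb, (B, T, _) = cache
        u = self.units
        if self.return_sequences:
            dHf = np.ascontiguousarray(d_out[:, :, :u])
            dHb = np.ascontiguousarray(d_out[:, ::-1, u:])
        else:
            dHf = np.zeros((B, T, u))
            dHb = np.zeros((B, T, u))
            dHf[:, -1] = d_out[:, :u]
            dHb[:, -1] = d_out[:, u:]
        dXf, gf = self.fw.backward(dHf, cf)
        dXb, gb = self.bw.backward(dHb, cb)
        dX = dXf + dXb[:, ::-1]
        return dX, (gf, gb)
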