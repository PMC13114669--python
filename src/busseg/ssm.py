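"""Selective state-space (S6) primitives.

The continuous-time system  h'(t) = A h(t) + B x(t),  y(t) = C h(t)  is
discretized with a zero-order hold over a per-token step size Delta:

    A_bar = exp(Delta A)
    B_bar = (Delta A)^{-1} (exp(Delta A) - I) Delta B    (diagonal A)

and run as the linear recurrence  h_t = A_bar_t h_{t-1} + B_bar_t x_t,
y_t = C_t h_t.  In the selective parameterization Delta, B and C are
input-dependent linear projections of the token, which is what lets the
model gate its memory per position.

``selective_scan_op`` is an autodiff primitive: the forward pass is a
vectorized loop over sequence positions, the backward pass is the exact
reverse-time adjoint recurrence (backpropagation through time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor

ZOH_SMALL = 1e-6  # |Delta*A| below this uses the series limit B_bar -> Delta*B


@dataclass
class SSMParams:
    """Hyperparameters of one selective-SSM (diagonal A convention)."""

    d_state: int = 16
    expand: int = 2
    conv_kernel: int = 3
    dt_rank: int | str = "auto"

    def resolve_dt_rank(self, inner_dim: int) -> int:
        if self.dt_rank == "auto":
            return int(np.ceil(inner_dim / 16))
        return int(self.dt_rank)

    def __post_init__(self):
        if self.d_state <= 0 or self.expand <= 0 or self.conv_kernel <= 0:
            raise ValueError("d_state, expand and conv_kernel must be positive integers")


def zoh_discretize(A, B, delta):
    """Zero-order-hold discretization for diagonal A (elementwise).

    Parameters are numpy arrays (or scalars) broadcastable against each
    other.  Returns ``(A_bar, B_bar)`` with the exact small-|Delta*A|
    limit ``B_bar -> Delta*B`` applied below ``ZOH_SMALL``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("Delta must be positive")
    dA = delta * A
    A_bar = np.exp(dA)
    small = np.abs(dA) < ZOH_SMALL
    safe_A = np.where(small, 1.0, A)
    # two-term series (exp(dA)-1)/dA ~ 1 + dA/2 keeps B_bar continuous
    # across the threshold; the dA -> 0 limit is still Delta * B
    B_bar = np.where(small, delta * B * (1.0 + dA / 2.0), (A_bar - 1.0) / safe_A * B)
    return A_bar, B_bar


def selective_scan_op(A_bar: Tensor, Bx: Tensor, C: Tensor) -> Tensor:
    """Run the discrete recurrence as an autodiff primitive.

    Shapes: ``A_bar``, ``Bx`` are (B, L, D, N); ``C`` is (B, L, N).
    Returns y of shape (B, L, D) with  h_t = A_bar_t * h_{t-1} + Bx_t,
    y_t = sum_n C_t[n] * h_t[:, n],  h_0 = 0.
    """
    Ab, bx, c = A_bar.data, Bx.data, C.data
    Bsz, L, D, N = bx.shape
    h = np.zeros((Bsz, D, N), dtype=bx.dtype)
    hs = np.empty((Bsz, L, D, N), dtype=bx.dtype)
    for t in range(L):
        h = Ab[:, t] * h + bx[:, t]
        hs[:, t] = h
    y = np.einsum("bldn,bln->bld", hs, c, optimize=True)

    def backward(g):
        # g: (B, L, D)
        dh_next = np.zeros((Bsz, D, N), dtype=bx.dtype)
        dAb = np.empty_like(Ab) if A_bar.requires_grad else None
        dBx = np.empty_like(bx) if Bx.requires_grad else None
        dC = np.einsum("bld,bldn->bln", g, hs, optimize=True) if C.requires_grad else None
        need_h = A_bar.requires_grad or Bx.requires_grad
        if need_h:
            for t in range(L - 1, -1, -1):
                dh = g[:, t, :, None] * c[:, t, None, :] + dh_next
                if dAb is not None:
                    h_prev = hs[:, t - 1] if t > 0 else np.zeros((Bsz, D, N), dtype=bx.dtype)
                    dAb[:, t] = dh * h_prev
                if dBx is not None:
                    dBx[:, t] = dh
                dh_next = Ab[:, t] * dh
        if dAb is not None:
            A_bar._accum(dAb)
        if dBx is not None:
            Bx._accum(dBx)
        if dC is not None:
            C._accum(dC)

    return Tensor._make(y, (A_bar, Bx, C), backward)


def selective_scan(x_seq: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Functional scan over one sequence (no autodiff, numpy in/out).

    ``x_seq``: (L, D) tokens; ``A``: (D, N) diagonal continuous state
    matrix; ``B``, ``C``: (L, N) input-dependent projections; ``delta``:
    (L, D) positive step sizes.  Returns y of shape (L, D).
    """
    x_seq = np.asarray(x_seq, dtype=float)
    L, D = x_seq.shape
    N = np.asarray(A).shape[-1]
    A_bar, _ = zoh_discretize(A[None, :, :], np.ones((1, D, N)), np.asarray(delta)[:, :, None])
    # B_bar per token: broadcast B over channels
    _, B_bar = zoh_discretize(A[None, :, :], np.asarray(B)[:, None, :], np.asarray(delta)[:, :, None])
    h = np.zeros((D, N))
    y = np.empty((L, D))
    for t in range(L):
        h = A_bar[t] * h + B_bar[t] * x_seq[t][:, None]
        y[t] = h @ np.asarray(C)[t]
    return y
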