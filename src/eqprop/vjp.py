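"""Analytic vector-Jacobian products of the one-step transition map.

The synchronous update of the network is ``s' = F(x, s, theta) = sigma(pre)``
with ``pre`` the bottom-up plus top-down pre-activation.  This module
provides, at a given evaluation point:

* ``step_param_vjp``  — ``(dF/dtheta)^T . delta`` for every parameter slot,
* ``step_state_vjp``  — ``(dF/ds)^T . a`` propagated to every layer,
* ``linearized_step_matvec`` / ``spectral_norm`` — the state-to-state
  linearization (activation derivative taken as 1, pooling indices frozen),
  used to certify that fixture networks are contractions.

Conventions: the hard-sigmoid derivative is 1 on the open interval (0, 1) of
the pre-activation and 0 at saturation; max-pooling argmax index maps are
treated as locally constant (valid almost everywhere).  All VJPs are batch
sums; callers divide by the batch size where a mean is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    ArchitectureSpec,
    BIDIRECTIONAL,
    Parameters,
    UNIDIRECTIONAL,
    bottom_up,
    top_down,
    _layer_input,
)
from .nnops import (
    conv2d,
    conv2d_input_grad,
    conv2d_weight_grad,
    hard_sigmoid_interior,
    maxpool,
    pool_gather,
    unpool,
)

__all__ = [
    "ParamGrads",
    "free_preactivations",
    "step_param_vjp",
    "step_state_vjp",
    "linearized_step_matvec",
    "spectral_norm",
]


@dataclass
class ParamGrads:
    """Per-parameter arrays mirroring ``Parameters`` (forward, biases, backward)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray | None]
    backward_weights: list[np.ndarray | None] | None = None
    w_out: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def zeros_like(cls, params: Parameters) -> "ParamGrads":
        return cls(
            weights=[np.zeros_like(w) for w in params.weights],
            biases=[None if b is None else np.zeros_like(b) for b in params.biases],
            backward_weights=None
            if params.backward_weights is None
            else [None if w is None else np.zeros_like(w) for w in params.backward_weights],
            w_out=None if params.w_out is None else np.zeros_like(params.w_out),
        )

    def scaled(self, a: float) -> "ParamGrads":
        return ParamGrads(
            weights=[a * w for w in self.weights],
            biases=[None if b is None else a * b for b in self.biases],
            backward_weights=None
            if self.backward_weights is None
            else [None if w is None else a * w for w in self.backward_weights],
            w_out=None if self.w_out is None else a * self.w_out,
            meta=dict(self.meta),
        )

    def plus(self, other: "ParamGrads", coeff: float = 1.0) -> "ParamGrads":
        out = ParamGrads(
            weights=[a + coeff * b for a, b in zip(self.weights, other.weights)],
            biases=[
                None if a is None else a + coeff * b
                for a, b in zip(self.biases, other.biases)
            ],
            backward_weights=None,
            w_out=None,
            meta=dict(self.meta),
        )
        if self.backward_weights is not None:
            out.backward_weights = [
                None if a is None else a + coeff * b
                for a, b in zip(self.backward_weights, other.backward_weights)
            ]
        if self.w_out is not None:
            ow = other.w_out if other.w_out is not None else 0.0
            out.w_out = self.w_out + coeff * ow
        return out

    def iadd_(self, other: "ParamGrads", coeff: float = 1.0) -> None:
        for a, b in zip(self.weights, other.weights):
            a += coeff * b
        for a, b in zip(self.biases, other.biases):
            if a is not None:
                a += coeff * b
        if self.backward_weights is not None and other.backward_weights is not None:
            for a, b in zip(self.backward_weights, other.backward_weights):
                if a is not None and b is not None:
                    a += coeff * b
        if self.w_out is not None and other.w_out is not None:
            self.w_out += coeff * other.w_out

    def norm(self) -> float:
        total = sum(float((w**2).sum()) for w in self.weights)
        total += sum(float((b**2).sum()) for b in self.biases if b is not None)
        if self.backward_weights is not None:
            total += sum(
                float((w**2).sum()) for w in self.backward_weights if w is not None
            )
        if self.w_out is not None:
            total += float((self.w_out**2).sum())
        return float(np.sqrt(total))

    def finite(self) -> bool:
        arrays = list(self.weights) + [b for b in self.biases if b is not None]
        if self.backward_weights is not None:
            arrays += [w for w in self.backward_weights if w is not None]
        if self.w_out is not None:
            arrays.append(self.w_out)
        return all(np.isfinite(a).all() for a in arrays)


def free_preactivations(
    x: np.ndarray, s: Sequence[np.ndarray], params: Parameters, arch: ArchitectureSpec
) -> tuple[list[np.ndarray], dict[int, np.ndarray], list[np.ndarray]]:
    """Full free pre-activations, pooling index maps, and subgradient masks at s."""
    drives, idx = bottom_up(x, s, params, arch)
    tds = top_down(s, params, arch, idx)
    pres = [
        d if td is None else d + td
        for d, td in zip(drives, tds)
    ]
    masks = [hard_sigmoid_interior(p) for p in pres]
    return pres, idx, masks


def _masked(delta: Sequence[np.ndarray], masks: Sequence[np.ndarray]) -> list[np.ndarray]:
    return [d * m for d, m in zip(delta, masks)]


def step_param_vjp(
    x: np.ndarray,
    s: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    delta: Sequence[np.ndarray],
    idx: dict[int, np.ndarray] | None = None,
    masks: Sequence[np.ndarray] | None = None,
) -> ParamGrads:
    """``(dF/dtheta)^T . delta`` at evaluation point (x, s, theta); batch-summed.

    Under bidirectional coupling the shared weight appears both in the
    bottom-up drive of its own layer and in the top-down drive into the layer
    below; both contributions accumulate into the single forward slot.  Under
    unidirectional coupling the top-down contribution lands in the backward
    slot instead.
    """
    if idx is None or masks is None:
        _, idx, masks = free_preactivations(x, s, params, arch)
    g = _masked(delta, masks)
    out = ParamGrads.zeros_like(params)
    shared = arch.coupling == BIDIRECTIONAL
    for n in range(1, arch.n_tot + 1):
        gn = g[n - 1]
        below = _layer_input(x, s, n)
        # bottom-up slot of layer n -> forward weight/bias of layer n
        if n <= arch.n_conv:
            cl = arch.conv_layers[n - 1]
            gu = unpool(gn, idx[n], cl.pool) if cl.pool is not None else gn
            out.weights[n - 1] += conv2d_weight_grad(below, gu, cl.kernel, cl.padding)
            if out.biases[n - 1] is not None:
                out.biases[n - 1] += gu.sum(axis=(0, 2, 3))
        else:
            below_flat = below.reshape(below.shape[0], -1)
            out.weights[n - 1] += gn.T @ below_flat
            if out.biases[n - 1] is not None:
                out.biases[n - 1] += gn.sum(axis=0)
        # top-down slot: layer n receives from layer n+1 through that layer's
        # backward (or shared) weight
        if n < arch.n_tot:
            src = n + 1
            s_src = s[src - 1]
            if src <= arch.n_conv:
                cl = arch.conv_layers[src - 1]
                v = unpool(s_src, idx[src], cl.pool) if cl.pool is not None else s_src
                dw = conv2d_weight_grad(gn, v, cl.kernel, cl.padding)
            else:
                gn_flat = gn.reshape(gn.shape[0], -1)
                dw = s_src.T @ gn_flat
            if shared:
                out.weights[src - 1] += dw
            else:
                out.backward_weights[src - 1] += dw
    return out


def step_state_vjp(
    x: np.ndarray,
    s: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    a: Sequence[np.ndarray],
    idx: dict[int, np.ndarray] | None = None,
    masks: Sequence[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """``(dF/ds)^T . a`` — propagate an adjoint one step backward in time."""
    if idx is None or masks is None:
        _, idx, masks = free_preactivations(x, s, params, arch)
    g = _masked(a, masks)
    new_a = [np.zeros_like(layer) for layer in s]
    for n in range(1, arch.n_tot + 1):
        gn = g[n - 1]
        # dependence of layer n's bottom-up drive on s^{n-1}
        if n >= 2:
            if n <= arch.n_conv:
                cl = arch.conv_layers[n - 1]
                gu = unpool(gn, idx[n], cl.pool) if cl.pool is not None else gn
                new_a[n - 2] += conv2d_input_grad(gu, params.weights[n - 1], cl.padding)
            else:
                contrib = gn @ params.weights[n - 1]
                new_a[n - 2] += contrib.reshape(new_a[n - 2].shape)
        # dependence of layer n's top-down drive on s^{n+1}
        if n < arch.n_tot:
            src = n + 1
            if arch.coupling == UNIDIRECTIONAL:
                wb = params.backward_weights[src - 1]
            else:
                wb = params.weights[src - 1]
            if src <= arch.n_conv:
                cl = arch.conv_layers[src - 1]
                full = conv2d(gn, wb, padding=cl.padding)
                new_a[src - 1] += (
                    pool_gather(full, idx[src], cl.pool) if cl.pool is not None else full
                )
            else:
                gn_flat = gn.reshape(gn.shape[0], -1)
                new_a[src - 1] += gn_flat @ wb.T
    return new_a


# ---------------------------------------------------------------------------
# linearization (contraction certificates for fixtures)
# ---------------------------------------------------------------------------

def linearized_step_matvec(
    v: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    idx: dict[int, np.ndarray],
) -> list[np.ndarray]:
    """Apply the state-to-state linearization A of the step map to v.

    Activation derivative set to 1 everywhere (the linear region) and pooling
    replaced by a gather at frozen index maps, so A is an honest linear
    operator whose largest singular value bounds the local contraction rate.
    """
    out = [np.zeros_like(layer) for layer in v]
    for n in range(1, arch.n_tot + 1):
        if n >= 2:  # bottom-up from v^{n-1} (input layer is clamped)
            below = v[n - 2]
            if n <= arch.n_conv:
                cl = arch.conv_layers[n - 1]
                u = conv2d(below, params.weights[n - 1], padding=cl.padding)
                out[n - 1] += (
                    pool_gather(u, idx[n], cl.pool) if cl.pool is not None else u
                )
            else:
                out[n - 1] += below.reshape(below.shape[0], -1) @ params.weights[n - 1].T
        if n < arch.n_tot:  # top-down from v^{n+1}
            src = n + 1
            if arch.coupling == UNIDIRECTIONAL:
                wb = params.backward_weights[src - 1]
            else:
                wb = params.weights[src - 1]
            v_src = v[src - 1]
            if src <= arch.n_conv:
                cl = arch.conv_layers[src - 1]
                vv = unpool(v_src, idx[src], cl.pool) if cl.pool is not None else v_src
                out[n - 1] += conv2d_input_grad(vv, wb, padding=cl.padding)
            else:
                out[n - 1] += (v_src @ wb).reshape(out[n - 1].shape)
    return out


def _linearized_step_rmatvec(u, params, arch, idx):
    """Adjoint of ``linearized_step_matvec`` (masks of 1, same frozen indices)."""
    out = [np.zeros_like(layer) for layer in u]
    for n in range(1, arch.n_tot + 1):
        gn = u[n - 1]
        if n >= 2:
            if n <= arch.n_conv:
                cl = arch.conv_layers[n - 1]
                gu = unpool(gn, idx[n], cl.pool) if cl.pool is not None else gn
                out[n - 2] += conv2d_input_grad(gu, params.weights[n - 1], cl.padding)
            else:
                out[n - 2] += (gn @ params.weights[n - 1]).reshape(out[n - 2].shape)
        if n < arch.n_tot:
            src = n + 1
            if arch.coupling == UNIDIRECTIONAL:
                wb = params.backward_weights[src - 1]
            else:
                wb = params.weights[src - 1]
            if src <= arch.n_conv:
                cl = arch.conv_layers[src - 1]
                full = conv2d(gn, wb, padding=cl.padding)
                out[src - 1] += (
                    pool_gather(full, idx[src], cl.pool) if cl.pool is not None else full
                )
            else:
                out[src - 1] += gn.reshape(gn.shape[0], -1) @ wb.T
    return out


def spectral_norm(
    params: Parameters,
    arch: ArchitectureSpec,
    idx: dict[int, np.ndarray],
    iters: int = 40,
    seed: int = 0,
) -> float:
    """Largest singular value of the linearized step map by power iteration on A^T A."""
    rng = np.random.default_rng(seed)
    v = [rng.standard_normal((1,) + shp) for shp in arch.state_shapes]
    nrm = np.sqrt(sum(float((layer**2).sum()) for layer in v))
    v = [layer / nrm for layer in v]
    sigma = 0.0
    for _ in range(iters):
        av = linearized_step_matvec(v, params, arch, idx)
        w = _linearized_step_rmatvec(av, params, arch, idx)
        nrm = np.sqrt(sum(float((layer**2).sum()) for layer in w))
        if nrm == 0.0:
            return 0.0
        sigma = np.sqrt(nrm)
        v = [layer / nrm for layer in w]
    return float(sigma)
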