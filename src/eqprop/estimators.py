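"""Equilibrium-propagation gradient estimators and the parameter-update rule.

Every estimator turns steady states of the free and nudged phases into a
per-parameter update direction that approximates ``-dL/dtheta`` (the ascent
direction), so the optimizer *adds* ``lr * estimate``:

* ``one_sided_estimate``   — classic two-phase EP, O(beta) bias,
* ``symmetric_estimate``   — three-phase +beta/-beta difference, O(beta^2) bias,
* ``random_sign_estimate`` — one-sided with a random nudging sign (unbiased to
  first order in expectation, but high variance),
* ``vf_estimate`` / ``sym_vf_estimate`` — vector-field estimators for networks
  whose dynamics do not derive from a primitive (unidirectional weights),
* ``kp_vf_estimate``       — Kolen-Pollack-style shared estimate that applies
  the *same* update to forward and backward weights, which together with a
  leakage term drives the two towards alignment.

``phi_param_grad`` is the workhorse of the primitive-based estimators: the
derivative of the scalar primitive with respect to each parameter at fixed
states, which for an fc weight reduces to the local Hebbian outer product
``s^{n+1} (s^n)^T`` and for conv kernels to a correlation routed through the
recorded max-pooling indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ArchitectureSpec,
    BIDIRECTIONAL,
    CE,
    Parameters,
    PhaseResult,
    UNIDIRECTIONAL,
    _layer_input,
    bottom_up,
    one_hot,
    readout_scores,
)
from .nnops import conv2d_weight_grad, unpool
from .vjp import ParamGrads, step_param_vjp

__all__ = [
    "EstimatorConfig",
    "GradientEstimate",
    "BIDIRECTIONAL_KINDS",
    "UNIDIRECTIONAL_KINDS",
    "phi_param_grad",
    "readout_grad",
    "one_sided_estimate",
    "symmetric_estimate",
    "random_sign_estimate",
    "vf_estimate",
    "sym_vf_estimate",
    "kp_vf_estimate",
    "SGDState",
    "apply_update",
]

BIDIRECTIONAL_KINDS = ("one_sided", "random_sign", "symmetric")
UNIDIRECTIONAL_KINDS = ("vf", "sym_vf", "kp_vf")


@dataclass(frozen=True)
class EstimatorConfig:
    """Which estimate to compute and with what nudging strength."""

    kind: str
    beta: float
    leakage: float = 0.0  # kp_vf only
    rng_seed: int | None = None  # random_sign only

    def __post_init__(self):
        if self.kind not in BIDIRECTIONAL_KINDS + UNIDIRECTIONAL_KINDS:
            raise ValueError(f"unknown estimator kind {self.kind!r}")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.leakage < 0:
            raise ValueError("leakage must be >= 0")
        if self.leakage > 0 and self.kind != "kp_vf":
            raise ValueError("leakage is only meaningful for kp_vf")


class GradientEstimate(ParamGrads):
    """ParamGrads plus estimator metadata (kind, beta, phase step counts)."""


def _as_estimate(g: ParamGrads, **meta) -> GradientEstimate:
    est = GradientEstimate(
        weights=g.weights,
        biases=g.biases,
        backward_weights=g.backward_weights,
        w_out=g.w_out,
        meta=dict(g.meta),
    )
    est.meta.update(meta)
    return est


# ---------------------------------------------------------------------------
# primitive-based local gradients
# ---------------------------------------------------------------------------

def phi_param_grad(
    x: np.ndarray,
    s: list[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
) -> ParamGrads:
    """dPhi/dtheta at fixed states, averaged over the batch.

    For an fc weight ``w_{n+1}`` this is the outer product of the adjacent
    layer states; for a conv kernel it is the correlation of the upper state
    (scattered back through the pooling argmax of the current bottom-up
    pre-activation) with the lower state.  Agrees with differentiating
    ``primitive_value`` because Phi is linear in each parameter.
    """
    if arch.coupling != BIDIRECTIONAL:
        raise ValueError("phi_param_grad requires bidirectional coupling (no primitive "
                         "exists otherwise)")
    batch = x.shape[0]
    _, idx = bottom_up(x, s, params, arch)
    out = ParamGrads.zeros_like(params)
    for n in range(1, arch.n_tot + 1):
        upper = s[n - 1]
        below = _layer_input(x, s, n)
        if n <= arch.n_conv:
            cl = arch.conv_layers[n - 1]
            if cl.pool is not None:
                if n not in idx:
                    raise ValueError(f"missing pooling indices for conv layer {n}")
                g = unpool(upper, idx[n], cl.pool)
            else:
                g = upper
            out.weights[n - 1] = conv2d_weight_grad(below, g, cl.kernel, cl.padding) / batch
            if out.biases[n - 1] is not None:
                out.biases[n - 1] = g.sum(axis=(0, 2, 3)) / batch
        else:
            below_flat = below.reshape(batch, -1)
            out.weights[n - 1] = upper.T @ below_flat / batch
            if out.biases[n - 1] is not None:
                out.biases[n - 1] = upper.mean(axis=0)
    return out


def readout_grad(
    s_top: np.ndarray, w_out: np.ndarray, y: np.ndarray, n_classes: int
) -> np.ndarray:
    """Ascent direction for the softmax readout at the free steady state.

    ``(y_onehot - softmax(w_out s)) s^T`` averaged over the batch — the
    negative cross-entropy gradient, local in pre-/post-synaptic activity.
    """
    batch = s_top.shape[0]
    flat = s_top.reshape(batch, -1)
    p = readout_scores(s_top, w_out)
    return (one_hot(y, n_classes) - p).T @ flat / batch


def _maybe_readout(
    est: ParamGrads,
    free: PhaseResult | None,
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray | None,
) -> None:
    if arch.loss_mode == CE and y is not None and free is not None and params.w_out is not None:
        est.w_out = readout_grad(free.final_state[-1], params.w_out, y, arch.n_classes)


# ---------------------------------------------------------------------------
# primitive-based estimators (bidirectional coupling)
# ---------------------------------------------------------------------------

def one_sided_estimate(
    x: np.ndarray,
    free: PhaseResult,
    nudged: PhaseResult,
    beta_signed: float,
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray | None = None,
) -> GradientEstimate:
    """Two-phase EP estimate ``(dPhi/dtheta(s^beta) - dPhi/dtheta(s_*)) / beta``."""
    if beta_signed == 0.0:
        raise ValueError("one-sided estimate undefined for beta = 0")
    if nudged.beta_used != beta_signed:
        raise ValueError(
            f"nudged phase ran at beta={nudged.beta_used}, estimate requested at {beta_signed}"
        )
    g_n = phi_param_grad(x, nudged.final_state, params, arch)
    g_f = phi_param_grad(x, free.final_state, params, arch)
    est = _as_estimate(
        g_n.plus(g_f, -1.0).scaled(1.0 / beta_signed),
        kind="one_sided",
        beta=beta_signed,
        steps=(len(free.residuals), len(nudged.residuals)),
    )
    _maybe_readout(est, free, params, arch, y)
    return est


def symmetric_estimate(
    x: np.ndarray,
    pos: PhaseResult,
    neg: PhaseResult,
    beta: float,
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray | None = None,
    free: PhaseResult | None = None,
) -> GradientEstimate:
    """Three-phase symmetric estimate ``(dPhi/dtheta(s^+b) - dPhi/dtheta(s^-b)) / 2b``.

    Algebraically the mean of the two one-sided estimates at +beta and -beta,
    which cancels the O(beta) bias term.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if pos.beta_used != beta or neg.beta_used != -beta:
        raise ValueError(
            f"phase nudging strengths ({pos.beta_used}, {neg.beta_used}) do not match "
            f"(+{beta}, -{beta})"
        )
    g_p = phi_param_grad(x, pos.final_state, params, arch)
    g_m = phi_param_grad(x, neg.final_state, params, arch)
    est = _as_estimate(
        g_p.plus(g_m, -1.0).scaled(1.0 / (2.0 * beta)),
        kind="symmetric",
        beta=beta,
        steps=(len(pos.residuals), len(neg.residuals)),
    )
    _maybe_readout(est, free, params, arch, y)
    return est


def random_sign_estimate(
    x: np.ndarray,
    free: PhaseResult,
    make_nudged,
    beta: float,
    rng: np.random.Generator,
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray | None = None,
) -> GradientEstimate:
    """One-sided estimate with the nudging sign drawn uniformly from {+1, -1}.

    ``make_nudged(signed_beta)`` must run one nudged phase from the free
    steady state.  The expectation over the sign equals the symmetric
    estimate, but single draws keep the full first-order bias with random
    sign, hence the high variance.
    """
    sign = 1.0 if rng.random() < 0.5 else -1.0
    nudged = make_nudged(sign * beta)
    est = one_sided_estimate(x, free, nudged, sign * beta, params, arch, y=y)
    est.meta.update(kind="random_sign", sign=sign, beta=beta)
    return est


# ---------------------------------------------------------------------------
# vector-field estimators (general transition function F)
# ---------------------------------------------------------------------------

def vf_estimate(
    x: np.ndarray,
    free: PhaseResult,
    nudged: PhaseResult,
    beta: float,
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray | None = None,
) -> GradientEstimate:
    """Vector-field estimate ``(dF/dtheta)^T(x, s_*, theta) . (s^beta - s_*) / beta``."""
    if nudged.beta_used == 0.0:
        raise ValueError("nudged phase ran at beta = 0")
    batch = x.shape[0]
    delta = [b - a for a, b in zip(free.final_state, nudged.final_state)]
    g = step_param_vjp(x, free.final_state, params, arch, delta)
    est = _as_estimate(
        g.scaled(1.0 / (nudged.beta_used * batch)),
        kind="vf",
        beta=nudged.beta_used,
        steps=(len(free.residuals), len(nudged.residuals)),
    )
    _maybe_readout(est, free, params, arch, y)
    return est


def sym_vf_estimate(
    x: np.ndarray,
    free: PhaseResult,
    pos: PhaseResult,
    neg: PhaseResult,
    beta: float,
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray | None = None,
) -> GradientEstimate:
    """Symmetric vector-field estimate, ``(dF/dtheta)^T(s_*) . (s^+b - s^-b) / 2b``.

    Forward and backward weights receive their *own* (different) gradient
    slots, which is precisely why this rule does not align them.
    """
    if pos.beta_used != beta or neg.beta_used != -beta:
        raise ValueError("phase nudging strengths do not match (+beta, -beta)")
    batch = x.shape[0]
    delta = [b - a for a, b in zip(neg.final_state, pos.final_state)]
    g = step_param_vjp(x, free.final_state, params, arch, delta)
    est = _as_estimate(
        g.scaled(1.0 / (2.0 * beta * batch)),
        kind="sym_vf",
        beta=beta,
        steps=(len(pos.residuals), len(neg.residuals)),
    )
    _maybe_readout(est, free, params, arch, y)
    return est


def kp_vf_estimate(
    x: np.ndarray,
    pos: PhaseResult,
    neg: PhaseResult,
    beta: float,
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray | None = None,
    free: PhaseResult | None = None,
) -> GradientEstimate:
    """Kolen-Pollack vector-field estimate with shared forward/backward slots.

    Per slot i in {forward, backward}:
        VFbar_i = [ (dF/dtheta_i)^T(s^+b) . s^+b - (dF/dtheta_i)^T(s^-b) . s^-b ] / 2b,
    then the shared estimate (VFbar_f + VFbar_b) / 2 is written identically to
    the forward and backward slots of every layer that has both.  Pooling and
    unpooling share the same argmax index maps inside each VJP.
    """
    if arch.coupling != UNIDIRECTIONAL or params.backward_weights is None:
        raise ValueError("kp_vf requires unidirectional coupling with backward weights")
    if pos.beta_used != beta or neg.beta_used != -beta:
        raise ValueError("phase nudging strengths do not match (+beta, -beta)")
    batch = x.shape[0]
    g_p = step_param_vjp(x, pos.final_state, params, arch, pos.final_state)
    g_m = step_param_vjp(x, neg.final_state, params, arch, neg.final_state)
    vfbar = g_p.plus(g_m, -1.0).scaled(1.0 / (2.0 * beta * batch))
    for n in range(2, arch.n_tot + 1):
        shared = 0.5 * (vfbar.weights[n - 1] + vfbar.backward_weights[n - 1])
        vfbar.weights[n - 1] = shared
        vfbar.backward_weights[n - 1] = shared.copy()
    est = _as_estimate(
        vfbar,
        kind="kp_vf",
        beta=beta,
        steps=(len(pos.residuals), len(neg.residuals)),
    )
    _maybe_readout(est, free, params, arch, y)
    return est


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

@dataclass
class SGDState:
    """Zero-initialized momentum buffers mirroring the parameter slots."""

    velocity: ParamGrads

    @classmethod
    def for_params(cls, params: Parameters) -> "SGDState":
        return cls(velocity=ParamGrads.zeros_like(params))


def apply_update(
    params: Parameters,
    est: ParamGrads,
    lr_per_layer,
    arch: ArchitectureSpec,
    momentum: float = 0.0,
    weight_decay: float = 0.0,
    leakage: float = 0.0,
    opt_state: SGDState | None = None,
    lr_out: float | None = None,
) -> Parameters:
    """Gradient-ascent step on the estimate, in place; returns ``params``.

    SGD with momentum; weight decay is decoupled (``-lr * wd * theta``) and
    applied to every parameter including the readout.  ``leakage`` adds the
    Kolen-Pollack term ``-lr * lambda * theta`` to forward *and* backward
    weights, so that with plain SGD a single step contracts
    ``theta_f - theta_b`` by exactly ``(1 - lr * lambda)``.
    Biases and backward weights share their layer's learning rate.
    """
    lrs = list(lr_per_layer)
    if len(lrs) != arch.n_tot:
        raise ValueError(f"lr_per_layer must have {arch.n_tot} entries, got {len(lrs)}")
    if any(lr < 0 for lr in lrs) or (lr_out is not None and lr_out < 0):
        raise ValueError("learning rates must be >= 0")
    vel = opt_state.velocity if opt_state is not None else None

    def _sgd(theta, grad, lr, buf_holder, slot, leak):
        if lr == 0.0:
            return
        if momentum != 0.0 and buf_holder is not None:
            buf = buf_holder[slot]
            buf *= momentum
            buf += grad
            grad = buf
        theta += lr * grad
        if weight_decay != 0.0:
            theta -= lr * weight_decay * theta
        if leak != 0.0:
            theta -= lr * leak * theta

    for n in range(1, arch.n_tot + 1):
        _sgd(params.weights[n - 1], est.weights[n - 1], lrs[n - 1],
             vel.weights if vel is not None else None, n - 1, leakage)
        if params.biases[n - 1] is not None and est.biases[n - 1] is not None:
            _sgd(params.biases[n - 1], est.biases[n - 1], lrs[n - 1],
                 vel.biases if vel is not None else None, n - 1, 0.0)
        if (
            params.backward_weights is not None
            and params.backward_weights[n - 1] is not None
            and est.backward_weights is not None
            and est.backward_weights[n - 1] is not None
        ):
            _sgd(params.backward_weights[n - 1], est.backward_weights[n - 1], lrs[n - 1],
                 vel.backward_weights if vel is not None else None, n - 1, leakage)
    if params.w_out is not None and est.w_out is not None and lr_out:
        if momentum != 0.0 and vel is not None:
            vel.w_out *= momentum
            vel.w_out += est.w_out
            g = vel.w_out
        else:
            g = est.w_out
        params.w_out += lr_out * g
        if weight_decay != 0.0:
            params.w_out -= lr_out * weight_decay * params.w_out
    return params
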