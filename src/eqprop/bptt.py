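"""Reference gradients by backpropagation through the unrolled free phase.

Because the free phase has converged (``s_{T-t} = ... = s_T = s_*``), every
Jacobian of the truncated unroll can be evaluated at the steady state itself:
the adjoint recursion

    a_T = dloss/ds(s_*),    g += (dF/dtheta)^T a_k,    a_{k-1} = (dF/ds)^T a_k

needs no stored trajectory and O(1) memory in the truncation depth t.  The
oracle returns ``-g`` (the loss-*decreasing* direction) so its output is
directly comparable with EP estimates, which approximate ``-dL/dtheta``.

``gdu_curves`` produces the per-time-step comparison between EP estimates and
truncated BPTT gradients — the operational form of the EP/BPTT equivalence:
for every truncation depth t, the one-sided EP estimate read off after t
nudged steps converges to the t-step truncated BPTT gradient as beta -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ArchitectureSpec,
    BIDIRECTIONAL,
    CE,
    MSE,
    Parameters,
    nudged_step,
    one_hot,
    readout_scores,
    relax,
    zeros_state,
)
from .estimators import GradientEstimate, phi_param_grad, readout_grad
from .vjp import ParamGrads, free_preactivations, step_param_vjp, step_state_vjp

__all__ = ["GDUCurves", "loss_value", "loss_state_adjoint", "bptt_truncated", "gdu_curves"]

CONVERGENCE_WARN_RESIDUAL = 1e-6


def loss_value(
    s: list[np.ndarray], params: Parameters, arch: ArchitectureSpec, y: np.ndarray
) -> float:
    """Batch-mean steady-state loss: squared error or readout cross-entropy."""
    batch = y.shape[0]
    y1 = one_hot(y, arch.n_classes)
    if arch.loss_mode == MSE:
        return float(0.5 * ((s[-1] - y1) ** 2).sum() / batch)
    p = readout_scores(s[-1], params.w_out)
    return float(-(y1 * np.log(p + 1e-300)).sum() / batch)


def loss_state_adjoint(
    s: list[np.ndarray], params: Parameters, arch: ArchitectureSpec, y: np.ndarray
) -> list[np.ndarray]:
    """dloss/ds of the batch-mean loss; nonzero only where the loss reads the state."""
    batch = y.shape[0]
    y1 = one_hot(y, arch.n_classes)
    a = [np.zeros_like(layer) for layer in s]
    if arch.loss_mode == MSE:
        a[-1] = (s[-1] - y1) / batch
    else:
        p = readout_scores(s[-1], params.w_out)
        g = (p - y1) @ params.w_out / batch
        a[-1] = g.reshape(s[-1].shape)
    return a


def bptt_truncated(
    x: np.ndarray,
    s_star: list[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray,
    t: int,
    residual: float | None = None,
) -> GradientEstimate:
    """Gradient of the steady-state loss by BPTT truncated to the last t steps.

    ``t = 0`` returns zeros.  A poorly converged ``s_star`` (residual above
    1e-6) is flagged in the metadata rather than raised, since truncation
    semantics remain well-defined.
    """
    if t < 0:
        raise ValueError("truncation depth t must be >= 0")
    out = ParamGrads.zeros_like(params)
    meta: dict = {"t": t, "oracle": "bptt"}
    if residual is not None and residual > CONVERGENCE_WARN_RESIDUAL:
        meta["convergence_warning"] = residual
    if t > 0:
        _, idx, masks = free_preactivations(x, s_star, params, arch)
        a = loss_state_adjoint(s_star, params, arch, y)
        for _ in range(t):
            out.iadd_(step_param_vjp(x, s_star, params, arch, a, idx=idx, masks=masks))
            a = step_state_vjp(x, s_star, params, arch, a, idx=idx, masks=masks)
        out = out.scaled(-1.0)
        if arch.loss_mode == CE and params.w_out is not None:
            out.w_out = readout_grad(s_star[-1], params.w_out, y, arch.n_classes)
    est = GradientEstimate(
        weights=out.weights,
        biases=out.biases,
        backward_weights=out.backward_weights,
        w_out=out.w_out,
        meta=meta,
    )
    return est


# ---------------------------------------------------------------------------
# GDU curves
# ---------------------------------------------------------------------------

@dataclass
class GDUCurves:
    """Per-parameter-group time series of EP estimates and truncated BPTT gradients.

    Each entry of the four series dicts maps a group name (``w1``, ``b1``, ...)
    to an array of shape ``(K,) + param_shape``; index ``k`` holds the value
    after ``t = k + 1`` nudged steps / at truncation depth ``t = k + 1``.
    """

    ep_pos: dict[str, np.ndarray]
    ep_neg: dict[str, np.ndarray]
    ep_sym: dict[str, np.ndarray]
    bptt: dict[str, np.ndarray]
    beta: float
    T: int
    K: int
    free_residual: float
    meta: dict = field(default_factory=dict)

    def groups(self) -> list[str]:
        return list(self.bptt.keys())

    def max_rel_rms_deviation(self, series: str = "ep_sym") -> dict[str, float]:
        """Per group: max_t RMS(series[t] - bptt[t]) / max_t RMS(bptt[t])."""
        chosen = getattr(self, series)
        out = {}
        for name, ref in self.bptt.items():
            k = ref.shape[0]
            ref_rms = np.sqrt((ref.reshape(k, -1) ** 2).mean(axis=1))
            diff = chosen[name] - ref
            diff_rms = np.sqrt((diff.reshape(k, -1) ** 2).mean(axis=1))
            out[name] = float(diff_rms.max() / (ref_rms.max() + 1e-300))
        return out


def _group_names(params: Parameters, arch: ArchitectureSpec) -> list[str]:
    names = [f"w{n}" for n in range(1, arch.n_tot + 1)]
    names += [f"b{n}" for n in range(1, arch.n_tot + 1) if params.biases[n - 1] is not None]
    return names


def _collect(g: ParamGrads, params: Parameters, arch: ArchitectureSpec) -> dict[str, np.ndarray]:
    out = {f"w{n}": g.weights[n - 1] for n in range(1, arch.n_tot + 1)}
    for n in range(1, arch.n_tot + 1):
        if params.biases[n - 1] is not None:
            out[f"b{n}"] = g.biases[n - 1]
    return out


def gdu_curves(
    x: np.ndarray,
    y: np.ndarray,
    params: Parameters,
    arch: ArchitectureSpec,
    beta: float,
    T: int,
    K: int,
) -> GDUCurves:
    """Run the free phase then K nudged steps at +beta and -beta, recording the
    per-step EP estimates next to the matching truncated BPTT gradients.
    """
    if arch.coupling != BIDIRECTIONAL:
        raise ValueError("GDU curves compare primitive-based EP with BPTT; "
                         "bidirectional coupling required")
    if beta == 0.0:
        raise ValueError("beta must be nonzero")
    if K > T:
        raise ValueError("K (nudged steps compared) cannot exceed T (free steps)")
    free = relax(x, zeros_state(arch, x.shape[0]), params, arch, steps=T)
    s_star = free.final_state
    residual = free.residuals[-1] if free.residuals else np.inf
    g_free = phi_param_grad(x, s_star, params, arch)

    names = _group_names(params, arch)
    series = {
        key: {name: [] for name in names} for key in ("ep_pos", "ep_neg", "ep_sym", "bptt")
    }

    # EP curves: advance both nudged trajectories one step at a time
    s_pos = [layer.copy() for layer in s_star]
    s_neg = [layer.copy() for layer in s_star]
    for _ in range(K):
        s_pos, _ = nudged_step(x, s_pos, params, arch, y, beta)
        s_neg, _ = nudged_step(x, s_neg, params, arch, y, -beta)
        g_pos = phi_param_grad(x, s_pos, params, arch)
        g_neg = phi_param_grad(x, s_neg, params, arch)
        ep_pos = g_pos.plus(g_free, -1.0).scaled(1.0 / beta)
        ep_neg = g_neg.plus(g_free, -1.0).scaled(-1.0 / beta)
        ep_sym = g_pos.plus(g_neg, -1.0).scaled(1.0 / (2.0 * beta))
        for key, g in (("ep_pos", ep_pos), ("ep_neg", ep_neg), ("ep_sym", ep_sym)):
            for name, arr in _collect(g, params, arch).items():
                series[key][name].append(arr)

    # BPTT curve: incremental adjoint recursion, O(K) total
    _, idx, masks = free_preactivations(x, s_star, params, arch)
    a = loss_state_adjoint(s_star, params, arch, y)
    acc = ParamGrads.zeros_like(params)
    for _ in range(K):
        acc.iadd_(step_param_vjp(x, s_star, params, arch, a, idx=idx, masks=masks))
        a = step_state_vjp(x, s_star, params, arch, a, idx=idx, masks=masks)
        for name, arr in _collect(acc.scaled(-1.0), params, arch).items():
            series["bptt"][name].append(arr)

    stack = lambda d: {name: np.stack(v) for name, v in d.items()}
    return GDUCurves(
        ep_pos=stack(series["ep_pos"]),
        ep_neg=stack(series["ep_neg"]),
        ep_sym=stack(series["ep_sym"]),
        bptt=stack(series["bptt"]),
        beta=beta,
        T=T,
        K=K,
        free_residual=float(residual),
    )
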