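"""Training loop for equilibrium propagation at configurable scale.

Implements the reference recipe: per-batch free phase (T steps from the zero
state), one or two nudged phases started from the free steady state according
to the estimator kind, a gradient-ascent step on the estimate with per-layer
learning rates, SGD momentum, decoupled weight decay and (for the
Kolen-Pollack rule) leakage, plus a cosine-annealing learning-rate schedule.
Per epoch, train/test error and — for unidirectional nets — the angle between
forward and backward weights are recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ArchitectureSpec,
    BIDIRECTIONAL,
    Batch,
    CE,
    Parameters,
    UNIDIRECTIONAL,
    predict,
    relax,
    zeros_state,
)
from .estimators import (
    BIDIRECTIONAL_KINDS,
    EstimatorConfig,
    SGDState,
    UNIDIRECTIONAL_KINDS,
    apply_update,
    kp_vf_estimate,
    one_sided_estimate,
    random_sign_estimate,
    sym_vf_estimate,
    symmetric_estimate,
    vf_estimate,
)

__all__ = [
    "TrainConfig",
    "MetricsRecord",
    "train",
    "cosine_lr",
    "alignment_angle",
    "dropout_mask",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run."""

    T: int = 30
    K: int = 10
    batch_size: int = 64
    lr_per_layer: tuple[float, ...] = (0.1, 0.05)
    lr_final: float = 1e-5
    weight_decay: float = 0.0
    momentum: float = 0.0
    epochs: int = 15
    cosine_decay_epochs: int = 15
    estimator: EstimatorConfig = field(default_factory=lambda: EstimatorConfig("symmetric", 1.0))
    dropout_p: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.K > self.T:
            raise ValueError("K (nudged steps) must not exceed T (free steps)")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")

    def validate_for(self, arch: ArchitectureSpec) -> None:
        groups = arch.n_tot + (1 if arch.loss_mode == CE else 0)
        if len(self.lr_per_layer) != groups:
            raise ValueError(
                f"lr_per_layer needs {groups} entries for this architecture "
                f"({arch.n_tot} layers{' + readout' if arch.loss_mode == CE else ''}), "
                f"got {len(self.lr_per_layer)}"
            )
        kind = self.estimator.kind
        if arch.coupling == BIDIRECTIONAL and kind not in BIDIRECTIONAL_KINDS:
            raise ValueError(f"estimator {kind!r} requires unidirectional coupling")
        if arch.coupling == UNIDIRECTIONAL and kind not in UNIDIRECTIONAL_KINDS:
            raise ValueError(f"estimator {kind!r} requires bidirectional coupling")


@dataclass
class MetricsRecord:
    """One evaluation row: errors in percent, angles in degrees."""

    epoch: int
    train_error_pct: float
    test_error_pct: float
    mean_free_residual: float
    lr: float
    angles_deg: dict[int, float] = field(default_factory=dict)


def cosine_lr(epoch: int, cfg: TrainConfig) -> np.ndarray:
    """Per-group learning rates: cosine interpolation from the initial rates
    down to ``lr_final`` over ``cosine_decay_epochs``, constant afterwards."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    lr0 = np.asarray(cfg.lr_per_layer, dtype=np.float64)
    if epoch >= cfg.cosine_decay_epochs:
        return np.full_like(lr0, cfg.lr_final)
    frac = epoch / cfg.cosine_decay_epochs
    return cfg.lr_final + 0.5 * (lr0 - cfg.lr_final) * (1.0 + math.cos(math.pi * frac))


def alignment_angle(params: Parameters, arch: ArchitectureSpec) -> dict[int, float]:
    """Angle (degrees) between forward and backward weights per layer.

    Backward weights are stored in the forward orientation, so the angle is
    the arccos of the plain cosine similarity of the flattened kernels.
    Undefined (absent) for layer 1, whose input is clamped.
    """
    if arch.coupling != UNIDIRECTIONAL or params.backward_weights is None:
        raise ValueError("alignment angle requires unidirectional coupling")
    out: dict[int, float] = {}
    for n in range(2, arch.n_tot + 1):
        wf = params.weights[n - 1].ravel()
        wb = params.backward_weights[n - 1].ravel()
        nf, nb = np.linalg.norm(wf), np.linalg.norm(wb)
        if nf == 0.0 or nb == 0.0:
            raise ValueError(f"zero-norm weights in layer {n}")
        c = float(np.clip(wf @ wb / (nf * nb), -1.0, 1.0))
        out[n] = math.degrees(math.acos(c))
    return out


def dropout_mask(
    arch: ArchitectureSpec, p: float, rng: np.random.Generator, batch: int = 1
) -> list[np.ndarray | None]:
    """Inverted-dropout masks for the neuron layer just above the conv stack.

    Bernoulli keep-probability 1-p, kept entries scaled by 1/(1-p) so the
    masked state is unbiased.  One mask per sample, held fixed across all time
    steps and phases of a mini-batch iteration.  ``p = 0`` gives identity
    masks for every layer.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError("dropout probability must lie in [0, 1)")
    masks: list[np.ndarray | None] = [None] * arch.n_tot
    target = arch.n_conv + 1 if arch.n_fc > 0 else arch.n_tot
    shape = (batch,) + arch.state_shapes[target - 1]
    if p == 0.0:
        masks[target - 1] = np.ones(shape)
    else:
        keep = rng.random(shape) >= p
        masks[target - 1] = keep.astype(np.float64) / (1.0 - p)
    return masks


def evaluate(
    params: Parameters,
    arch: ArchitectureSpec,
    data: Batch,
    T: int,
    batch_size: int = 256,
) -> float:
    """Free-phase error percentage: 100 * (1 - accuracy); no nudging, no dropout."""
    wrong = 0
    for lo in range(0, len(data), batch_size):
        xb = data.x[lo : lo + batch_size]
        yb = data.y[lo : lo + batch_size]
        free = relax(xb, zeros_state(arch, xb.shape[0]), params, arch, steps=T)
        _, labels = predict(xb, free.final_state, params, arch)
        wrong += int((labels != yb).sum())
    return 100.0 * wrong / len(data)


def _batch_estimate(xb, yb, params, arch, cfg: TrainConfig, rng, unit_masks):
    """Free phase + estimator-specific nudged phase(s) -> (estimate, free residual)."""
    est_cfg = cfg.estimator
    beta = est_cfg.beta
    free = relax(
        xb, zeros_state(arch, xb.shape[0]), params, arch, steps=cfg.T, unit_masks=unit_masks
    )
    run = lambda b: relax(
        xb, free.final_state, params, arch, steps=cfg.K, y=yb, beta=b, unit_masks=unit_masks
    )
    kind = est_cfg.kind
    if kind == "one_sided":
        est = one_sided_estimate(xb, free, run(beta), beta, params, arch, y=yb)
    elif kind == "symmetric":
        est = symmetric_estimate(xb, run(beta), run(-beta), beta, params, arch, y=yb, free=free)
    elif kind == "random_sign":
        est = random_sign_estimate(xb, free, run, beta, rng, params, arch, y=yb)
    elif kind == "vf":
        est = vf_estimate(xb, free, run(beta), beta, params, arch, y=yb)
    elif kind == "sym_vf":
        est = sym_vf_estimate(xb, free, run(beta), run(-beta), beta, params, arch, y=yb)
    elif kind == "kp_vf":
        est = kp_vf_estimate(xb, run(beta), run(-beta), beta, params, arch, y=yb, free=free)
    else:  # pragma: no cover - guarded by EstimatorConfig
        raise ValueError(kind)
    return est, free.residuals[-1]


def train(
    params: Parameters,
    arch: ArchitectureSpec,
    train_data: Batch,
    test_data: Batch,
    cfg: TrainConfig,
    on_epoch=None,
) -> tuple[Parameters, list[MetricsRecord]]:
    """Train in place and return (params, per-epoch metrics).

    Row 0 of the metrics is the pre-training evaluation; row e >= 1 follows
    epoch e.  Fully deterministic given the config seed.
    """
    cfg.validate_for(arch)
    params.validate(arch)
    rng = np.random.default_rng(cfg.seed)
    opt = SGDState.for_params(params)
    n = len(train_data)

    def snapshot(epoch: int, residual: float, lr: float) -> MetricsRecord:
        angles = (
            alignment_angle(params, arch) if arch.coupling == UNIDIRECTIONAL else {}
        )
        return MetricsRecord(
            epoch=epoch,
            train_error_pct=evaluate(params, arch, train_data, cfg.T),
            test_error_pct=evaluate(params, arch, test_data, cfg.T),
            mean_free_residual=residual,
            lr=lr,
            angles_deg=angles,
        )

    metrics = [snapshot(0, math.nan, float(cosine_lr(0, cfg)[0]))]
    for epoch in range(cfg.epochs):
        lrs = cosine_lr(epoch, cfg)
        lr_layers, lr_out = (
            (lrs[:-1], float(lrs[-1])) if arch.loss_mode == CE else (lrs, None)
        )
        order = rng.permutation(n)
        residuals = []
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            xb, yb = train_data.x[sel], train_data.y[sel]
            unit_masks = (
                dropout_mask(arch, cfg.dropout_p, rng, batch=xb.shape[0])
                if cfg.dropout_p > 0.0
                else None
            )
            est, res = _batch_estimate(xb, yb, params, arch, cfg, rng, unit_masks)
            if not est.finite():
                raise FloatingPointError(
                    f"non-finite gradient estimate at epoch {epoch}, batch {lo // cfg.batch_size}"
                )
            residuals.append(res)
            apply_update(
                params,
                est,
                lr_layers,
                arch,
                momentum=cfg.momentum,
                weight_decay=cfg.weight_decay,
                leakage=cfg.estimator.leakage if cfg.estimator.kind == "kp_vf" else 0.0,
                opt_state=opt,
                lr_out=lr_out,
            )
        metrics.append(snapshot(epoch + 1, float(np.mean(residuals)), float(lrs[0])))
        if on_epoch is not None:
            on_epoch(epoch + 1, params, metrics[-1])
    return params, metrics
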