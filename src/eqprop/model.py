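"""Network data model and relaxation dynamics of the convergent recurrent ConvNet.

The network is an energy-style recurrent network with a static input ``x``:
conv layers (each optionally followed by non-overlapping max pooling) below a
stack of fully connected layers.  With bidirectional (shared) weights the
dynamics derive from a scalar primitive

    Phi(x, {s}) = sum_conv  s^{n+1} . P(w_{n+1} * s^n + b_{n+1})
                + sum_fc    s^{n+1}^T (w_{n+1} s^n + b_{n+1}),

and one synchronous step of every layer is the hard-sigmoid of the
state-gradient of Phi: bottom-up drive plus top-down drive routed through the
inverse pooling P^-1 at the argmax indices of the *current* bottom-up
pre-activation.  With unidirectional coupling the top-down drive uses
independent backward weights instead, and no primitive exists.

Two output couplings are supported:

* ``mse_output_layer`` — the topmost layer of the dynamics is the output;
  nudging adds ``beta * (y - y_hat)`` to its pre-activation.
* ``ce_readout`` — the prediction is a softmax readout ``w_out`` of the top
  layer, which itself stays outside the dynamics; nudging injects
  ``beta * w_out^T (y - softmax(w_out s_top))`` into the top layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nnops import (
    conv2d,
    conv2d_input_grad,
    hard_sigmoid,
    maxpool,
    pool_gather,
    softmax,
    unpool,
)

__all__ = [
    "ArchitectureSpec",
    "ConvLayerSpec",
    "Parameters",
    "PhaseResult",
    "Batch",
    "zeros_state",
    "validate_state",
    "primitive_value",
    "free_step",
    "nudged_step",
    "relax",
    "predict",
    "readout_scores",
]

RESIDUAL_EPS = 1e-12

BIDIRECTIONAL = "bidirectional"
UNIDIRECTIONAL = "unidirectional"
MSE = "mse_output_layer"
CE = "ce_readout"


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolutional layer: stride-1 conv, optional non-overlapping max pool."""

    out_channels: int
    kernel: int
    padding: int = 0
    pool: int | None = None  # pooling window == pooling stride

    def to_dict(self) -> dict:
        return {
            "out_channels": self.out_channels,
            "kernel": self.kernel,
            "padding": self.padding,
            "pool": self.pool,
        }


@dataclass(frozen=True)
class ArchitectureSpec:
    """Topology, coupling mode and loss coupling of the network.

    ``fc_layers`` lists hidden/output fully connected widths above the conv
    stack.  In ``mse_output_layer`` mode the last fc layer is the output and
    must have ``n_classes`` units; in ``ce_readout`` mode no layer of the
    dynamics is an output layer and a ``C x dim(top)`` readout matrix exists.
    """

    input_shape: tuple[int, int, int]
    conv_layers: tuple[ConvLayerSpec, ...]
    fc_layers: tuple[int, ...]
    n_classes: int
    coupling: str = BIDIRECTIONAL
    loss_mode: str = CE
    activation: str = "hard_sigmoid"
    has_biases: bool = True

    def __post_init__(self):
        if self.coupling not in (BIDIRECTIONAL, UNIDIRECTIONAL):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.loss_mode not in (MSE, CE):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")
        if self.activation != "hard_sigmoid":
            raise ValueError("only the hard-sigmoid activation is supported")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.loss_mode == MSE:
            if not self.fc_layers or self.fc_layers[-1] != self.n_classes:
                raise ValueError(
                    "mse_output_layer mode requires the topmost fc layer to have "
                    f"n_classes={self.n_classes} units (got fc_layers={self.fc_layers})"
                )
        if self.n_tot < 1:
            raise ValueError("network needs at least one layer")
        self.state_shapes  # raises on inconsistent conv geometry

    # ---- derived sizes -------------------------------------------------
    @property
    def n_conv(self) -> int:
        return len(self.conv_layers)

    @property
    def n_fc(self) -> int:
        return len(self.fc_layers)

    @property
    def n_tot(self) -> int:
        return self.n_conv + self.n_fc

    @property
    def state_shapes(self) -> tuple[tuple[int, ...], ...]:
        """Per-layer state shapes s^1..s^{n_tot} (conv post-pooling, fc flat)."""
        shapes: list[tuple[int, ...]] = []
        c, h, w = self.input_shape
        for i, cl in enumerate(self.conv_layers, start=1):
            if not (0 <= cl.padding < cl.kernel):
                raise ValueError(f"conv layer {i}: padding must lie in [0, kernel)")
            h = h + 2 * cl.padding - cl.kernel + 1
            w = w + 2 * cl.padding - cl.kernel + 1
            if h <= 0 or w <= 0:
                raise ValueError(f"conv layer {i}: non-positive output size ({h},{w})")
            if cl.pool is not None:
                if cl.pool < 1 or h % cl.pool or w % cl.pool:
                    raise ValueError(
                        f"conv layer {i}: pool window {cl.pool} does not divide ({h},{w})"
                    )
                h //= cl.pool
                w //= cl.pool
            c = cl.out_channels
            shapes.append((c, h, w))
        dim = int(np.prod(shapes[-1])) if shapes else int(np.prod(self.input_shape))
        for units in self.fc_layers:
            shapes.append((units,))
            dim = units
        return tuple(shapes)

    def layer_in_dim(self, n: int) -> int:
        """Flat input dimension of fc layer n (1-based over all layers)."""
        below = self.state_shapes[n - 2] if n >= 2 else self.input_shape
        return int(np.prod(below))

    @property
    def top_dim(self) -> int:
        return int(np.prod(self.state_shapes[-1]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_shape": list(self.input_shape),
                "conv_layers": [cl.to_dict() for cl in self.conv_layers],
                "fc_layers": list(self.fc_layers),
                "n_classes": self.n_classes,
                "coupling": self.coupling,
                "loss_mode": self.loss_mode,
                "activation": self.activation,
                "has_biases": self.has_biases,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ArchitectureSpec":
        d = json.loads(payload)
        return cls(
            input_shape=tuple(d["input_shape"]),
            conv_layers=tuple(
                ConvLayerSpec(
                    out_channels=c["out_channels"],
                    kernel=c["kernel"],
                    padding=c["padding"],
                    pool=c["pool"],
                )
                for c in d["conv_layers"]
            ),
            fc_layers=tuple(d["fc_layers"]),
            n_classes=d["n_classes"],
            coupling=d["coupling"],
            loss_mode=d["loss_mode"],
            activation=d["activation"],
            has_biases=d["has_biases"],
        )


@dataclass
class Parameters:
    """Weights of the network.

    ``weights[i]``/``biases[i]`` belong to layer i+1 (conv kernels
    ``(Cout, Cin, k, k)`` below fc matrices ``(units_out, units_in)``).
    ``backward_weights`` exist only under unidirectional coupling, mirror the
    forward shapes, carry no biases, and the entry for layer 1 is ``None``
    (the input is clamped, so a backward weight into it is never used).
    ``w_out`` is the ``C x top_dim`` softmax readout (ce_readout mode only).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray | None]
    backward_weights: list[np.ndarray | None] | None = None
    w_out: np.ndarray | None = None

    def copy(self) -> "Parameters":
        return Parameters(
            weights=[w.copy() for w in self.weights],
            biases=[None if b is None else b.copy() for b in self.biases],
            backward_weights=None
            if self.backward_weights is None
            else [None if w is None else w.copy() for w in self.backward_weights],
            w_out=None if self.w_out is None else self.w_out.copy(),
        )

    def validate(self, arch: ArchitectureSpec) -> None:
        if len(self.weights) != arch.n_tot:
            raise ValueError(f"expected {arch.n_tot} weight arrays, got {len(self.weights)}")
        if arch.coupling == BIDIRECTIONAL and self.backward_weights is not None:
            raise ValueError("bidirectional coupling uses implicit transposed weights; "
                             "backward_weights must be absent")
        if arch.coupling == UNIDIRECTIONAL:
            if self.backward_weights is None:
                raise ValueError("unidirectional coupling requires backward_weights")
            for n in range(2, arch.n_tot + 1):
                wb = self.backward_weights[n - 1]
                if wb is None or wb.shape != self.weights[n - 1].shape:
                    raise ValueError(f"backward weight of layer {n} missing or mis-shaped")
        if arch.loss_mode == CE:
            if self.w_out is None:
                raise ValueError("ce_readout mode requires a readout matrix w_out")
            if self.w_out.shape != (arch.n_classes, arch.top_dim):
                raise ValueError(
                    f"w_out shape {self.w_out.shape} != ({arch.n_classes}, {arch.top_dim})"
                )


@dataclass
class PhaseResult:
    """Outcome of one relaxation phase."""

    final_state: list[np.ndarray]
    pool_indices: list[dict[int, np.ndarray]]  # per step: {layer n: argmax map}
    residuals: list[float]
    beta_used: float
    trajectory: list[list[np.ndarray]] | None = None


@dataclass
class Batch:
    """A mini-batch of static inputs with integer class labels."""

    x: np.ndarray  # (B, C, H, W)
    y: np.ndarray  # (B,) ints in [0, n_classes)

    def __post_init__(self):
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("batch dims of x and y disagree")

    def __len__(self) -> int:
        return self.x.shape[0]


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------

def zeros_state(arch: ArchitectureSpec, batch: int, dtype=np.float64) -> list[np.ndarray]:
    return [np.zeros((batch,) + shp, dtype=dtype) for shp in arch.state_shapes]


def validate_state(s: Sequence[np.ndarray], arch: ArchitectureSpec) -> None:
    if len(s) != arch.n_tot:
        raise ValueError(f"state has {len(s)} layers, architecture has {arch.n_tot}")
    for n, (layer, shp) in enumerate(zip(s, arch.state_shapes), start=1):
        if layer.shape[1:] != shp:
            raise ValueError(f"layer {n}: state shape {layer.shape[1:]} != expected {shp}")
        if not np.isfinite(layer).all():
            raise FloatingPointError(f"layer {n}: non-finite state values")


def one_hot(y: np.ndarray, n_classes: int, dtype=np.float64) -> np.ndarray:
    out = np.zeros((y.shape[0], n_classes), dtype=dtype)
    out[np.arange(y.shape[0]), y] = 1.0
    return out


# ---------------------------------------------------------------------------
# primitive
# ---------------------------------------------------------------------------

def _layer_input(x: np.ndarray, s: Sequence[np.ndarray], n: int, flat: bool = False) -> np.ndarray:
    """State below layer n (1-based); layer 1 sees the clamped input x."""
    below = x if n == 1 else s[n - 2]
    if flat:
        below = below.reshape(below.shape[0], -1)
    return below


def bottom_up(
    x: np.ndarray, s: Sequence[np.ndarray], params: Parameters, arch: ArchitectureSpec
) -> tuple[list[np.ndarray], dict[int, np.ndarray]]:
    """Bottom-up drive of every layer: pooled conv (bias before pooling) or affine fc.

    Returns the per-layer drives and the pooling argmax index maps recorded at
    this evaluation — the maps shared with the inverse pooling.
    """
    drives: list[np.ndarray] = []
    idx_maps: dict[int, np.ndarray] = {}
    for n in range(1, arch.n_tot + 1):
        w = params.weights[n - 1]
        b = params.biases[n - 1]
        if n <= arch.n_conv:
            cl = arch.conv_layers[n - 1]
            u = conv2d(_layer_input(x, s, n), w, padding=cl.padding)
            if b is not None:
                u = u + b[None, :, None, None]
            if cl.pool is not None:
                u, idx = maxpool(u, cl.pool)
                idx_maps[n] = idx
            drives.append(u)
        else:
            u = _layer_input(x, s, n, flat=True) @ w.T
            if b is not None:
                u = u + b[None, :]
            drives.append(u)
    return drives, idx_maps


def primitive_value(
    x: np.ndarray, s: Sequence[np.ndarray], params: Parameters, arch: ArchitectureSpec
) -> np.ndarray:
    """The scalar primitive Phi, one value per batch element.

    Exists only under bidirectional coupling; bilinear in the states of
    adjacent layers and linear in each parameter.
    """
    if arch.coupling != BIDIRECTIONAL:
        raise ValueError("no primitive exists: unidirectional coupling has no "
                         "scalar function whose state-gradient gives the dynamics")
    validate_state(s, arch)
    drives, _ = bottom_up(x, s, params, arch)
    b = x.shape[0]
    phi = np.zeros(b, dtype=np.float64)
    for n in range(1, arch.n_tot + 1):
        phi += (s[n - 1].reshape(b, -1) * drives[n - 1].reshape(b, -1)).sum(axis=1)
    return phi


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _backward_weight(params: Parameters, arch: ArchitectureSpec, n: int) -> np.ndarray:
    """Weight used in the top-down drive from layer n into layer n-1."""
    if arch.coupling == UNIDIRECTIONAL:
        wb = params.backward_weights[n - 1] if params.backward_weights else None
        if wb is None:
            raise ValueError(f"missing backward weight for layer {n} (unidirectional mode)")
        return wb
    return params.weights[n - 1]


def top_down(
    s: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    idx_maps: dict[int, np.ndarray],
) -> list[np.ndarray | None]:
    """Top-down drive into each layer n from layer n+1 (None for the top layer).

    Conv sources scatter through P^-1 at the index maps recorded by the
    matching bottom-up pass, then transpose-convolve; fc sources multiply by
    the transposed (or independent backward) matrix.
    """
    tds: list[np.ndarray | None] = [None] * arch.n_tot
    for n in range(1, arch.n_tot):  # drive into layer n from layer n+1
        src = n + 1
        wb = _backward_weight(params, arch, src)
        if src <= arch.n_conv:
            cl = arch.conv_layers[src - 1]
            v = s[src - 1]
            if cl.pool is not None:
                v = unpool(v, idx_maps[src], cl.pool)
            tds[n - 1] = conv2d_input_grad(v, wb, padding=cl.padding)
        else:
            td = s[src - 1] @ wb  # (B, units_src) @ (units_src, in_dim)
            tds[n - 1] = td.reshape((-1,) + arch.state_shapes[n - 1])
    return tds


def nudge_term(
    s: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray,
    beta: float,
) -> np.ndarray:
    """Pre-activation nudge injected into the topmost layer of the dynamics.

    mse mode: beta * (y_onehot - y_hat_t); ce mode: the top layer feels the
    readout error pulled back through w_out, beta * w_out^T (y_onehot - p_t).
    """
    y1 = one_hot(y, arch.n_classes)
    top = s[-1]
    if arch.loss_mode == MSE:
        return beta * (y1 - top)
    if params.w_out is None:
        raise ValueError("cross-entropy nudging requested without readout weights")
    p = softmax(top.reshape(top.shape[0], -1) @ params.w_out.T)
    g = (y1 - p) @ params.w_out
    return beta * g.reshape(top.shape)


def _step(
    x: np.ndarray,
    s: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray | None,
    beta: float,
    unit_masks: Sequence[np.ndarray | None] | None = None,
) -> tuple[list[np.ndarray], dict[int, np.ndarray]]:
    drives, idx_maps = bottom_up(x, s, params, arch)
    tds = top_down(s, params, arch, idx_maps)
    new_s: list[np.ndarray] = []
    for n in range(1, arch.n_tot + 1):
        pre = drives[n - 1]
        if tds[n - 1] is not None:
            pre = pre + tds[n - 1]
        if beta != 0.0 and n == arch.n_tot:
            pre = pre + nudge_term(s, params, arch, y, beta)
        out = hard_sigmoid(pre)
        if unit_masks is not None and unit_masks[n - 1] is not None:
            out = out * unit_masks[n - 1]
        new_s.append(out)
    return new_s, idx_maps


def free_step(
    x: np.ndarray,
    s: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    unit_masks=None,
) -> tuple[list[np.ndarray], dict[int, np.ndarray]]:
    """One synchronous unperturbed update of every layer; returns pooling maps too."""
    validate_state(s, arch)
    return _step(x, s, params, arch, y=None, beta=0.0, unit_masks=unit_masks)


def nudged_step(
    x: np.ndarray,
    s: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    y: np.ndarray,
    beta: float,
    unit_masks=None,
) -> tuple[list[np.ndarray], dict[int, np.ndarray]]:
    """One synchronous update with the output-error nudge of signed strength beta.

    ``beta == 0`` reduces bit-exactly to ``free_step``.
    """
    validate_state(s, arch)
    return _step(x, s, params, arch, y=y, beta=beta, unit_masks=unit_masks)


def relax(
    x: np.ndarray,
    s0: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
    steps: int,
    y: np.ndarray | None = None,
    beta: float = 0.0,
    record_trajectory: bool = False,
    unit_masks=None,
) -> PhaseResult:
    """Iterate the (possibly nudged) dynamics for a fixed number of steps.

    The free phase is conventionally started from the all-zero state; nudged
    phases must start from the free steady state supplied as ``s0``.
    Residuals ||s_{t+1} - s_t|| / (||s_t|| + eps) are recorded per step.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if beta != 0.0 and y is None:
        raise ValueError("nudged relaxation (beta != 0) requires labels y")
    s = [layer.copy() for layer in s0]
    validate_state(s, arch)
    residuals: list[float] = []
    idx_hist: list[dict[int, np.ndarray]] = []
    traj: list[list[np.ndarray]] | None = [] if record_trajectory else None
    for t in range(steps):
        new_s, idx = _step(x, s, params, arch, y=y, beta=beta, unit_masks=unit_masks)
        for n, layer in enumerate(new_s, start=1):
            if not np.isfinite(layer).all():
                raise FloatingPointError(f"non-finite state in layer {n} at step {t}")
        num = math.sqrt(sum(float(((a - b) ** 2).sum()) for a, b in zip(new_s, s)))
        den = math.sqrt(sum(float((b**2).sum()) for b in s)) + RESIDUAL_EPS
        residuals.append(num / den)
        idx_hist.append(idx)
        s = new_s
        if record_trajectory:
            traj.append([layer.copy() for layer in s])
    return PhaseResult(
        final_state=s,
        pool_indices=idx_hist,
        residuals=residuals,
        beta_used=beta,
        trajectory=traj,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def readout_scores(s_top: np.ndarray, w_out: np.ndarray) -> np.ndarray:
    return softmax(s_top.reshape(s_top.shape[0], -1) @ w_out.T)


def predict(
    x: np.ndarray,
    s_star: Sequence[np.ndarray],
    params: Parameters,
    arch: ArchitectureSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Class scores and argmax labels at the free steady state.

    ce_readout mode returns the softmax readout of the top layer (rows sum to
    one); mse mode returns the output-layer state as raw scores.
    """
    validate_state(s_star, arch)
    if arch.loss_mode == CE:
        if params.w_out is None:
            raise ValueError("ce_readout prediction requires w_out")
        scores = readout_scores(s_star[-1], params.w_out)
    else:
        scores = s_star[-1].copy()
    return scores, scores.argmax(axis=1)
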