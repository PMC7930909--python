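"""Synthetic datasets and fixture networks for desk-scale experiments.

``make_toy_images`` builds a download-free stand-in for a small image
classification task: each class has a fixed random spatial template, and
samples are the template plus unit Gaussian pixel noise, squashed into
[0, 1].  The template-to-noise ratio is a knob that makes the task provably
easy (linearly separable) at high values, so training-based thresholds can be
principled.

``make_fixture_net`` constructs the three reference networks used throughout
the tests: a scalar net with a closed-form fixed point, a small
fully connected net, and a small two-layer ConvNet with the same layer pattern
(3x3 conv + 2x2 max pool) as the full-scale architecture, at reduced width.  Fixture weights are rescaled at construction
until the linearized step map is a certified contraction, so the steady-state
theorems' convergence hypothesis holds on every fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ArchitectureSpec,
    BIDIRECTIONAL,
    Batch,
    CE,
    ConvLayerSpec,
    MSE,
    Parameters,
    UNIDIRECTIONAL,
    bottom_up,
)
from .vjp import spectral_norm

__all__ = [
    "ToyDatasetSpec",
    "make_toy_images",
    "make_fixture_net",
    "kaiming_uniform_init",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("scalar", "fc_small", "conv_small")

# Pixel scale of the toy images: signal std is 0.12 * template_snr and noise
# std is 0.12 around a 0.5 gray level, so snr=3 images remain mostly inside
# [0, 1] while the classes are far apart relative to the noise.
_PIXEL_SCALE = 0.12
_CONTRACTION_TARGET = 0.8


@dataclass(frozen=True)
class ToyDatasetSpec:
    """Class-template-plus-noise toy image task."""

    n_classes: int = 4
    image_size: tuple[int, int, int] = (1, 8, 8)
    n_train: int = 256
    n_test: int = 256
    template_snr: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_train <= 0 or self.n_test <= 0:
            raise ValueError("dataset sizes must be positive")
        if self.template_snr <= 0:
            raise ValueError("template_snr must be positive")


def _sample_split(rng, templates, n, spec):
    labels = np.arange(n) % spec.n_classes  # balanced by construction
    rng.shuffle(labels)
    noise = rng.standard_normal((n,) + spec.image_size)
    x = 0.5 + _PIXEL_SCALE * (spec.template_snr * templates[labels] + noise)
    return Batch(x=np.clip(x, 0.0, 1.0), y=labels)


def make_toy_images(spec: ToyDatasetSpec) -> tuple[Batch, Batch]:
    """Deterministic (train, test) batches; splits are disjoint draws by construction."""
    rng = np.random.default_rng(spec.seed)
    templates = rng.standard_normal((spec.n_classes,) + spec.image_size)
    train = _sample_split(rng, templates, spec.n_train, spec)
    test = _sample_split(rng, templates, spec.n_test, spec)
    return train, test


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _fan_in(shape: tuple[int, ...]) -> int:
    return int(np.prod(shape[1:]))


def kaiming_uniform_init(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(_fan_in(shape))
    return rng.uniform(-bound, bound, size=shape)


def init_parameters(
    arch: ArchitectureSpec, rng: np.random.Generator, weight_scale: float = 1.0
) -> Parameters:
    """Fresh parameters for an architecture: Kaiming-uniform forward weights,
    matching-shape independent backward weights under unidirectional coupling
    (no biases on the backward side), and a readout matrix in ce mode."""
    weights: list[np.ndarray] = []
    biases: list[np.ndarray | None] = []
    for n in range(1, arch.n_tot + 1):
        if n <= arch.n_conv:
            cl = arch.conv_layers[n - 1]
            cin = arch.input_shape[0] if n == 1 else arch.conv_layers[n - 2].out_channels
            shape = (cl.out_channels, cin, cl.kernel, cl.kernel)
            bshape = (cl.out_channels,)
        else:
            shape = (arch.fc_layers[n - arch.n_conv - 1], arch.layer_in_dim(n))
            bshape = (shape[0],)
        w = weight_scale * kaiming_uniform_init(shape, rng)
        weights.append(w)
        if arch.has_biases:
            bound = 1.0 / np.sqrt(_fan_in(shape))
            biases.append(rng.uniform(-bound, bound, size=bshape))
        else:
            biases.append(None)
    backward = None
    if arch.coupling == UNIDIRECTIONAL:
        backward = [None] + [
            weight_scale * kaiming_uniform_init(weights[n - 1].shape, rng)
            for n in range(2, arch.n_tot + 1)
        ]
    w_out = None
    if arch.loss_mode == CE:
        w_out = kaiming_uniform_init((arch.n_classes, arch.top_dim), rng)
    return Parameters(weights=weights, biases=biases, backward_weights=backward, w_out=w_out)


def _enforce_contraction(
    params: Parameters, arch: ArchitectureSpec, rng: np.random.Generator
) -> float:
    """Rescale all recurrent weights until the linearized step map has
    spectral norm below the contraction target; returns the certified norm.

    The linearization is jointly linear in the weight set, so a global scale
    factor scales its norm proportionally.  Pooling indices are frozen from a
    bottom-up pass at a random reference state.
    """
    ref = [rng.uniform(0.2, 0.8, size=(1,) + shp) for shp in arch.state_shapes]
    x_ref = rng.uniform(0.0, 1.0, size=(1,) + arch.input_shape)
    _, idx = bottom_up(x_ref, ref, params, arch)
    sigma = spectral_norm(params, arch, idx)
    if sigma > _CONTRACTION_TARGET:
        scale = _CONTRACTION_TARGET / sigma
        for w in params.weights:
            w *= scale
        if params.backward_weights is not None:
            for w in params.backward_weights:
                if w is not None:
                    w *= scale
        sigma = spectral_norm(params, arch, idx)
    return sigma


# ---------------------------------------------------------------------------
# fixture networks
# ---------------------------------------------------------------------------

def make_fixture_net(
    kind: str,
    coupling: str = BIDIRECTIONAL,
    loss_mode: str = CE,
    seed: int = 0,
    n_classes: int = 4,
) -> tuple[ArchitectureSpec, Parameters]:
    """Reference networks with certified-contractive free dynamics.

    * ``scalar``     — one input pixel, one unit, one weight (closed-form
      steady state ``s_* = sigma(w x + b)``); always mse with one output unit.
    * ``fc_small``   — two 16-unit fc layers on flattened 1x4x4 inputs.
    * ``conv_small`` — two 3x3 conv layers (8 then 16 channels, zero-padding 1,
      2x2 max pool) on 1x8x8 inputs; a reduced-width two-layer ConvNet.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(seed)
    if kind == "scalar":
        arch = ArchitectureSpec(
            input_shape=(1, 1, 1),
            conv_layers=(),
            fc_layers=(1,),
            n_classes=1,
            coupling=coupling,
            loss_mode=MSE,
        )
        params = Parameters(
            weights=[np.array([[0.5]])],
            biases=[np.array([0.0])],
            backward_weights=[None] if coupling == UNIDIRECTIONAL else None,
        )
        return arch, params
    if kind == "fc_small":
        fc = (16, 16) + ((n_classes,) if loss_mode == MSE else ())
        arch = ArchitectureSpec(
            input_shape=(1, 4, 4),
            conv_layers=(),
            fc_layers=fc,
            n_classes=n_classes,
            coupling=coupling,
            loss_mode=loss_mode,
        )
        # Interior fixture: weak couplings and mid-range biases give every unit
        # a saturation margin at the free *and* nudged (|beta| <= 0.2) steady
        # states, so the smooth-expansion hypotheses of the bias-order and
        # estimator-equivalence results hold on this fixture.
        params = init_parameters(arch, rng, weight_scale=0.35)
        for n in range(arch.n_tot):
            params.biases[n] = rng.uniform(0.42, 0.58, size=params.biases[n].shape)
        _enforce_contraction(params, arch, rng)
        return arch, params
    # conv_small
    arch = ArchitectureSpec(
        input_shape=(1, 8, 8),
        conv_layers=(
            ConvLayerSpec(out_channels=8, kernel=3, padding=1, pool=2),
            ConvLayerSpec(out_channels=16, kernel=3, padding=1, pool=2),
        ),
        fc_layers=(n_classes,) if loss_mode == MSE else (),
        n_classes=n_classes,
        coupling=coupling,
        loss_mode=loss_mode,
    )
    params = init_parameters(arch, rng)
    _enforce_contraction(params, arch, rng)
    return arch, params
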