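"""Decoder assembly: session-dependent feature layers + shared regression stack.

The decoder has two parts:

* **Feature layers** — per-session pointwise affine maps followed by leaky
  ReLU, with no temporal extent (length 1 in time).  They compress each
  session's neural channels (27 by default) down to a shared low-dimensional
  feature space (9 by default, widths 27 → 21 → 15 → 9), compensating for
  day-to-day electrode micro-drift: every session gets its own stack, but all
  stacks target the same feature space.
* **Regression layers** — causal convolution layers shared across sessions
  (widths 9 → 6 → 3 → 1), with leaky ReLU between layers and a raw final
  output.  In the ``gamma`` configuration each kernel is a closed-form Gamma
  function (300 ms span); in the ``naive`` configuration kernels are free
  10-bin (100 ms) tap vectors.  A ``linear`` configuration — a single
  pointwise affine map with no rectification and no temporal memory — serves
  as the baseline control decoder.

Because convolutions are front-padded, the whole network is causal: the
prediction at bin t depends only on inputs at bins ≤ t.

Gradients are computed by explicit reverse-mode passes (`backward`); every
layer's backward rule is closed-form and checked against finite differences
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gammadecoder.gamma_core import (
    GammaLayerParams,
    conv_grid_backward,
    conv_grid_forward,
    gamma_layer_backward,
    gamma_layer_forward,
    layer_taps,
)
from gammadecoder.signal_prep import TrialTensor

__all__ = [
    "NetworkSpec",
    "FeatureLayerParams",
    "DecoderModel",
    "feature_layer_forward",
    "naive_conv_layer_forward",
    "forward",
    "forward_cached",
    "backward",
    "build_model",
]


@dataclass
class NetworkSpec:
    """Architecture description.

    ``feature_widths`` lists channel counts through the per-session pointwise
    stack (first entry = number of neural channels); ``regression_widths``
    lists channel counts through the shared temporal stack (last entry must
    be 1, the predicted EMG channel).  ``regression_kind`` selects Gamma
    kernels, free (naive) kernels, or the pointwise linear control.
    """

    feature_widths: tuple[int, ...] = (27, 21, 15, 9)
    regression_widths: tuple[int, ...] = (9, 6, 3, 1)
    regression_kind: str = "gamma"
    gamma_kernel_ms: float = 300.0
    naive_kernel_bins: int = 10
    leaky_slope: float = 0.01
    bin_width: float = 0.01
    theta: float = 10.0

    def __post_init__(self) -> None:
        self.feature_widths = tuple(int(w) for w in self.feature_widths)
        self.regression_widths = tuple(int(w) for w in self.regression_widths)
        if self.regression_kind not in ("gamma", "naive", "linear"):
            raise ValueError(f"unknown regression_kind {self.regression_kind!r}")
        if any(w <= 0 for w in self.feature_widths + self.regression_widths):
            raise ValueError("all layer widths must be positive")
        if self.regression_widths[-1] != 1:
            raise ValueError("final regression width must be 1 (single EMG channel)")
        if self.feature_widths[-1] != self.regression_widths[0]:
            raise ValueError(
                "last feature width must equal first regression width, got "
                f"{self.feature_widths[-1]} vs {self.regression_widths[0]}"
            )
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def gamma_taps(self) -> int:
        """Gamma kernel length in bins (300 ms at 10 ms bins → 30 taps)."""
        return int(round(self.gamma_kernel_ms / 1000.0 / self.bin_width))

    @property
    def n_input_channels(self) -> int:
        return self.feature_widths[0]


@dataclass
class FeatureLayerParams:
    """Pointwise affine + leaky ReLU: out = leaky(x @ W + b) at every bin."""

    weights: np.ndarray
    biases: np.ndarray
    slope: float = 0.01

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be (d_in, d_out)")
        if self.biases.shape != (self.weights.shape[1],):
            raise ValueError("biases must be (d_out,)")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.biases))):
            raise ValueError("feature layer parameters must be finite")


@dataclass
class DecoderModel:
    """Per-session feature stacks plus a shared regression stack."""

    spec: NetworkSpec
    feature_stacks: dict[str, list[FeatureLayerParams]] = field(default_factory=dict)
    # list of GammaLayerParams (gamma), ndarray kernels (naive),
    # or a single FeatureLayerParams with slope 1 (linear)
    regression_stack: list = field(default_factory=list)

    @property
    def session_ids(self) -> list[str]:
        return list(self.feature_stacks.keys())

    # -- flat parameter state ------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        """Copy of every trainable array, keyed by a stable path string."""
        state: dict[str, np.ndarray] = {}
        for sid, stack in self.feature_stacks.items():
            for k, p in enumerate(stack):
                state[f"feat/{sid}/{k}/W"] = p.weights.copy()
                state[f"feat/{sid}/{k}/b"] = p.biases.copy()
        for k, layer in enumerate(self.regression_stack):
            if isinstance(layer, GammaLayerParams):
                state[f"reg/{k}/alpha"] = layer.alpha.copy()
                state[f"reg/{k}/log_beta"] = layer.log_beta.copy()
                state[f"reg/{k}/log_t0"] = layer.log_t0.copy()
            elif isinstance(layer, FeatureLayerParams):
                state[f"reg/{k}/W"] = layer.weights.copy()
                state[f"reg/{k}/b"] = layer.biases.copy()
            else:
                state[f"reg/{k}/kernels"] = np.asarray(layer).copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for sid, stack in self.feature_stacks.items():
            for k, p in enumerate(stack):
                p.weights = state[f"feat/{sid}/{k}/W"].copy()
                p.biases = state[f"feat/{sid}/{k}/b"].copy()
        for k, layer in enumerate(self.regression_stack):
            if isinstance(layer, GammaLayerParams):
                layer.alpha = state[f"reg/{k}/alpha"].copy()
                layer.log_beta = state[f"reg/{k}/log_beta"].copy()
                layer.log_t0 = state[f"reg/{k}/log_t0"].copy()
            elif isinstance(layer, FeatureLayerParams):
                layer.weights = state[f"reg/{k}/W"].copy()
                layer.biases = state[f"reg/{k}/b"].copy()
            else:
                self.regression_stack[k] = state[f"reg/{k}/kernels"].copy()


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z >= 0, z, slope * z)


def feature_layer_forward(x: np.ndarray, p: FeatureLayerParams) -> np.ndarray:
    """Apply a pointwise feature layer independently at every time bin."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or x.shape[2] != p.weights.shape[0]:
        raise ValueError(
            f"input must be (trials, bins, {p.weights.shape[0]}), got {x.shape}"
        )
    return _leaky(x @ p.weights + p.biases, p.slope)


def naive_conv_layer_forward(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Free-kernel causal convolution layer, summed over input channels.

    ``kernels`` is (d_in, d_out, n_bins).  Identical convolution operator to
    the Gamma layer — only the tap parameterization differs — so setting the
    kernels to sampled Gamma taps reproduces ``gamma_layer_forward`` exactly.
    """
    x = np.asarray(x, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if x.ndim != 3 or kernels.ndim != 3 or x.shape[2] != kernels.shape[0]:
        raise ValueError(
            f"shape mismatch: input {x.shape} vs kernels {kernels.shape}"
        )
    return conv_grid_forward(x, kernels)


# ---------------------------------------------------------------------------
# cached forward / reverse-mode backward
# ---------------------------------------------------------------------------

def forward_cached(model: DecoderModel, sessions: dict[str, np.ndarray]):
    """Forward pass retaining intermediates for the backward pass.

    ``sessions`` maps session id → (trials, bins, channels) array (or
    TrialTensor).  Per-session feature stacks produce the shared feature
    space; features are concatenated along the trial axis, pushed through the
    shared regression stack, and split back per session.
    """
    spec = model.spec
    cache: dict = {"order": [], "sizes": [], "feat": {}, "reg": []}
    feats = []
    for sid, x in sessions.items():
        if sid not in model.feature_stacks:
            raise KeyError(f"model has no feature stack for session {sid!r}")
        if isinstance(x, TrialTensor):
            x = x.data
        x = np.asarray(x, dtype=float)
        layer_caches = []
        h = x
        for p in model.feature_stacks[sid]:
            z = h @ p.weights + p.biases
            mask = z >= 0
            layer_caches.append((h, mask))
            h = np.where(mask, z, p.slope * z)
        cache["feat"][sid] = layer_caches
        cache["order"].append(sid)
        cache["sizes"].append(h.shape[0])
        feats.append(h)
    h = np.concatenate(feats, axis=0) if len(feats) > 1 else feats[0]

    n_reg = len(model.regression_stack)
    for k, layer in enumerate(model.regression_stack):
        last = k == n_reg - 1
        if isinstance(layer, GammaLayerParams):
            z = gamma_layer_forward(h, layer)
        elif isinstance(layer, FeatureLayerParams):
            z = h @ layer.weights + layer.biases
        else:
            z = conv_grid_forward(h, np.asarray(layer, dtype=float))
        if last or isinstance(layer, FeatureLayerParams):
            # raw prediction; linear control has no rectification anywhere
            cache["reg"].append((h, None))
            h = z
        else:
            mask = z >= 0
            cache["reg"].append((h, mask))
            h = np.where(mask, z, spec.leaky_slope * z)

    preds: dict[str, np.ndarray] = {}
    start = 0
    for sid, n in zip(cache["order"], cache["sizes"]):
        preds[sid] = h[start:start + n]
        start += n
    return preds, cache


def forward(model: DecoderModel, sessions: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Predicted EMG envelope per session, (trials, bins, 1)."""
    preds, _ = forward_cached(model, sessions)
    return preds


def backward(
    model: DecoderModel, cache: dict, grad_preds: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Reverse-mode gradients of a scalar loss given d(loss)/d(prediction).

    Gradients from all sessions accumulate on the shared regression stack;
    each per-session feature stack receives only its own session's gradient.
    """
    spec = model.spec
    g = np.concatenate(
        [np.asarray(grad_preds[sid], dtype=float) for sid in cache["order"]], axis=0
    )
    grads: dict[str, np.ndarray] = {}

    n_reg = len(model.regression_stack)
    for k in range(n_reg - 1, -1, -1):
        layer = model.regression_stack[k]
        h_in, mask = cache["reg"][k]
        if mask is not None:
            g = np.where(mask, g, spec.leaky_slope * g)
        if isinstance(layer, GammaLayerParams):
            g, layer_grads = gamma_layer_backward(h_in, layer, g)
            for name, arr in layer_grads.items():
                grads[f"reg/{k}/{name}"] = arr
        elif isinstance(layer, FeatureLayerParams):
            grads[f"reg/{k}/W"] = np.einsum("tbi,tbo->io", h_in, g, optimize=True)
            grads[f"reg/{k}/b"] = g.sum(axis=(0, 1))
            g = g @ layer.weights.T
        else:
            kern = np.asarray(layer, dtype=float)
            g, gk = conv_grid_backward(h_in, kern, g)
            grads[f"reg/{k}/kernels"] = gk

    start = 0
    for sid, n in zip(cache["order"], cache["sizes"]):
        gs = g[start:start + n]
        start += n
        stack = model.feature_stacks[sid]
        for k in range(len(stack) - 1, -1, -1):
            p = stack[k]
            h_in, mask = cache["feat"][sid][k]
            gz = np.where(mask, gs, p.slope * gs)
            grads[f"feat/{sid}/{k}/W"] = np.einsum("tbi,tbo->io", h_in, gz, optimize=True)
            grads[f"feat/{sid}/{k}/b"] = gz.sum(axis=(0, 1))
            gs = gz @ p.weights.T
    return grads


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def build_model(
    spec: NetworkSpec, session_ids: list[str], rng_seed: int
) -> DecoderModel:
    """Initialize a decoder; deterministic given the seed.

    Feature weights and kernel areas use Xavier (Glorot) uniform
    initialization so signal variance is roughly preserved layer to layer;
    feature biases start at 0.  Gamma onset delays t0 and warped times to
    peak 1/beta are drawn uniformly from 5–30 ms (both on the order of 10 ms)
    and optimized through their logarithms.
    """
    rng = np.random.default_rng(rng_seed)
    model = DecoderModel(spec=spec)
    fw = spec.feature_widths
    for sid in session_ids:
        stack = []
        for d_in, d_out in zip(fw[:-1], fw[1:]):
            stack.append(
                FeatureLayerParams(
                    weights=_xavier(rng, d_in, d_out, (d_in, d_out)),
                    biases=np.zeros(d_out),
                    slope=spec.leaky_slope,
                )
            )
        model.feature_stacks[sid] = stack

    rw = spec.regression_widths
    if spec.regression_kind == "gamma":
        for d_in, d_out in zip(rw[:-1], rw[1:]):
            alpha = _xavier(rng, d_in, d_out, (d_in, d_out))
            t0 = rng.uniform(0.005, 0.030, size=(d_in, d_out))
            tau = rng.uniform(0.005, 0.030, size=(d_in, d_out))  # warped time to peak = 1/beta
            model.regression_stack.append(
                GammaLayerParams(
                    alpha=alpha,
                    log_beta=-np.log(tau),
                    log_t0=np.log(t0),
                    theta=spec.theta,
                    n_taps=spec.gamma_taps,
                    dt=spec.bin_width,
                )
            )
    elif spec.regression_kind == "naive":
        L = spec.naive_kernel_bins
        for d_in, d_out in zip(rw[:-1], rw[1:]):
            model.regression_stack.append(
                _xavier(rng, d_in * L, d_out, (d_in, d_out, L))
            )
    else:  # linear control: one pointwise affine map, no rectification
        if len(rw) != 2:
            raise ValueError("linear decoder takes exactly one regression layer")
        model.regression_stack.append(
            FeatureLayerParams(
                weights=_xavier(rng, rw[0], rw[1], (rw[0], rw[1])),
                biases=np.zeros(rw[1]),
                slope=1.0,
            )
        )
    return model


def regression_kernels(model: DecoderModel) -> list[np.ndarray]:
    """Sampled (d_in, d_out, n_taps) tap arrays of every regression layer."""
    out = []
    for layer in model.regression_stack:
        if isinstance(layer, GammaLayerParams):
            out.append(layer_taps(layer))
        elif isinstance(layer, FeatureLayerParams):
            out.append(layer.weights[:, :, None])
        else:
            out.append(np.asarray(layer))
    return out
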