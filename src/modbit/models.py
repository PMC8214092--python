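"""The convolutional classifier zoo: two architectures x four variants.

Both architectures share the shape "3 conv(+2x2 pool) stages, two dense
hidden layers, softmax output" on 28x28 inputs, differing in widths and
activations:

    Entity  : conv 32 relu / 64 tanh / 16 sigmoid; dense 512 relu, 288 tanh
    Concept : conv 16 tanh / 16 relu / 32 relu;    dense 320 relu, 448 sigmoid

Variants:

    baseline       — the plain classifier; Hebbian probes attach to its
                     dense-layer pre-activations during pretraining.
    experimental   — the flattened convolutional features are concatenated
                     with one extra scalar per example: the +-1 modality bit
                     decoded by a frozen probe.
    expanded_base  — baseline with one extra node in dense layer 1, a
                     parameter-count control with no extra information.
    constant_input — structurally identical to experimental but fed a
                     constant 1, equalizing parameter counts exactly.

Convolutions are valid (no padding), so 28 -> 26 -> 13 -> 11 -> 5 -> 3 -> 1
spatially and the flattened convolutional feature width equals the last
stage's filter count.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .nn import Adam, Conv2D, Dense, MaxPool2D, softmax_cross_entropy

__all__ = ["LayerSpec", "ArchitectureSpec", "ModelVariant", "TapHandle",
           "ConvClassifier", "build", "count_params",
           "ENTITY_SPEC", "CONCEPT_SPEC"]


@dataclass(frozen=True)
class LayerSpec:
    kind: str                       # conv | maxpool | dense | output
    filters_or_nodes: int = 0
    kernel_or_pool: tuple[int, int] = (0, 0)
    activation: str = "linear"


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer descriptions for one task's optimised classifier."""

    name: str
    layers: tuple[LayerSpec, ...]

    @property
    def conv_stages(self) -> list[LayerSpec]:
        return [l for l in self.layers if l.kind == "conv"]

    @property
    def dense_layers(self) -> list[LayerSpec]:
        return [l for l in self.layers if l.kind == "dense"]


def _arch(name: str, convs: list[tuple[int, str]],
          denses: list[tuple[int, str]]) -> ArchitectureSpec:
    layers: list[LayerSpec] = []
    for f, act in convs:
        layers.append(LayerSpec("conv", f, (3, 3), act))
        layers.append(LayerSpec("maxpool", 0, (2, 2)))
    for n, act in denses:
        layers.append(LayerSpec("dense", n, activation=act))
    layers.append(LayerSpec("output", 0, activation="softmax"))
    return ArchitectureSpec(name, tuple(layers))


ENTITY_SPEC = _arch("entity",
                    [(32, "relu"), (64, "tanh"), (16, "sigmoid")],
                    [(512, "relu"), (288, "tanh")])
CONCEPT_SPEC = _arch("concept",
                     [(16, "tanh"), (16, "relu"), (32, "relu")],
                     [(320, "relu"), (448, "sigmoid")])


class ModelVariant(str, Enum):
    BASELINE = "baseline"
    EXPERIMENTAL = "experimental"
    EXPANDED_BASE = "expanded_base"
    CONSTANT_INPUT = "constant_input"


@dataclass(frozen=True)
class TapHandle:
    """Identifies one dense hidden layer whose pre-activations are exposed."""

    layer_index: int  # 1 or 2
    width: int


class ConvClassifier:
    """A Table-of-architectures CNN with dense-layer taps and a bit input.

    ``forward_taps`` returns softmax probabilities together with both dense
    hidden layers' pre-activation matrices (the values before the dense
    nonlinearities), which is what the Hebbian probes consume.
    """

    INPUT_SHAPE = (28, 28)

    def __init__(self, spec: ArchitectureSpec, variant: ModelVariant,
                 n_outputs: int, rng: np.random.Generator):
        if not isinstance(variant, ModelVariant):
            try:
                variant = ModelVariant(variant)
            except ValueError:
                raise ValueError(f"unknown variant: {variant!r}") from None
        if n_outputs <= 0:
            raise ValueError("n_outputs must be positive")
        self.spec = spec
        self.variant = variant
        self.n_outputs = n_outputs
        self.trainable = True

        self.takes_bit = variant in (ModelVariant.EXPERIMENTAL,
                                     ModelVariant.CONSTANT_INPUT)

        self.convs: list[Conv2D] = []
        self.pools: list[MaxPool2D] = []
        c_in = 1
        side = self.INPUT_SHAPE[0]
        for conv_spec in spec.conv_stages:
            self.convs.append(Conv2D(c_in, conv_spec.filters_or_nodes, 3,
                                     conv_spec.activation, rng))
            self.pools.append(MaxPool2D(2))
            side = (side - 2) // 2
            c_in = conv_spec.filters_or_nodes
        self.flat_width = side * side * c_in

        d1_spec, d2_spec = spec.dense_layers
        d1_nodes = d1_spec.filters_or_nodes
        if variant == ModelVariant.EXPANDED_BASE:
            d1_nodes += 1
        d1_in = self.flat_width + (1 if self.takes_bit else 0)
        self.dense1 = Dense(d1_in, d1_nodes, d1_spec.activation, rng)
        self.dense2 = Dense(d1_nodes, d2_spec.filters_or_nodes,
                            d2_spec.activation, rng)
        self.output = Dense(d2_spec.filters_or_nodes, n_outputs, "linear", rng)

    # -- introspection -----------------------------------------------------

    @property
    def taps(self) -> tuple[TapHandle, TapHandle]:
        return (TapHandle(1, self.dense1.n_out), TapHandle(2, self.dense2.n_out))

    @property
    def tap_widths(self) -> tuple[int, int]:
        return (self.dense1.n_out, self.dense2.n_out)

    def parameters(self):
        ps = []
        for layer in (*self.convs, self.dense1, self.dense2, self.output):
            ps.extend(layer.params())
        return ps

    def weight_state(self) -> list[np.ndarray]:
        """Copies of all parameter arrays (for immutability checks)."""
        return [p.value.copy() for p in self.parameters()]

    # -- forward / backward ------------------------------------------------

    def _prepare_bits(self, n: int, bits: np.ndarray | None) -> np.ndarray | None:
        if self.variant == ModelVariant.CONSTANT_INPUT:
            return np.ones((n, 1), dtype=np.float32)
        if self.variant == ModelVariant.EXPERIMENTAL:
            if bits is None:
                raise ValueError(
                    "experimental variant requires a +-1 bit per example")
            bits = np.asarray(bits, dtype=np.float32).reshape(n, 1)
            if not np.all(np.isin(bits, (1.0, -1.0))):
                raise ValueError("bit values must be +1 or -1")
            return bits
        if bits is not None:
            raise ValueError(f"{self.variant.value} variant takes no bit input")
        return None

    def forward_taps(self, pixels: np.ndarray, bits: np.ndarray | None = None
                     ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
        """Forward pass returning (probabilities, (z1, z2) pre-activations)."""
        x = np.asarray(pixels, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        n = len(x)
        a = x[..., None]  # NHWC, one channel
        for conv, pool in zip(self.convs, self.pools):
            a = pool.forward(conv.forward(a))
        flat = a.reshape(n, -1)
        col = self._prepare_bits(n, bits)
        if col is not None:
            flat = np.concatenate([flat, col], axis=1)
        a1 = self.dense1.forward(flat)
        a2 = self.dense2.forward(a1)
        logits = self.output.forward(a2)
        from .nn import softmax
        return softmax(logits), (self.dense1.preact, self.dense2.preact)

    def train_step(self, pixels: np.ndarray, labels: np.ndarray,
                   optimizer: Adam, bits: np.ndarray | None = None
                   ) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
        """One optimizer step on cross-entropy; returns (loss, acc, taps)."""
        if not self.trainable:
            raise RuntimeError("model is frozen")
        x = np.asarray(pixels, dtype=np.float32)
        n = len(x)
        a = x[..., None]
        for conv, pool in zip(self.convs, self.pools):
            a = pool.forward(conv.forward(a))
        conv_shape = a.shape
        flat = a.reshape(n, -1)
        col = self._prepare_bits(n, bits)
        width = flat.shape[1]
        if col is not None:
            flat = np.concatenate([flat, col], axis=1)
        a1 = self.dense1.forward(flat)
        a2 = self.dense2.forward(a1)
        logits = self.output.forward(a2)

        loss, dlogits, probs = softmax_cross_entropy(logits, labels)
        acc = float(np.mean(probs.argmax(axis=1) == labels))

        d = self.output.backward(dlogits)
        d = self.dense2.backward(d)
        d = self.dense1.backward(d)
        d = d[:, :width]  # gradient w.r.t. the injected bit is discarded
        d = d.reshape(conv_shape)
        for conv, pool in zip(reversed(self.convs), reversed(self.pools)):
            d = conv.backward(pool.backward(d))
        optimizer.step()
        return loss, acc, (self.dense1.preact, self.dense2.preact)

    def evaluate(self, pixels: np.ndarray, labels: np.ndarray,
                 bits: np.ndarray | None = None, batch: int = 512
                 ) -> tuple[float, float]:
        """Mean cross-entropy loss and accuracy over a sample set."""
        losses, correct, n = [], 0, len(labels)
        for i in range(0, n, batch):
            sl = slice(i, min(i + batch, n))
            b = None if bits is None else bits[sl]
            p, _ = self.forward_taps(pixels[sl], b)
            y = labels[sl]
            eps = 1e-12
            losses.append(-np.log(p[np.arange(len(y)), y] + eps))
            correct += int(np.sum(p.argmax(axis=1) == y))
        return float(np.mean(np.concatenate(losses))), correct / n

    # -- lifecycle ---------------------------------------------------------

    def freeze(self) -> "ConvClassifier":
        self.trainable = False
        return self

    def copy(self) -> "ConvClassifier":
        return copy.deepcopy(self)


def build(spec: ArchitectureSpec, variant: ModelVariant | str, n_outputs: int,
          rng: np.random.Generator) -> ConvClassifier:
    """Construct a classifier for ``spec`` in the requested variant role."""
    return ConvClassifier(spec, variant, n_outputs, rng)


def count_params(model: ConvClassifier) -> int:
    """Total trainable scalar parameters (0 for a frozen model)."""
    if not model.trainable:
        return 0
    return int(sum(p.value.size for p in model.parameters()))
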