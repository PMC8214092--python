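"""Supervised Hebbian probes over dense-layer pre-activations.

A probe is a bias-free linear decoder attached to one dense hidden layer of
a host network.  It reads the layer's *pre-activation* values, binarizes
them to +-1 by sign, and is trained with the plain supervised Hebb rule

    w  <-  w + eta * label * xbin

to predict the input's modality (+1 sound, -1 image).  Probe training never
touches the host network's weights.

Conventions for degenerate values: an exact zero pre-activation binarizes
to +1; a zero inner product at prediction time emits +1 but is scored as an
error, so a freshly reset probe has accuracy 0 by definition.
"""

from __future__ import annotations

import numpy as np

__all__ = ["HebbianProbe", "binarize", "probe_accuracy"]


def binarize(preact: np.ndarray) -> np.ndarray:
    """Element-wise sign of pre-activations, with exact zeros mapped to +1."""
    preact = np.asarray(preact, dtype=np.float64)
    if not np.all(np.isfinite(preact)):
        raise ValueError("pre-activations must be finite")
    return np.where(preact >= 0.0, 1.0, -1.0)


class HebbianProbe:
    """Hebbian linear decoder of modality from binarized pre-activations.

    Parameters
    ----------
    width : int
        Number of units in the attached layer; fixed at attachment time.
    learning_rate : float
        Hebb rule step size ``eta``.  With sign-based predictions any
        positive value yields identical decisions; kept for completeness.
    """

    def __init__(self, width: int, learning_rate: float = 1.0):
        if width <= 0:
            raise ValueError("width must be positive")
        self.width = int(width)
        self.learning_rate = float(learning_rate)
        self.weights = np.zeros(self.width, dtype=np.float64)
        self.updates_seen = 0
        self.frozen = False

    # -- training ----------------------------------------------------------

    def update(self, xbin: np.ndarray, label: int) -> "HebbianProbe":
        """One Hebb step: ``w += eta * label * xbin``."""
        return self.update_batch(np.asarray(xbin)[None, :], np.array([label]))

    def update_batch(self, xbin: np.ndarray, labels: np.ndarray) -> "HebbianProbe":
        """Accumulate Hebb steps for a batch of binarized vectors.

        The Hebb rule is linear, so a batch update equals the sum of the
        per-example updates in any order.
        """
        if self.frozen:
            raise RuntimeError("probe is frozen")
        xbin = np.asarray(xbin, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.float64)
        if xbin.ndim != 2 or xbin.shape[1] != self.width:
            raise ValueError(f"expected (n, {self.width}) binarized input")
        if not np.all(np.isin(labels, (1.0, -1.0))):
            raise ValueError("labels must be +1 or -1")
        self.weights += self.learning_rate * (labels @ xbin)
        self.updates_seen += len(labels)
        return self

    def reset(self) -> "HebbianProbe":
        """Zero the weights and the update counter (idempotent)."""
        self.weights = np.zeros(self.width, dtype=np.float64)
        self.updates_seen = 0
        return self

    # -- inference ---------------------------------------------------------

    def scores(self, xbin: np.ndarray) -> np.ndarray:
        xbin = np.asarray(xbin, dtype=np.float64)
        if xbin.shape[-1] != self.width:
            raise ValueError(
                f"input width {xbin.shape[-1]} != probe width {self.width}")
        return xbin @ self.weights

    def predict(self, xbin: np.ndarray) -> int:
        """Sign of ``w . xbin``; a zero inner product emits +1."""
        return int(1 if self.scores(xbin) >= 0 else -1)

    def predict_batch(self, xbin: np.ndarray) -> np.ndarray:
        s = self.scores(xbin)
        return np.where(s >= 0, 1, -1).astype(np.int8)

    def copy(self) -> "HebbianProbe":
        p = HebbianProbe(self.width, self.learning_rate)
        p.weights = self.weights.copy()
        p.updates_seen = self.updates_seen
        p.frozen = self.frozen
        return p


def probe_accuracy(probe: HebbianProbe, preacts: np.ndarray,
                   labels: np.ndarray) -> float:
    """Fraction of examples whose modality the probe decodes correctly.

    ``preacts`` are raw pre-activations ``(n, width)``; they are binarized
    before scoring.  Zero inner products are counted as errors, which makes
    the accuracy of a freshly reset probe exactly 0.
    """
    preacts = np.asarray(preacts)
    labels = np.asarray(labels)
    if preacts.size == 0:
        raise ValueError("evaluation set must be non-empty")
    s = probe.scores(binarize(preacts))
    pred = np.where(s >= 0, 1, -1)
    correct = (pred == labels) & (s != 0)
    return float(np.mean(correct))
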