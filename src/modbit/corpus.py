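"""Synthetic bimodal corpus: class-distinct images and waveforms, the
sound-to-image preprocessing pipeline, and Entity/Concept dataset assembly.

The corpus emulates a two-modality classification problem: 28x28 grayscale
"images" (oriented gratings with a class-dependent blob) and 1-second
"sounds" (class-indexed harmonic stacks at 22050 samples/s).  Sounds are
rendered to the image format by Mel-spectrogram conversion (128x44),
zero-padding to 140x56 and 5x2 max pooling down to 28x28, so that a single
convolutional network can consume both modalities.

Modality is tagged +1 for sound and -1 for image throughout the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "MODALITY_SOUND",
    "MODALITY_IMAGE",
    "Waveform",
    "ModalitySample",
    "CorpusConfig",
    "SampleSet",
    "BimodalDataset",
    "MinMaxNormalizer",
    "synth_image",
    "synth_waveform",
    "mel_spectrogram",
    "pool_to_emnist_shape",
    "normalize",
    "sound_to_image",
    "assemble_entity",
    "assemble_concept",
    "split_validation",
    "sample_batch",
]

MODALITY_SOUND = 1
MODALITY_IMAGE = -1

IMAGE_SHAPE = (28, 28)
MEL_SHAPE = (128, 44)
PAD_SHAPE = (140, 56)
POOL_SIZE = (5, 2)


@dataclass(frozen=True)
class Waveform:
    """A mono audio clip: amplitude samples plus a sampling rate."""

    samples: np.ndarray
    rate: int = 22050

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))

    def __len__(self) -> int:
        return len(self.samples)

    def fixed_length(self, duration_s: float) -> "Waveform":
        """Pad with zeros / truncate to exactly ``duration_s`` seconds."""
        n = int(round(duration_s * self.rate))
        s = self.samples[:n]
        if len(s) < n:
            s = np.pad(s, (0, n - len(s)))
        return Waveform(s, self.rate)


@dataclass(frozen=True)
class ModalitySample:
    """One training example: 28x28 pixels, a +-1 modality tag, a class label."""

    pixels: np.ndarray
    modality: int
    class_id: int

    def __post_init__(self) -> None:
        if self.modality not in (MODALITY_SOUND, MODALITY_IMAGE):
            raise ValueError(f"modality must be +1 or -1, got {self.modality}")
        if self.class_id < 0:
            raise ValueError("class_id must be non-negative")


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of the synthetic corpus and its preprocessing pipeline.

    Defaults reproduce the audio pipeline of the experiment: 1-second clips
    at 22050 samples/s converted to 128-band Mel power spectrograms with
    n_fft=2048 and hop=512 (centered frames), giving 128x44 matrices, and a
    20% stratified validation split.
    """

    n_image_classes: int = 30
    n_sound_classes: int = 30
    samples_per_class: int = 200
    val_fraction: float = 0.2
    duration_s: float = 1.0
    sample_rate: int = 22050
    n_mels: int = 128
    n_fft: int = 2048
    hop: int = 512
    image_noise: float = 0.05
    sound_noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        for name in ("n_image_classes", "n_sound_classes", "samples_per_class",
                     "sample_rate", "n_mels", "n_fft", "hop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CorpusConfig":
        return cls(**json.loads(text))

    def with_(self, **kw) -> "CorpusConfig":
        return replace(self, **kw)


class SampleSet:
    """A column-oriented collection of :class:`ModalitySample`.

    Stores pixels ``(n, 28, 28)``, modality tags ``(n,)`` in {+1, -1} and
    integer labels ``(n,)`` as arrays for efficient batched access.
    """

    def __init__(self, pixels: np.ndarray, modality: np.ndarray, labels: np.ndarray):
        pixels = np.asarray(pixels, dtype=np.float32)
        modality = np.asarray(modality, dtype=np.int8)
        labels = np.asarray(labels, dtype=np.int64)
        if not (len(pixels) == len(modality) == len(labels)):
            raise ValueError("pixels, modality and labels must have equal length")
        self.pixels = pixels
        self.modality = modality
        self.labels = labels

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> ModalitySample:
        return ModalitySample(self.pixels[i], int(self.modality[i]), int(self.labels[i]))

    def __iter__(self) -> Iterator[ModalitySample]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, idx: np.ndarray) -> "SampleSet":
        return SampleSet(self.pixels[idx], self.modality[idx], self.labels[idx])

    @staticmethod
    def concatenate(parts: list["SampleSet"]) -> "SampleSet":
        return SampleSet(
            np.concatenate([p.pixels for p in parts]),
            np.concatenate([p.modality for p in parts]),
            np.concatenate([p.labels for p in parts]),
        )


@dataclass
class BimodalDataset:
    """Train/validation partitions of a combined image+sound task."""

    train: SampleSet
    validation: SampleSet
    n_labels: int
    task: str  # "entity" | "concept"
    pair_map: dict[int, int] | None = None  # sound class -> image class (concept)
    config: CorpusConfig | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# synthetic generators


def synth_image(class_id: int, cfg: CorpusConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one 28x28 synthetic image for ``class_id``.

    Each class has a deterministic template — an oriented sinusoidal grating
    whose orientation and spatial frequency index the class, plus a Gaussian
    blob whose position also indexes the class — overlaid with additive
    Gaussian pixel noise of standard deviation ``cfg.image_noise``.  Output
    values are clipped to [0, 1].
    """
    if not (0 <= class_id < cfg.n_image_classes):
        raise ValueError(
            f"class_id {class_id} out of range [0, {cfg.n_image_classes})")
    tmpl = _image_template(class_id, cfg.n_image_classes)
    if cfg.image_noise > 0:
        tmpl = tmpl + rng.normal(0.0, cfg.image_noise, size=tmpl.shape)
    return np.clip(tmpl, 0.0, 1.0)


def _image_template(class_id: int, n_classes: int) -> np.ndarray:
    h, w = IMAGE_SHAPE
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.pi * class_id / max(n_classes, 1)
    freq = 1.5 + (class_id % 5)  # cycles across the image
    u = (xx * np.cos(theta) + yy * np.sin(theta)) / w
    grating = 0.5 + 0.45 * np.cos(2.0 * np.pi * freq * u)
    # class-indexed blob breaks the grating's translational symmetry
    cy = 6 + 16 * ((class_id * 7) % n_classes) / max(n_classes - 1, 1)
    cx = 6 + 16 * ((class_id * 3) % n_classes) / max(n_classes - 1, 1)
    blob = 0.35 * np.exp(-(((yy - cy) ** 2) + ((xx - cx) ** 2)) / (2 * 3.0**2))
    return np.clip(grating * 0.8 + blob, 0.0, 1.0)


def synth_waveform(class_id: int, cfg: CorpusConfig, rng: np.random.Generator) -> Waveform:
    """Draw one 1-second waveform for ``class_id``.

    Classes are harmonic stacks: class ``c`` has fundamental
    ``f0 = 200 + 120 c`` Hz with partials at 1x, 2x, 3x (amplitudes 1, 0.5,
    0.25), so the dominant spectral peak is class-distinct.  Additive
    Gaussian noise of standard deviation ``cfg.sound_noise`` is applied and
    amplitudes are clipped to [-1, 1].
    """
    if not (0 <= class_id < cfg.n_sound_classes):
        raise ValueError(
            f"class_id {class_id} out of range [0, {cfg.n_sound_classes})")
    n = int(round(cfg.duration_s * cfg.sample_rate))
    t = np.arange(n, dtype=np.float64) / cfg.sample_rate
    f0 = 200.0 + 120.0 * class_id
    s = np.zeros(n)
    for h, amp in ((1, 1.0), (2, 0.5), (3, 0.25)):
        s += amp * np.sin(2.0 * np.pi * h * f0 * t)
    s *= 0.9 / np.max(np.abs(s))
    if cfg.sound_noise > 0:
        s = s + rng.normal(0.0, cfg.sound_noise, size=n)
    return Waveform(np.clip(s, -1.0, 1.0), cfg.sample_rate)


# ---------------------------------------------------------------------------
# sound -> image pipeline


def _hann(n: int) -> np.ndarray:
    # periodic Hann window, the convention used for spectrogram analysis
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)


def _mel_filterbank(sr: int, n_fft: int, n_mels: int) -> np.ndarray:
    """Triangular Mel filterbank (HTK mel scale) on the rfft bin centres."""
    fmax = sr / 2.0
    mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)  # noqa: E731
    imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)  # noqa: E731
    pts = imel(np.linspace(0.0, mel(fmax), n_mels + 2))
    freqs = np.linspace(0.0, fmax, n_fft // 2 + 1)
    fb = np.zeros((n_mels, len(freqs)))
    for m in range(n_mels):
        lo, ctr, hi = pts[m], pts[m + 1], pts[m + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_spectrogram(w: Waveform, cfg: CorpusConfig) -> np.ndarray:
    """Mel power spectrogram of a clip, shape ``(cfg.n_mels, T)``.

    The clip is first fixed to ``cfg.duration_s`` (zero-pad / truncate), then
    analysed with centered Hann-windowed frames of ``cfg.n_fft`` samples at
    stride ``cfg.hop``: ``T = floor(n / hop) + 1``.  For the defaults
    (22050 samples, n_mels=128, hop=512) the result is 128x44.
    """
    if len(w) == 0:
        raise ValueError("cannot compute a spectrogram of an empty waveform")
    if w.rate != cfg.sample_rate:
        raise ValueError(
            f"waveform rate {w.rate} != configured rate {cfg.sample_rate}")
    s = w.fixed_length(cfg.duration_s).samples
    n = len(s)
    pad = cfg.n_fft // 2
    padded = np.pad(s, (pad, pad))
    n_frames = n // cfg.hop + 1
    idx = np.arange(cfg.n_fft)[None, :] + cfg.hop * np.arange(n_frames)[:, None]
    frames = padded[idx] * _hann(cfg.n_fft)
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2  # (T, n_fft//2+1)
    fb = _mel_filterbank(cfg.sample_rate, cfg.n_fft, cfg.n_mels)
    return fb @ power.T  # (n_mels, T)


def pool_to_emnist_shape(spec: np.ndarray) -> np.ndarray:
    """Reduce a 128x44 spectrogram to 28x28 by zero-pad + max pooling.

    Zero rows are appended below and zero columns to the right to reach
    140x56, then non-overlapping 5x2 max pooling yields 28x28.  The global
    maximum is preserved and every output value comes from its input block.
    """
    spec = np.asarray(spec)
    if spec.shape != MEL_SHAPE:
        raise ValueError(f"expected shape {MEL_SHAPE}, got {spec.shape}")
    ph, pw = PAD_SHAPE
    padded = np.zeros(PAD_SHAPE, dtype=spec.dtype)
    padded[: spec.shape[0], : spec.shape[1]] = spec
    kh, kw = POOL_SIZE
    return padded.reshape(ph // kh, kh, pw // kw, kw).max(axis=(1, 3))


def sound_to_image(w: Waveform, cfg: CorpusConfig) -> np.ndarray:
    """Full sound-side pipeline: Mel spectrogram then pad/pool to 28x28."""
    return pool_to_emnist_shape(mel_spectrogram(w, cfg))


# ---------------------------------------------------------------------------
# normalization


class MinMaxNormalizer:
    """Affine [0, 1] rescaling fit on a training collection.

    The same affine map is reused on validation data; mapped values outside
    [0, 1] (possible when validation exceeds the training range) are clipped.
    """

    def __init__(self) -> None:
        self.lo: float | None = None
        self.hi: float | None = None

    def fit(self, samples: np.ndarray) -> "MinMaxNormalizer":
        samples = np.asarray(samples)
        if samples.size == 0:
            raise ValueError("cannot fit a normalizer on an empty collection")
        self.lo = float(samples.min())
        self.hi = float(samples.max())
        if self.hi == self.lo:
            warnings.warn(
                "constant-valued collection: min == max, mapping to zeros",
                stacklevel=2)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise RuntimeError("normalizer must be fit before transform")
        x = np.asarray(x, dtype=np.float64)
        if self.hi == self.lo:
            return np.zeros_like(x)
        return np.clip((x - self.lo) / (self.hi - self.lo), 0.0, 1.0)


def normalize(samples: np.ndarray) -> np.ndarray:
    """Min-max rescale a collection of matrices to [0, 1] (fit on itself)."""
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("cannot normalize an empty collection")
    return MinMaxNormalizer().fit(samples).transform(samples)


# ---------------------------------------------------------------------------
# assembly


def _generate_modality(cfg: CorpusConfig, modality: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Raw (un-normalized) stacked matrices and class ids for one modality."""
    if modality == MODALITY_IMAGE:
        n_classes = cfg.n_image_classes
        make = lambda c: synth_image(c, cfg, rng)  # noqa: E731
    else:
        n_classes = cfg.n_sound_classes
        make = lambda c: sound_to_image(synth_waveform(c, cfg, rng), cfg)  # noqa: E731
    mats = np.empty((n_classes * cfg.samples_per_class, *IMAGE_SHAPE), dtype=np.float64)
    classes = np.empty(n_classes * cfg.samples_per_class, dtype=np.int64)
    k = 0
    for c in range(n_classes):
        for _ in range(cfg.samples_per_class):
            mats[k] = make(c)
            classes[k] = c
            k += 1
    return mats, classes


def _assemble(cfg: CorpusConfig, task: str) -> BimodalDataset:
    if task == "concept" and cfg.n_image_classes != cfg.n_sound_classes:
        raise ValueError(
            "concept assembly requires equal image and sound class counts")
    root = np.random.default_rng(cfg.seed)
    rng_img, rng_snd, rng_split = root.spawn(3)

    parts = {"train": [], "val": []}
    pair_map = None
    for modality, rng in ((MODALITY_IMAGE, rng_img), (MODALITY_SOUND, rng_snd)):
        mats, classes = _generate_modality(cfg, modality, rng)
        if task == "entity":
            labels = classes if modality == MODALITY_IMAGE \
                else classes + cfg.n_image_classes
        else:
            # pair sorted class lists by index: sound class c <-> image class c
            labels = classes
        ss = SampleSet(mats, np.full(len(mats), modality), labels)
        train, val = split_validation(ss, cfg.val_fraction, rng_split)
        # fit per-modality min-max on the training partition only
        norm = MinMaxNormalizer().fit(train.pixels)
        parts["train"].append(SampleSet(norm.transform(train.pixels),
                                        train.modality, train.labels))
        parts["val"].append(SampleSet(norm.transform(val.pixels),
                                      val.modality, val.labels))
    if task == "entity":
        n_labels = cfg.n_image_classes + cfg.n_sound_classes
    else:
        n_labels = cfg.n_image_classes
        pair_map = {c: c for c in range(cfg.n_sound_classes)}
    return BimodalDataset(
        train=SampleSet.concatenate(parts["train"]),
        validation=SampleSet.concatenate(parts["val"]),
        n_labels=n_labels, task=task, pair_map=pair_map, config=cfg)


def assemble_entity(cfg: CorpusConfig) -> BimodalDataset:
    """Entity task: image classes and sound classes are distinct labels.

    Image classes keep labels ``0 .. n_image-1``; sound classes are shifted
    to ``n_image .. n_image+n_sound-1``, so the label spaces are disjoint.
    """
    return _assemble(cfg, "entity")


def assemble_concept(cfg: CorpusConfig) -> BimodalDataset:
    """Concept task: image class c and sound class c share label c."""
    return _assemble(cfg, "concept")


def split_validation(samples: SampleSet, fraction: float,
                     rng: np.random.Generator) -> tuple[SampleSet, SampleSet]:
    """Stratified train/validation split; disjoint and covering the input."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    val_idx = []
    for c in np.unique(samples.labels):
        idx = np.flatnonzero(samples.labels == c)
        n_val = int(round(fraction * len(idx)))
        val_idx.append(rng.choice(idx, size=n_val, replace=False))
    val_idx = np.sort(np.concatenate(val_idx)) if val_idx else np.array([], int)
    mask = np.zeros(len(samples), dtype=bool)
    mask[val_idx] = True
    return samples.subset(~mask), samples.subset(mask)


def sample_batch(ds: BimodalDataset, batch_size: int,
                 rng: np.random.Generator) -> SampleSet:
    """Draw a training batch, sampling uniformly between the modalities.

    Each element is drawn by a fair coin on modality, then uniformly within
    the chosen modality's training pool.
    """
    train = ds.train
    img_pool = np.flatnonzero(train.modality == MODALITY_IMAGE)
    snd_pool = np.flatnonzero(train.modality == MODALITY_SOUND)
    if len(img_pool) == 0 or len(snd_pool) == 0:
        raise ValueError("both modalities must be present in the training set")
    coins = rng.random(batch_size) < 0.5  # True -> sound
    idx = np.where(coins,
                   snd_pool[rng.integers(0, len(snd_pool), size=batch_size)],
                   img_pool[rng.integers(0, len(img_pool), size=batch_size)])
    return train.subset(idx)
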