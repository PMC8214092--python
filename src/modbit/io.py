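"""Optional real-data readers and corpus export/import.

The synthetic corpus is the default data source; these helpers let the same
pipeline run on the real datasets the experiment used — EMNIST balanced
(IDX format, first 30 classes) and Speech Commands (16-bit PCM WAV at
16 kHz, resampled to 22050 samples/s on load) — and persist an assembled
corpus as a compressed archive of matrices plus a JSON manifest.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .corpus import BimodalDataset, CorpusConfig, SampleSet, Waveform

__all__ = ["read_idx", "load_emnist_images", "load_emnist_labels",
           "load_speech_commands_wav", "save_corpus", "load_corpus"]

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.dtype(">i2"),
               0x0C: np.dtype(">i4"), 0x0D: np.dtype(">f4"),
               0x0E: np.dtype(">f8")}


def read_idx(path: str | Path) -> np.ndarray:
    """Read one IDX-format array (optionally gzip-compressed)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        data = fh.read()
    if data[0] != 0 or data[1] != 0:
        raise ValueError("not an IDX file: bad magic prefix")
    dtype, ndim = _IDX_DTYPES[data[2]], data[3]
    shape = tuple(int.from_bytes(data[4 + 4 * i: 8 + 4 * i], "big")
                  for i in range(ndim))
    arr = np.frombuffer(data, dtype=dtype, offset=4 + 4 * ndim)
    return arr.reshape(shape)


def load_emnist_images(path: str | Path, n_classes: int = 30,
                       labels_path: str | Path | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Load EMNIST images/labels, keeping only the first ``n_classes``.

    EMNIST images are stored transposed relative to the usual orientation;
    they are transposed back here.  Pixel values are scaled to [0, 1].
    """
    images = read_idx(path).astype(np.float64) / 255.0
    if labels_path is None:
        raise ValueError("labels_path is required to filter classes")
    labels = load_emnist_labels(labels_path)
    keep = labels < n_classes
    return images[keep].transpose(0, 2, 1), labels[keep].astype(np.int64)


def load_emnist_labels(path: str | Path) -> np.ndarray:
    return read_idx(path).astype(np.int64)


def load_speech_commands_wav(path: str | Path,
                             target_rate: int = 22050) -> Waveform:
    """Load one Speech Commands clip and resample it to ``target_rate``."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    if rate != target_rate:
        from math import gcd
        g = gcd(target_rate, rate)
        data = resample_poly(data, target_rate // g, rate // g)
    return Waveform(data, target_rate)


def save_corpus(ds: BimodalDataset, path: str | Path) -> None:
    """Persist a dataset as a compressed npz + JSON manifest sidecar."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        train_pixels=ds.train.pixels, train_modality=ds.train.modality,
        train_labels=ds.train.labels,
        val_pixels=ds.validation.pixels, val_modality=ds.validation.modality,
        val_labels=ds.validation.labels)
    manifest = {
        "n_labels": ds.n_labels,
        "task": ds.task,
        "pair_map": ds.pair_map,
        "config": None if ds.config is None else json.loads(ds.config.to_json()),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_corpus(path: str | Path) -> BimodalDataset:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    pair_map = manifest["pair_map"]
    if pair_map is not None:
        pair_map = {int(k): int(v) for k, v in pair_map.items()}
    cfg = manifest["config"]
    return BimodalDataset(
        train=SampleSet(arrays["train_pixels"], arrays["train_modality"],
                        arrays["train_labels"]),
        validation=SampleSet(arrays["val_pixels"], arrays["val_modality"],
                             arrays["val_labels"]),
        n_labels=int(manifest["n_labels"]), task=manifest["task"],
        pair_map=pair_map,
        config=None if cfg is None else CorpusConfig(**cfg))
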