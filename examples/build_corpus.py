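"""Build a small synthetic bimodal corpus and inspect its structure.

Sounds are 1-second harmonic stacks at 22050 samples/s, rendered to the
image format via a 128x44 Mel power spectrogram, zero-padding to 140x56 and
5x2 max pooling down to 28x28 — the same shape as the image samples.
"""

import numpy as np

import modbit as mb

cfg = mb.CorpusConfig(n_image_classes=4, n_sound_classes=4,
                      samples_per_class=50, seed=0)

w = mb.synth_waveform(0, cfg, np.random.default_rng(0))
spec = mb.mel_spectrogram(w, cfg)
img = mb.pool_to_emnist_shape(spec)
print(f"waveform: {len(w)} samples at {w.rate}/s")
print(f"mel spectrogram: {spec.shape[0]}x{spec.shape[1]}")
print(f"pooled sound image: {img.shape[0]}x{img.shape[1]}")

entity = mb.assemble_entity(cfg)
concept = mb.assemble_concept(cfg)
print(f"entity task: {entity.n_labels} labels "
      f"({cfg.n_image_classes} image + {cfg.n_sound_classes} sound), "
      f"{len(entity.train)} train / {len(entity.validation)} validation")
print(f"concept task: {concept.n_labels} labels, pair map {concept.pair_map}")

batch = mb.sample_batch(entity, 32, np.random.default_rng(1))
frac = np.mean(batch.modality == mb.MODALITY_SOUND)
print(f"one batch of 32: {100 * frac:.0f}% sound "
      f"(each element drawn by a fair modality coin)")
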