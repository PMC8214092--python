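"""Run a desk-scale version of the four-variant Entity condition.

Pretrains and freezes a baseline + probe, then trains all four variants
(baseline, experimental with the decoded +-1 bit, expanded-base and
constant-input controls) for a few epochs each, and reports every variant's
mean minimum validation loss with a 95% confidence interval and mean
epochs-to-minimum.  At this scale no direction between variants is asserted
— the run illustrates the full pipeline, not the full-scale effect.
"""

import numpy as np

import modbit as mb

corpus_cfg = mb.CorpusConfig(n_image_classes=4, n_sound_classes=4,
                             samples_per_class=60, seed=0)
train_cfg = mb.TrainingConfig(batch_size=32, epochs=4, steps_per_epoch=25,
                              runs=3, max_pretrain_epochs=5, seed=2024)

result = mb.run_condition(mb.condition_spec(1), corpus_cfg, train_cfg,
                          out_dir="scratch/condition1_desk")

print(f"condition 1, {train_cfg.runs} runs x {train_cfg.epochs} epochs "
      f"x {train_cfg.steps_per_epoch} steps (seed {train_cfg.seed})")
for variant, summaries in result.summaries.items():
    losses = np.array([s.min_val_loss for s in summaries])
    epochs = np.array([s.epoch_of_min for s in summaries])
    half = 1.96 * losses.std(ddof=1) / np.sqrt(len(losses))
    print(f"  {variant:14s} min val loss {losses.mean():.3f} "
          f"+- {half:.3f} (95% CI), epochs-to-min {epochs.mean():.1f}")
print("(the +- band is a normal-approximation CI over runs; with this few "
      "runs and epochs, overlapping bands are expected)")
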