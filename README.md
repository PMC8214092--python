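# modbit

Bimodal CNN classification with Hebbian modality probes and 1-bit
"experience" injection.

modbit is a desk-scale laboratory for a question from synthetic
phenomenology: if a network that classifies both images and sounds is
given an explicit, self-generated representation of *which sense* its
current input came from, does that help it learn?  The package

- builds a synthetic bimodal corpus — 28×28 image classes plus 1-second
  sound classes rendered to the same 28×28 format via a 128×44 Mel power
  spectrogram, zero-padding to 140×56 and 5×2 max pooling;
- trains convolutional classifiers on the combined data in two framings
  (*Entity*: image and sound classes are separate labels; *Concept*: each
  image class shares a label with a paired sound class);
- attaches **Hebbian probes** to the dense hidden layers: bias-free linear
  decoders trained with the plain Hebb rule Δw = η·y·x̄ on sign-binarized
  pre-activations x̄ ∈ {±1}ⁿ to predict the modality y ∈ {+1 sound,
  −1 image}, without ever touching the host network;
- freezes the classifier and its best probe once that probe exceeds 99%
  validation accuracy, then feeds the decoded ±1 bit to a second
  classifier as one extra dense-stage input, alongside two controls
  (expanded base and constant input) that match parameters but add no
  information;
- compares per-run outcomes (minimum validation loss, epochs-to-minimum)
  with Kruskal–Wallis, Conover–Iman + Holm, and Mann–Whitney U.

Everything is deterministic numpy given a seed, including the CNN training
stack.  See `docs/methods.md` for the model, conventions and limitations.

## Worked example

`examples/probe_decoding.py` trains the Entity baseline for one short
epoch on a 4+4-class corpus while two probes watch its dense layers:

```
probe on dense layer 1 (512 units): 100.0% validation accuracy
probe on dense layer 2 (288 units): 100.0%
freeze criterion met after 1 epoch(s); frozen probe reads layer 1
decoded +-1 bit matches the true modality for 100.0% of validation samples (+1 = sound, -1 = image)
```

The classifier was never told which inputs were sounds, yet a linear
Hebbian decoder reads the modality perfectly from its hidden
pre-activations — the "emergent symbol of experience" the experiment then
injects.  `examples/run_condition_desk.py` runs all four variants at desk
scale (3 runs × 4 epochs × 25 steps):

```
condition 1, 3 runs x 4 epochs x 25 steps (seed 2024)
  baseline       min val loss 0.576 +- 0.033 (95% CI), epochs-to-min 4.0
  experimental   min val loss 0.327 +- 0.013 (95% CI), epochs-to-min 4.0
  expanded_base  min val loss 0.587 +- 0.071 (95% CI), epochs-to-min 4.0
  constant_input min val loss 0.550 +- 0.084 (95% CI), epochs-to-min 4.0
```

Here the bit-fed experimental model reaches a visibly lower validation
loss while both parameter-matched controls track the baseline; at this
scale that is an illustration, not a tested claim — the effect is known
to be architecture- and data-dependent.  `examples/build_corpus.py` and
`examples/stats_battery.py` walk the corpus pipeline and the statistics.

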