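"""Experiment orchestration: baseline pretraining with probes, the probe
freeze criterion, experimental/control training, and the four conditions.

The protocol mirrors the source experiment: each training run draws batches
of 128 examples (fair coin between modalities), optimizes sparse categorical
cross-entropy with Adam at learning rate 5e-4, and lasts ``epochs`` epochs
of ``steps_per_epoch`` steps.  During baseline training, Hebbian probes on
both dense hidden layers are reset at every epoch start, updated each step
from the binarized pre-activations, and evaluated on the validation set at
epoch end.  Baselines are pretrained until some probe exceeds the 99%
validation-accuracy freeze criterion; then the baseline and the more
accurate probe are frozen and supply the +-1 modality bit that the
experimental variant receives as an extra dense-stage input.

Condition table (dataset / architectures / variants):

    1  entity  / entity  / baseline, experimental, expanded_base, constant_input
    2  concept / concept / baseline, experimental
    3  entity  / concept / baseline, experimental
    4  concept / entity  / baseline, experimental

If the freeze criterion fails for a condition's own baseline (the
condition-4 situation), a donor baseline whose architecture matches the
dataset's task is pretrained and its frozen probe is used instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import BimodalDataset, CorpusConfig, assemble_concept, assemble_entity, sample_batch
from .models import CONCEPT_SPEC, ENTITY_SPEC, ArchitectureSpec, ConvClassifier, ModelVariant, build
from .nn import Adam
from .probe import HebbianProbe, binarize, probe_accuracy

__all__ = [
    "TrainingConfig", "ConditionSpec", "EpochRecord", "RunRecord",
    "RunSummary", "ConditionResult", "FrozenPair", "CriterionNotMet",
    "train_epoch", "train_run", "pretrain_and_freeze", "train_experimental",
    "run_condition", "condition_spec", "summarize_run",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol parameters (defaults are the full protocol)."""

    learning_rate: float = 0.0005
    batch_size: int = 128
    epochs: int = 500
    steps_per_epoch: int = 1000
    runs: int = 30
    freeze_threshold: float = 0.99
    max_pretrain_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "epochs", "runs",
                     "freeze_threshold", "max_pretrain_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.steps_per_epoch < 0:
            raise ValueError("steps_per_epoch must be non-negative")


_CONDITIONS = {
    1: ("entity", "entity",
        (ModelVariant.BASELINE, ModelVariant.EXPERIMENTAL,
         ModelVariant.EXPANDED_BASE, ModelVariant.CONSTANT_INPUT)),
    2: ("concept", "concept", (ModelVariant.BASELINE, ModelVariant.EXPERIMENTAL)),
    3: ("entity", "concept", (ModelVariant.BASELINE, ModelVariant.EXPERIMENTAL)),
    4: ("concept", "entity", (ModelVariant.BASELINE, ModelVariant.EXPERIMENTAL)),
}


@dataclass(frozen=True)
class ConditionSpec:
    condition_id: int
    dataset: str       # task used to assemble the data
    model_spec: str    # architecture family
    variants: tuple[ModelVariant, ...]


def condition_spec(condition_id: int) -> ConditionSpec:
    if condition_id not in _CONDITIONS:
        raise ValueError("condition_id must be in {1, 2, 3, 4}")
    ds, ms, variants = _CONDITIONS[condition_id]
    return ConditionSpec(condition_id, ds, ms, variants)


@dataclass
class EpochRecord:
    train_loss: float
    train_acc: float
    val_loss: float
    val_acc: float
    probe_val_acc: tuple[float, float] | None = None


@dataclass
class RunRecord:
    epochs: list[EpochRecord] = field(default_factory=list)

    def val_losses(self) -> np.ndarray:
        return np.array([e.val_loss for e in self.epochs])

    def to_frame(self, **ids) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.epochs, start=1):
            row = dict(ids, epoch=i, train_loss=e.train_loss,
                       train_acc=e.train_acc, val_loss=e.val_loss,
                       val_acc=e.val_acc)
            if e.probe_val_acc is not None:
                row["probe1_acc"], row["probe2_acc"] = e.probe_val_acc
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RunSummary:
    min_val_loss: float
    epoch_of_min: int  # 1-based, first occurrence


def summarize_run(record: RunRecord) -> RunSummary:
    """Minimum validation loss and its 1-based first-occurrence epoch."""
    losses = record.val_losses()
    if len(losses) == 0:
        raise ValueError("run record has no epochs")
    i = int(np.argmin(losses))
    return RunSummary(float(losses[i]), i + 1)


@dataclass
class ConditionResult:
    condition_id: int
    summaries: dict[str, list[RunSummary]]
    pretrain_epochs: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "condition": self.condition_id,
            "pretrain_epochs": self.pretrain_epochs,
            "variants": {
                v: [{"min_val_loss": s.min_val_loss,
                     "epoch_of_min": s.epoch_of_min} for s in ss]
                for v, ss in self.summaries.items()
            },
        }
        return json.dumps(payload, indent=2)

    def losses(self, variant: str) -> list[float]:
        return [s.min_val_loss for s in self.summaries[variant]]

    def epochs_to_min(self, variant: str) -> list[int]:
        return [s.epoch_of_min for s in self.summaries[variant]]


class CriterionNotMet(RuntimeError):
    """Raised when no probe exceeds the freeze threshold in time.

    Carries each probe's best validation accuracy so the caller can decide
    on the donor fallback.
    """

    def __init__(self, best_accuracies: tuple[float, float]):
        self.best_accuracies = best_accuracies
        super().__init__(
            f"no probe exceeded the freeze criterion; best accuracies "
            f"{best_accuracies}")


@dataclass
class FrozenPair:
    """A frozen pretrained baseline plus its frozen Hebbian probe."""

    model: ConvClassifier
    probe: HebbianProbe
    layer_index: int  # 1-based tap index the probe is attached to
    pretrain_epochs: int

    def bits_for(self, pixels: np.ndarray) -> np.ndarray:
        """Decode the +-1 modality bit for a batch of inputs."""
        _, taps = self.model.forward_taps(pixels)
        z = taps[self.layer_index - 1]
        return self.probe.predict_batch(binarize(z))


# ---------------------------------------------------------------------------
# training loops


def _check_labels(model: ConvClassifier, ds: BimodalDataset) -> None:
    if model.n_outputs != ds.n_labels:
        raise ValueError(
            f"model has {model.n_outputs} outputs but dataset has "
            f"{ds.n_labels} labels")


def _bits_or_none(model: ConvClassifier, frozen: FrozenPair | None,
                  pixels: np.ndarray) -> np.ndarray | None:
    if model.variant == ModelVariant.EXPERIMENTAL:
        if frozen is None:
            raise ValueError("experimental variant needs a frozen donor pair")
        return frozen.bits_for(pixels)
    return None  # constant_input supplies its own 1s; others take no bit


def train_epoch(model: ConvClassifier, dataset: BimodalDataset,
                cfg: TrainingConfig, rng: np.random.Generator,
                optimizer: Adam, probes: list[HebbianProbe] | None = None,
                frozen: FrozenPair | None = None) -> EpochRecord:
    """One epoch: ``cfg.steps_per_epoch`` optimizer steps plus validation.

    If ``probes`` are attached (baseline pretraining), they are reset at
    epoch start and updated each step from the binarized dense pre-activations
    and the batch's +-1 modality tags; the host's weights are unaffected by
    those updates.  If the model is the experimental variant, ``frozen``
    supplies the decoded modality bit per example.
    """
    _check_labels(model, dataset)
    if probes is not None:
        for p in probes:
            p.reset()
    step_losses, step_accs = [], []
    for _ in range(cfg.steps_per_epoch):
        batch = sample_batch(dataset, cfg.batch_size, rng)
        bits = _bits_or_none(model, frozen, batch.pixels)
        loss, acc, taps = model.train_step(batch.pixels, batch.labels,
                                           optimizer, bits)
        step_losses.append(loss)
        step_accs.append(acc)
        if probes is not None:
            for p, z in zip(probes, taps):
                p.update_batch(binarize(z), batch.modality)
    val = dataset.validation
    val_bits = _bits_or_none(model, frozen, val.pixels)
    val_loss, val_acc = model.evaluate(val.pixels, val.labels, val_bits)
    probe_acc = None
    if probes is not None:
        _, taps = model.forward_taps(val.pixels)
        probe_acc = tuple(probe_accuracy(p, z, val.modality)
                          for p, z in zip(probes, taps))
    train_loss = float(np.mean(step_losses)) if step_losses else val_loss
    train_acc = float(np.mean(step_accs)) if step_accs else val_acc
    return EpochRecord(train_loss, train_acc, val_loss, val_acc, probe_acc)


def train_run(model: ConvClassifier, dataset: BimodalDataset,
              cfg: TrainingConfig, rng: np.random.Generator,
              probes: list[HebbianProbe] | None = None,
              frozen: FrozenPair | None = None) -> RunRecord:
    """A full training run of ``cfg.epochs`` epochs."""
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    record = RunRecord()
    for _ in range(cfg.epochs):
        record.epochs.append(
            train_epoch(model, dataset, cfg, rng, opt, probes, frozen))
    return record


def pretrain_and_freeze(model: ConvClassifier, dataset: BimodalDataset,
                        cfg: TrainingConfig, rng: np.random.Generator
                        ) -> tuple[FrozenPair, RunRecord]:
    """Pretrain a baseline until a probe beats the freeze criterion.

    Probes are attached to both dense hidden layers.  After each epoch the
    probes' validation accuracies are checked; once one exceeds
    ``cfg.freeze_threshold`` the baseline and the more accurate probe (ties
    favour layer 1) are frozen copies.  Raises :class:`CriterionNotMet`
    after ``cfg.max_pretrain_epochs`` epochs without success.
    """
    if model.variant != ModelVariant.BASELINE:
        raise ValueError("pretraining expects the baseline variant")
    probes = [HebbianProbe(w) for w in model.tap_widths]
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    record = RunRecord()
    best = [0.0, 0.0]
    for epoch in range(1, cfg.max_pretrain_epochs + 1):
        rec = train_epoch(model, dataset, cfg, rng, opt, probes)
        record.epochs.append(rec)
        accs = rec.probe_val_acc
        best = [max(b, a) for b, a in zip(best, accs)]
        if max(accs) > cfg.freeze_threshold:
            chosen = int(np.argmax(accs))  # tie -> first (layer 1)
            frozen_model = model.copy().freeze()
            frozen_probe = probes[chosen].copy()
            frozen_probe.frozen = True
            return (FrozenPair(frozen_model, frozen_probe, chosen + 1, epoch),
                    record)
    raise CriterionNotMet(tuple(best))


def train_experimental(frozen: FrozenPair, model: ConvClassifier,
                       dataset: BimodalDataset, cfg: TrainingConfig,
                       rng: np.random.Generator) -> RunRecord:
    """Train an experimental-variant model fed by a frozen baseline+probe."""
    if frozen.model.trainable or not frozen.probe.frozen:
        raise ValueError("donor pair must be frozen")
    return train_run(model, dataset, cfg, rng, frozen=frozen)


# ---------------------------------------------------------------------------
# conditions


_ARCHS: dict[str, ArchitectureSpec] = {"entity": ENTITY_SPEC,
                                       "concept": CONCEPT_SPEC}
_ASSEMBLE = {"entity": assemble_entity, "concept": assemble_concept}


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_condition(spec: ConditionSpec, corpus_cfg: CorpusConfig,
                  cfg: TrainingConfig, out_dir: str | Path | None = None
                  ) -> ConditionResult:
    """Execute one condition: ``cfg.runs`` repetitions of every variant.

    Each run derives independent seeded streams for corpus assembly, weight
    initialization and batch sampling from the master seed, pretrains and
    freezes a baseline (with the dataset-task-matched donor fallback if the
    criterion is not met), trains each variant, and records the minimum
    validation loss and its epoch.  Per-epoch metrics are written as CSV and
    the summary as JSON when ``out_dir`` is given.
    """
    master = np.random.SeedSequence(cfg.seed)
    arch = _ARCHS[spec.model_spec]
    summaries: dict[str, list[RunSummary]] = {v.value: [] for v in spec.variants}
    pretrain_epochs: list[int] = []
    frames: list[pd.DataFrame] = []

    for run_idx in range(cfg.runs):
        ss_corpus, ss_init, ss_batch, ss_donor = master.spawn(4)
        ds = _ASSEMBLE[spec.dataset](
            corpus_cfg.with_(seed=_derive_seed(ss_corpus)))
        init_rng = np.random.default_rng(ss_init)
        batch_rng = np.random.default_rng(ss_batch)

        base = build(arch, ModelVariant.BASELINE, ds.n_labels, init_rng)
        try:
            frozen, pre_rec = pretrain_and_freeze(
                base, ds, cfg, np.random.default_rng(ss_batch.spawn(1)[0]))
        except CriterionNotMet:
            # donor: baseline whose architecture matches the dataset's task
            donor_arch = _ARCHS[spec.dataset]
            donor = build(donor_arch, ModelVariant.BASELINE, ds.n_labels,
                          np.random.default_rng(ss_donor))
            frozen, pre_rec = pretrain_and_freeze(
                donor, ds, cfg, np.random.default_rng(ss_donor.spawn(1)[0]))
        pretrain_epochs.append(frozen.pretrain_epochs)

        for variant in spec.variants:
            model = build(arch, variant, ds.n_labels,
                          np.random.default_rng(ss_init.spawn(1)[0]))
            rng = np.random.default_rng(ss_batch.spawn(1)[0])
            rec = train_run(model, ds, cfg, rng,
                            frozen=frozen if variant == ModelVariant.EXPERIMENTAL
                            else None)
            summaries[variant.value].append(summarize_run(rec))
            frames.append(rec.to_frame(run=run_idx, variant=variant.value))

    result = ConditionResult(spec.condition_id, summaries, pretrain_epochs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"condition{spec.condition_id}_metrics.csv", index=False)
        (out / f"condition{spec.condition_id}_summary.json").write_text(
            result.to_json())
    return result
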