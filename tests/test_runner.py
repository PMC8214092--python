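"""Experiment orchestration: epochs, freeze criterion, frozen immutability,
condition execution and summaries."""

import numpy as np
import pytest

import modbit as mb
from modbit.models import _arch
from modbit.nn import Adam
from modbit.runner import _CONDITIONS

# final conv stage is tanh (centered) so that pre-activation sign patterns
# vary across inputs even at this small width, keeping the corpus decodable
SMALL_SPEC = _arch("small", [(4, "relu"), (4, "tanh"), (4, "tanh")],
                   [(16, "relu"), (8, "tanh")])

FAST = mb.TrainingConfig(batch_size=16, epochs=2, steps_per_epoch=5, runs=2,
                         max_pretrain_epochs=3, seed=42)


def _small_model(ds, variant="baseline", seed=0):
    return mb.build(SMALL_SPEC, variant, ds.n_labels, np.random.default_rng(seed))


class _StubTapModel:
    """Minimal model interface whose dense-1 tap copies pixel (0, 0).

    With a dataset whose pixel (0, 0) encodes the modality, the layer-1
    probe decodes perfectly; with constant taps no probe can learn.
    """

    variant = mb.ModelVariant.BASELINE
    n_outputs = 2
    tap_widths = (4, 4)
    trainable = True

    def __init__(self, constant_taps=False):
        self.constant = constant_taps

    def _taps(self, pixels):
        n = len(pixels)
        z1 = np.ones((n, 4))
        if not self.constant:
            z1 = z1 * pixels[:, 0, 0][:, None]
        return z1, np.ones((n, 4))

    def parameters(self):
        return []

    def forward_taps(self, pixels, bits=None):
        n = len(pixels)
        return np.full((n, 2), 0.5), self._taps(pixels)

    def train_step(self, pixels, labels, optimizer, bits=None):
        return 0.7, 0.5, self._taps(pixels)

    def evaluate(self, pixels, labels, bits=None, batch=512):
        return 0.7, 0.5

    def copy(self):
        return self

    def freeze(self):
        self.trainable = False
        return self


def _stub_dataset(n=40):
    rng = np.random.default_rng(0)
    modality = np.where(np.arange(n) % 2 == 0, 1, -1)
    pixels = rng.random((n, 28, 28)) * 0.5
    pixels[:, 0, 0] = modality  # stub taps read this cell
    labels = (modality > 0).astype(int)
    ss = mb.SampleSet(pixels, modality, labels)
    return mb.BimodalDataset(ss, ss, 2, "entity")


class TestConditionSpecs:
    def test_table_of_conditions(self):
        c1 = mb.condition_spec(1)
        assert (c1.dataset, c1.model_spec) == ("entity", "entity")
        assert len(c1.variants) == 4
        for cid, (ds, ms, nvar) in {2: ("concept", "concept", 2),
                                    3: ("entity", "concept", 2),
                                    4: ("concept", "entity", 2)}.items():
            spec = mb.condition_spec(cid)
            assert (spec.dataset, spec.model_spec, len(spec.variants)) == \
                (ds, ms, nvar)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            mb.condition_spec(5)


class TestSummaries:
    def _record(self, losses):
        rec = mb.RunRecord()
        for v in losses:
            rec.epochs.append(mb.EpochRecord(1.0, 0.5, v, 0.5))
        return rec

    def test_min_and_epoch(self):
        s = mb.summarize_run(self._record([0.5, 0.3, 0.4]))
        assert s.min_val_loss == 0.3 and s.epoch_of_min == 2

    def test_tie_takes_first_occurrence(self):
        s = mb.summarize_run(self._record([0.3, 0.3]))
        assert s.epoch_of_min == 1

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            mb.summarize_run(mb.RunRecord())


class TestTrainEpoch:
    def test_probe_updates_leave_host_weights_identical(self, tiny_entity):
        """Identical seeds, with and without probes: bit-identical weights."""
        states = []
        for attach in (False, True):
            m = _small_model(tiny_entity, seed=3)
            opt = Adam(m.parameters(), lr=FAST.learning_rate)
            probes = [mb.HebbianProbe(w) for w in m.tap_widths] if attach else None
            mb.train_epoch(m, tiny_entity, FAST, np.random.default_rng(11),
                           opt, probes=probes)
            states.append(m.weight_state())
        for a, b in zip(*states):
            np.testing.assert_array_equal(a, b)

    def test_probes_reset_at_epoch_start(self, tiny_entity):
        m = _small_model(tiny_entity)
        opt = Adam(m.parameters(), lr=FAST.learning_rate)
        probes = [mb.HebbianProbe(w) for w in m.tap_widths]
        probes[0].update(np.ones(16), 1)  # stale state from a previous epoch
        cfg = mb.TrainingConfig(batch_size=16, epochs=1, steps_per_epoch=3,
                                runs=1, seed=0)
        mb.train_epoch(m, tiny_entity, cfg, np.random.default_rng(0), opt,
                       probes=probes)
        # after reset + 3 steps of 16, exactly 48 updates were folded in
        assert all(p.updates_seen == 48 for p in probes)

    def test_zero_steps_keeps_model_untrained(self, tiny_entity):
        m = _small_model(tiny_entity, seed=5)
        ref_loss, ref_acc = m.evaluate(tiny_entity.validation.pixels,
                                       tiny_entity.validation.labels)
        cfg = mb.TrainingConfig(batch_size=16, epochs=1, steps_per_epoch=0,
                                runs=1, seed=0)
        opt = Adam(m.parameters(), lr=cfg.learning_rate)
        rec = mb.train_epoch(m, tiny_entity, cfg, np.random.default_rng(1), opt)
        assert rec.val_loss == ref_loss and rec.val_acc == ref_acc

    def test_label_count_mismatch_rejected(self, tiny_entity):
        m = mb.build(SMALL_SPEC, "baseline", 99, np.random.default_rng(0))
        opt = Adam(m.parameters(), lr=0.001)
        with pytest.raises(ValueError):
            mb.train_epoch(m, tiny_entity, FAST, np.random.default_rng(0), opt)


class TestPretrainAndFreeze:
    def test_perfectly_encoding_taps_freeze_after_one_epoch(self):
        ds = _stub_dataset()
        frozen, rec = mb.pretrain_and_freeze(_StubTapModel(), ds, FAST,
                                             np.random.default_rng(1))
        assert frozen.pretrain_epochs == 1
        assert frozen.layer_index == 1
        assert rec.epochs[0].probe_val_acc[0] == 1.0
        assert not frozen.model.trainable and frozen.probe.frozen

    def test_modality_independent_taps_never_meet_criterion(self):
        ds = _stub_dataset()
        with pytest.raises(mb.CriterionNotMet) as exc:
            mb.pretrain_and_freeze(_StubTapModel(constant_taps=True), ds,
                                   FAST, np.random.default_rng(1))
        assert len(exc.value.best_accuracies) == 2
        assert max(exc.value.best_accuracies) <= FAST.freeze_threshold

    def test_synthetic_separable_corpus_freezes_first_epoch(self, tiny_entity):
        cfg = mb.TrainingConfig(batch_size=32, epochs=1, steps_per_epoch=25,
                                runs=1, max_pretrain_epochs=3, seed=0)
        m = _small_model(tiny_entity, seed=1)
        frozen, _ = mb.pretrain_and_freeze(m, tiny_entity, cfg,
                                           np.random.default_rng(2))
        assert frozen.pretrain_epochs == 1

    def test_non_baseline_rejected(self, tiny_entity):
        m = _small_model(tiny_entity, variant="experimental")
        with pytest.raises(ValueError):
            mb.pretrain_and_freeze(m, tiny_entity, FAST,
                                   np.random.default_rng(0))


@pytest.fixture(scope="module")
def frozen_pair():
    ds = _stub_dataset()
    frozen, _ = mb.pretrain_and_freeze(_StubTapModel(), ds, FAST,
                                       np.random.default_rng(1))
    return frozen, ds


class TestTrainExperimental:
    def test_frozen_components_bit_identical_after_training(self, tiny_entity):
        cfg = mb.TrainingConfig(batch_size=16, epochs=1, steps_per_epoch=4,
                                runs=1, max_pretrain_epochs=3, seed=0)
        base = _small_model(tiny_entity, seed=1)
        frozen, _ = mb.pretrain_and_freeze(
            base, tiny_entity, mb.TrainingConfig(
                batch_size=32, epochs=1, steps_per_epoch=25, runs=1, seed=0),
            np.random.default_rng(2))
        w_before = frozen.model.weight_state()
        probe_before = frozen.probe.weights.copy()
        exp = _small_model(tiny_entity, variant="experimental", seed=9)
        mb.train_experimental(frozen, exp, tiny_entity, cfg,
                              np.random.default_rng(3))
        for a, b in zip(w_before, frozen.model.weight_state()):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(probe_before, frozen.probe.weights)

    def test_perfect_probe_bit_equals_modality(self, frozen_pair):
        frozen, ds = frozen_pair
        bits = frozen.bits_for(ds.train.pixels)
        np.testing.assert_array_equal(bits, ds.train.modality)

    def test_unfrozen_donor_rejected(self, tiny_entity):
        donor = _small_model(tiny_entity, seed=1)
        pair = mb.FrozenPair(donor, mb.HebbianProbe(16), 1, 1)
        exp = _small_model(tiny_entity, variant="experimental")
        with pytest.raises(ValueError):
            mb.train_experimental(pair, exp, tiny_entity, FAST,
                                  np.random.default_rng(0))

    def test_information_channel_is_one_bit(self, tiny_entity):
        """Negating the bit changes the dense-1 pre-activations and nothing
        else widens: dense-1 input is flat conv width + exactly 1."""
        exp = _small_model(tiny_entity, variant="experimental", seed=2)
        assert exp.dense1.n_in == exp.flat_width + 1
        x = tiny_entity.train.pixels[:4]
        _, (z_pos, _) = exp.forward_taps(x, bits=np.ones(4))
        _, (z_neg, _) = exp.forward_taps(x, bits=-np.ones(4))
        assert np.any(z_pos != z_neg)


@pytest.fixture(scope="module")
def result_and_dir(tmp_path_factory):
    corpus_cfg = mb.CorpusConfig(n_image_classes=2, n_sound_classes=2,
                                 samples_per_class=10, seed=1)
    cfg = mb.TrainingConfig(batch_size=16, epochs=2, steps_per_epoch=4,
                            runs=2, max_pretrain_epochs=3, seed=77)
    out = tmp_path_factory.mktemp("cond")
    # condition 2 exercises the concept path with 2 variants (fast)
    result = mb.run_condition(mb.condition_spec(2), corpus_cfg, cfg, out)
    return result, out, corpus_cfg, cfg


class TestRunCondition:
    def test_pairs_per_variant_match_runs(self, result_and_dir):
        result = result_and_dir[0]
        assert set(result.summaries) == {"baseline", "experimental"}
        for ss in result.summaries.values():
            assert len(ss) == 2
            for s in ss:
                assert 1 <= s.epoch_of_min <= 2 and s.min_val_loss >= 0

    def test_outputs_persisted(self, result_and_dir):
        import pandas as pd

        _, out, _, _ = result_and_dir
        df = pd.read_csv(out / "condition2_metrics.csv")
        assert {"run", "variant", "epoch", "train_loss", "val_loss",
                "val_acc"} <= set(df.columns)
        assert len(df) == 2 * 2 * 2  # runs x variants x epochs
        assert (out / "condition2_summary.json").exists()

    def test_identical_master_seed_reproduces_result(self, result_and_dir):
        result, _, corpus_cfg, cfg = result_and_dir
        again = mb.run_condition(mb.condition_spec(2), corpus_cfg, cfg)
        for variant in result.summaries:
            for s1, s2 in zip(result.summaries[variant],
                              again.summaries[variant]):
                assert s1 == s2


def test_condition_table_matches_variant_roles():
    assert _CONDITIONS[1][2] == (mb.ModelVariant.BASELINE,
                                 mb.ModelVariant.EXPERIMENTAL,
                                 mb.ModelVariant.EXPANDED_BASE,
                                 mb.ModelVariant.CONSTANT_INPUT)
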