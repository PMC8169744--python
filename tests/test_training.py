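"""Training procedure: schedule, sampler, losses, hard negatives, loop."""

import numpy as np
import pytest

import cacscore as c
from cacscore import training as tr
from cacscore.scoring import ScoringConfig


@pytest.fixture(scope="module")
def lesion_dataset():
    spec = c.PhantomSpec(n_slices=4, image_size=32, seed=5, noise_sd=5.0,
                         n_lesions_per_vessel={"LCA": 1, "LAD": 1,
                                               "LCX": 1, "RCA": 1},
                         lesion_radius_range=(1.5, 2.0),
                         distractor_counts={})
    vol, gt = c.generate_volume(spec)
    return tr.build_slice_dataset([(vol, gt)])


class TestSchedule:
    CFG = tr.TrainingConfig()

    def test_zero_at_start(self):
        assert tr.lr_schedule(0, 1e-3, self.CFG) == 0.0

    def test_base_rate_at_warmup_end(self):
        assert tr.lr_schedule(5_000, 1e-3, self.CFG) == 1e-3

    def test_zero_at_anneal_end(self):
        assert tr.lr_schedule(305_000, 1e-3, self.CFG) <= 1e-12

    def test_continuous_at_junction(self):
        before = tr.lr_schedule(4_999, 1e-3, self.CFG)
        at = tr.lr_schedule(5_000, 1e-3, self.CFG)
        after = tr.lr_schedule(5_001, 1e-3, self.CFG)
        assert abs(at - before) < 1e-6 and abs(after - at) < 1e-6

    def test_pretrained_group_is_pure_time_shift(self):
        for it in (0, 3_000, 10_000, 17_500, 80_000, 320_000):
            assert tr.pretrained_lr(it + 10_000, 1e-4, self.CFG) == \
                tr.lr_schedule(it, 1e-4, self.CFG)
        # clamped at zero before the delay elapses
        assert tr.pretrained_lr(5_000, 1e-4, self.CFG) == 0.0

    def test_scale_factor_shrinks_counts(self):
        cfg = tr.TrainingConfig(scale_factor=1e-3)
        assert cfg.warmup_scaled == 5
        assert cfg.anneal_scaled == 300
        assert cfg.delay_scaled == 10


class TestSampler:
    def test_first_epoch_is_permutation_of_lesion_slices(self,
                                                         lesion_dataset):
        n = len(lesion_dataset.lesion_indices())
        cfg = tr.TrainingConfig(batch_size=n, seed=0)
        state = tr.SamplerState.initial(lesion_dataset, 0)
        _, idx, epoch_end = tr.sample_minibatch(lesion_dataset, cfg, state)
        assert sorted(idx) == lesion_dataset.lesion_indices()
        assert epoch_end

    def test_reproducible_batch_sequence(self, lesion_dataset):
        cfg = tr.TrainingConfig(batch_size=2, seed=7)
        seqs = []
        for _ in range(2):
            state = tr.SamplerState.initial(lesion_dataset, 7)
            seqs.append([tr.sample_minibatch(lesion_dataset, cfg, state)[1]
                         for _ in range(6)])
        assert seqs[0] == seqs[1]

    def test_no_negative_slices_before_expansion(self, lesion_dataset):
        cfg = tr.TrainingConfig(batch_size=3, seed=1)
        state = tr.SamplerState.initial(lesion_dataset, 1)
        negatives = set(lesion_dataset.negative_indices())
        for _ in range(100):
            _, idx, _ = tr.sample_minibatch(lesion_dataset, cfg, state)
            assert not (set(idx) & negatives)


class TestCompositeLoss:
    def test_hand_computed_dice_on_toy_mask(self):
        # prediction p over 4 pixels, mask with 3 positives
        p = np.array([0.9, 0.8, 0.1, 0.4]).reshape(1, 1, 2, 2)
        m = np.array([1, 1, 0, 1]).reshape(1, 2, 2)
        pc = c._nn.constant(p)
        pv = c._nn.constant(np.full((1, 4, 2, 2), 0.25))
        total, dice_l, ce_l = tr.composite_loss(pc, pv, m,
                                                np.zeros((1, 2, 2), int),
                                                dice_smooth=1.0)
        inter = 0.9 + 0.8 + 0.4
        expected = 1 - (2 * inter + 1) / (p.sum() + 3 + 1)
        assert dice_l.data == pytest.approx(expected, abs=1e-9)
        assert ce_l.data == 0.0

    def test_perfect_prediction_loss_below_smoothing_epsilon(self):
        m = np.zeros((1, 4, 4))
        m[0, 1:3, 1:3] = 1
        pc = c._nn.constant(m[:, None] * 0.999 + 0.0005)
        pv = c._nn.constant(np.full((1, 4, 4, 4), 0.25))
        _, dice_l, _ = tr.composite_loss(pc, pv, m, np.zeros((1, 4, 4), int))
        assert dice_l.data < 0.01

    def test_all_background_is_finite(self):
        pc = c._nn.constant(np.full((2, 1, 4, 4), 1e-6))
        pv = c._nn.constant(np.full((2, 4, 4, 4), 0.25))
        total, dice_l, ce_l = tr.composite_loss(
            pc, pv, np.zeros((2, 4, 4)), np.zeros((2, 4, 4), int))
        assert np.isfinite(total.data)
        assert dice_l.data < 0.01

    def test_vessel_ce_only_on_calcium_pixels(self):
        rng = np.random.default_rng(0)
        pvdata = rng.uniform(0.05, 1, (1, 4, 3, 3))
        pvdata /= pvdata.sum(axis=1, keepdims=True)
        mask = np.zeros((1, 3, 3))
        mask[0, 0, 0] = 1
        vmap = np.zeros((1, 3, 3), int)
        vmap[0, 0, 0] = 2  # LAD
        pc = c._nn.constant(np.full((1, 1, 3, 3), 0.5))
        _, _, ce = tr.composite_loss(pc, c._nn.constant(pvdata), mask, vmap)
        assert ce.data == pytest.approx(-np.log(pvdata[0, 1, 0, 0] + 1e-12),
                                        abs=1e-9)


class _StubModel:
    """Deterministic stand-in: predicts calcium wherever HU > 150."""

    def __init__(self, dataset):
        self._hu = {id(s.image): s.hu for s in dataset.samples}

    def predict_slice(self, image):
        hu = self._hu[id(image)]
        pc = np.where(hu > 150.0, 0.9, 0.1)
        pv = np.full((4,) + hu.shape, 0.25)
        return pc, pv


@pytest.fixture(scope="module")
def mixed_dataset():
    lesioned = c.generate_volume(c.PhantomSpec(
        n_slices=2, image_size=32, seed=1, noise_sd=0.0,
        n_lesions_per_vessel={"LCA": 1, "LAD": 1, "LCX": 0, "RCA": 0},
        distractor_counts={}))
    # calcium-free exam whose distractors will fool the stub model
    negatives = c.generate_volume(c.PhantomSpec(
        n_slices=4, image_size=32, seed=2, noise_sd=0.0,
        n_lesions_per_vessel=dict.fromkeys(c.VESSELS, 0),
        distractor_counts={"aortic_wall": 2}))
    return tr.build_slice_dataset([lesioned, negatives])


class TestHardNegatives:
    def test_expansion_matches_brute_force_rescan(self, mixed_dataset):
        model = _StubModel(mixed_dataset)
        state = tr.SamplerState.initial(mixed_dataset, 0)
        before = set(state.pool)
        tr.expand_hard_negatives(model, mixed_dataset, state)
        expected = set(before)
        for i in mixed_dataset.negative_indices():
            s = mixed_dataset.samples[i]
            pc, _ = model.predict_slice(s.image)
            lesions = c.extract_lesions((pc > 0.5)[None], s.hu[None],
                                        mixed_dataset.pixel_area_mm2,
                                        ScoringConfig())
            if any(l.agatston(ScoringConfig()) > 0 for l in lesions):
                expected.add(i)
        assert state.pool == expected
        assert expected > before  # the distractor slices were caught

    def test_expansion_is_monotone_and_idempotent(self, mixed_dataset):
        model = _StubModel(mixed_dataset)
        state = tr.SamplerState.initial(mixed_dataset, 0)
        tr.expand_hard_negatives(model, mixed_dataset, state)
        once = set(state.pool)
        tr.expand_hard_negatives(model, mixed_dataset, state)
        assert state.pool == once

    def test_model_predicting_nothing_leaves_pool_unchanged(
            self, mixed_dataset):
        class Silent:
            def predict_slice(self, image):
                return (np.full(image.shape, 0.01),
                        np.full((4,) + image.shape, 0.25))

        state = tr.SamplerState.initial(mixed_dataset, 0)
        before = set(state.pool)
        tr.expand_hard_negatives(Silent(), mixed_dataset, state)
        assert state.pool == before


class TestTrainLoop:
    def test_zero_iterations_returns_model_unchanged(self, tiny_model,
                                                     lesion_dataset):
        before = {k: v.data.copy()
                  for k, v in tiny_model.parameters().items()}
        model, trace = tr.train(tiny_model, lesion_dataset,
                                tr.TrainingConfig(total_iters=0))
        assert trace == []
        for k, v in model.parameters().items():
            assert np.array_equal(v.data, before[k])

    def test_trace_length_and_loss_decreases(self, lesion_dataset):
        model = c.build_model(c.ModelConfig(
            encoder_depth=10, base_channels=4, decoder_channels=(8, 8, 4, 4),
            cardinality=2, se_reduction=2, seed=1))
        cfg = tr.TrainingConfig(batch_size=4, total_iters=60,
                                scale_factor=1e-3, seed=0)
        model, trace = tr.train(model, lesion_dataset, cfg)
        assert len(trace) == 60
        assert trace[-1]["loss"] < trace[0]["loss"]
        assert all(np.isfinite(t["loss"]) for t in trace)

    def test_deterministic_for_fixed_seed(self, lesion_dataset):
        losses = []
        for _ in range(2):
            model = c.build_model(c.ModelConfig(
                encoder_depth=10, base_channels=2,
                decoder_channels=(4, 4, 2, 2), cardinality=1,
                se_reduction=2, seed=3))
            cfg = tr.TrainingConfig(batch_size=2, total_iters=10,
                                    scale_factor=1e-3, seed=5)
            _, trace = tr.train(model, lesion_dataset, cfg)
            losses.append([t["loss"] for t in trace])
        assert losses[0] == losses[1]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            tr.TrainingConfig(warmup_iters=10, anneal_iters=10)
        with pytest.raises(ValueError):
            tr.TrainingConfig(scale_factor=0.0)
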