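"""Training schedule, augmentation alignment, and loop bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcmstain import PhantomSpec, generate_pair
from rcmstain.training import (schedule_g_per_d, augment, AugmentConfig,
                               TrainConfig, RegisteredPair, train_vsaa,
                               train_vshe)
from rcmstain.networks import (Generator, GeneratorConfig, Discriminator,
                               DiscriminatorConfig)


class TestSchedule:
    @pytest.mark.parametrize("t_d,expected", [
        # floor(12 - 0.25 * floor(t_d / 1000)) with a floor of 3:
        # 11.75 already truncates to 11 in the second block
        (0, 12), (999, 12), (1000, 11), (4500, 11), (5000, 10),
        (8000, 10), (36000, 3), (100000, 3),
    ])
    def test_exact_values(self, t_d, expected):
        assert schedule_g_per_d(t_d) == expected

    def test_negative_iteration_count_rejected(self):
        with pytest.raises(ValueError):
            schedule_g_per_d(-1)

    @given(st.integers(min_value=0, max_value=500000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_nonincreasing_bounded_and_blockwise_constant(self, t_d):
        val = schedule_g_per_d(t_d)
        assert 3 <= val <= 12
        assert val >= schedule_g_per_d(t_d + 1000)
        # piecewise constant on 1000-iteration blocks
        assert val == schedule_g_per_d((t_d // 1000) * 1000)

    def test_first_thousand_iterations_accumulate_12000_generator_steps(self):
        total = sum(schedule_g_per_d(t) for t in range(1000))
        assert total == 12000

    def test_full_range_is_exactly_three_to_twelve(self):
        seen = {schedule_g_per_d(t) for t in range(0, 60001, 500)}
        assert seen == set(range(3, 13))


class TestAugment:
    def test_disabled_augmentation_is_identity(self, rng):
        inp, tgt = rng.random((7, 16, 16)), rng.random((16, 16))
        out_i, out_t = augment(inp, tgt, 0, AugmentConfig(enabled=False))
        assert np.array_equal(out_i, inp)
        assert np.array_equal(out_t, tgt)

    def test_same_seed_transform_applied_twice_cancels_flips(self, rng):
        inp, tgt = rng.random((7, 16, 16)), rng.random((16, 16))
        cfg = AugmentConfig(rotate90=False, flip=True)
        a_i, a_t = augment(inp, tgt, 7, cfg)
        b_i, b_t = augment(a_i, a_t, 7, cfg)
        assert np.array_equal(b_i, inp)
        assert np.array_equal(b_t, tgt)

    def test_planted_landmark_stays_colocated(self, rng):
        inp = np.zeros((7, 32, 32))
        tgt = np.zeros((32, 32))
        inp[:, 10, 20] = 1.0
        tgt[10, 20] = 1.0
        cfg = AugmentConfig(elastic_magnitude=2.0)
        out_i, out_t = augment(inp, tgt, 3, cfg)
        pos_i = np.unravel_index(np.argmax(out_i[3]), out_i[3].shape)
        pos_t = np.unravel_index(np.argmax(out_t), out_t.shape)
        assert np.hypot(pos_i[0] - pos_t[0], pos_i[1] - pos_t[1]) < 0.5

    def test_misaligned_patches_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(rng.random((7, 16, 16)), rng.random((8, 8)), 0)


@pytest.fixture(scope="module")
def train_pairs(small_pair):
    p = small_pair
    return [RegisteredPair(p.unstained.voxels[z - 3:z + 4],
                           p.stained.voxels[z]) for z in range(3, 11)]


class TestTrainVsaa:
    def test_zero_budget_returns_initial_weights_and_empty_history(
            self, train_pairs):
        gen = Generator(GeneratorConfig(base_channels=4, seed=5))
        before = {k: v.copy() for k, v in gen.state_dict().items()}
        cfg = TrainConfig(batch_size=2, patch_size=64, total_d_iterations=0,
                          seed=0)
        result = train_vsaa(train_pairs, cfg, generator=gen)
        assert result.history == []
        after = result.generator.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_vsaa([], TrainConfig())

    def test_iteration_bookkeeping_follows_schedule(self, train_pairs):
        gen = Generator(GeneratorConfig(base_channels=4, seed=5))
        disc = Discriminator(DiscriminatorConfig(base_channels=4, fc_width=16,
                                                 seed=5))
        cfg = TrainConfig(batch_size=2, patch_size=64, total_d_iterations=2,
                          seed=0)
        result = train_vsaa(train_pairs, cfg, generator=gen,
                            discriminator=disc)
        assert result.d_steps == 2
        assert result.g_steps == 2 * 12     # schedule start value
        phases = [h["phase"] for h in result.history]
        assert phases.count("D") == 2 and phases.count("G") == 24

    def test_fixed_seed_reproduces_loss_history(self, train_pairs):
        histories = []
        for _ in range(2):
            gen = Generator(GeneratorConfig(base_channels=4, seed=5))
            disc = Discriminator(DiscriminatorConfig(base_channels=4,
                                                     fc_width=16, seed=5))
            cfg = TrainConfig(batch_size=2, patch_size=64,
                              total_d_iterations=1, seed=9)
            res = train_vsaa(train_pairs, cfg, generator=gen,
                             discriminator=disc)
            histories.append([h["total"] for h in res.history])
        assert histories[0] == histories[1]


class TestTrainVshe:
    def test_zero_budget_returns_initial_weights(self, small_pair):
        from rcmstain.networks import build_vshe_network
        from rcmstain.hne import extract_foreground, render_analytic_hne
        p = small_pair
        i_in = np.clip(p.unstained.voxels[0], 0, 1)
        i_tg = np.clip(p.stained.voxels[0], 0, 1)
        analytic = render_analytic_hne(extract_foreground(i_tg, i_in), i_in)
        model = build_vshe_network(base_channels=4, n_levels=2, seed=1)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        res = train_vshe([(i_tg, i_in)], [np.moveaxis(analytic, -1, 0)],
                         TrainConfig(batch_size=1), model=model,
                         n_iterations=0)
        after = res.generator.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_input_target_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train_vshe([(np.zeros((8, 8)), np.zeros((8, 8)))], [])
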