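"""DRAN/MDRAN architecture and training: shape propagation, decoder
geometry, weighted loss arithmetic, schedules and freeze contracts."""

import numpy as np
import pytest

from histotools import fixtures, seg_data
from histotools.io import TileRecord
from histotools.nn.autodiff import Tensor
from histotools.seg_net import (
    BORDER_WEIGHTS,
    Phase,
    TrainSchedule,
    build_contracting_path,
    build_dran,
    build_mdran,
    default_dran_schedule,
    default_mdran_schedule,
    dran_output_side,
    train_dran,
    train_mdran,
    weighted_loss,
)

TINY = dict(width_divisor=16, blocks=(1, 1, 1, 1))


@pytest.fixture(scope="module")
def training_patches():
    spec = fixtures.SyntheticTileSpec(n_nuclei=12, touching_fraction=0.2,
                                      seed=21)
    image, mask = fixtures.generate_nuclei_tile(spec)
    tile = TileRecord(image, mask, id="train")
    return seg_data.extract_nbl(tile, n_random=4,
                                rng=np.random.default_rng(0))[:8]


class TestContractingPath:
    def test_stage_spatial_chain_96_96_48_24_12(self):
        net = build_contracting_path(seed=0, **TINY).eval()
        x = Tensor(np.zeros((1, 3, 102, 102), dtype=np.float32))
        s1, s2, s3, s4 = net(x)
        assert s1.shape[2:] == (96, 96)
        assert s2.shape[2:] == (48, 48)
        assert s3.shape[2:] == (24, 24)
        assert s4.shape[2:] == (12, 12)

    def test_stem_is_valid_stride_one_7x7(self):
        net = build_contracting_path(seed=0, **TINY)
        assert net.stem.weight.shape[2:] == (7, 7)
        assert net.stem.stride == 1 and net.stem.padding == "valid"

    def test_full_width_channel_chain(self):
        net = build_contracting_path(seed=0, blocks=(1, 1, 1, 1))
        assert net.stage_channels == [256, 512, 1024, 2048]


class TestDranArchitecture:
    def test_decoder_channel_plan_matches_published_table(self):
        net = build_dran(seed=0, blocks=(1, 1, 1, 1))
        # decoder3 [5x5 -> 1024 | grouped 3x3 C=256 | 1x1 -> 512]
        assert net.decoder3.conv5.weight.shape[0] == 1024
        assert net.decoder3.groups == 256
        assert net.decoder3.conv1.weight.shape[0] == 512
        assert net.decoder2.conv5.weight.shape[0] == 512
        assert net.decoder2.groups == 128
        assert net.decoder2.conv1.weight.shape[0] == 256
        assert net.decoder1.conv5.weight.shape[0] == 256
        assert net.decoder1.groups == 64
        assert net.decoder1.conv1.weight.shape[0] == 128

    def test_decoders_shrink_each_side_by_six(self):
        # structural: valid 5x5 (-4) plus valid grouped 3x3 (-2)
        net = build_dran(seed=0, **TINY).eval()
        x = Tensor(np.zeros((1, net.decoder2.conv5.weight.shape[1], 30, 30),
                            dtype=np.float32))
        assert net.decoder2(x).shape[2:] == (24, 24)

    def test_forward_102_gives_54_probabilities(self):
        net = build_dran(seed=1, **TINY).eval()
        rng = np.random.default_rng(0)
        out = net(Tensor(rng.random((2, 3, 102, 102), dtype=np.float32)))
        assert out.shape == (2, 2, 54, 54)
        assert np.allclose(out.data.sum(axis=1), 1.0, atol=1e-5)

    @pytest.mark.parametrize("side", [86, 94, 102, 110, 118, 126, 134])
    def test_shape_oracle_matches_forward(self, side):
        net = build_dran(seed=2, **TINY).eval()
        x = Tensor(np.zeros((1, 3, side, side), dtype=np.float32))
        assert net(x).shape[2] == dran_output_side(side)

    def test_too_small_input_raises(self):
        with pytest.raises(ValueError):
            dran_output_side(40)


class TestMdran:
    def test_forward_matches_x1_branch_grid(self):
        net = build_mdran(seed=0, **TINY).eval()
        x = Tensor(np.zeros((1, 3, 102, 102), dtype=np.float32))
        out = net(x)
        assert out.shape == (1, 2, 54, 54)
        assert np.allclose(out.data.sum(axis=1), 1.0, atol=1e-5)

    def test_decoder4_consumes_128_channels_at_full_width(self):
        net = build_mdran(seed=0, blocks=(1, 1, 1, 1))
        assert net.decoder4.conv5.weight.shape[1] == 128
        assert net.decoder4.conv5.weight.shape[0] == 256
        assert net.decoder4.conv5.padding == "same"

    def test_missing_branch_weights_rejected(self):
        donor = build_dran(seed=3, **TINY)
        with pytest.raises(ValueError):
            build_mdran(branch_weights={1.0: donor.state_dict()}, **TINY)

    def test_branch_weight_injection(self):
        donor = build_dran(seed=3, **TINY)
        weights = {s: donor.state_dict() for s in (0.5, 1.0, 2.0)}
        net = build_mdran(branch_weights=weights, seed=9, **TINY)
        for dran in net.branches().values():
            assert np.array_equal(dran.head.weight.data,
                                  donor.head.weight.data)


class TestWeightedLoss:
    def test_border_pixel_correctly_predicted(self):
        p = np.array([0.5, 0.5]).reshape(1, 2, 1, 1)
        # tie at 0.5 resolves to the border class
        loss = weighted_loss(p, np.ones((1, 1, 1), int), BORDER_WEIGHTS)
        assert loss.item() == pytest.approx(5.0 * np.log(2), rel=1e-4)

    def test_border_pixel_missed_as_background(self):
        p = np.array([0.7, 0.3]).reshape(1, 2, 1, 1)
        loss = weighted_loss(p, np.ones((1, 1, 1), int), BORDER_WEIGHTS)
        assert loss.item() == pytest.approx(6.0 * -np.log(0.3), rel=1e-4)

    def test_background_pixel_missed_as_border(self):
        p = np.array([0.4, 0.6]).reshape(1, 2, 1, 1)
        loss = weighted_loss(p, np.zeros((1, 1, 1), int), BORDER_WEIGHTS)
        assert loss.item() == pytest.approx(4.0 * -np.log(0.4), rel=1e-4)

    def test_perfect_background_prediction_is_zero(self):
        p = np.array([1.0, 0.0]).reshape(1, 2, 1, 1)
        loss = weighted_loss(p, np.zeros((1, 1, 1), int), BORDER_WEIGHTS)
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_zero_probability_clamped(self):
        p = np.array([0.0, 1.0]).reshape(1, 2, 1, 1)
        loss = weighted_loss(p, np.zeros((1, 1, 1), int), BORDER_WEIGHTS)
        assert np.isfinite(loss.item())


class TestSchedules:
    def test_dran_phase1_breakpoints(self):
        sched = default_dran_schedule()
        p1 = sched.phases[0]
        assert p1.epochs == 35
        assert p1.lr_at(0) == 1.0e-4
        assert p1.lr_at(1) == 5.0e-5
        assert p1.lr_at(14) == 5.0e-5
        assert p1.lr_at(15) == 1.0e-5
        assert p1.lr_at(16) == 1.0e-5
        assert p1.lr_at(25) == 7.5e-6
        assert sched.phases[1].epochs == 40
        assert sched.batch_size == 32 and sched.l2_factor == 1.0e-5
        assert sched.adam_betas == (0.9, 0.999) and sched.adam_eps == 1e-8

    def test_mdran_schedule(self):
        sched = default_mdran_schedule()
        a, b = sched.phases
        assert (a.epochs, a.trainable) == (10, "decoder4")
        assert a.lr_at(9) == 1.0e-4
        assert b.epochs == 35
        assert b.lr_at(14) == 1.0e-4
        assert b.lr_at(15) == 1.0e-5
        assert b.lr_at(30) == 1.0e-6


class TestTraining:
    def test_smoke_run_records_history_and_freezes_contracting(
            self, training_patches):
        model = build_dran(seed=4, **TINY)
        before = {k: v.copy()
                  for k, v in model.contracting.state_dict().items()}
        sched = TrainSchedule(
            (Phase("expanding", 2, "expanding", {0: 1e-4}),), batch_size=4)
        state, history = train_dran(model, training_patches, sched, seed=0,
                                    task="blob", steps_per_epoch=2)
        assert len(history) == 2
        assert all(h["lr"] == 1e-4 for h in history)
        after = model.contracting.state_dict()
        for k in before:
            assert np.array_equal(before[k], after[k]), k

    def test_second_phase_trains_contracting(self, training_patches):
        model = build_dran(seed=4, **TINY)
        before = {k: v.copy() for k, v in model.contracting.state_dict().items()
                  if k.endswith("weight")}
        sched = TrainSchedule(
            (Phase("expanding", 1, "expanding", {0: 1e-3}),
             Phase("all", 1, "all", {0: 1e-3})), batch_size=4)
        train_dran(model, training_patches, sched, seed=0, task="border",
                   steps_per_epoch=1)
        after = model.contracting.state_dict()
        changed = [k for k in before if not np.array_equal(before[k], after[k])]
        assert changed  # contracting weights moved in the all-trainable phase

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_dran(build_dran(seed=0, **TINY), [], seed=0)

    def test_loss_decreases_when_overfitting(self, training_patches):
        model = build_dran(seed=7, **TINY)
        sched = TrainSchedule(
            (Phase("all", 6, "all", {0: 3e-4}),), batch_size=8)
        _, history = train_dran(model, training_patches[:5], sched, seed=1,
                                task="blob")
        assert history[-1]["loss"] < history[0]["loss"]

    def test_mdran_phase_freeze_contract(self, training_patches):
        model = build_mdran(seed=5, **TINY)
        branch_before = {
            s: {k: v.copy() for k, v in d.state_dict().items()}
            for s, d in model.branches().items()}
        sched = TrainSchedule(
            (Phase("decoder4", 1, "decoder4", {0: 1e-3}),), batch_size=2)
        train_mdran(model, training_patches[:2], sched, seed=0,
                    steps_per_epoch=1)
        for s, d in model.branches().items():
            after = d.state_dict()
            for k in branch_before[s]:
                assert np.array_equal(branch_before[s][k], after[k]), (s, k)

        contracting_before = {
            s: {k: v.copy() for k, v in d.contracting.state_dict().items()}
            for s, d in model.branches().items()}
        sched_b = TrainSchedule(
            (Phase("branches", 1, "branches", {0: 1e-3}),), batch_size=2)
        train_mdran(model, training_patches[:2], sched_b, seed=0,
                    steps_per_epoch=1)
        expanding_changed = False
        for s, d in model.branches().items():
            after = d.contracting.state_dict()
            for k in contracting_before[s]:
                assert np.array_equal(contracting_before[s][k], after[k]), (s, k)
            if not np.array_equal(branch_before[s]["decoder1.conv5.weight"],
                                  d.decoder1.conv5.weight.data):
                expanding_changed = True
        assert expanding_changed
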