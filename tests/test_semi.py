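"""Mixed-view consistency losses: closed forms, masking, stop-gradient, schedule."""

import numpy as np
import pytest

from coverseg import (
    AffinityGraph,
    SynthSpec,
    TinyAffinityNet,
    TrainConfig,
    Volume3D,
    bce_voxelwise,
    labels_to_affinity,
    loss_inter,
    loss_intra_labeled,
    loss_intra_unlabeled,
    loss_semi,
    pseudo_labels,
    sq_error_voxelwise,
    synth_instances,
    train_semi,
)
from coverseg.autodiff import Tensor
from coverseg.mixing import MixMask, make_mask
from coverseg.semi import ConstantModel, TrainingBatch, sample_batch

SHAPE = (4, 8, 8)


def const_graph(v):
    return AffinityGraph(np.full((3,) + SHAPE, v))


def make_test_batch(rng, pi3=None, shape=SHAPE):
    raw1, lab1 = synth_instances(SynthSpec(shape=shape, n_instances=2, seed=1))
    raw2, lab2 = synth_instances(SynthSpec(shape=shape, n_instances=2, seed=2))
    u1, _ = synth_instances(SynthSpec(shape=shape, n_instances=2, seed=3))
    u2, _ = synth_instances(SynthSpec(shape=shape, n_instances=2, seed=4))
    masks = [make_mask(shape, "quarter", rng=rng) for _ in range(3)]
    if pi3 is not None:
        masks[2] = pi3
    return TrainingBatch(
        l1=raw1, y1=labels_to_affinity(lab1), l2=raw2, y2=labels_to_affinity(lab2),
        u1=u1, u2=u2,
        l1_aug=raw1, l2_aug=raw2, u1_aug=u1, u2_aug=u2,  # augmentations disabled
        pi1=masks[0], pi2=masks[1], pi3=masks[2],
    )


def ones_mask(shape=SHAPE):
    return MixMask(np.ones(shape, dtype=int), "rectangle", 0.5)


def zeros_mask(shape=SHAPE):
    return MixMask(np.zeros(shape, dtype=int), "rectangle", 0.5)


class TestElementaryLosses:
    def test_bce_perfect_prediction_near_zero(self):
        t = const_graph(1.0)
        assert float(bce_voxelwise(t, t)) <= 1e-6

    def test_bce_uniform_half_is_ln2(self, rng):
        target = AffinityGraph(rng.integers(0, 2, (3,) + SHAPE).astype(float))
        assert float(bce_voxelwise(const_graph(0.5), target)) == pytest.approx(np.log(2))

    def test_bce_single_voxel_closed_form(self):
        p = AffinityGraph(np.full((3, 1, 1, 1), 0.5))
        t = AffinityGraph(np.ones((3, 1, 1, 1)))
        assert float(bce_voxelwise(p, t)) == pytest.approx(0.69315, abs=1e-5)

    def test_sq_error_closed_forms(self):
        assert float(sq_error_voxelwise(const_graph(0.5), const_graph(0.5))) == 0.0
        assert float(sq_error_voxelwise(const_graph(0.75), const_graph(0.25))) == pytest.approx(0.25)
        p = AffinityGraph(np.array([0.0, 1.0]).reshape(1, 1, 1, 2).repeat(3, axis=0))
        t = AffinityGraph(np.array([0.0, 0.0]).reshape(1, 1, 1, 2).repeat(3, axis=0))
        assert float(sq_error_voxelwise(p, t)) == pytest.approx(0.5)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            bce_voxelwise(const_graph(0.5), const_graph(1.0), region=np.zeros((3,) + SHAPE))


class TestPseudoLabels:
    def test_constant_model_gives_constant_graphs(self, rng):
        batch = make_test_batch(rng)
        p1, p2 = pseudo_labels(ConstantModel(0.3), batch.u1, batch.u2)
        assert (p1.values == 0.3).all() and (p2.values == 0.3).all()

    def test_no_gradient_flows_through_pseudo_labels(self, rng):
        """Parameter grads equal finite differences of the loss with the
        pseudo labels FROZEN: the live pseudo-label path contributes zero."""
        batch = make_test_batch(rng)
        model = TinyAffinityNet(n_hidden=2, seed=0)
        pl = pseudo_labels(model, batch.u1, batch.u2)
        loss = loss_intra_unlabeled(model, batch, pseudo=pl)
        loss.backward()
        w = model.k1[0]
        g_auto = w.grad[1, 1, 1]

        h = 1e-5
        vals = []
        for delta in (h, -h):
            w.data[1, 1, 1] += delta
            # pseudo labels stay frozen at the original parameters
            vals.append(float(loss_intra_unlabeled(model, batch, pseudo=pl)))
            w.data[1, 1, 1] -= delta
        fd = (vals[0] - vals[1]) / (2 * h)
        assert g_auto == pytest.approx(fd, abs=1e-6)

    def test_identity_probe_model(self, rng):
        class Broadcast:
            def __call__(self, v):
                x = v.data if isinstance(v, Volume3D) else np.asarray(v)
                return Tensor(np.repeat(x[None], 3, axis=0))

            def parameters(self):
                return []

        batch = make_test_batch(rng)
        p1, _ = pseudo_labels(Broadcast(), batch.u1, batch.u2)
        np.testing.assert_array_equal(p1.values, np.repeat(batch.u1.data[None], 3, axis=0))


class TestIntraLosses:
    def test_constant_half_model_gives_ln2(self, rng):
        batch = make_test_batch(rng)
        assert float(loss_intra_labeled(ConstantModel(0.5), batch)) == pytest.approx(np.log(2))

    def test_all_ones_mask_reduces_to_supervised(self, rng):
        batch = make_test_batch(rng, shape=SHAPE)
        batch.pi1 = ones_mask()
        model = TinyAffinityNet(n_hidden=2, seed=3)
        got = float(loss_intra_labeled(model, batch))
        want = float(bce_voxelwise(model(batch.l1_aug), batch.y1))
        assert got == pytest.approx(want)

    def test_intra_unlabeled_self_consistency_is_zero(self, rng):
        batch = make_test_batch(rng)
        batch.pi2 = ones_mask()
        model = TinyAffinityNet(n_hidden=2, seed=5)
        # no augmentation, mask keeps u1 only: prediction equals its pseudo label
        assert float(loss_intra_unlabeled(model, batch)) == pytest.approx(0.0, abs=1e-12)

    def test_intra_unlabeled_constant_model_zero_any_mask(self, rng):
        batch = make_test_batch(rng)
        assert float(loss_intra_unlabeled(ConstantModel(0.7), batch)) == pytest.approx(0.0)

    def test_intra_unlabeled_hand_toy(self, rng):
        batch = make_test_batch(rng)
        pl = (const_graph(0.6), const_graph(0.6))
        val = loss_intra_unlabeled(ConstantModel(0.8), batch, pseudo=pl)
        assert float(val) == pytest.approx(0.04)


class TestInterLoss:
    def test_all_ones_mask(self, rng):
        batch = make_test_batch(rng, pi3=ones_mask())
        model = TinyAffinityNet(n_hidden=2, seed=7)
        with pytest.warns(UserWarning):
            inter_l, inter_u = loss_inter(model, batch)
        assert float(inter_u) == 0.0
        want = float(bce_voxelwise(model(batch.l1_aug), batch.y1))
        assert float(inter_l) == pytest.approx(want)

    def test_all_zeros_mask(self, rng):
        batch = make_test_batch(rng, pi3=zeros_mask())
        with pytest.warns(UserWarning):
            inter_l, _ = loss_inter(ConstantModel(0.5), batch)
        assert float(inter_l) == 0.0

    def test_constant_half_model_closed_forms(self, rng):
        batch = make_test_batch(rng)  # quarter mask: both regions non-empty
        inter_l, inter_u = loss_inter(ConstantModel(0.5), batch)
        assert float(inter_l) == pytest.approx(np.log(2))
        assert float(inter_u) == pytest.approx(0.0)

    def test_inter_l_ignores_opposite_region(self, rng):
        batch = make_test_batch(rng)
        inter_l, _ = loss_inter(ConstantModel(0.5), batch)
        # corrupt y1 only where Pi3 = 0: the labeled-region loss is unchanged
        flipped = AffinityGraph(np.where(batch.pi3.mask[None] == 0, 1 - batch.y1.values, batch.y1.values))
        batch2 = make_test_batch(np.random.default_rng(0))
        batch2.pi3 = batch.pi3
        batch2.y1 = flipped
        batch2.l1_aug, batch2.u1_aug, batch2.u1 = batch.l1_aug, batch.u1_aug, batch.u1
        inter_l2, _ = loss_inter(ConstantModel(0.5), batch2)
        assert float(inter_l) == pytest.approx(float(inter_l2))


class TestLossSemi:
    def test_lambda_zero_drops_unlabeled_terms(self):
        total, bd = loss_semi(1.0, 5.0, 2.0, 7.0, lambda_u=0.0)
        assert float(total) == pytest.approx(3.0)
        assert bd.total == pytest.approx(3.0)

    def test_unit_components_weighting(self):
        total, bd = loss_semi(1.0, 1.0, 1.0, 1.0, lambda_u=0.2)
        assert float(total) == pytest.approx(2.4)
        assert bd.total == pytest.approx(bd.intra_l + bd.inter_l + 0.2 * (bd.intra_u + bd.inter_u))

    def test_zero_components(self):
        total, _ = loss_semi(0.0, 0.0, 0.0, 0.0)
        assert float(total) == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            loss_semi(1.0, 1.0, 1.0, 1.0, lambda_u=-0.1)


class TestTrainSemi:
    def _data(self, n=2, shape=(12, 24, 24)):
        vols = [synth_instances(SynthSpec(shape=shape, n_instances=3, seed=20 + i)) for i in range(n)]
        labeled = [(r, labels_to_affinity(l)) for r, l in vols[:1]]
        unlabeled = [r for r, _ in vols[1:]]
        return labeled, unlabeled

    def test_warmup_trace_is_pure_intra_labeled(self):
        labeled, unlabeled = self._data()
        cfg = TrainConfig(steps=4, warmup_steps=2, crop_size=(8, 16, 16), learning_rate=1e-3)
        _, trace = train_semi(TinyAffinityNet(n_hidden=2, seed=0), labeled, unlabeled, cfg, np.random.default_rng(1))
        for b in trace[:2]:
            assert b.total == b.intra_l and b.intra_u == b.inter_l == b.inter_u == 0.0
        assert any(b.intra_u > 0 or b.inter_u > 0 for b in trace[2:])

    def test_fixed_seed_reproducible(self):
        labeled, unlabeled = self._data()
        cfg = TrainConfig(steps=3, warmup_steps=1, crop_size=(8, 16, 16))
        traces = []
        for _ in range(2):
            _, t = train_semi(TinyAffinityNet(n_hidden=2, seed=0), labeled, unlabeled, cfg, np.random.default_rng(9))
            traces.append([(b.intra_l, b.intra_u, b.inter_l, b.inter_u) for b in t])
        assert traces[0] == traces[1]

    def test_lambda_zero_no_unlabeled_is_supervised_mixing(self):
        labeled, _ = self._data()
        cfg = TrainConfig(steps=3, warmup_steps=0, lambda_u=0.0, crop_size=(8, 16, 16))
        _, trace = train_semi(TinyAffinityNet(n_hidden=2, seed=0), labeled, [], cfg, np.random.default_rng(2))
        for b in trace:
            assert b.total == b.intra_l
            assert b.intra_u == b.inter_l == b.inter_u == 0.0

    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValueError):
            train_semi(TinyAffinityNet(), [], [], TrainConfig(steps=1), np.random.default_rng(0))
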