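"""Mixed-view consistency regularization for semi-supervised affinity learning.

A segmentation model S maps a raw volume (D, H, W) to a 3-channel affinity
graph in [0, 1]. Training combines four loss terms over a batch of two
labeled pairs (l1, y1), (l2, y2) and two unlabeled volumes u1, u2, each
mixed under axial-through masks Π1..Π3:

* intra-labeled   — cross-entropy of S on the Π1-mixed augmented labeled
  views against the Π1-mixed ground-truth affinities;
* intra-unlabeled — squared error of S on the Π2-mixed augmented unlabeled
  views against the Π2-mixed *stop-gradient* pseudo labels S(u1), S(u2)
  computed on the un-augmented inputs;
* inter-dataset   — one forward pass on the Π3-mix of a labeled and an
  unlabeled view; the Π3=1 region is supervised by y1 (cross-entropy), the
  Π3=0 region by the pseudo label S(u1) (squared error).

The total is  L = L_intraL + L_interL + λ (L_intraU + L_interU),  λ = 0.2
by default. Because a randomly initialized network emits useless pseudo
labels, training warms up on the intra-labeled term alone before switching
to the full objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .affinity import AffinityGraph
from .embedding import AugmentConfig, augment
from .mixing import MixMask, make_mask, mix_affinity, mix_raw
from .volumes import Volume3D

__all__ = [
    "SegmentationModel",
    "TinyAffinityNet",
    "TrainingBatch",
    "LossBreakdown",
    "TrainConfig",
    "bce_voxelwise",
    "sq_error_voxelwise",
    "pseudo_labels",
    "loss_intra_labeled",
    "loss_intra_unlabeled",
    "loss_inter",
    "loss_semi",
    "train_semi",
]

EPS = 1e-7


def _vals(x) -> Union[np.ndarray, Tensor]:
    if isinstance(x, AffinityGraph):
        return x.values
    if isinstance(x, Volume3D):
        return x.data
    return x


class SegmentationModel:
    """Contract: callable (D, H, W) → Tensor (3, D, H, W) with values in [0, 1]."""

    def __call__(self, vol) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def parameters(self) -> List[Tensor]:  # pragma: no cover - interface
        return []


class TinyAffinityNet(SegmentationModel):
    """Two-layer residual 3D conv backbone with sigmoid affinity outputs.

    conv(1→F, k=3) → relu → conv(F→3, k=3) + skip(1→3, k=1) → sigmoid.
    A desk-scale stand-in for the pluggable U-Net slot: big enough to learn
    boundary darkness on synthetic volumes, small enough for CPU tests.
    """

    def __init__(self, n_hidden: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        k = (3, 3, 3)
        s1 = 1.0 / np.sqrt(np.prod(k))
        self.k1 = [Tensor(rng.normal(0, s1, k), requires_grad=True) for _ in range(n_hidden)]
        s2 = 1.0 / np.sqrt(np.prod(k) * n_hidden)
        self.k2 = [
            [Tensor(rng.normal(0, s2, k), requires_grad=True) for _ in range(n_hidden)]
            for _ in range(3)
        ]
        self.skip = [Tensor(rng.normal(0, 1.0, (1, 1, 1)), requires_grad=True) for _ in range(3)]
        self.bias = [Tensor(0.0, requires_grad=True) for _ in range(3)]
        self.n_hidden = n_hidden

    def __call__(self, vol) -> Tensor:
        x = Tensor._lift(_vals(vol))
        h = [ad.relu(ad.correlate3d(x, kc)) for kc in self.k1]
        outs = []
        for c in range(3):
            acc = ad.correlate3d(h[0], self.k2[c][0])
            for i in range(1, self.n_hidden):
                acc = ad.add(acc, ad.correlate3d(h[i], self.k2[c][i]))
            acc = ad.add(acc, ad.correlate3d(x, self.skip[c]))
            outs.append(ad.sigmoid(ad.add(acc, self.bias[c])))
        return ad.stack(outs)

    def parameters(self) -> List[Tensor]:
        ps = list(self.k1) + self.skip + self.bias
        for row in self.k2:
            ps.extend(row)
        return ps


class ConstantModel(SegmentationModel):
    """Probe model emitting a constant affinity value (analytic loss checks)."""

    def __init__(self, value: float = 0.5):
        self.value = float(value)

    def __call__(self, vol) -> Tensor:
        x = _vals(vol)
        shape = x.shape if not isinstance(x, Tensor) else x.data.shape
        return Tensor(np.full((3,) + tuple(shape), self.value))

    def parameters(self) -> List[Tensor]:
        return []


@dataclass
class TrainingBatch:
    """One mixed-view batch: labeled pairs, unlabeled volumes, views, masks."""

    l1: Volume3D
    y1: AffinityGraph
    l2: Volume3D
    y2: AffinityGraph
    u1: Volume3D
    u2: Volume3D
    l1_aug: Volume3D
    l2_aug: Volume3D
    u1_aug: Volume3D
    u2_aug: Volume3D
    pi1: MixMask
    pi2: MixMask
    pi3: MixMask


@dataclass
class LossBreakdown:
    intra_l: float
    intra_u: float
    inter_l: float
    inter_u: float
    lambda_u: float

    @property
    def total(self) -> float:
        return self.intra_l + self.inter_l + self.lambda_u * (self.intra_u + self.inter_u)


def _masked_mean(elem: Tensor, region: Optional[np.ndarray]) -> Tensor:
    if region is None:
        return ad.mean(elem)
    w = np.broadcast_to(np.asarray(region, dtype=float), elem.shape)
    total = float(w.sum())
    if total == 0:
        raise ValueError("empty region in masked loss")
    return ad.mul(ad.sum_(ad.mul(elem, w)), 1.0 / total)


def bce_voxelwise(pred, target, region: Optional[np.ndarray] = None) -> Tensor:
    """Mean binary cross-entropy over the (optionally masked) channel-voxels.

    Predictions are clipped to [1e-7, 1 − 1e-7] before the logarithm.
    """
    p = ad.clip(Tensor._lift(_vals(pred)), EPS, 1.0 - EPS)
    t = np.asarray(_vals(target).data if isinstance(_vals(target), Tensor) else _vals(target))
    ce = ad.add(
        ad.mul(ad.mul(ad.log(p), t), -1.0),
        ad.mul(ad.mul(ad.log(ad.add(ad.mul(p, -1.0), 1.0)), 1.0 - t), -1.0),
    )
    return _masked_mean(ce, region)


def sq_error_voxelwise(pred, target, region: Optional[np.ndarray] = None) -> Tensor:
    """Mean squared error over the (optionally masked) channel-voxels."""
    p = Tensor._lift(_vals(pred))
    t = _vals(target)
    t = t.detach() if isinstance(t, Tensor) else np.asarray(t)
    diff = ad.add(p, ad.mul(Tensor._lift(t), -1.0))
    return _masked_mean(ad.mul(diff, diff), region)


def pseudo_labels(model: SegmentationModel, u1: Volume3D, u2: Volume3D) -> Tuple[AffinityGraph, AffinityGraph]:
    """Soft pseudo labels S(u1), S(u2) on UN-augmented inputs, gradient-blocked."""
    g1 = model(u1)
    g2 = model(u2)
    g1 = g1.detach().data if isinstance(g1, Tensor) else np.asarray(g1)
    g2 = g2.detach().data if isinstance(g2, Tensor) else np.asarray(g2)
    return AffinityGraph(g1), AffinityGraph(g2)


def loss_intra_labeled(model: SegmentationModel, batch: TrainingBatch) -> Tensor:
    """Cross-entropy of S on Π1-mixed labeled views vs Π1-mixed affinities."""
    mixed_in = mix_raw(batch.l1_aug, batch.l2_aug, batch.pi1)
    mixed_y = mix_affinity(batch.y1, batch.y2, batch.pi1)
    return bce_voxelwise(model(mixed_in), mixed_y)


def loss_intra_unlabeled(
    model: SegmentationModel,
    batch: TrainingBatch,
    pseudo: Optional[Tuple[AffinityGraph, AffinityGraph]] = None,
) -> Tensor:
    """Squared error of S on Π2-mixed unlabeled views vs mixed pseudo labels."""
    if pseudo is None:
        pseudo = pseudo_labels(model, batch.u1, batch.u2)
    mixed_in = mix_raw(batch.u1_aug, batch.u2_aug, batch.pi2)
    mixed_pl = mix_affinity(pseudo[0], pseudo[1], batch.pi2)
    return sq_error_voxelwise(model(mixed_in), mixed_pl)


def loss_inter(
    model: SegmentationModel,
    batch: TrainingBatch,
    pseudo: Optional[Tuple[AffinityGraph, AffinityGraph]] = None,
) -> Tuple[Tensor, Tensor]:
    """Inter-dataset mixing: one forward pass, region-split supervision.

    The Π3=1 (labeled) region is scored by cross-entropy against y1; the
    Π3=0 (unlabeled) region by squared error against the pseudo label
    S(u1). A region that is empty contributes 0 (with a warning).
    """
    if pseudo is None:
        pseudo = pseudo_labels(model, batch.u1, batch.u2)
    mixed_in = mix_raw(batch.l1_aug, batch.u1_aug, batch.pi3)
    pred = model(mixed_in)
    lab_region = batch.pi3.mask[None]
    unl_region = 1 - lab_region
    if lab_region.sum() == 0:
        warnings.warn("inter-dataset mask has no labeled region; inter_l = 0")
        inter_l: Tensor = Tensor(0.0)
    else:
        inter_l = bce_voxelwise(pred, batch.y1, region=lab_region)
    if unl_region.sum() == 0:
        warnings.warn("inter-dataset mask has no unlabeled region; inter_u = 0")
        inter_u: Tensor = Tensor(0.0)
    else:
        inter_u = sq_error_voxelwise(pred, pseudo[0], region=unl_region)
    return inter_l, inter_u


def loss_semi(
    intra_l, intra_u, inter_l, inter_u, lambda_u: float = 0.2
) -> Tuple[Tensor, LossBreakdown]:
    """Combine the four components: L = intra_l + inter_l + λ(intra_u + inter_u)."""
    if lambda_u < 0:
        raise ValueError("lambda must be >= 0")
    comps = [Tensor._lift(c) for c in (intra_l, intra_u, inter_l, inter_u)]
    total = ad.add(
        ad.add(comps[0], comps[2]),
        ad.mul(ad.add(comps[1], comps[3]), lambda_u),
    )
    bd = LossBreakdown(
        intra_l=float(comps[0]), intra_u=float(comps[1]),
        inter_l=float(comps[2]), inter_u=float(comps[3]),
        lambda_u=lambda_u,
    )
    return total, bd


@dataclass
class TrainConfig:
    """Semi-supervised training hyper-parameters.

    Defaults mirror the reference configuration: λ = 0.2, rectangle masks
    with β in [0.25, 0.5], learning rate 1e-4; crop size and step counts
    are desk-scale knobs.
    """

    steps: int = 200
    warmup_steps: int = 0
    lambda_u: float = 0.2
    beta_range: Tuple[float, float] = (0.25, 0.5)
    mask_strategy: str = "rectangle"
    crop_size: Tuple[int, int, int] = (16, 32, 32)
    learning_rate: float = 1e-4
    augment_cfg: Optional[AugmentConfig] = None

    def __post_init__(self):
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be >= 0")


def _photometric_cfg() -> AugmentConfig:
    # spatial transforms would break alignment with fixed affinity targets
    return AugmentConfig(
        reflections=False, rotations=False, misalign=False,
        blur=True, blur_sigma=(0.0, 0.6),
        noise=True, noise_sd=0.03,
        photometric=True, photometric_scale=0.05, photometric_shift=0.05,
        masking=True, masking_fraction=0.02,
    )


def _random_crop(rng, vol: Volume3D, size, aff: Optional[AffinityGraph] = None):
    D, H, W = vol.shape
    d, h, w = size
    z = int(rng.integers(0, D - d + 1))
    y = int(rng.integers(0, H - h + 1))
    x = int(rng.integers(0, W - w + 1))
    v = Volume3D(vol.data[z: z + d, y: y + h, x: x + w].copy())
    if aff is None:
        return v
    a = AffinityGraph(aff.values[:, z: z + d, y: y + h, x: x + w].copy())
    return v, a


def sample_batch(
    rng: np.random.Generator,
    labeled: Sequence[Tuple[Volume3D, AffinityGraph]],
    unlabeled: Sequence[Volume3D],
    cfg: TrainConfig,
) -> TrainingBatch:
    """Draw crops, augmented views and the three mixing masks for one step."""
    aug = cfg.augment_cfg or _photometric_cfg()
    i1, i2 = rng.integers(len(labeled)), rng.integers(len(labeled))
    l1, y1 = _random_crop(rng, labeled[int(i1)][0], cfg.crop_size, labeled[int(i1)][1])
    l2, y2 = _random_crop(rng, labeled[int(i2)][0], cfg.crop_size, labeled[int(i2)][1])
    if unlabeled:
        u1 = _random_crop(rng, unlabeled[int(rng.integers(len(unlabeled)))], cfg.crop_size)
        u2 = _random_crop(rng, unlabeled[int(rng.integers(len(unlabeled)))], cfg.crop_size)
    else:
        u1, u2 = l1, l2
    masks = [
        make_mask(cfg.crop_size, cfg.mask_strategy,
                  beta=float(rng.uniform(*cfg.beta_range)) if cfg.mask_strategy == "rectangle" else None,
                  rng=rng)
        for _ in range(3)
    ]
    return TrainingBatch(
        l1=l1, y1=y1, l2=l2, y2=y2, u1=u1, u2=u2,
        l1_aug=augment(l1, aug, rng), l2_aug=augment(l2, aug, rng),
        u1_aug=augment(u1, aug, rng), u2_aug=augment(u2, aug, rng),
        pi1=masks[0], pi2=masks[1], pi3=masks[2],
    )


def train_semi(
    model: SegmentationModel,
    labeled: Sequence[Tuple[Volume3D, AffinityGraph]],
    unlabeled: Sequence[Volume3D],
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> Tuple[SegmentationModel, List[LossBreakdown]]:
    """Warm-up on the intra-labeled loss, then optimize the full objective.

    Returns the trained model and the per-step loss trace; fully
    deterministic for a fixed ``rng`` state.
    """
    if not labeled:
        raise ValueError("train_semi requires a non-empty labeled set")
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    trace: List[LossBreakdown] = []
    use_unlabeled = bool(unlabeled) and cfg.lambda_u > 0
    for step in range(cfg.steps):
        batch = sample_batch(rng, labeled, unlabeled, cfg)
        if step < cfg.warmup_steps:
            il = loss_intra_labeled(model, batch)
            total = il
            bd = LossBreakdown(float(il), 0.0, 0.0, 0.0, cfg.lambda_u)
        else:
            il = loss_intra_labeled(model, batch)
            if use_unlabeled:
                pl = pseudo_labels(model, batch.u1, batch.u2)
                iu = loss_intra_unlabeled(model, batch, pseudo=pl)
                el, eu = loss_inter(model, batch, pseudo=pl)
            else:
                # no unlabeled data: the inter-dataset pass degenerates to
                # supervised mixing, already covered by the intra term
                iu, eu, el = Tensor(0.0), Tensor(0.0), Tensor(0.0)
            total, bd = loss_semi(il, iu, el, eu, lambda_u=cfg.lambda_u)
        opt.zero_grad()
        total.backward()
        opt.step()
        trace.append(bd)
    return model, trace
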