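"""Patch-grid partitioning, augmentations, and siamese patch representation.

The representation learner follows the stop-gradient siamese recipe: two
augmented views of the same patch pass through a weight-sharing encoder
``f`` and projector ``g``; a predictor ``h`` on one branch is trained to
match the *detached* projection of the other, with the symmetrized negative
cosine similarity as the objective. The trained encoder then maps every
patch of the unlabeled volume to an L-dimensional embedding — the universal
set U that coverage-based selection operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor
from .volumes import Volume3D

__all__ = [
    "PatchGrid",
    "EmbeddingSet",
    "EncoderStack",
    "AugmentConfig",
    "partition",
    "augment",
    "neg_cosine",
    "simsiam_loss",
    "embed_patches",
    "train_encoder",
    "ConvEncoder",
    "Linear",
]


@dataclass(frozen=True)
class PatchGrid:
    """All fully-contained sliding windows of a volume, z-major raster order.

    Count per axis is floor((extent - patch) / stride) + 1; trailing voxels
    not covered by a full window are dropped (no padding).
    """

    patch_size: Tuple[int, int, int]
    stride: Tuple[int, int, int]
    origins: Tuple[Tuple[int, int, int], ...]
    volume_shape: Tuple[int, int, int]

    @classmethod
    def build(cls, volume_shape, patch_size, stride) -> "PatchGrid":
        if any(p > s for p, s in zip(patch_size, volume_shape)):
            raise ValueError(
                f"patch {patch_size} larger than volume {volume_shape}"
            )
        if any(s < 1 for s in stride):
            raise ValueError("stride must be >= 1 per axis")
        axes = [
            range(0, volume_shape[a] - patch_size[a] + 1, stride[a]) for a in range(3)
        ]
        origins = tuple(
            (z, y, x) for z in axes[0] for y in axes[1] for x in axes[2]
        )
        return cls(tuple(patch_size), tuple(stride), origins, tuple(volume_shape))

    def __len__(self) -> int:
        return len(self.origins)


def partition(vol: Volume3D, patch_size, stride) -> PatchGrid:
    """Enumerate the sliding-window patch grid of a volume."""
    return PatchGrid.build(vol.shape, patch_size, stride)


@dataclass
class EmbeddingSet:
    """N patch embeddings of dimension L with row-aligned patch origins (U)."""

    vectors: np.ndarray  # (N, L) float
    origins: np.ndarray  # (N, 3) int, patch origins (z, y, x)
    patch_size: Tuple[int, int, int]
    stride: Tuple[int, int, int]
    volume_shape: Optional[Tuple[int, int, int]] = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.origins = np.asarray(self.origins, dtype=np.int64)
        if self.vectors.ndim != 2 or len(self.vectors) != len(self.origins):
            raise ValueError("vectors must be (N, L) aligned with N origins")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embeddings must be finite")

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]


@dataclass
class AugmentConfig:
    """Semantic-preserving augmentations for anisotropic EM patches.

    Geometric transforms stay in-plane (reflections may also flip z, but
    rotations are xy multiples of 90° only) so section-axis anisotropy is
    never mixed into xy. Misalignment applies an independent small integer
    in-plane shift per z-section with reflect padding, the standard ssEM
    misregistration model.
    """

    reflections: bool = True
    rotations: bool = True
    blur: bool = True
    blur_sigma: Tuple[float, float] = (0.0, 1.0)  # in-plane sigma range
    noise: bool = True
    noise_sd: float = 0.05
    misalign: bool = True
    misalign_max: int = 2  # voxels per section
    photometric: bool = True
    photometric_scale: float = 0.1
    photometric_shift: float = 0.1
    masking: bool = True
    masking_fraction: float = 0.1
    mask_value: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.masking_fraction < 1.0:
            raise ValueError("masking_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.misalign_max < 0:
            raise ValueError("augmentation magnitudes must be non-negative")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(
            reflections=False, rotations=False, blur=False, noise=False,
            misalign=False, photometric=False, masking=False,
        )


def augment(patch: Volume3D, cfg: AugmentConfig, rng: np.random.Generator) -> Volume3D:
    """Apply the configured random perturbations; identity when all disabled."""
    a = patch.data.copy()
    if cfg.reflections:
        for ax in range(3):
            if rng.random() < 0.5:
                a = np.flip(a, axis=ax)
    if cfg.rotations:
        k = int(rng.integers(0, 4))
        a = np.rot90(a, k=k, axes=(1, 2))
    if cfg.misalign and cfg.misalign_max > 0:
        shifts = rng.integers(-cfg.misalign_max, cfg.misalign_max + 1, size=(a.shape[0], 2))
        a = np.stack(
            [
                ndimage.shift(a[d], shifts[d], order=0, mode="reflect")
                for d in range(a.shape[0])
            ]
        )
    if cfg.blur:
        sigma = rng.uniform(*cfg.blur_sigma)
        if sigma > 0:
            a = ndimage.gaussian_filter(a, sigma=(0.0, sigma, sigma))
    if cfg.noise and cfg.noise_sd > 0:
        a = a + rng.normal(0.0, cfg.noise_sd, size=a.shape)
    if cfg.photometric:
        scale = 1.0 + rng.uniform(-cfg.photometric_scale, cfg.photometric_scale)
        shift = rng.uniform(-cfg.photometric_shift, cfg.photometric_shift)
        a = a * scale + shift
    if cfg.masking and cfg.masking_fraction > 0:
        n_mask = int(np.floor(cfg.masking_fraction * a.size))
        idx = rng.choice(a.size, size=n_mask, replace=False)
        a = np.ascontiguousarray(a)
        a.ravel()[idx] = cfg.mask_value
    return Volume3D(np.clip(np.ascontiguousarray(a), 0.0, 1.0))


def neg_cosine(a, b) -> float:
    """Negative cosine similarity of two nonzero vectors, in [-1, 1]."""
    return float(ad.neg_cosine(np.asarray(a, dtype=float).ravel(),
                               np.asarray(b, dtype=float).ravel()))


# ---------------------------------------------------------------------------
# encoder stack


class Linear:
    """Dense layer y = x W + b on 1-D inputs."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.W), self.b)

    def parameters(self) -> List[Tensor]:
        return [self.W, self.b]


class ConvEncoder:
    """Small strided 3D conv stack with global pooling to an L-vector.

    conv(k=3) → relu → subsample(1,2,2) → conv(k=3) → relu → global mean
    pool per channel → linear to L. The default desk-scale stand-in for the
    pluggable encoder contract.
    """

    def __init__(self, n_channels: int = 8, out_dim: int = 80, seed: int = 0):
        rng = np.random.default_rng(seed)
        k = (3, 3, 3)
        scale1 = 1.0 / np.sqrt(np.prod(k))
        self.k1 = [
            Tensor(rng.normal(0.0, scale1, size=k), requires_grad=True)
            for _ in range(n_channels)
        ]
        scale2 = 1.0 / np.sqrt(np.prod(k) * n_channels)
        self.k2 = [
            [
                Tensor(rng.normal(0.0, scale2, size=k), requires_grad=True)
                for _ in range(n_channels)
            ]
            for _ in range(n_channels)
        ]
        self.head = Linear(n_channels, out_dim, rng)
        self.n_channels = n_channels
        self.out_dim = out_dim

    def __call__(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        h1 = [
            ad.relu(ad.correlate3d(x, self.k1[c], None))
            for c in range(self.n_channels)
        ]
        h1 = [ad.subsample(h, (1, 2, 2)) for h in h1]
        h2 = []
        for o in range(self.n_channels):
            acc = ad.correlate3d(h1[0], self.k2[o][0], None)
            for i in range(1, self.n_channels):
                acc = ad.add(acc, ad.correlate3d(h1[i], self.k2[o][i], None))
            h2.append(ad.relu(acc))
        pooled = ad.concat([ad.mean(h) for h in h2])
        return self.head(pooled)

    def parameters(self) -> List[Tensor]:
        ps = list(self.k1)
        for row in self.k2:
            ps.extend(row)
        return ps + self.head.parameters()


@dataclass
class EncoderStack:
    """Weight-sharing encoder f, projector g and predictor h (siamese stack)."""

    f: Callable[[Tensor], Tensor]
    g: Callable[[Tensor], Tensor]
    h: Callable[[Tensor], Tensor]
    out_dim: int = 80

    @classmethod
    def identity(cls, out_dim: int = 2) -> "EncoderStack":
        """Pass-through stack (flattens input); useful as an analytic probe."""
        ident = lambda x: ad.reshape(x if isinstance(x, Tensor) else Tensor(x), (-1,))
        return cls(f=ident, g=lambda x: x, h=lambda x: x, out_dim=out_dim)

    @classmethod
    def small_conv(cls, out_dim: int = 80, n_channels: int = 8, seed: int = 0) -> "EncoderStack":
        rng = np.random.default_rng(seed + 1)
        enc = ConvEncoder(n_channels=n_channels, out_dim=out_dim, seed=seed)
        proj = Linear(out_dim, out_dim, rng)
        pred = Linear(out_dim, out_dim, rng)
        stack = cls(f=enc, g=proj, h=pred, out_dim=out_dim)
        stack._modules = [enc, proj, pred]  # type: ignore[attr-defined]
        return stack

    def parameters(self) -> List[Tensor]:
        ps: List[Tensor] = []
        for m in getattr(self, "_modules", []):
            ps.extend(m.parameters())
        return ps


def simsiam_loss(stack: EncoderStack, view1, view2) -> Tensor:
    """Symmetrized stop-gradient siamese loss of two views of one patch.

    ½·N(h(g(f(v₁))), detach(g(f(v₂)))) + ½·N(h(g(f(v₂))), detach(g(f(v₁))))
    where N is the negative cosine similarity. Detaching one branch per term
    is what prevents representational collapse.
    """
    v1 = view1.data if isinstance(view1, Volume3D) else view1
    v2 = view2.data if isinstance(view2, Volume3D) else view2
    z1 = stack.g(stack.f(Tensor._lift(v1)))
    z2 = stack.g(stack.f(Tensor._lift(v2)))
    p1, p2 = stack.h(z1), stack.h(z2)
    t1 = ad.neg_cosine(p1, z2.detach())
    t2 = ad.neg_cosine(p2, z1.detach())
    return ad.add(ad.mul(t1, 0.5), ad.mul(t2, 0.5))


def embed_patches(vol: Volume3D, grid: PatchGrid, stack: EncoderStack) -> EmbeddingSet:
    """Encode every grid patch with f; rows align with grid order."""
    rows = []
    pd, ph, pw = grid.patch_size
    for (z, y, x) in grid.origins:
        patch = vol.data[z: z + pd, y: y + ph, x: x + pw]
        v = stack.f(Tensor(patch))
        v = v.data if isinstance(v, Tensor) else np.asarray(v, dtype=float)
        rows.append(np.ravel(v))
    vectors = np.stack(rows) if rows else np.zeros((0, stack.out_dim))
    return EmbeddingSet(
        vectors=vectors,
        origins=np.asarray(grid.origins),
        patch_size=grid.patch_size,
        stride=grid.stride,
        volume_shape=grid.volume_shape,
    )


def train_encoder(
    volumes: Sequence[Volume3D],
    stack: EncoderStack,
    cfg: AugmentConfig,
    steps: int,
    rng: np.random.Generator,
    patch_size: Tuple[int, int, int] = (8, 16, 16),
    lr: float = 1e-3,
) -> Tuple[EncoderStack, List[float]]:
    """Siamese pre-training loop: sample a patch, two views, one Adam step.

    Returns the updated stack and the per-step loss trace. Deterministic for
    a fixed ``rng`` state.
    """
    if not volumes:
        raise ValueError("train_encoder requires at least one volume")
    params = stack.parameters()
    opt = ad.Adam(params, lr=lr)
    trace: List[float] = []
    for _ in range(max(0, int(steps))):
        vol = volumes[int(rng.integers(len(volumes)))]
        D, H, W = vol.shape
        pd, ph, pw = patch_size
        z = int(rng.integers(0, D - pd + 1))
        y = int(rng.integers(0, H - ph + 1))
        x = int(rng.integers(0, W - pw + 1))
        patch = Volume3D(vol.data[z: z + pd, y: y + ph, x: x + pw].copy())
        v1, v2 = augment(patch, cfg, rng), augment(patch, cfg, rng)
        loss = simsiam_loss(stack, v1, v2)
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss))
    return stack, trace
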