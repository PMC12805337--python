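"""Synthetic volumes and patch embeddings with the structure the pipeline assumes.

Two generators:

* :func:`synth_instances` — small anisotropic 3D volumes with dense connected
  instance labels (anisotropic nearest-seed tessellation) and an intensity
  model of bright interiors, dark inter-instance faces and Gaussian noise.
  This captures exactly the properties the downstream stages rely on — dense
  labels, boundary contrast, z-anisotropy — with simple verifiable geometry.
* :func:`synth_embeddings` — clustered patch embeddings in which each Gaussian
  cluster occupies one contiguous spatial block of the patch grid, emulating
  the biologically-structured embedding spaces that coverage-based selection
  exploits.

All outputs are reproducible from (spec, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .volumes import InstanceVolume, Volume3D

__all__ = [
    "SynthSpec",
    "SynthEmbeddingSpec",
    "synth_instances",
    "synth_embeddings",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic instance-volume generator.

    anisotropy scales seed distances along z, mimicking the coarse section
    axis of ssEM (e.g. 5 for 30 nm sections at 6 nm in-plane).
    """

    shape: Tuple[int, int, int] = (16, 64, 64)
    n_instances: int = 5
    anisotropy: float = 5.0
    boundary_darkness: float = 0.6
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_instances > int(np.prod(self.shape)):
            raise ValueError("n_instances exceeds voxel count")


@dataclass(frozen=True)
class SynthEmbeddingSpec:
    """Parameters of the clustered-embedding generator.

    ``cluster_separation`` is the ratio of between-center distance to the
    within-cluster standard deviation; blocks are laid out as contiguous
    z-slabs of the patch grid unless ``block_axis`` says otherwise.
    """

    n_clusters: int = 6
    n_per_cluster: int = 128
    dimension: int = 80
    cluster_separation: float = 20.0
    patch_size: Tuple[int, int, int] = (8, 40, 40)
    stride: Tuple[int, int, int] = (8, 40, 40)
    block_shape: Tuple[int, int, int] = (2, 8, 8)  # patches per block (z, y, x)
    block_axis: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_separation <= 0:
            raise ValueError("cluster_separation must be > 0")
        if int(np.prod(self.block_shape)) != self.n_per_cluster:
            raise ValueError("block_shape must contain n_per_cluster patches")

    @property
    def volume_shape(self) -> Tuple[int, int, int]:
        """Shape of the implied parent volume (blocks stacked along block_axis)."""
        counts = list(self.block_shape)
        counts[self.block_axis] *= self.n_clusters
        return tuple(
            self.patch_size[a] + (counts[a] - 1) * self.stride[a] for a in range(3)
        )


def _ensure_connected(ids: np.ndarray, n_instances: int) -> np.ndarray:
    """Repair rare digitization artifacts: make every id one 6-connected blob.

    Minority components of an id are reassigned to the most frequent
    neighboring id until all instances are connected.
    """
    struct = ndimage.generate_binary_structure(3, 1)
    for _ in range(8):
        dirty = False
        for inst in range(1, n_instances + 1):
            comp, n = ndimage.label(ids == inst, structure=struct)
            if n <= 1:
                continue
            dirty = True
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, range(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            for c in range(1, n + 1):
                if c == keep:
                    continue
                region = comp == c
                ring = ndimage.binary_dilation(region, structure=struct) & ~region
                neigh = ids[ring]
                neigh = neigh[neigh != inst]
                if neigh.size == 0:
                    continue
                vals, counts = np.unique(neigh, return_counts=True)
                ids[region] = vals[np.argmax(counts)]
        if not dirty:
            break
    return ids


def synth_instances(spec: SynthSpec) -> Tuple[Volume3D, InstanceVolume]:
    """Generate a (raw, labels) pair by anisotropic nearest-seed tessellation.

    Every voxel is assigned the id (1..n_instances) of its nearest seed under
    a metric that stretches z by ``anisotropy``; intensities are bright in
    instance interiors and darkened on faces between different instances.
    """
    rng = np.random.default_rng(spec.seed)
    D, H, W = spec.shape
    # distinct seed voxels, deterministic order
    flat = rng.choice(D * H * W, size=spec.n_instances, replace=False)
    seeds = np.stack(np.unravel_index(flat, spec.shape), axis=1).astype(np.float64)

    zz, yy, xx = np.meshgrid(
        np.arange(D, dtype=np.float64),
        np.arange(H, dtype=np.float64),
        np.arange(W, dtype=np.float64),
        indexing="ij",
    )
    best = np.full(spec.shape, np.inf)
    ids = np.ones(spec.shape, dtype=np.int64)
    for i, (sz, sy, sx) in enumerate(seeds, start=1):
        d2 = (
            (spec.anisotropy * (zz - sz)) ** 2
            + (yy - sy) ** 2
            + (xx - sx) ** 2
        )
        better = d2 < best  # ties resolve to the smaller id
        ids[better] = i
        best = np.minimum(best, d2)
    ids = _ensure_connected(ids, spec.n_instances)

    # boundary faces: voxel differs from its -1 neighbor along any axis
    boundary = np.zeros(spec.shape, dtype=bool)
    for ax in range(3):
        diff = np.diff(ids, axis=ax) != 0
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(1, None)
        hi[ax] = slice(None, -1)
        boundary[tuple(lo)] |= diff
        boundary[tuple(hi)] |= diff

    intensity = np.full(spec.shape, 0.9)
    intensity[boundary] -= spec.boundary_darkness
    intensity += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    intensity = np.clip(intensity, 0.0, 1.0)
    return Volume3D(intensity), InstanceVolume(ids)


def synth_embeddings(
    spec: SynthEmbeddingSpec,
) -> Tuple["EmbeddingSet", np.ndarray]:
    """Generate clustered embeddings whose clusters tile contiguous blocks.

    Returns an :class:`~coverseg.embedding.EmbeddingSet` whose rows follow the
    z-major raster order of the full patch grid, plus the generating cluster
    label per row. Patch n's cluster is the block its origin falls in, so a
    sub-volume confined to one block holds embeddings of exactly one cluster.
    """
    from .embedding import EmbeddingSet, PatchGrid, partition

    rng = np.random.default_rng(spec.seed)
    vol_shape = spec.volume_shape
    grid = PatchGrid.build(vol_shape, spec.patch_size, spec.stride)
    origins = np.asarray(grid.origins)

    # map each patch to the block (= cluster) along block_axis
    ax = spec.block_axis
    block_extent = spec.block_shape[ax] * spec.stride[ax]
    labels = (origins[:, ax] // block_extent).astype(np.int64)
    assert labels.max() == spec.n_clusters - 1

    centers = rng.normal(0.0, 1.0, size=(spec.n_clusters, spec.dimension))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= spec.cluster_separation / np.sqrt(2.0)  # pairwise ≈ separation
    vectors = centers[labels] + rng.normal(0.0, 1.0, size=(len(labels), spec.dimension))
    emb = EmbeddingSet(
        vectors=vectors,
        origins=origins,
        patch_size=spec.patch_size,
        stride=spec.stride,
        volume_shape=vol_shape,
    )
    return emb, labels
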