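"""Affinity-graph boundary representation and a minimal post-processor.

An affinity graph encodes, per voxel, whether it belongs to the same
instance as its nearest preceding neighbor along each of the z, x and y
axes (1 = same neuron, 0 = boundary). Ground-truth graphs derived from
dense instance labels are binary; network predictions live in [0, 1].

Conventions (declared defaults): the affinity at voxel p and channel c
refers to the voxel pair (p, p − e_axis); the first plane along each axis
has no predecessor and gets 0; any pair touching the ignore id 0 gets 0.
Channel order is (z, x, y).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .volumes import InstanceVolume

__all__ = ["AffinityGraph", "labels_to_affinity", "affinity_to_segmentation", "CHANNEL_AXES"]

# channel c refers to the neighbor at offset -1 along CHANNEL_AXES[c]
CHANNEL_AXES: Tuple[int, int, int] = (0, 2, 1)  # channels ordered (z, x, y)


@dataclass
class AffinityGraph:
    """3-channel per-voxel neighbor connectivity, shape (3, D, H, W)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4 or self.values.shape[0] != 3:
            raise ValueError(
                f"AffinityGraph requires shape (3, D, H, W), got {self.values.shape}"
            )
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("affinities must lie in [0, 1]")

    @property
    def shape(self) -> Tuple[int, int, int, int]:
        return self.values.shape

    @property
    def volume_shape(self) -> Tuple[int, int, int]:
        return self.values.shape[1:]


def labels_to_affinity(labels: InstanceVolume) -> AffinityGraph:
    """Derive the binary ground-truth affinity graph from instance labels."""
    ids = labels.ids
    aff = np.zeros((3,) + ids.shape, dtype=np.float64)
    for c, ax in enumerate(CHANNEL_AXES):
        same = np.take(ids, range(1, ids.shape[ax]), axis=ax) == np.take(
            ids, range(0, ids.shape[ax] - 1), axis=ax
        )
        fg = (np.take(ids, range(1, ids.shape[ax]), axis=ax) != 0) & (
            np.take(ids, range(0, ids.shape[ax] - 1), axis=ax) != 0
        )
        sl = [slice(None)] * 3
        sl[ax] = slice(1, None)
        aff[(c,) + tuple(sl)] = (same & fg).astype(np.float64)
    return AffinityGraph(aff)


def affinity_to_segmentation(
    aff: AffinityGraph, threshold: float = 0.5
) -> InstanceVolume:
    """Threshold-and-connected-components plumbing from affinities to instances.

    Voxels joined by an edge with affinity >= threshold form one component;
    components are labeled 1..n by the raster order of their first voxel.
    This is a demo post-processor, not a watershed/agglomeration replacement.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    shape = aff.volume_shape
    n = int(np.prod(shape))
    flat = np.arange(n).reshape(shape)
    rows, cols = [], []
    for c, ax in enumerate(CHANNEL_AXES):
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        on = aff.values[(c,) + tuple(sl_hi)] >= threshold
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        rows.append(flat[tuple(sl_hi)][on])
        cols.append(flat[tuple(sl_lo)][on])
    r = np.concatenate(rows) if rows else np.array([], dtype=int)
    c_ = np.concatenate(cols) if cols else np.array([], dtype=int)
    adj = coo_matrix((np.ones(len(r)), (r, c_)), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    # relabel so component ids follow first-voxel raster order, starting at 1
    n_comp = int(comp.max()) + 1
    first_idx = np.full(n_comp, n, dtype=np.int64)
    np.minimum.at(first_idx, comp, np.arange(n))
    order = np.empty(n_comp, dtype=np.int64)
    order[np.argsort(first_idx, kind="stable")] = np.arange(1, n_comp + 1)
    return InstanceVolume(order[comp].reshape(shape))
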