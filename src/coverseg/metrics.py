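"""Variation of information and adapted Rand error for instance segmentations.

Both metrics are computed from the joint contingency table of a proposal
segmentation A against a ground truth T:

* ``VI = VI_split + VI_merge = H(A|T) + H(T|A)`` — the conditional entropies
  quantify over-segmentation (split) and under-segmentation (merge) errors;
* ``ARAND = 1 − 2·Σ_ij p_ij² / (Σ_i a_i² + Σ_j b_j²)`` with a_i, b_j the
  marginals of p — one minus the F-score of same-segment voxel-pair
  agreement.

Ground-truth id 0 marks unannotated (ignore) voxels — e.g. myelin in
cortical EM ground truth — and is excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import sparse

from .volumes import InstanceVolume

__all__ = ["ContingencyTable", "MetricResult", "contingency", "vi", "arand", "evaluate"]


@dataclass
class ContingencyTable:
    """Sparse joint voxel counts n_ij of proposal segment i vs truth segment j."""

    counts: sparse.csr_matrix
    n: int
    seg_ids: np.ndarray
    gt_ids: np.ndarray

    @property
    def p(self) -> sparse.csr_matrix:
        return self.counts / self.n

    @property
    def row_marginals(self) -> np.ndarray:
        """Proposal segment probabilities a_i."""
        return np.asarray(self.counts.sum(axis=1)).ravel() / self.n

    @property
    def col_marginals(self) -> np.ndarray:
        """Ground-truth segment probabilities b_j."""
        return np.asarray(self.counts.sum(axis=0)).ravel() / self.n


@dataclass
class MetricResult:
    vi_split: float
    vi_merge: float
    vi: float
    arand: float
    n_voxels: int
    log_base: str = "e"


def contingency(
    seg: InstanceVolume, gt: InstanceVolume, ignore_zero_gt: bool = True
) -> ContingencyTable:
    """Joint segment counts; voxels with gt id 0 are dropped when flagged."""
    if seg.shape != gt.shape:
        raise ValueError("segmentation and ground truth must share a shape")
    s, t = seg.ids.ravel(), gt.ids.ravel()
    if ignore_zero_gt:
        keep = t != 0
        s, t = s[keep], t[keep]
    if s.size == 0:
        raise ValueError("no evaluable voxels (ground truth entirely ignored)")
    seg_ids, si = np.unique(s, return_inverse=True)
    gt_ids, ti = np.unique(t, return_inverse=True)
    counts = sparse.coo_matrix(
        (np.ones(s.size), (si, ti)), shape=(len(seg_ids), len(gt_ids))
    ).tocsr()
    return ContingencyTable(counts, int(s.size), seg_ids, gt_ids)


def _log(x: np.ndarray, base: str) -> np.ndarray:
    lx = np.log(x)
    if base == "2":
        lx = lx / np.log(2.0)
    elif base != "e":
        raise ValueError("log_base must be 'e' or '2'")
    return lx


def vi(table: ContingencyTable, log_base: str = "e") -> Tuple[float, float, float]:
    """Split/merge decomposition of the variation of information.

    Returns (vi_split, vi_merge, vi) with vi_split = H(A|T) and
    vi_merge = H(T|A).
    """
    p = table.p.tocoo()
    pij = np.asarray(p.data)
    a = table.row_marginals  # proposal A
    b = table.col_marginals  # truth T
    # H(A|T) = -sum_ij p_ij log(p_ij / b_j); H(T|A) = -sum_ij p_ij log(p_ij / a_i)
    h_a_given_t = -float(np.sum(pij * _log(pij / b[p.col], log_base)))
    h_t_given_a = -float(np.sum(pij * _log(pij / a[p.row], log_base)))
    h_a_given_t = max(h_a_given_t, 0.0)
    h_t_given_a = max(h_t_given_a, 0.0)
    return h_a_given_t, h_t_given_a, h_a_given_t + h_t_given_a


def arand(table: ContingencyTable) -> float:
    """Adapted Rand error: 1 minus the Rand F-score of the partition pair."""
    pij2 = float(np.sum(np.asarray(table.p.data) ** 2))
    a2 = float(np.sum(table.row_marginals ** 2))
    b2 = float(np.sum(table.col_marginals ** 2))
    return 1.0 - 2.0 * pij2 / (a2 + b2)


def evaluate(
    seg: InstanceVolume,
    gt: InstanceVolume,
    ignore_zero_gt: bool = True,
    log_base: str = "e",
) -> MetricResult:
    """Compute VI (split/merge/total) and ARAND for a proposal vs ground truth."""
    table = contingency(seg, gt, ignore_zero_gt=ignore_zero_gt)
    s, m, tot = vi(table, log_base=log_base)
    return MetricResult(
        vi_split=s, vi_merge=m, vi=tot, arand=arand(table),
        n_voxels=table.n, log_base=log_base,
    )
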