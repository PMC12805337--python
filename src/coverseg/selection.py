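"""Coverage-based selective labeling of EM sub-volumes.

Given the universal set U of patch embeddings of an unlabeled volume, each
vector semantically "covers" its K nearest neighbors in U. The constrained
coverage rate

    CCR(S, U) = |C(S, U)| / |U|,   C(S, U) = ∪_{v ∈ S} V(v, U),

measures how representative a selected set S is of the whole distribution.
Coverage-based greedy selection (CGS) spends an annotation budget of
sub-volumes one at a time, committing at every step the candidate window
whose member patches yield the largest CCR(subset ∪ S, U) — a linear-time
surrogate for the intractable exhaustive search, with the usual (1 − 1/e)
guarantee of monotone submodular maximization.

Variants: a fixed-radius coverage function (CGS_FD) and negative-cosine
similarity instead of Euclidean distance (CGS_CS), plus random and
equispaced sub-volume baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .embedding import EmbeddingSet, PatchGrid
from .volumes import SubVolumeSpec

__all__ = [
    "CoverageIndex",
    "SelectionResult",
    "build_index",
    "covered",
    "ccr",
    "enumerate_candidates",
    "cgs",
    "cgs_fixed_distance",
    "random_select",
    "equispaced_select",
]

DEFAULT_K = 30


@dataclass
class CoverageIndex:
    """Exact K-nearest-neighbor table over U (self always included).

    ``neighbor_table[n]`` holds the indices of the K nearest vectors to
    v_n, ties broken by smaller index; with the ``neg_cosine`` metric the
    distance is the negative cosine similarity. ``neighbor_lists`` is the
    general form used by the fixed-radius variant, where rows may have
    variable cardinality.
    """

    neighbor_lists: List[np.ndarray]
    n: int
    metric: str
    k: Optional[int] = None
    radius: Optional[float] = None

    @property
    def neighbor_table(self) -> np.ndarray:
        if self.k is None:
            raise ValueError("index was built with a fixed radius, not K")
        return np.stack(self.neighbor_lists)


def _pairwise_distances(vectors: np.ndarray, metric: str, rows: slice) -> np.ndarray:
    x = vectors[rows]
    if metric == "euclidean":
        d2 = (
            np.sum(x * x, axis=1)[:, None]
            + np.sum(vectors * vectors, axis=1)[None, :]
            - 2.0 * x @ vectors.T
        )
        return np.sqrt(np.maximum(d2, 0.0))
    if metric == "neg_cosine":
        norms = np.linalg.norm(vectors, axis=1)
        if np.any(norms == 0):
            raise ValueError("neg_cosine metric requires nonzero embeddings")
        sim = (x @ vectors.T) / (norms[rows][:, None] * norms[None, :])
        return -sim
    raise ValueError(f"unsupported metric {metric!r}")


def build_index(
    U: EmbeddingSet,
    k: int = DEFAULT_K,
    metric: str = "euclidean",
    chunk: int = 1024,
) -> CoverageIndex:
    """Exact KNN table; ties broken deterministically by smaller index."""
    n = len(U)
    if not 1 <= k <= n:
        raise ValueError(f"K must satisfy 1 <= K <= N, got K={k}, N={n}")
    rows: List[np.ndarray] = []
    idx = np.arange(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        d = _pairwise_distances(U.vectors, metric, sl)
        for r in range(d.shape[0]):
            order = np.lexsort((idx, d[r]))  # distance, then index
            rows.append(order[:k].astype(np.int64))
    return CoverageIndex(rows, n=n, metric=metric, k=k)


def build_radius_index(
    U: EmbeddingSet, radius: float, metric: str = "euclidean", chunk: int = 1024
) -> CoverageIndex:
    """Fixed-distance coverage: V(v, U) = {u : d(u, v) <= radius}."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n = len(U)
    rows: List[np.ndarray] = []
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        d = _pairwise_distances(U.vectors, metric, sl)
        for r in range(d.shape[0]):
            rows.append(np.flatnonzero(d[r] <= radius).astype(np.int64))
    return CoverageIndex(rows, n=n, metric=metric, radius=radius)


def covered(S_rows: Iterable[int], index: CoverageIndex) -> np.ndarray:
    """Boolean mask over U: true where some member of S covers the vector."""
    mask = np.zeros(index.n, dtype=bool)
    for r in S_rows:
        mask[index.neighbor_lists[int(r)]] = True
    return mask


def ccr(S_rows: Iterable[int], index: CoverageIndex) -> float:
    """Constrained coverage rate |C(S, U)| / |U| in [0, 1]."""
    return float(covered(S_rows, index).sum()) / index.n


@dataclass
class SelectionResult:
    """Ordered chosen sub-volumes with the CCR trajectory of the greedy run."""

    chosen: List[SubVolumeSpec]
    chosen_patch_indices: List[np.ndarray]
    ccr_trace: List[float]
    covered_mask: np.ndarray

    @property
    def final_ccr(self) -> float:
        return self.ccr_trace[-1] if self.ccr_trace else 0.0


def enumerate_candidates(
    grid: PatchGrid,
    subvol_size: Tuple[int, int, int],
    scan_stride: Optional[Tuple[int, int, int]] = None,
    exclusions: Sequence[SubVolumeSpec] = (),
) -> List[Tuple[SubVolumeSpec, np.ndarray]]:
    """All candidate windows with their member patch rows.

    A member is a patch whose full extent lies inside the candidate window;
    candidates overlapping any exclusion window are dropped. The scan
    stride defaults to the patch stride so candidates align with the grid.
    """
    if any(sv < p for sv, p in zip(subvol_size, grid.patch_size)):
        raise ValueError("sub-volume size must be at least the patch size")
    scan_stride = tuple(scan_stride or grid.stride)
    if any(s < 1 for s in scan_stride):
        raise ValueError("scan stride must be >= 1 per axis")
    shape = grid.volume_shape
    origins = np.asarray(grid.origins)
    p = np.asarray(grid.patch_size)
    out: List[Tuple[SubVolumeSpec, np.ndarray]] = []
    axes = [
        range(0, shape[a] - subvol_size[a] + 1, scan_stride[a]) for a in range(3)
    ]
    for z in axes[0]:
        for y in axes[1]:
            for x in axes[2]:
                spec = SubVolumeSpec((z, y, x), tuple(subvol_size))
                if any(spec.overlaps(e) for e in exclusions):
                    continue
                lo = np.array([z, y, x])
                hi = lo + np.asarray(subvol_size)
                inside = np.all((origins >= lo) & (origins + p <= hi), axis=1)
                out.append((spec, np.flatnonzero(inside)))
    return out


def _greedy(
    U: EmbeddingSet,
    grid: PatchGrid,
    sizes: Sequence[Tuple[int, int, int]],
    index: CoverageIndex,
    scan_stride: Optional[Tuple[int, int, int]],
) -> SelectionResult:
    chosen: List[SubVolumeSpec] = []
    chosen_rows: List[np.ndarray] = []
    trace: List[float] = []
    mask = np.zeros(index.n, dtype=bool)
    for size in sizes:
        candidates = enumerate_candidates(grid, size, scan_stride, exclusions=chosen)
        if not candidates:
            raise RuntimeError(
                f"no feasible candidate of size {tuple(size)} (space exhausted)"
            )
        best_gain = -1
        best: Optional[Tuple[SubVolumeSpec, np.ndarray, np.ndarray]] = None
        for spec, members in candidates:
            # incremental update: union the members' coverage into a trial mask
            new = np.zeros(index.n, dtype=bool)
            for m in members:
                new[index.neighbor_lists[int(m)]] = True
            gain = int(np.count_nonzero(new & ~mask))
            if gain > best_gain:  # strict: earlier (lexicographic) origin wins ties
                best_gain = gain
                best = (spec, members, new)
        assert best is not None
        spec, members, new = best
        mask |= new
        chosen.append(spec)
        chosen_rows.append(members)
        trace.append(float(mask.sum()) / index.n)
    return SelectionResult(chosen, chosen_rows, trace, mask)


def cgs(
    U: EmbeddingSet,
    grid: PatchGrid,
    sizes: Sequence[Tuple[int, int, int]],
    k: int = DEFAULT_K,
    metric: str = "euclidean",
    scan_stride: Optional[Tuple[int, int, int]] = None,
    index: Optional[CoverageIndex] = None,
) -> SelectionResult:
    """Coverage-based greedy selection over an annotation budget of sizes.

    Candidates are enumerated in lexicographic (z, y, x) origin order and
    ties in coverage gain resolve to the earliest candidate; selected
    windows never spatially overlap. Pass ``metric='neg_cosine'`` for the
    cosine-similarity variant.
    """
    index = index or build_index(U, k=k, metric=metric)
    return _greedy(U, grid, sizes, index, scan_stride)


def cgs_fixed_distance(
    U: EmbeddingSet,
    grid: PatchGrid,
    sizes: Sequence[Tuple[int, int, int]],
    radius: float,
    metric: str = "euclidean",
    scan_stride: Optional[Tuple[int, int, int]] = None,
) -> SelectionResult:
    """CGS with fixed-radius coverage sets instead of K nearest neighbors."""
    index = build_radius_index(U, radius=radius, metric=metric)
    return _greedy(U, grid, sizes, index, scan_stride)


def _result_from_specs(
    specs: List[SubVolumeSpec],
    candidates_per_size: List[List[Tuple[SubVolumeSpec, np.ndarray]]],
    index: Optional[CoverageIndex],
    n: int,
) -> SelectionResult:
    rows: List[np.ndarray] = []
    for spec, cands in zip(specs, candidates_per_size):
        members = next(m for s, m in cands if s == spec)
        rows.append(members)
    mask = np.zeros(n, dtype=bool)
    trace: List[float] = []
    for members in rows:
        if index is not None:
            for m in members:
                mask[index.neighbor_lists[int(m)]] = True
            trace.append(float(mask.sum()) / n)
        else:
            trace.append(0.0)
    return SelectionResult(specs, rows, trace, mask)


def random_select(
    grid: PatchGrid,
    sizes: Sequence[Tuple[int, int, int]],
    seed: int,
    scan_stride: Optional[Tuple[int, int, int]] = None,
    index: Optional[CoverageIndex] = None,
) -> SelectionResult:
    """Uniform non-overlapping draws from the candidate lattice (Random_V)."""
    rng = np.random.default_rng(seed)
    chosen: List[SubVolumeSpec] = []
    per_size: List[List[Tuple[SubVolumeSpec, np.ndarray]]] = []
    for size in sizes:
        cands = enumerate_candidates(grid, size, scan_stride, exclusions=chosen)
        if not cands:
            raise RuntimeError("no feasible non-overlapping random candidate")
        pick = cands[int(rng.integers(len(cands)))]
        chosen.append(pick[0])
        per_size.append(cands)
    n = index.n if index is not None else len(grid)
    return _result_from_specs(chosen, per_size, index, n)


def equispaced_select(
    grid: PatchGrid,
    sizes: Sequence[Tuple[int, int, int]],
    scan_stride: Optional[Tuple[int, int, int]] = None,
    index: Optional[CoverageIndex] = None,
) -> SelectionResult:
    """Sub-volumes on a maximally even lattice across the volume (Equispaced_V).

    All sizes must be equal. Per-axis counts are grown greedily on the axis
    with the most candidate positions until the lattice holds the budget;
    positions are then spread evenly over the feasible range per axis.
    """
    sizes = [tuple(s) for s in sizes]
    if len(set(sizes)) != 1:
        raise ValueError("equispaced selection requires a single sub-volume size")
    size = sizes[0]
    budget = len(sizes)
    shape = grid.volume_shape
    avail = [
        len(range(0, shape[a] - size[a] + 1, (scan_stride or grid.stride)[a]))
        for a in range(3)
    ]
    counts = [1, 1, 1]
    while int(np.prod(counts)) < budget:
        # grow the axis with the largest remaining headroom
        head = [avail[a] / counts[a] for a in range(3)]
        a = int(np.argmax(head))
        if counts[a] >= avail[a]:
            raise RuntimeError("budget exceeds the equispaced lattice capacity")
        counts[a] += 1
    positions = []
    for a in range(3):
        span = shape[a] - size[a]
        if counts[a] == 1:
            positions.append([0])
        else:
            positions.append(
                [round(i * span / (counts[a] - 1)) for i in range(counts[a])]
            )
    lattice = [
        SubVolumeSpec((z, y, x), size)
        for z in positions[0]
        for y in positions[1]
        for x in positions[2]
    ][:budget]
    origins = np.asarray(grid.origins)
    p = np.asarray(grid.patch_size)
    rows = []
    for s in lattice:
        lo = np.asarray(s.origin)
        hi = lo + np.asarray(s.size)
        rows.append(np.flatnonzero(np.all((origins >= lo) & (origins + p <= hi), axis=1)))
    n = index.n if index is not None else len(grid)
    mask = np.zeros(n, dtype=bool)
    trace: List[float] = []
    for members in rows:
        if index is not None:
            for m in members:
                mask[index.neighbor_lists[int(m)]] = True
            trace.append(float(mask.sum()) / n)
        else:
            trace.append(0.0)
    return SelectionResult(lattice, rows, trace, mask)
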