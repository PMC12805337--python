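"""End-to-end orchestration: synth → embed → select → annotate → train → evaluate.

A single top-level seed drives every stage through spawned sub-seeds, all
recorded in the report, so any intermediate artifact can be regenerated
bit-identically. The demo configuration runs entirely on synthetic inputs:
clustered embeddings with a known cluster-to-block layout for selection,
and a tessellated instance volume for training and evaluation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .affinity import affinity_to_segmentation, labels_to_affinity
from .embedding import PatchGrid
from .metrics import evaluate
from .selection import build_index, cgs, random_select
from .semi import TinyAffinityNet, TrainConfig, train_semi
from .synth import SynthEmbeddingSpec, SynthSpec, synth_embeddings, synth_instances
from .volumes import SubVolumeSpec, crop

logger = logging.getLogger("coverseg")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of the synthetic end-to-end demo pipeline.

    Selection defaults mirror the reference setup: stride 8×40×40, K = 30,
    L = 80, λ = 0.2. The synthetic embedding layout (6 clusters in 6
    spatial blocks) is the recovery scenario coverage selection is designed
    for.
    """

    seed: int = 0
    # selection stage
    n_clusters: int = 6
    n_per_cluster: int = 128
    embedding_dim: int = 80
    k: int = 30
    metric: str = "euclidean"
    subvol_size: Tuple[int, int, int] = (16, 320, 160)
    scan_stride: Tuple[int, int, int] = (16, 40, 40)  # aligned to sub-volume depth
    budget: int = 6
    n_random_baselines: int = 4
    # training stage
    volume_spec: SynthSpec = field(
        default_factory=lambda: SynthSpec(shape=(24, 64, 64), n_instances=6)
    )
    train: TrainConfig = field(default_factory=lambda: TrainConfig(steps=60, warmup_steps=20, learning_rate=5e-3))
    n_train_volumes: int = 2
    segment_threshold: float = 0.5


def run_pipeline(config: PipelineConfig, out_dir: Optional[Path] = None) -> dict:
    """Execute every stage in order and return (and optionally write) a report."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    report: dict = {"seed": config.seed, "stage_seeds": seeds}

    # --- stage 1: synthetic embeddings with a known block layout -----------
    espec = SynthEmbeddingSpec(
        n_clusters=config.n_clusters,
        n_per_cluster=config.n_per_cluster,
        dimension=config.embedding_dim,
        seed=seeds[0],
    )
    emb, clusters = synth_embeddings(espec)
    grid = PatchGrid.build(espec.volume_shape, espec.patch_size, espec.stride)
    logger.info("embeddings: N=%d, L=%d, volume=%s", len(emb), emb.dimension, espec.volume_shape)

    # --- stage 2: coverage-based greedy selection vs random baseline ------
    index = build_index(emb, k=config.k, metric=config.metric)
    sizes = [config.subvol_size] * config.budget
    scan = config.scan_stride
    sel = cgs(emb, grid, sizes, index=index, scan_stride=scan)
    random_ccrs = [
        random_select(grid, sizes, seed=seeds[1] + r, scan_stride=scan, index=index).final_ccr
        for r in range(config.n_random_baselines)
    ]
    report["selection"] = {
        "ccr_trace": sel.ccr_trace,
        "final_ccr": sel.final_ccr,
        "chosen": [{"origin": list(s.origin), "size": list(s.size)} for s in sel.chosen],
        "random_baseline_ccrs": random_ccrs,
        "random_baseline_mean": float(np.mean(random_ccrs)),
    }
    logger.info("CGS final CCR %.4f vs random mean %.4f", sel.final_ccr, np.mean(random_ccrs))

    # --- stage 3: synthetic volumes; annotate the selected region ----------
    vols = []
    for i in range(config.n_train_volumes):
        vspec = SynthSpec(
            shape=config.volume_spec.shape,
            n_instances=config.volume_spec.n_instances,
            anisotropy=config.volume_spec.anisotropy,
            boundary_darkness=config.volume_spec.boundary_darkness,
            noise_sd=config.volume_spec.noise_sd,
            seed=seeds[2] + i,
        )
        vols.append(synth_instances(vspec))
    test_raw, test_labels = synth_instances(
        SynthSpec(shape=config.volume_spec.shape, n_instances=config.volume_spec.n_instances,
                  anisotropy=config.volume_spec.anisotropy, seed=seeds[3])
    )
    labeled = [(raw, labels_to_affinity(lab)) for raw, lab in vols[: max(1, len(vols) // 2)]]
    unlabeled = [raw for raw, _ in vols[max(1, len(vols) // 2):]]

    # --- stage 4: semi-supervised training ---------------------------------
    model = TinyAffinityNet(seed=seeds[4])
    model, trace = train_semi(model, labeled, unlabeled, config.train, np.random.default_rng(seeds[5]))
    report["training"] = {
        "steps": config.train.steps,
        "warmup_steps": config.train.warmup_steps,
        "intra_l_trace": [b.intra_l for b in trace],
        "total_trace": [b.total for b in trace],
    }

    # --- stage 5: segment the test volume and evaluate ----------------------
    pred = model(test_raw)
    pred = pred.data if hasattr(pred, "data") else np.asarray(pred)
    from .affinity import AffinityGraph

    seg = affinity_to_segmentation(AffinityGraph(np.clip(pred, 0, 1)), config.segment_threshold)
    res = evaluate(seg, test_labels, ignore_zero_gt=False)
    report["evaluation"] = {
        "vi_split": res.vi_split, "vi_merge": res.vi_merge,
        "vi": res.vi, "arand": res.arand, "n_voxels": res.n_voxels,
    }
    logger.info("test VI %.4f (split %.4f merge %.4f) ARAND %.4f",
                res.vi, res.vi_split, res.vi_merge, res.arand)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
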