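"""Reproducible synthetic-data experiments: the package's own benchmarks.

Two self-contained studies, both fully seeded:

* :func:`oracle_roundtrip` feeds perfect one-hot probability maps of
  generated cores straight into the post-processing stack, bypassing the
  network.  On this input every duct and every ring must be recovered,
  so the run measures the correctness of thresholding, shape filtering,
  watershed, merging and measurement in isolation.

* :func:`scaled_down_benchmark` exercises the full pipeline end to end
  at desk scale: it trains the attention U-Net on patches sampled from a
  handful of synthetic cores and scores duct and ring-boundary detection
  on held-out cores at the object level.
"""

from __future__ import annotations

import numpy as np

from ductseg.config import PipelineConfig
from ductseg.evaluation import (DetectionCounts, boundary_truth_labels,
                                duct_truth_labels, match, precision, sensitivity)
from ductseg.metrics import ScanScale, measure_all
from ductseg.nn import ModelConfig, TrainConfig, build_model, sample_patches, train
from ductseg.pipeline import postprocess_maps, run_pipeline
from ductseg.rings import ring_boundary_masks
from ductseg.synthetic import generate_core, one_hot_maps, random_core_spec, rasterize

__all__ = ["oracle_roundtrip", "scaled_down_benchmark"]


def _sum_counts(counts: list[DetectionCounts]) -> DetectionCounts:
    return DetectionCounts(tp=sum(c.tp for c in counts),
                           fn=sum(c.fn for c in counts),
                           fp=sum(c.fp for c in counts))


def _make_core(seed: int, n_rings: int, height_px: int, width_range: tuple[int, int]):
    spec = random_core_spec(seed, n_rings=n_rings, height_px=height_px,
                            ring_width_range_px=width_range)
    image, gt = generate_core(spec)
    mask = rasterize(gt, image.shape[:2])
    return image, mask, gt


def oracle_roundtrip(
    seed: int = 0,
    n_cores: int = 20,
    n_rings: int = 4,
    height_px: int = 150,
    width_range: tuple[int, int] = (60, 180),
    cfg: PipelineConfig = PipelineConfig(),
) -> dict:
    """Post-processing on perfect probability maps across many seeded cores.

    Returns aggregate duct detection counts and SEN/PREC, the number of
    cores whose ring count was recovered exactly, and the worst ring
    width error in pixel units.
    """
    duct_counts = []
    ring_exact = 0
    max_width_err_px = 0.0
    max_coverage_err = 0.0
    scale = ScanScale(cfg.dpi)
    for i in range(n_cores):
        _, mask, gt = _make_core(seed + i, n_rings, height_px, width_range)
        maps = one_hot_maps(mask)
        ducts, rings = postprocess_maps(maps, cfg)
        duct_counts.append(match(ducts.labels, duct_truth_labels(gt, mask.shape)))
        ring_exact += int(rings.max()) == len(gt.ring_extents)
        records = measure_all(rings, ducts.support, scale)
        for rec, (lo, hi) in zip(records, gt.ring_extents):
            err_px = abs(rec.width_mm / scale.mm_per_px - (hi - lo))
            max_width_err_px = max(max_width_err_px, err_px)
            ring_mask = rings == rec.ring_id
            geometric = float((ring_mask & ducts.support).sum()) / float(ring_mask.sum())
            max_coverage_err = max(max_coverage_err, abs(rec.duct_coverage - geometric))
    counts = _sum_counts(duct_counts)
    return {
        "n_cores": n_cores,
        "duct_counts": counts,
        "duct_sen": sensitivity(counts),
        "duct_prec": precision(counts),
        "ring_count_exact_cores": ring_exact,
        "max_width_err_px": max_width_err_px,
        "max_coverage_err": max_coverage_err,
    }


def scaled_down_benchmark(
    seed: int = 1,
    n_train_cores: int = 5,
    n_test_cores: int = 2,
    patches_per_core: int = 40,
    n_rings: int = 5,
    height_px: int = 160,
    width_range: tuple[int, int] = (60, 140),
    max_epochs: int = 40,
    patience: int = 10,
    batch_size: int = 16,
) -> dict:
    """Train the network at desk scale and score held-out synthetic cores.

    About 200 training patches from 5 cores, early stopping with
    patience 10, then object-level duct and ring-boundary SEN/PREC on
    held-out cores.  All randomness derives from ``seed``.
    """
    tcfg = TrainConfig(patches_per_image=patches_per_core, max_epochs=max_epochs,
                       patience=patience, batch_size=batch_size, seed=seed)
    train_cores = [_make_core(100 + seed * 10 + i, n_rings, height_px, width_range)
                   for i in range(n_train_cores)]
    test_cores = [_make_core(200 + seed * 10 + i, n_rings, height_px, width_range)
                  for i in range(n_test_cores)]

    rng = np.random.default_rng(seed)
    pairs = []
    for image, mask, _ in train_cores:
        pairs.extend(sample_patches(image, mask, tcfg, rng))
    model = build_model(ModelConfig(seed=seed))
    model, history = train(model, pairs, tcfg)

    cfg = PipelineConfig(seed=seed)
    duct_counts, ring_counts = [], []
    for image, _, gt in test_cores:
        result = run_pipeline(model, image, cfg)
        shape = image.shape[:2]
        duct_counts.append(match(result.ducts.labels, duct_truth_labels(gt, shape)))
        ring_counts.append(match(ring_boundary_masks(result.rings),
                                 boundary_truth_labels(gt, shape)))
    dc, rc = _sum_counts(duct_counts), _sum_counts(ring_counts)
    return {
        "n_patches": len(pairs),
        "epochs_run": len(history["val_loss"]),
        "best_val_loss": min(history["val_loss"]),
        "duct_counts": dc,
        "duct_sen": sensitivity(dc),
        "duct_prec": precision(dc),
        "ring_counts": rc,
        "ring_sen": sensitivity(rc),
        "ring_prec": precision(rc),
    }
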