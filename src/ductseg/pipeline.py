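"""End-to-end orchestration: image -> probability maps -> ducts, rings, records."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ductseg.config import PipelineConfig
from ductseg.ducts import DuctLabelMap, detect_ducts
from ductseg.inference import predict_full
from ductseg.metrics import RingRecord, ScanScale, measure_all
from ductseg.rings import segment_rings

__all__ = ["PipelineResult", "postprocess_maps", "run_pipeline"]

#: probability channel order everywhere in the package
CH_RING, CH_DUCT, CH_BACKGROUND = 0, 1, 2


@dataclass
class PipelineResult:
    maps: np.ndarray            # (H, W, 3) probabilities (ring, duct, background)
    ducts: DuctLabelMap
    rings: np.ndarray           # (H, W) ring labels 1..K
    records: list[RingRecord]


def postprocess_maps(maps: np.ndarray, cfg: PipelineConfig = PipelineConfig()
                     ) -> tuple[DuctLabelMap, np.ndarray]:
    """Probability maps -> (duct label map, ring label map)."""
    ducts = detect_ducts(maps[..., CH_DUCT], cfg.duct_window, cfg.duct_offset,
                         cfg.circularity_threshold, cfg.area_fraction)
    rings = segment_rings(maps[..., CH_RING], cfg.ring_window, cfg.merge_min_area)
    return ducts, rings


def run_pipeline(model, image: np.ndarray,
                 cfg: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full chain on one core image with a trained model."""
    maps = predict_full(model, image, window=cfg.patch_size, stride=cfg.stride)
    ducts, rings = postprocess_maps(maps, cfg)
    records = measure_all(rings, ducts.support, ScanScale(cfg.dpi))
    return PipelineResult(maps=maps, ducts=ducts, rings=rings, records=records)
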