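import numpy as np
import pytest

import ductseg as ds


@pytest.fixture(scope="session")
def small_core():
    """One deterministic small synthetic core with all derived rasters."""
    spec = ds.CoreSpec(
        height_px=128,
        ring_widths_px=(100, 150, 200),
        duct_count_per_ring=(2, 3, 2),
        seed=7,
    )
    image, gt = ds.generate_core(spec)
    mask = ds.rasterize(gt, image.shape[:2])
    maps = ds.one_hot_maps(mask)
    return spec, image, gt, mask, maps


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained network for cheap structural checks."""
    return ds.build_model(ds.ModelConfig(input_size=32, depth=2, base_filters=2, seed=0))
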