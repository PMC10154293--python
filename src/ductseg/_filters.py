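"""Shared raster filters."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def local_mean(raster: np.ndarray, window: int) -> np.ndarray:
    """Mean over a window x window neighbourhood, restricted to the image.

    Near the borders the window shrinks to its in-image part, so no
    padding value can bias the estimate in the thin margins of a core.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    h, w = raster.shape
    if window > h or window > w:
        raise ValueError(f"window {window} larger than image {h}x{w}")
    x = raster.astype(np.float64)
    total = ndi.uniform_filter(x, size=window, mode="constant", cval=0.0) * window**2
    ones = np.ones_like(x)
    count = ndi.uniform_filter(ones, size=window, mode="constant", cval=0.0) * window**2
    return total / count
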