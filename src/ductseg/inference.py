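"""Seamless whole-core prediction by overlapping sliding-window tiling.

Core scans are far too wide for the fixed 128 px network input, so the
trained model is slid across the image in 128x128 tiles that overlap by
a 20 px stride in both directions; the per-pixel class probabilities of
all tiles covering a pixel are averaged.  Averaging normalised vectors
keeps the per-pixel probability sum at one, and the dense overlap hides
tile seams.

Images shorter or narrower than one window are reflection-padded up to
the window size and the padding is cropped from the output.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["predict_full", "tile_anchors", "coverage_counts"]

#: model signature: (N, win, win, C) float batch -> (N, win, win, classes)
TileModel = Callable[[np.ndarray], np.ndarray]


def tile_anchors(extent: int, window: int, stride: int) -> list[int]:
    """Anchor offsets covering [0, extent): multiples of the stride plus a
    final anchor flush with the far edge so the last pixels are covered."""
    if stride <= 0 or stride > window:
        raise ValueError(f"stride must be in (0, window]; got {stride}")
    if extent < window:
        raise ValueError(f"extent {extent} smaller than window {window}")
    anchors = list(range(0, extent - window + 1, stride))
    if anchors[-1] != extent - window:
        anchors.append(extent - window)
    return anchors


def coverage_counts(shape: tuple[int, int], window: int, stride: int) -> np.ndarray:
    """Per-pixel count of tiles covering each pixel of the tiling grid."""
    h, w = shape
    cnt = np.zeros((h, w), dtype=np.int64)
    for r in tile_anchors(h, window, stride):
        for c in tile_anchors(w, window, stride):
            cnt[r:r + window, c:c + window] += 1
    return cnt


def predict_full(
    model: TileModel,
    image: np.ndarray,
    window: int = 128,
    stride: int = 20,
    batch_size: int = 64,
) -> np.ndarray:
    """Average overlapping tile predictions into whole-image probability maps.

    Parameters
    ----------
    model
        Callable mapping an (N, window, window, C) image batch to
        (N, window, window, classes) per-pixel probabilities; typically a
        trained :class:`~ductseg.nn.unet.AttentionUNet`.
    image
        (H, W, C) float array in [0, 1].
    window, stride
        Tile size and overlap stride, both in pixels and applied to both
        axes.

    Returns
    -------
    (H, W, classes) array where each pixel is the arithmetic mean of the
    predictions of every tile covering it.
    """
    if image.ndim != 3:
        raise ValueError("image must be (H, W, C)")
    h, w = image.shape[:2]
    pad_r, pad_c = max(0, window - h), max(0, window - w)
    padded = np.pad(image, ((0, pad_r), (0, pad_c), (0, 0)), mode="reflect") \
        if (pad_r or pad_c) else image
    ph, pw = padded.shape[:2]
    coords = [(r, c) for r in tile_anchors(ph, window, stride)
              for c in tile_anchors(pw, window, stride)]

    n_classes = None
    acc = None
    cnt = np.zeros((ph, pw, 1), dtype=np.float64)
    for i in range(0, len(coords), batch_size):
        chunk = coords[i:i + batch_size]
        batch = np.stack([padded[r:r + window, c:c + window] for r, c in chunk])
        preds = np.asarray(model(batch), dtype=np.float64)
        if acc is None:
            n_classes = preds.shape[-1]
            acc = np.zeros((ph, pw, n_classes), dtype=np.float64)
        for (r, c), p in zip(chunk, preds):
            acc[r:r + window, c:c + window] += p
            cnt[r:r + window, c:c + window] += 1
    out = acc / cnt
    return out[:h, :w].astype(np.float32)
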