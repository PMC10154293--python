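"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import numpy as np

from ductseg.rings import region_adjacency


def voronoi_partition(rng: np.random.Generator, shape=(48, 48), k=8) -> np.ndarray:
    """Random connected label partition: nearest-seed cells (ties: lower seed)."""
    h, w = shape
    seeds = np.stack([rng.integers(0, h, k), rng.integers(0, w, k)], axis=1)
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr[None] - seeds[:, 0, None, None]) ** 2 + (cc[None] - seeds[:, 1, None, None]) ** 2
    return d2.argmin(axis=0).astype(np.int64) + 1


def merge_regions_bruteforce(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Reference merger: recompute the full adjacency from the raster after
    every single merge; repeatedly absorb the globally smallest undersized
    region into its longest-common-boundary neighbour (ties: larger area,
    then lower label) until no undersized region remains."""
    labels = np.asarray(labels).copy()
    while True:
        areas, pairs = region_adjacency(labels)
        if len(areas) == 1:
            break
        small = [v for v in areas if areas[v] < min_area]
        if not small:
            break
        v = min(small, key=lambda u: (areas[u], u))
        nbrs = {}
        for (a, b), c in pairs.items():
            if a == v:
                nbrs[b] = c
            elif b == v:
                nbrs[a] = c
        if not nbrs:
            break
        target = max(nbrs, key=lambda n: (nbrs[n], areas[n], -n))
        labels[labels == v] = target
    # relabel 1..K by centroid column order
    out = np.zeros_like(labels)
    vals = np.unique(labels)
    cols = np.arange(labels.shape[1])[None, :]
    cents = sorted(vals, key=lambda u: (labels == u).astype(float).__mul__(cols).sum()
                   / (labels == u).sum())
    for new, v in enumerate(cents, start=1):
        out[labels == v] = new
    return out


def tiled_mean_bruteforce(model, image: np.ndarray, window: int, stride: int) -> np.ndarray:
    """Reference overlap-average: explicit per-pixel sum over the tile list."""
    h, w = image.shape[:2]

    def anchors(extent):
        a = list(range(0, extent - window + 1, stride))
        if a[-1] != extent - window:
            a.append(extent - window)
        return a

    acc = None
    cnt = np.zeros((h, w, 1))
    for r in anchors(h):
        for c in anchors(w):
            pred = np.asarray(model(image[None, r:r + window, c:c + window]))[0]
            if acc is None:
                acc = np.zeros((h, w, pred.shape[-1]))
            acc[r:r + window, c:c + window] += pred
            cnt[r:r + window, c:c + window] += 1
    return acc / cnt
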