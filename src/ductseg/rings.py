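"""Tree-ring segmentation from the ring-boundary probability map.

Three steps.  Suppression zeroes every pixel below its 25x25 local mean
while leaving the rest untouched, so weak background response disappears
but boundary evidence keeps its relative strength.  The suppressed map,
read as an elevation surface, is flooded by the watershed transform:
zero plateaus between boundary crests become basins that roughly
correspond to rings, with borders on the crests.  Watershed typically
over-segments, so finally every region smaller than a pixel-area
threshold (1500 px by default) is absorbed into the neighbour with which
it shares the longest discrete boundary, smallest region first, until no
undersized region remains.  Output labels partition the raster and are
numbered 1..K left to right.
"""

from __future__ import annotations

import heapq

import numpy as np
from skimage.segmentation import watershed

from ductseg._filters import local_mean

__all__ = [
    "suppress",
    "watershed_rings",
    "merge_regions",
    "segment_rings",
    "region_adjacency",
    "ring_boundary_masks",
]


def suppress(p_ring: np.ndarray, window: int = 25) -> np.ndarray:
    """Zero pixels below their local window mean; keep the rest unchanged."""
    p = np.asarray(p_ring, dtype=np.float64)
    mean = local_mean(p, window)
    # the >= comparison must be robust to the filter's float rounding so a
    # uniform map (value equal to its own mean) passes through unchanged
    tol = 1e-9 * np.maximum(1.0, np.abs(mean))
    return np.where(p >= mean - tol, p, 0.0)


def watershed_rings(suppressed: np.ndarray) -> np.ndarray:
    """Watershed the suppressed boundary map treated as elevation.

    Basins flood from the regional minima (the zero plateaus between
    boundary crests); no markers are imposed since downstream merging
    absorbs over-segmentation.  Every pixel, including crest pixels, is
    assigned to some region, so the labels partition the raster.
    """
    s = np.asarray(suppressed, dtype=np.float64)
    if (s < 0).any():
        raise ValueError("suppressed raster must be non-negative")
    labels = watershed(s).astype(np.int64)
    if labels.max() == 0:  # perfectly flat raster: one basin covering everything
        labels[...] = 1
    return labels


def region_adjacency(labels: np.ndarray) -> tuple[dict[int, int], dict[tuple[int, int], int]]:
    """Areas and shared-boundary lengths of a label partition.

    Two regions are neighbours when any of their pixels are 4-adjacent;
    the shared boundary length is the number of such 4-adjacent pixel
    pairs.  Returns ``(areas, pair_counts)`` with pair keys ``(a, b)``,
    ``a < b``.
    """
    labels = np.asarray(labels)
    vals, counts = np.unique(labels, return_counts=True)
    areas = {int(v): int(c) for v, c in zip(vals, counts)}
    pairs: dict[tuple[int, int], int] = {}
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = a != b
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        keys, cnts = np.unique(np.stack([lo, hi], axis=1), axis=0, return_counts=True)
        for (x, y), c in zip(keys, cnts):
            k = (int(x), int(y))
            pairs[k] = pairs.get(k, 0) + int(c)
    return areas, pairs


def merge_regions(labels: np.ndarray, min_area: int = 1500) -> np.ndarray:
    """Absorb undersized regions into their longest-boundary neighbour.

    Regions smaller than ``min_area`` are merged smallest-first, to
    fixpoint, each into the neighbour sharing the longest common
    boundary (ties: larger neighbour area, then lower label).  The sole
    remaining region is never removed.  Output is relabelled 1..K in
    left-to-right centroid order.
    """
    labels = np.asarray(labels)
    areas, pairs = region_adjacency(labels)
    nbrs: dict[int, dict[int, int]] = {v: {} for v in areas}
    for (a, b), c in pairs.items():
        nbrs[a][b] = c
        nbrs[b][a] = c

    parent = {v: v for v in areas}

    def root(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    heap = [(area, v) for v, area in areas.items() if area < min_area]
    heapq.heapify(heap)
    alive = set(areas)
    while heap and len(alive) > 1:
        area, v = heapq.heappop(heap)
        if v not in alive or areas[v] != area or areas[v] >= min_area:
            continue  # stale entry
        if not nbrs[v]:
            continue  # isolated undersized region: nothing to merge into
        target = max(nbrs[v], key=lambda n: (nbrs[v][n], areas[n], -n))
        # merge v into target
        alive.discard(v)
        parent[v] = target
        areas[target] += areas[v]
        for n, c in nbrs[v].items():
            if n == target:
                continue
            nbrs[target][n] = nbrs[target].get(n, 0) + c
            nbrs[n][target] = nbrs[target][n]
            del nbrs[n][v]
        nbrs[target].pop(v, None)
        del nbrs[v]
        if areas[target] < min_area:
            heapq.heappush(heap, (areas[target], target))

    # relabel roots 1..K by centroid column order
    flat = labels.ravel()
    lut_root = {v: root(v) for v in parent}
    roots = sorted(alive)
    max_label = int(flat.max())
    root_arr = np.zeros(max_label + 1, dtype=np.int64)
    for v, r in lut_root.items():
        root_arr[v] = r
    rooted = root_arr[flat].reshape(labels.shape)
    col_sums = {r: 0.0 for r in roots}
    cols = np.arange(labels.shape[1], dtype=np.float64)[None, :]
    for r in roots:
        m = rooted == r
        col_sums[r] = float((m * cols).sum()) / float(m.sum())
    order = sorted(roots, key=lambda r: col_sums[r])
    final_lut = np.zeros(max_label + 1, dtype=np.int64)
    for new, r in enumerate(order, start=1):
        final_lut[r] = new
    return final_lut[rooted.ravel()].reshape(labels.shape)


def segment_rings(p_ring: np.ndarray, window: int = 25, min_area: int = 1500) -> np.ndarray:
    """suppress -> watershed -> merge: ring label map 1..K, left to right."""
    return merge_regions(watershed_rings(suppress(p_ring, window)), min_area)


def ring_boundary_masks(ring_labels: np.ndarray) -> list[np.ndarray]:
    """One boolean mask per detected inter-ring boundary.

    The boundary between two adjacent ring regions is the set of pixels
    of either region that are 4-adjacent to the other; each adjacent
    label pair yields one detected boundary object.
    """
    labels = np.asarray(ring_labels)
    _, pairs = region_adjacency(labels)
    masks = []
    for (a, b) in sorted(pairs):
        m = np.zeros(labels.shape, dtype=bool)
        for ax, sl_a, sl_b in (
            (0, np.s_[:-1, :], np.s_[1:, :]),
            (1, np.s_[:, :-1], np.s_[:, 1:]),
        ):
            la, lb = labels[sl_a], labels[sl_b]
            hit = ((la == a) & (lb == b)) | ((la == b) & (lb == a))
            m[sl_a] |= hit
            m[sl_b] |= hit
        masks.append(m)
    return masks
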