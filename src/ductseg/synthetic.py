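"""Synthetic wood-core image generator with exact ground truth.

Real increment cores are extremely wide, short RGB rasters scanned at
2400 dpi: ring boundaries appear as dark, near-vertical lines and resin
ducts as small dark roundish blobs (diameter roughly 20--30 px at that
resolution).  This module emulates that structure with fully known
geometry so that every downstream stage -- segmentation, post-processing,
measurement, evaluation -- can be exercised against an exact oracle.

Coordinate convention: (row, col), 0-based, origin top-left.  Rings are
ordered left to right along the columns, i.e. in chronological order
along the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoreSpec",
    "GroundTruth",
    "generate_core",
    "rasterize",
    "one_hot_maps",
    "random_core_spec",
]

#: class labels used in rasterized masks
BACKGROUND, RING_BOUNDARY, RESIN_DUCT = 0, 1, 2


@dataclass(frozen=True)
class CoreSpec:
    """Parameters of one synthetic core.

    ``ring_widths_px`` are the column widths of consecutive rings; their
    sum is the image width.  ``duct_count_per_ring`` requests that many
    non-overlapping ducts fully inside each ring.  ``contrast`` in (0, 1]
    scales how much darker ducts and boundaries are than the surrounding
    wood; ``noise_sd`` is the standard deviation of additive Gaussian
    noise on the [0, 1] intensity scale.  ``boundary_wobble_px`` optionally
    bends boundaries sinusoidally to emulate curved or arch-shaped rings.
    """

    height_px: int = 300
    ring_widths_px: tuple[int, ...] = (120, 90, 160, 110, 140)
    duct_count_per_ring: tuple[int, ...] = (3, 2, 4, 2, 3)
    duct_radius_range_px: tuple[int, int] = (10, 15)
    boundary_thickness_px: int = 3
    noise_sd: float = 0.03
    contrast: float = 0.5
    boundary_wobble_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 128:
            raise ValueError("height_px must be >= 128")
        if len(self.ring_widths_px) != len(self.duct_count_per_ring):
            raise ValueError("ring_widths_px and duct_count_per_ring lengths differ")
        if any(w < 2 * self.boundary_thickness_px for w in self.ring_widths_px):
            raise ValueError(
                "every ring width must be >= 2 * boundary_thickness_px"
            )
        rmin, rmax = self.duct_radius_range_px
        if not (0 < rmin <= rmax):
            raise ValueError("invalid duct_radius_range_px")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def width_px(self) -> int:
        return int(sum(self.ring_widths_px))


@dataclass(frozen=True)
class GroundTruth:
    """Exact geometry of a synthetic core.

    ``duct_disks`` holds (center_row, center_col, radius_px) triples;
    ``boundary_columns`` the center column of each internal ring boundary
    (strictly increasing); ``ring_extents`` half-open ``[col_start,
    col_end)`` intervals tiling ``[0, width)``, one per ring.
    """

    duct_disks: tuple[tuple[int, int, int], ...]
    boundary_columns: tuple[int, ...]
    ring_extents: tuple[tuple[int, int], ...]
    boundary_thickness_px: int = 3
    height_px: int = 300

    def __post_init__(self) -> None:
        cols = self.boundary_columns
        if any(b >= a for a, b in zip(cols[1:], cols[:-1])):
            raise ValueError("boundary_columns must be strictly increasing")
        ext = self.ring_extents
        for (s0, e0), (s1, e1) in zip(ext[:-1], ext[1:]):
            if e0 != s1:
                raise ValueError("ring_extents must tile the width without gaps")

    @property
    def width_px(self) -> int:
        return self.ring_extents[-1][1]

    def ring_of_duct(self, disk: tuple[int, int, int]) -> int:
        """0-based index of the ring whose extent contains the disk."""
        _, c, r = disk
        for i, (s, e) in enumerate(self.ring_extents):
            if s <= c - r and c + r < e:
                return i
        raise ValueError(f"duct {disk} not contained in any ring extent")


def _boundary_offsets(gt_height: int, wobble: float, rng: np.random.Generator) -> np.ndarray:
    """Per-row sinusoidal column offset for one boundary line."""
    if wobble <= 0:
        return np.zeros(gt_height)
    phase = rng.uniform(0, 2 * np.pi)
    period = rng.uniform(0.7, 1.5) * gt_height
    rows = np.arange(gt_height)
    return wobble * np.sin(2 * np.pi * rows / period + phase)


def generate_core(spec: CoreSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic core image together with its ground truth.

    Returns ``(image, gt)`` where ``image`` is a float32 RGB array of
    shape ``(height_px, sum(ring_widths_px), 3)`` with values in [0, 1].
    Deterministic for a fixed ``spec.seed``.

    Raises
    ------
    ValueError
        If a ring is too narrow (or the core too short) to contain a
        requested duct; the message names the offending ring index.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    t = spec.boundary_thickness_px

    # ring extents and internal boundary columns
    edges = np.cumsum((0,) + tuple(spec.ring_widths_px))
    ring_extents = tuple((int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]))
    boundary_columns = tuple(int(c) for c in edges[1:-1])

    # place non-overlapping ducts strictly inside each ring
    disks: list[tuple[int, int, int]] = []
    rmin, rmax = spec.duct_radius_range_px
    for i, ((s, e), n_ducts) in enumerate(zip(ring_extents, spec.duct_count_per_ring)):
        placed: list[tuple[int, int, int]] = []
        for _ in range(int(n_ducts)):
            ok = False
            for _attempt in range(10_000):
                r = int(rng.integers(rmin, rmax + 1))
                lo_c, hi_c = s + t + r + 1, e - t - r - 1
                lo_r, hi_r = r + 1, h - r - 2
                if lo_c > hi_c or lo_r > hi_r:
                    break  # geometrically impossible at this radius; retry draws radius again
                cc = int(rng.integers(lo_c, hi_c + 1))
                cr = int(rng.integers(lo_r, hi_r + 1))
                if all((cr - pr) ** 2 + (cc - pc) ** 2 > (r + prr + 2) ** 2
                       for pr, pc, prr in placed):
                    placed.append((cr, cc, r))
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"ring {i} (width {e - s} px) cannot contain a requested duct "
                    f"of radius in {spec.duct_radius_range_px}"
                )
        disks.extend(placed)

    gt = GroundTruth(
        duct_disks=tuple(disks),
        boundary_columns=boundary_columns,
        ring_extents=ring_extents,
        boundary_thickness_px=t,
        height_px=h,
    )

    # --- render intensity ---------------------------------------------------
    # per-ring earlywood->latewood ramp so plain global thresholding is not
    # sufficient; base wood tone is bright
    base = np.empty((h, w), dtype=np.float32)
    cols = np.arange(w)
    for (s, e) in ring_extents:
        ramp = np.linspace(0.0, 1.0, e - s, dtype=np.float32)
        tone = rng.uniform(0.75, 0.9)
        base[:, s:e] = tone - 0.12 * ramp  # latewood slightly darker
    dark = spec.contrast * 0.8

    rows = np.arange(h)[:, None]
    # boundaries: near-vertical dark bands (optionally wobbled)
    for c in boundary_columns:
        off = _boundary_offsets(h, spec.boundary_wobble_px, rng)[:, None]
        dist = np.abs(cols[None, :] - (c + off))
        band = dist <= (t - 1) / 2 + 0.5
        base[band] -= dark

    # ducts: dark disks with a soft edge
    for (cr, cc, r) in disks:
        d2 = (rows - cr) ** 2 + (cols[None, :] - cc) ** 2
        core = d2 <= r * r
        base[core] -= dark * 0.9

    noise = rng.normal(0.0, spec.noise_sd, size=(h, w)).astype(np.float32)
    gray = np.clip(base + noise, 0.0, 1.0)

    # mild wood coloration: stronger red/green than blue channel
    image = np.stack([gray, gray * 0.82, gray * 0.62], axis=-1).astype(np.float32)
    return image, gt


def rasterize(gt: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize ground truth into a 3-class mask of the given (H, W) shape.

    Boundary columns become vertical bands of ``boundary_thickness_px``
    labelled 1; duct disks are filled with label 2 (ducts drawn last, so a
    duct pixel wins on overlap); everything else is 0.
    """
    h, w = shape
    if gt.width_px > w or gt.height_px > h:
        raise ValueError(f"ground-truth geometry {gt.height_px}x{gt.width_px} "
                         f"does not fit in shape {shape}")
    mask = np.zeros((h, w), dtype=np.uint8)
    t = gt.boundary_thickness_px
    half = (t - 1) // 2
    for c in gt.boundary_columns:
        lo = c - half
        hi = lo + t
        if lo < 0 or hi > w:
            raise ValueError(f"boundary band at column {c} out of bounds")
        mask[:, lo:hi] = RING_BOUNDARY
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for (cr, cc, r) in gt.duct_disks:
        if cr - r < 0 or cr + r >= h or cc - r < 0 or cc + r >= w:
            raise ValueError(f"duct disk {(cr, cc, r)} out of bounds")
        disk = (rows - cr) ** 2 + (cols - cc) ** 2 <= r * r
        mask[disk] = RESIN_DUCT
    return mask


def one_hot_maps(mask: np.ndarray) -> np.ndarray:
    """Indicator probability maps (H, W, 3) ordered (P_R, P_D, P_B).

    Turns a class mask into the perfect-network output: the ring-boundary,
    duct and background channels are exact indicators and sum to one at
    every pixel.
    """
    labels = np.unique(mask)
    if not set(labels.tolist()) <= {BACKGROUND, RING_BOUNDARY, RESIN_DUCT}:
        raise ValueError(f"mask labels {labels} outside {{0,1,2}}")
    maps = np.zeros(mask.shape + (3,), dtype=np.float32)
    maps[..., 0] = mask == RING_BOUNDARY
    maps[..., 1] = mask == RESIN_DUCT
    maps[..., 2] = mask == BACKGROUND
    return maps


def random_core_spec(
    seed: int,
    n_rings: int = 5,
    height_px: int = 300,
    ring_width_range_px: tuple[int, int] = (60, 220),
    duct_count_range: tuple[int, int] = (1, 5),
    duct_radius_range_px: tuple[int, int] = (10, 15),
    noise_sd: float = 0.03,
    contrast: float = 0.5,
    boundary_wobble_px: float = 0.0,
) -> CoreSpec:
    """Draw a randomized :class:`CoreSpec` with study-like variability.

    Ring widths and per-ring duct counts are sampled uniformly from the
    given ranges; the spec's own ``seed`` is derived from ``seed`` so the
    rendered core is reproducible from this single integer.
    """
    rng = np.random.default_rng(seed)
    widths = tuple(int(v) for v in rng.integers(*ring_width_range_px, size=n_rings))
    counts = tuple(int(v) for v in rng.integers(duct_count_range[0],
                                                duct_count_range[1] + 1, size=n_rings))
    return CoreSpec(
        height_px=height_px,
        ring_widths_px=widths,
        duct_count_per_ring=counts,
        duct_radius_range_px=duct_radius_range_px,
        noise_sd=noise_sd,
        contrast=contrast,
        boundary_wobble_px=boundary_wobble_px,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
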