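"""Reading core scans and writing measurements, maps and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from ductseg.evaluation import DetectionCounts
from ductseg.metrics import RingRecord, records_to_frame
from ductseg.synthetic import GroundTruth

__all__ = [
    "read_image",
    "write_image",
    "write_probability_maps",
    "read_probability_maps",
    "write_label_map",
    "read_label_map",
    "write_measurements",
    "read_measurements",
    "write_metrics",
    "write_ground_truth",
    "read_ground_truth",
]

MEASUREMENT_COLUMNS = ["ring_id", "width_mm", "area_mm2", "n_ducts", "duct_coverage"]


def read_image(path: str | Path, default_dpi: float = 2400.0) -> tuple[np.ndarray, float]:
    """Load a TIFF/PNG core scan as float RGB in [0, 1] plus its dpi.

    Resolution metadata is honoured when the file carries it (TIFF
    resolution tags, PNG pHYs/dpi info); otherwise ``default_dpi`` is
    assumed.  16-bit images are rescaled to [0, 1]; grayscale images are
    replicated to three channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dpi = float(default_dpi)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is not None:
                num, den = xres.value
                res = num / den if den else 0.0
                if res > 0:
                    # unit 2 = inch (default), 3 = cm
                    dpi = res * 2.54 if (unit is not None and unit.value == 3) else res
    else:
        with Image.open(path) as im:
            if "dpi" in im.info:
                dpi = float(im.info["dpi"][0]) or dpi
            arr = np.asarray(im)
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        img = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        img = arr.astype(np.float32) / 65535.0
    else:
        img = arr.astype(np.float32)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    if img.shape[-1] == 4:  # drop alpha
        img = img[..., :3]
    return img, dpi


def write_image(image: np.ndarray, path: str | Path, dpi: float = 2400.0) -> None:
    """Save a float [0,1] RGB image as 8-bit PNG/TIFF with dpi metadata."""
    path = Path(path)
    arr8 = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr8, resolution=(dpi, dpi), photometric="rgb")
    else:
        Image.fromarray(arr8).save(path, dpi=(dpi, dpi))


def write_probability_maps(maps: np.ndarray, path: str | Path) -> None:
    """Save (H, W, 3) probability maps as a planar multi-channel float TIFF."""
    planar = np.ascontiguousarray(np.transpose(np.asarray(maps, np.float32), (2, 0, 1)))
    tifffile.imwrite(Path(path), planar, photometric="minisblack")


def read_probability_maps(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path)).astype(np.float32)
    if arr.ndim == 3 and arr.shape[0] == 3 and arr.shape[-1] != 3:
        arr = np.transpose(arr, (1, 2, 0))
    return arr


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Save an integer label raster as 16-bit PNG."""
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("label values outside 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(Path(path))


def read_label_map(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(Path(path))).astype(np.int64)


def write_measurements(records: list[RingRecord], path: str | Path) -> None:
    """Write the per-ring measurement time series as CSV (full precision)."""
    records_to_frame(records).to_csv(Path(path), index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_metrics(counts: DetectionCounts, sen: float, prec: float, path: str | Path,
                  extra: dict | None = None) -> None:
    """JSON detection report: TP/FN/FP plus sensitivity and precision."""
    payload = {"tp": counts.tp, "fn": counts.fn, "fp": counts.fp,
               "sensitivity": sen, "precision": prec}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Serialize synthetic ground-truth geometry to JSON."""
    payload = {
        "duct_disks": [list(d) for d in gt.duct_disks],
        "boundary_columns": list(gt.boundary_columns),
        "ring_extents": [list(e) for e in gt.ring_extents],
        "boundary_thickness_px": gt.boundary_thickness_px,
        "height_px": gt.height_px,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        duct_disks=tuple(tuple(int(v) for v in d) for d in data["duct_disks"]),
        boundary_columns=tuple(int(v) for v in data["boundary_columns"]),
        ring_extents=tuple(tuple(int(v) for v in e) for e in data["ring_extents"]),
        boundary_thickness_px=int(data["boundary_thickness_px"]),
        height_px=int(data["height_px"]),
    )
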