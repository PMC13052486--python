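"""Readers and writers: TIFF stacks, ROI masks, trace CSVs, sidecar JSON.

The canonical interchange format is a grayscale multi-page TIFF (one page per
frame, float32 or uint16) with an optional sidecar JSON (``<stack>.json``)
carrying :class:`~lsci.core.StackMetadata`.  A directory of single-frame
PNG/TIFF images, ordered lexicographically by filename, is accepted as an
alternative stack source.  ROI masks are 8-bit PNGs (nonzero = inside) or
JSON polygons (closed, pixel coordinates, even-odd fill).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from lsci.core import FormatError, RoiMask, SpeckleStack, StackMetadata
from lsci.contrast import ContrastMap, FrameSeriesStats

logger = logging.getLogger(__name__)

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: SpeckleStack, path: str | Path, dtype: str = "float32") -> Path:
    """Write a stack as a multi-page TIFF plus a sidecar metadata JSON.

    ``dtype`` may be ``"float32"`` (default) or ``"uint16"``; uint16 output
    requires integer-valued pixels within range.
    """
    path = Path(path)
    if dtype == "float32":
        data = stack.pixels.astype(np.float32)
    elif dtype == "uint16":
        if stack.pixels.min() < 0 or stack.pixels.max() > np.iinfo(np.uint16).max:
            raise FormatError("pixel values outside uint16 range")
        data = stack.pixels.astype(np.uint16)
    else:
        raise FormatError(f"unsupported stack dtype {dtype!r}")
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = stack.metadata.to_dict()
    sidecar["frame_indices"] = [int(i) for i in stack.frame_indices]
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_stack(path: str | Path) -> SpeckleStack:
    """Read a stack from a multi-page TIFF or a directory of frame images.

    Directory frames are ordered lexicographically by filename and must share
    one shape and dtype.  Missing sidecar metadata falls back to the
    documented defaults (5 ms exposure, 40 Hz) with a logged warning.
    Integer pixel values are preserved unscaled.
    """
    path = Path(path)
    if path.is_dir():
        frames, names = [], []
        for p in sorted(path.iterdir()):
            if p.suffix.lower() in _FRAME_SUFFIXES:
                names.append(p.name)
                if p.suffix.lower() == ".png":
                    import imageio.v3 as iio

                    img = np.asarray(iio.imread(p))
                    if img.ndim == 3:  # collapse identical RGB channels
                        img = img[..., 0]
                else:
                    img = tifffile.imread(p)
                frames.append(img)
        if not frames:
            raise FormatError(f"no frame images (*.png, *.tif) found in {path}")
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            bad = names[[f.shape for f in frames].index(sorted(shapes)[-1])]
            raise FormatError(f"mixed frame shapes in {path}: offending frame {bad}")
        dtypes = {f.dtype for f in frames}
        if len(dtypes) > 1:
            raise FormatError(f"mixed frame dtypes in {path}: {sorted(map(str, dtypes))}")
        pixels = np.stack(frames)
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            pixels = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - surface as a format error
            raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
        if pixels.ndim == 2:
            pixels = pixels[None]
        if pixels.ndim != 3:
            raise FormatError(f"stack {path} is not grayscale page-per-frame: shape {pixels.shape}")

    sidecar = _sidecar_path(path)
    frame_indices = None
    if sidecar.exists():
        meta_d = json.loads(sidecar.read_text())
        frame_indices = meta_d.pop("frame_indices", None)
        meta = StackMetadata.from_dict(meta_d)
    else:
        logger.warning(
            "no sidecar metadata for %s; assuming defaults (5 ms exposure, 40 Hz)", path
        )
        meta = StackMetadata(source=str(path))
    return SpeckleStack(pixels=pixels, metadata=meta, frame_indices=frame_indices)


def write_contrast_map(cmap: ContrastMap, path: str | Path) -> Path:
    """Write a contrast map as a float32 TIFF (NaN marks undefined pixels)."""
    path = Path(path)
    tifffile.imwrite(path, cmap.k_values.astype(np.float32), photometric="minisblack")
    return path


def read_contrast_map(path: str | Path, window_size: int = 5) -> ContrastMap:
    return ContrastMap(k_values=tifffile.imread(Path(path)), window_size=window_size)


def read_roi_mask(path: str | Path, label: str | None = None) -> RoiMask:
    """Read an ROI from an 8-bit PNG (nonzero = inside) or a JSON polygon.

    The JSON form is ``{"shape": [rows, cols], "polygon": [[r, c], ...],
    "label": ...}`` with a closed polygon in pixel coordinates, filled with
    the even-odd rule.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        mask = polygon_to_mask(doc["polygon"], tuple(doc["shape"]))
        return RoiMask(mask, label=label or doc.get("label", path.stem))
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return RoiMask(img != 0, label=label or path.stem)


def write_roi_mask(roi: RoiMask, path: str | Path) -> Path:
    """Write an ROI as an 8-bit PNG (255 = inside)."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (roi.mask.astype(np.uint8) * 255))
    return path


def polygon_to_mask(polygon: list[list[float]], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed (row, col) polygon with the even-odd fill rule."""
    from matplotlib.path import Path as MplPath

    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise FormatError("polygon must be a list of >= 3 [row, col] points")
    if not np.array_equal(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[:1]])  # close the ring explicitly
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    inside = MplPath(poly, closed=True).contains_points(pts)
    return inside.reshape(shape)


_TRACE_COLUMNS = ["frame_index", "mean_k", "sd_k", "n_pixels", "group_label", "roi_label"]


def write_series_csv(stats: FrameSeriesStats, path: str | Path) -> Path:
    """Write a frame-series trace as CSV."""
    df = pd.DataFrame(
        {
            "frame_index": stats.frame_indices,
            "mean_k": stats.per_frame_mean_k,
            "sd_k": stats.per_frame_sd_k,
            "n_pixels": stats.per_frame_n_pixels,
            "group_label": stats.group_label,
            "roi_label": stats.roi_label,
        }
    )
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_series_csv(path: str | Path) -> FrameSeriesStats:
    """Read a frame-series trace written by :func:`write_series_csv`."""
    df = pd.read_csv(Path(path))
    missing = [c for c in _TRACE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(f"trace CSV {path} missing columns {missing}")
    return FrameSeriesStats(
        roi_label=str(df["roi_label"].iloc[0]) if "roi_label" in df else "",
        group_label=str(df["group_label"].iloc[0]) if "group_label" in df else "",
        per_frame_mean_k=df["mean_k"].to_numpy(),
        per_frame_sd_k=df["sd_k"].to_numpy(),
        per_frame_n_pixels=df["n_pixels"].to_numpy(),
        frame_indices=df["frame_index"].to_numpy(),
    )
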