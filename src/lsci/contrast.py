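"""Spatial speckle-contrast maps and ROI frame-series statistics.

The spatial contrast at a pixel is K = sigma_s / <I>: the standard deviation
of the intensities in a window centered on the pixel divided by their mean.
A 5x5 window is scanned across the frame (the field-standard choice, small
enough to preserve vascular detail, large enough for a usable K estimate).
Values near 0 indicate fast scatterer motion (high flow) blurring the speckle
within the exposure; high K indicates slow or absent flow.

Conventions (recorded in the map metadata):

* sample standard deviation (ddof=1, n=25 for the 5x5 window);
* no padding — K is undefined (NaN) in the border where the full window does
  not fit, and in windows with non-positive mean;
* K is scale-invariant, so raw integer counts are used without normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from lsci.core import InvalidInputError, RoiMask, SpeckleFrame, SpeckleStack

logger = logging.getLogger(__name__)


@dataclass
class ContrastMap:
    """Per-pixel spatial contrast K for one frame.

    ``k_values`` is NaN wherever K is undefined: in the half-window border
    and in windows whose mean intensity is not positive.
    """

    k_values: np.ndarray
    window_size: int = 5
    source_frame_index: int = 0
    std_ddof: int = 1

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=float)
        if self.k_values.ndim != 2:
            raise InvalidInputError("k_values must be 2-D")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise InvalidInputError(
                f"window_size must be odd and >= 3, got {self.window_size}"
            )

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of pixels where K is defined."""
        return np.isfinite(self.k_values)

    def mean(self) -> float:
        """Mean K over all defined pixels."""
        if not self.defined.any():
            raise InvalidInputError("contrast map has no defined pixels")
        return float(np.nanmean(self.k_values))


class RoiContrast(NamedTuple):
    """ROI reduction of a contrast map."""

    mean: float
    sd: float
    n_pixels: int


@dataclass
class FrameSeriesStats:
    """Per-frame ROI-mean contrast trace for one region and condition group."""

    roi_label: str
    group_label: str
    per_frame_mean_k: np.ndarray
    per_frame_sd_k: np.ndarray
    per_frame_n_pixels: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        self.per_frame_mean_k = np.asarray(self.per_frame_mean_k, dtype=float)
        self.per_frame_sd_k = np.asarray(self.per_frame_sd_k, dtype=float)
        self.per_frame_n_pixels = np.asarray(self.per_frame_n_pixels, dtype=int)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        n = len(self.per_frame_mean_k)
        if not (
            len(self.per_frame_sd_k) == len(self.frame_indices) == len(self.per_frame_n_pixels) == n
        ):
            raise InvalidInputError("frame-series lists must have equal length")
        if np.any(self.per_frame_mean_k < 0):
            raise InvalidInputError("ROI mean contrast cannot be negative")

    def __len__(self) -> int:
        return len(self.per_frame_mean_k)


def compute_contrast_map(frame: SpeckleFrame, window_size: int = 5) -> ContrastMap:
    """Sliding-window spatial contrast map of one frame.

    At each pixel where the full ``window_size`` x ``window_size`` window
    fits, K = sample std / mean of the window's intensities.  Border pixels
    and zero-mean windows are NaN.

    Raises
    ------
    InvalidInputError
        If the frame is smaller than the window or the window is even/<3.
    """
    if window_size < 3 or window_size % 2 == 0:
        raise InvalidInputError(f"window_size must be odd and >= 3, got {window_size}")
    px = np.asarray(frame.pixels, dtype=np.float64)
    if px.shape[0] < window_size or px.shape[1] < window_size:
        raise InvalidInputError(
            f"frame {px.shape} smaller than {window_size}x{window_size} window"
        )

    # Center on the global mean before the second moment: the windowed
    # variance is then free of the large-offset cancellation that plagues
    # E[x^2] - E[x]^2 on high-count integer frames.
    offset = px.mean()
    c = px - offset
    win_mean_c = ndimage.uniform_filter(c, size=window_size, mode="constant")
    win_mean_c2 = ndimage.uniform_filter(c * c, size=window_size, mode="constant")
    n = window_size * window_size
    var = (win_mean_c2 - win_mean_c * win_mean_c) * (n / (n - 1))
    # snap roundoff residue to exactly 0 so constant windows report K = 0
    var[var < 1e-12 * (win_mean_c2 + win_mean_c * win_mean_c)] = 0.0
    np.clip(var, 0.0, None, out=var)
    win_mean = win_mean_c + offset

    k = np.full(px.shape, np.nan)
    half = window_size // 2
    interior = np.zeros(px.shape, dtype=bool)
    interior[half : px.shape[0] - half, half : px.shape[1] - half] = True
    valid = interior & (win_mean > 0)
    k[valid] = np.sqrt(var[valid]) / win_mean[valid]

    if not valid.any():
        warnings.warn(
            "contrast map entirely undefined (all-zero or degenerate frame)",
            RuntimeWarning,
            stacklevel=2,
        )
    return ContrastMap(
        k_values=k, window_size=window_size, source_frame_index=frame.frame_index
    )


def mean_roi_contrast(cmap: ContrastMap, roi: RoiMask) -> RoiContrast:
    """Spatial mean and SD of K over the ROI's defined pixels.

    Raises
    ------
    InvalidInputError
        If shapes differ or the ROI contains no defined contrast pixel
        (e.g. it lies entirely in the undefined border).
    """
    if roi.mask.shape != cmap.k_values.shape:
        raise InvalidInputError(
            f"ROI shape {roi.mask.shape} does not match map {cmap.k_values.shape}"
        )
    sel = roi.mask & cmap.defined
    n = int(sel.sum())
    if n == 0:
        raise InvalidInputError(
            f"ROI '{roi.label}' contains no defined contrast pixels"
        )
    vals = cmap.k_values[sel]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return RoiContrast(mean=float(vals.mean()), sd=sd, n_pixels=n)


def series_roi_stats(
    stack: SpeckleStack,
    roi: RoiMask,
    group_label: str = "",
    max_frames: int = 30,
    window_size: int = 5,
) -> FrameSeriesStats:
    """ROI-mean contrast trace over the first ``max_frames`` frames.

    Applies :func:`compute_contrast_map` then :func:`mean_roi_contrast` to
    each frame in stack order.  A stack shorter than ``max_frames`` is used
    in full with a logged warning.
    """
    if len(stack) == 0:
        raise InvalidInputError("cannot compute frame-series stats of an empty stack")
    if max_frames < 1:
        raise InvalidInputError(f"max_frames must be >= 1, got {max_frames}")
    n_use = min(max_frames, len(stack))
    if n_use < max_frames:
        logger.warning(
            "stack has %d frames, fewer than max_frames=%d; using all %d",
            len(stack), max_frames, n_use,
        )
    means, sds, counts, idx = [], [], [], []
    for i in range(n_use):
        fr = stack.frame(i)
        rc = mean_roi_contrast(compute_contrast_map(fr, window_size=window_size), roi)
        means.append(rc.mean)
        sds.append(rc.sd)
        counts.append(rc.n_pixels)
        idx.append(fr.frame_index)
    return FrameSeriesStats(
        roi_label=roi.label,
        group_label=group_label,
        per_frame_mean_k=np.array(means),
        per_frame_sd_k=np.array(sds),
        per_frame_n_pixels=np.array(counts),
        frame_indices=np.array(idx),
    )
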