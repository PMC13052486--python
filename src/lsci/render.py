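"""False-color rendering of contrast maps.

Maps K linearly onto a blue-to-red colormap over a fixed range, 0 (blue,
high flow) to 0.4 (red, low/no flow) by default — the conventional display
for intraoperative perfusion review.  Values outside the range are clipped;
undefined pixels render as neutral gray.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lsci.core import InvalidInputError
from lsci.contrast import ContrastMap

#: RGB for undefined (NaN) contrast pixels.
UNDEFINED_COLOR = (128, 128, 128)


@dataclass(frozen=True)
class RenderSpec:
    """Display range and colormap for contrast rendering."""

    k_min: float = 0.0
    k_max: float = 0.4
    colormap_name: str = "jet"

    def __post_init__(self) -> None:
        if not self.k_min < self.k_max:
            raise InvalidInputError(
                f"k_min must be < k_max, got [{self.k_min}, {self.k_max}]"
            )


def render_contrast(
    cmap: ContrastMap, spec: RenderSpec | None = None, colorbar: bool = False
) -> np.ndarray:
    """Render a contrast map as an 8-bit RGB image.

    K is clipped to ``[k_min, k_max]`` and mapped linearly onto the colormap
    (blue end = ``k_min``, red end = ``k_max`` for the default ``jet``).
    With ``colorbar=True`` a vertical colorbar strip is appended on the
    right.
    """
    import matplotlib

    spec = spec or RenderSpec()
    lut = matplotlib.colormaps[spec.colormap_name]
    k = cmap.k_values
    pos = np.clip((k - spec.k_min) / (spec.k_max - spec.k_min), 0.0, 1.0)
    defined = np.isfinite(k)
    rgba = lut(np.where(defined, pos, 0.0))
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[~defined] = UNDEFINED_COLOR
    if colorbar:
        rgb = np.concatenate([rgb, _colorbar_strip(lut, rgb.shape[0])], axis=1)
    return rgb


def _colorbar_strip(lut, height: int, width: int = 16) -> np.ndarray:
    ramp = np.linspace(1.0, 0.0, height)[:, None].repeat(width, axis=1)
    return (lut(ramp)[..., :3] * 255).round().astype(np.uint8)


def write_render(path, cmap: ContrastMap, spec: RenderSpec | None = None,
                 colorbar: bool = False):
    """Render and write a PNG; returns the path."""
    import imageio.v3 as iio

    iio.imwrite(path, render_contrast(cmap, spec, colorbar=colorbar))
    return path
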