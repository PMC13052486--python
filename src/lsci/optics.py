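"""Diffraction-limited speckle size and detector sampling adequacy.

The minimum speckle diameter on the detector of a diffraction-limited imager
is

    rho_speckle = 2.44 * lambda * (1 + M) * f/#

with wavelength lambda, magnification M and system f-number f/#.  The ratio
of speckle diameter to pixel pitch governs how much of the theoretical
contrast the camera actually reads out: speckle smaller than ~2 pixels is
spatially undersampled and averages down within each pixel, which is the
usual explanation when two systems imaging the same target report different
absolute K.
"""

from __future__ import annotations

from dataclasses import dataclass

from lsci.core import InvalidInputError

#: Minimum speckle-to-pixel ratio for adequate (Nyquist) sampling.
NYQUIST_RATIO = 2.0


@dataclass(frozen=True)
class SamplingReport:
    """Speckle-to-pixel sampling summary for one camera configuration."""

    speckle_diameter_um: float
    pixel_pitch_um: float
    speckle_per_pixel_ratio: float
    adequately_sampled: bool


def speckle_diameter(wavelength_nm: float, magnification: float, f_number: float) -> float:
    """Diffraction-limited speckle diameter in micrometers.

    ``2.44 * lambda * (1 + M) * f/#`` with the wavelength given in nm and
    converted to um internally.

    >>> round(speckle_diameter(785, 1.0, 2.7), 2)
    10.34
    """
    if wavelength_nm <= 0 or f_number <= 0 or magnification < 0:
        raise InvalidInputError(
            "wavelength and f-number must be positive and magnification nonnegative"
        )
    return 2.44 * (wavelength_nm / 1000.0) * (1.0 + magnification) * f_number


def sampling_report(diameter_um: float, pixel_pitch_um: float) -> SamplingReport:
    """Sampling adequacy of a speckle diameter against a pixel pitch.

    Adequate means at least :data:`NYQUIST_RATIO` (two) pixels per speckle.
    """
    if diameter_um <= 0 or pixel_pitch_um <= 0:
        raise InvalidInputError("diameter and pixel pitch must be positive")
    ratio = diameter_um / pixel_pitch_um
    return SamplingReport(
        speckle_diameter_um=diameter_um,
        pixel_pitch_um=pixel_pitch_um,
        speckle_per_pixel_ratio=ratio,
        adequately_sampled=ratio >= NYQUIST_RATIO,
    )
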