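"""Orientation band-pass filters built from wrapped Gaussians.

A filter is a gain map over the two-sided discrete Fourier plane.  Its value
at each spectral coordinate is the sum, over the filter's peak orientations,
of a wrapped Gaussian in *image-structure* orientation (0 deg = horizontal
contours).  Horizontal structure carries its power along the vertical
spectral axis, so the gain map is indexed at the spectral angle + 90 deg.

Two filters are used to build hybrid stimuli:

* the *cardinal* filter, peaks at 0 and 90 deg, passing horizontal and
  vertical structure;
* the *intercardinal* filter, the same shape rotated 45 deg (peaks at 45 and
  135 deg), passing oblique structure.

Each lobe has unit peak amplitude and a configurable half-width at half
height (default 23.6 deg).  Orientation is 180-deg periodic.  The gain at the
DC coordinate is set to 1 so that mean luminance survives filtering; mean
level is remapped for display later in the pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CARDINAL_PEAKS",
    "INTERCARDINAL_PEAKS",
    "DEFAULT_HWHH",
    "OrientationFilter",
    "hwhh_to_sigma",
    "wrapped_gaussian_gain",
    "structure_orientation_grid",
    "build_filter",
    "cardinal_filter",
    "intercardinal_filter",
    "apply_filter",
    "filter_to_png",
]

#: Peak image-structure orientations of the two filters, in degrees.
CARDINAL_PEAKS: tuple[float, float] = (0.0, 90.0)
INTERCARDINAL_PEAKS: tuple[float, float] = (45.0, 135.0)

#: Default half-width at half height of each wrapped-Gaussian lobe (degrees).
DEFAULT_HWHH: float = 23.6

# Wraps k in [-2, 2] suffice: at hwhh = 23.6 deg (sigma ~ 20 deg) the first
# neglected wrap contributes exp(-(3*180)^2 / (2*20^2)) << 1e-12.
_WRAPS = (-2, -1, 0, 1, 2)


def hwhh_to_sigma(hwhh: float) -> float:
    """Convert a half-width at half height to a Gaussian scale (both degrees).

    sigma = hwhh / sqrt(2 ln 2), so that a unit-amplitude Gaussian falls to
    exactly 0.5 at an offset of ``hwhh`` from its peak.
    """
    if hwhh <= 0:
        raise ValueError(f"hwhh must be positive, got {hwhh}")
    return hwhh / math.sqrt(2.0 * math.log(2.0))


def wrapped_gaussian_gain(theta, peak: float, sigma: float):
    """Gain of a unit-amplitude Gaussian wrapped on the 180-deg circle.

    Parameters
    ----------
    theta
        Orientation(s) in degrees (scalar or array).
    peak
        Peak orientation in degrees.
    sigma
        Gaussian scale in degrees; must be positive.

    Returns
    -------
    Gain in (0, 1], same shape as ``theta``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    theta = np.asarray(theta, dtype=float)
    # principal offset in [-90, 90); the wraps then cover any sigma <= ~25 deg
    offset = (theta - peak + 90.0) % 180.0 - 90.0
    gain = np.zeros_like(theta)
    for k in _WRAPS:
        gain += np.exp(-((offset + 180.0 * k) ** 2) / (2.0 * sigma**2))
    if gain.ndim == 0:
        return float(gain)
    return gain


def structure_orientation_grid(size: tuple[int, int]) -> np.ndarray:
    """Image-structure orientation (degrees in [0, 180)) at each DFT coordinate.

    Uses the standard two-sided frequency layout (zero frequency at index
    [0, 0], negative frequencies in the upper halves).  The spectral angle is
    atan2(fy, fx); structure orientation is that angle + 90 deg, mod 180.
    """
    rows, cols = size
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    spectral_angle = np.degrees(np.arctan2(fy, fx))
    return (spectral_angle + 90.0) % 180.0


@dataclass(frozen=True)
class OrientationFilter:
    """A gain map over the discrete Fourier plane.

    Attributes
    ----------
    peak_orientations
        Peak image-structure orientations, degrees.
    hwhh
        Half-width at half height of each lobe, degrees.
    sigma
        Gaussian scale derived from ``hwhh``, degrees.
    size
        (rows, cols) of the spectral grid.
    ppd
        Pixels per degree of the display mapping (metadata only; the filter
        acts on orientation, not radial frequency).
    gain
        Dimensionless gain at each spectral coordinate, point-symmetric.
    """

    peak_orientations: tuple[float, ...]
    hwhh: float
    sigma: float
    size: tuple[int, int]
    ppd: float
    gain: np.ndarray = field(repr=False)

    def descriptor(self) -> dict:
        """JSON-serializable description sufficient to rebuild the filter."""
        return {
            "peaks": list(self.peak_orientations),
            "hwhh": self.hwhh,
            "size": list(self.size),
            "ppd": self.ppd,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.descriptor(), indent=2))


def build_filter(
    size: tuple[int, int],
    peaks,
    hwhh: float = DEFAULT_HWHH,
    ppd: float = 100.0 / 3.0,
) -> OrientationFilter:
    """Build an orientation filter as a sum of wrapped Gaussians.

    The gain at each spectral coordinate is the sum over ``peaks`` of the
    wrapped Gaussian evaluated at that coordinate's structure orientation.
    The DC coordinate's gain is defined as 1 (orientation is undefined there
    and the image mean must pass unchanged).
    """
    rows, cols = size
    if rows < 2 or cols < 2:
        raise ValueError(f"grid must be at least 2x2, got {size}")
    peaks = tuple(float(p) for p in peaks)
    if not peaks:
        raise ValueError("at least one peak orientation is required")
    sigma = hwhh_to_sigma(hwhh)
    theta = structure_orientation_grid(size)
    gain = np.zeros(size, dtype=float)
    for peak in peaks:
        gain += wrapped_gaussian_gain(theta, peak, sigma)
    gain[0, 0] = 1.0
    return OrientationFilter(
        peak_orientations=peaks, hwhh=hwhh, sigma=sigma, size=(rows, cols),
        ppd=ppd, gain=gain,
    )


def cardinal_filter(size, hwhh: float = DEFAULT_HWHH, ppd: float = 100.0 / 3.0):
    """Filter passing near-horizontal and near-vertical structure."""
    return build_filter(size, CARDINAL_PEAKS, hwhh=hwhh, ppd=ppd)


def intercardinal_filter(size, hwhh: float = DEFAULT_HWHH, ppd: float = 100.0 / 3.0):
    """The cardinal filter rotated 45 deg: passes oblique structure."""
    return build_filter(size, INTERCARDINAL_PEAKS, hwhh=hwhh, ppd=ppd)


def apply_filter(image: np.ndarray, filt: OrientationFilter) -> np.ndarray:
    """Multiply an image's amplitude spectrum by the filter gain.

    The output is real because the gain is point-symmetric over the spectral
    grid; the residual imaginary part is discarded after an internal sanity
    check.  The image mean is preserved (DC gain is 1).
    """
    image = np.asarray(image, dtype=float)
    if image.shape != filt.gain.shape:
        raise ValueError(
            f"image shape {image.shape} does not match filter grid {filt.gain.shape}"
        )
    spectrum = np.fft.fft2(image) * filt.gain
    out = np.fft.ifft2(spectrum)
    scale = np.max(np.abs(out.real)) or 1.0
    if np.max(np.abs(out.imag)) > 1e-8 * scale:
        raise FloatingPointError("filtered image has non-negligible imaginary part")
    return out.real


def filter_to_png(filt: OrientationFilter, path: str | Path) -> None:
    """Export the gain map as an 8-bit grayscale PNG (0 -> black, 1 -> white)."""
    from PIL import Image

    arr = np.clip(filt.gain, 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8), mode="L").save(path)
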