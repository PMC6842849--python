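"""Window of visibility and visible-energy computation.

The *window of visibility* (WV) is a fixed nonnegative gain map over the
spatial-frequency plane that models early visual contrast sensitivity.  The
*notionally visible energy* of an image is the dot product between the
image's Fourier power spectrum and the WV.  Equating two filtered component
images for visible energy lets a hybrid stimulus present both components at
(nominally) matched visibility.

The radial profile of the WV is a log-parabola contrast-sensitivity function
(CSF): unit gain at a peak spatial frequency, falling off as a Gaussian in
log2 frequency with a configurable half-amplitude bandwidth in octaves.  An
optional oblique-attenuation term reduces gain at oblique spectral angles.
The map is normalized to unit maximum and the DC gain is forced to zero
(zero frequency carries no contrast), which makes visible energy invariant
to the image mean.

Transform convention (pinned): the unnormalized forward DFT (`numpy.fft.fft2`
default), so with WV == 1 everywhere except DC, visible energy equals the
spatial-domain variance times the squared pixel count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .orientation_filters import structure_orientation_grid

__all__ = [
    "DEFAULT_PPD",
    "CSFParams",
    "WindowOfVisibility",
    "build_wv",
    "visible_energy",
    "AnisotropyProfile",
    "anisotropy_profile",
    "cardinal_to_oblique_ratio",
]

#: Display mapping: each pixel subtends 1.8 arcmin, i.e. 33.33 pixels/degree.
DEFAULT_PPD: float = 100.0 / 3.0


@dataclass(frozen=True)
class CSFParams:
    """Parameters of the contrast-sensitivity model behind the WV.

    peak_sensitivity is a dimensionless amplitude (the map is renormalized to
    unit maximum, so it only matters for exported metadata); peak_frequency
    is in cycles/degree; bandwidth_octaves is the full width at half
    amplitude of the log-parabola; oblique_strength in [0, 1) is the
    fractional attenuation at 45 deg spectral angle (0 = isotropic).
    """

    peak_sensitivity: float = 1.0
    peak_frequency_cpd: float = 3.0
    bandwidth_octaves: float = 2.0
    oblique_strength: float = 0.3


@dataclass(frozen=True)
class WindowOfVisibility:
    size: tuple[int, int]
    ppd: float
    params: CSFParams
    gain: np.ndarray = field(repr=False)

    def descriptor(self) -> dict:
        return {"size": list(self.size), "ppd": self.ppd, "params": asdict(self.params)}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.descriptor(), indent=2))

    def to_png(self, path: str | Path) -> None:
        """Export the gain map as an 8-bit grayscale heat map."""
        from PIL import Image

        arr = np.clip(self.gain, 0.0, 1.0)
        Image.fromarray((arr * 255.0).round().astype(np.uint8), mode="L").save(path)


def _frequency_grids(size: tuple[int, int], ppd: float):
    rows, cols = size
    fy = np.fft.fftfreq(rows)[:, None] * ppd  # cycles/degree
    fx = np.fft.fftfreq(cols)[None, :] * ppd
    return fy, fx


def build_wv(
    size: tuple[int, int],
    ppd: float = DEFAULT_PPD,
    params: CSFParams | None = None,
) -> WindowOfVisibility:
    """Construct the window of visibility on a spectral grid.

    Gain = radial log-parabola CSF x oblique-attenuation term, normalized to
    unit maximum, with DC forced to 0.
    """
    if ppd <= 0:
        raise ValueError(f"ppd must be positive, got {ppd}")
    params = params or CSFParams()
    fy, fx = _frequency_grids(size, ppd)
    f = np.hypot(fy, fx)

    # Log-parabola: half amplitude at +-(bandwidth/2) octaves from the peak.
    half_bw = params.bandwidth_octaves / 2.0
    log_sigma = half_bw / np.sqrt(2.0 * np.log(2.0))
    with np.errstate(divide="ignore"):
        log_offset = np.log2(
            np.where(f > 0, f, np.nan) / params.peak_frequency_cpd
        )
    radial = np.where(
        f > 0, np.exp(-(log_offset**2) / (2.0 * log_sigma**2)), 0.0
    )

    spectral_angle = np.degrees(np.arctan2(fy, fx))
    oblique = 1.0 - params.oblique_strength * np.sin(np.radians(2.0 * spectral_angle)) ** 2

    gain = params.peak_sensitivity * radial * oblique
    gain[0, 0] = 0.0
    peak = gain.max()
    if peak > 0:
        gain = gain / peak
    return WindowOfVisibility(size=tuple(size), ppd=ppd, params=params, gain=gain)


def visible_energy(image: np.ndarray, wv: WindowOfVisibility) -> float:
    """Dot product of the image's power spectrum with the WV gain.

    Uses the unnormalized forward DFT.  Nonnegative; scales with the square
    of image amplitude; invariant to adding a constant (DC gain is 0).
    """
    image = np.asarray(image, dtype=float)
    if image.shape != wv.gain.shape:
        raise ValueError(
            f"image shape {image.shape} does not match WV grid {wv.gain.shape}"
        )
    power = np.abs(np.fft.fft2(image)) ** 2
    return float(np.sum(power * wv.gain))


class AnisotropyProfile(NamedTuple):
    """Orientation histogram of spectral power (DC excluded).

    ``power`` partitions the total non-DC power; ``counts`` gives the number
    of spectral coordinates per bin.  On a square grid the corner regions put
    more coordinates in oblique bins, so isotropy is judged on the mean power
    per coordinate, ``power / counts``.
    """

    bin_edges: np.ndarray  # degrees, length n_bins + 1, spanning [0, 180]
    power: np.ndarray  # total power per bin, sums to total non-DC power
    counts: np.ndarray  # spectral coordinates per bin

    @property
    def mean_power(self) -> np.ndarray:
        return self.power / np.maximum(self.counts, 1)


def anisotropy_profile(image: np.ndarray, bin_width: float = 15.0) -> AnisotropyProfile:
    """Partition an image's non-DC spectral power into orientation bins.

    Orientation is image-structure orientation (0 deg = horizontal contours);
    bins cover [0, 180) and ``bin_width`` must divide 180.  The bin powers sum
    to the total non-DC power of the spectrum.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be a positive divisor of 180, got {bin_width}")
    n_bins = int(round(180.0 / bin_width))
    if n_bins < 1 or abs(n_bins * bin_width - 180.0) > 1e-9:
        raise ValueError(f"bin_width must be a positive divisor of 180, got {bin_width}")

    image = np.asarray(image, dtype=float)
    power = np.abs(np.fft.fft2(image)) ** 2
    theta = structure_orientation_grid(image.shape)
    idx = np.minimum((theta / bin_width).astype(int), n_bins - 1)
    mask = np.ones_like(power, dtype=bool)
    mask[0, 0] = False  # exclude DC
    binned = np.bincount(idx[mask].ravel(), weights=power[mask].ravel(), minlength=n_bins)
    counts = np.bincount(idx[mask].ravel(), minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return AnisotropyProfile(bin_edges=edges, power=binned, counts=counts)


def cardinal_to_oblique_ratio(image: np.ndarray, min_cycles: float = 4.0) -> float:
    """Mean spectral power near cardinal vs oblique structure orientations.

    Coordinates are classified by whether their structure orientation lies
    within 22.5 deg of a cardinal axis (0/90 deg) or of an oblique axis
    (45/135 deg).  Only coordinates inside the inscribed spectral disc
    (radial frequency <= 0.5 cycles/pixel) are used, so that the two classes
    sample matched radial-frequency ranges, and radii below ``min_cycles``
    cycles per image are excluded because angular sampling there is too
    coarse to assign an orientation; with both guards an isotropic spectrum
    yields a ratio of ~1.  Returns mean-per-coordinate cardinal power divided
    by mean-per-coordinate oblique power.
    """
    image = np.asarray(image, dtype=float)
    power = np.abs(np.fft.fft2(image)) ** 2
    rows, cols = image.shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fy, fx)
    theta = structure_orientation_grid(image.shape)

    dist_cardinal = np.minimum.reduce(
        [np.abs(theta - a) for a in (0.0, 90.0, 180.0)]
    )
    in_disc = (radius <= 0.5) & (radius > min_cycles / max(rows, cols))
    cardinal = in_disc & (dist_cardinal <= 22.5)
    oblique = in_disc & (dist_cardinal > 22.5)
    mean_c = power[cardinal].mean()
    mean_o = power[oblique].mean()
    return float(mean_c / mean_o)
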