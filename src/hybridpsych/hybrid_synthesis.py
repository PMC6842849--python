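"""Hybrid-stimulus construction.

A hybrid superimposes two component images from distinct object categories:
one filtered to retain near-cardinal structure orientations, the other to
retain near-intercardinal ones.  The amplitude spectrum of each filtered
component is rescaled (about its mean) so that the two visible energies have
a fixed sum S and a requested natural-log ratio r:

    E_cardinal + E_intercardinal = S,   ln(E_cardinal / E_intercardinal) = r

with S = 1.33e8 by default.  The components are then summed, remapped to the
display range with the background mean at mid-gray, and shown inside a
hard-edged circular aperture of 9.4 deg diameter.  A phase-scrambled mask is
made for every hybrid by adding the phase spectrum of a seeded uniform white
noise image to the hybrid's phase spectrum, which preserves the amplitude
spectrum exactly.

Preprocessing applies a soft circular spatial window to each component; an
optional zero pad (50 px in the second experiment's variant) widens the
canvas before windowing so that the taper falls mostly outside the cropped
image, reducing edge blur.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .orientation_filters import (
    OrientationFilter,
    apply_filter,
    cardinal_filter,
    intercardinal_filter,
)
from .visibility import DEFAULT_PPD, WindowOfVisibility, build_wv, visible_energy

__all__ = [
    "TOTAL_ENERGY",
    "CANVAS_SIZE",
    "WINDOW_DIAMETER_DEG",
    "DegenerateStimulusError",
    "HybridSpec",
    "HybridStimulus",
    "load_image",
    "preprocess_component",
    "soft_circular_window",
    "solve_target_energies",
    "equate_components",
    "compose_hybrid",
    "apply_aperture",
    "make_mask",
    "make_hybrid",
]

#: Fixed sum of the two components' visible energies (arbitrary energy units).
TOTAL_ENERGY: float = 1.33e8

#: Working canvas in pixels: 300 px at 33.33 px/deg is a 9-deg image, matching
#: the 300 x 300 white-noise pattern used for masks.
CANVAS_SIZE: int = 300

#: Diameter of the hard-edged circular display aperture, degrees.
WINDOW_DIAMETER_DEG: float = 9.4


class DegenerateStimulusError(ValueError):
    """A component has (near-)zero visible energy and cannot be equated."""


@dataclass(frozen=True)
class HybridSpec:
    """Target parameters for one hybrid stimulus."""

    total_energy: float = TOTAL_ENERGY
    log_ratio: float = 0.0
    pad: int = 0  # zero-pad width in px before windowing (0 or 50)
    window_diameter_deg: float = WINDOW_DIAMETER_DEG
    ppd: float = DEFAULT_PPD
    seed: int | None = None

    def __post_init__(self):
        if self.total_energy <= 0:
            raise ValueError("total_energy must be positive")
        if self.window_diameter_deg <= 0:
            raise ValueError("window_diameter_deg must be positive")
        if self.pad < 0:
            raise ValueError("pad must be nonnegative")


@dataclass
class HybridStimulus:
    """A composed hybrid with its components, energies and mask.

    ``image`` and ``mask`` are the working-canvas display-range fields (in
    [0, 1]); ``display_image``/``display_mask`` are the same fields placed on
    the aperture canvas with the hard circular window applied.
    """

    image: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    display_image: np.ndarray = field(repr=False)
    display_mask: np.ndarray = field(repr=False)
    cardinal_component: np.ndarray = field(repr=False)
    intercardinal_component: np.ndarray = field(repr=False)
    e_cardinal: float = 0.0
    e_intercardinal: float = 0.0
    realized_log_ratio: float = 0.0
    clip_fraction: float = 0.0
    alpha_cardinal: float = 1.0
    alpha_intercardinal: float = 1.0
    spec: HybridSpec | None = None

    def metadata(self) -> dict:
        meta = {
            "e_cardinal": self.e_cardinal,
            "e_intercardinal": self.e_intercardinal,
            "realized_log_ratio": self.realized_log_ratio,
            "clip_fraction": self.clip_fraction,
            "alpha_cardinal": self.alpha_cardinal,
            "alpha_intercardinal": self.alpha_intercardinal,
        }
        if self.spec is not None:
            meta["spec"] = {
                "total_energy": self.spec.total_energy,
                "log_ratio": self.spec.log_ratio,
                "pad": self.spec.pad,
                "window_diameter_deg": self.spec.window_diameter_deg,
                "ppd": self.spec.ppd,
                "seed": self.spec.seed,
            }
        return meta

    def write(self, prefix: str | Path) -> None:
        """Write hybrid PNG, mask PNG and a JSON metadata sidecar."""
        from PIL import Image

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        for suffix, arr in (("hybrid", self.display_image), ("mask", self.display_mask)):
            img = (np.clip(arr, 0, 1) * 255.0).round().astype(np.uint8)
            Image.fromarray(img, mode="L").save(f"{prefix}_{suffix}.png")
        Path(f"{prefix}_meta.json").write_text(json.dumps(self.metadata(), indent=2))


# --------------------------------------------------------------------------
# preprocessing


def load_image(path: str | Path) -> np.ndarray:
    """Read a raster file as a float grayscale array in [0, 1].

    Color images are converted with ITU-R BT.601 luma weights
    (0.299 R + 0.587 G + 0.114 B).
    """
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # plugins raise a zoo of error types
        raise OSError(f"cannot read image file {str(path)!r}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def _resize(image: np.ndarray, target_size: int) -> np.ndarray:
    if image.shape == (target_size, target_size):
        return image
    from PIL import Image

    img = Image.fromarray(image.astype(np.float32), mode="F")
    img = img.resize((target_size, target_size), resample=Image.BILINEAR)
    return np.asarray(img, dtype=float)


def soft_circular_window(size: int, taper_frac: float = 0.1) -> np.ndarray:
    """Radial raised-cosine (Tukey) window on a square canvas.

    Unity inside radius (1 - taper_frac) * size/2, cosine taper to zero at
    radius size/2, zero beyond.
    """
    half = size / 2.0
    yy, xx = np.indices((size, size))
    r = np.hypot(yy - (size - 1) / 2.0, xx - (size - 1) / 2.0)
    r0 = (1.0 - taper_frac) * half
    w = np.ones((size, size))
    taper = (r > r0) & (r <= half)
    w[taper] = 0.5 * (1.0 + np.cos(np.pi * (r[taper] - r0) / (half - r0)))
    w[r > half] = 0.0
    return w


def preprocess_component(
    image: np.ndarray | str | Path,
    target_size: int = CANVAS_SIZE,
    pad: int = 0,
    taper_frac: float = 0.1,
) -> np.ndarray:
    """Grayscale, resize, optionally zero-pad, soft-window and crop a component.

    The soft circular window is applied to the mean-removed image on the
    (optionally padded) canvas; with a pad, most of the taper falls outside
    the crop, so edges near the image boundary stay sharp.  The mean level of
    the windowed interior is preserved.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    if isinstance(image, (str, Path)):
        image = load_image(image)
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image[..., :3] @ np.array([0.299, 0.587, 0.114])
    image = _resize(image, target_size)

    mean = image.mean()
    centered = image - mean
    if pad > 0:
        centered = np.pad(centered, pad)
    window = soft_circular_window(centered.shape[0], taper_frac=taper_frac)
    windowed = centered * window
    if pad > 0:
        windowed = windowed[pad:-pad, pad:-pad]
    return windowed + mean


# --------------------------------------------------------------------------
# energy equating and composition


def solve_target_energies(total_energy: float, log_ratio: float) -> tuple[float, float]:
    """Split a total energy S into (E_cardinal, E_intercardinal).

    E_c = S e^r / (1 + e^r), E_i = S / (1 + e^r); the pair sums to S and has
    natural-log ratio r.
    """
    if total_energy <= 0:
        raise ValueError("total_energy must be positive")
    if not math.isfinite(log_ratio):
        raise ValueError("log_ratio must be finite")
    er = math.exp(log_ratio)
    e_i = total_energy / (1.0 + er)
    e_c = total_energy * er / (1.0 + er)
    return e_c, e_i


def equate_components(
    comp_cardinal: np.ndarray,
    comp_intercardinal: np.ndarray,
    spec: HybridSpec,
    wv: WindowOfVisibility,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Scale two filtered components to the target visible energies.

    Each component is scaled about its own mean by alpha =
    sqrt(E_target / E_current); since the WV's DC gain is zero, visible
    energy scales exactly with alpha^2.  Returns the scaled pair and a dict
    with the alphas and realized energies.
    """
    e_c_target, e_i_target = solve_target_energies(spec.total_energy, spec.log_ratio)
    out = []
    alphas = []
    for comp, target in (
        (comp_cardinal, e_c_target),
        (comp_intercardinal, e_i_target),
    ):
        comp = np.asarray(comp, dtype=float)
        current = visible_energy(comp, wv)
        if current <= 0 or not math.isfinite(current):
            raise DegenerateStimulusError(
                "component has zero visible energy; cannot equate"
            )
        alpha = math.sqrt(target / current)
        mean = comp.mean()
        out.append(mean + alpha * (comp - mean))
        alphas.append(alpha)
    info = {
        "alpha_cardinal": alphas[0],
        "alpha_intercardinal": alphas[1],
        "e_cardinal": visible_energy(out[0], wv),
        "e_intercardinal": visible_energy(out[1], wv),
    }
    return out[0], out[1], info


def compose_hybrid(
    scaled_cardinal: np.ndarray,
    scaled_intercardinal: np.ndarray,
    spec: HybridSpec | None = None,
) -> tuple[np.ndarray, float]:
    """Sum the mean-removed components and remap to the display range.

    The affine remap places the background mean at mid-gray (0.5) and maps
    +-3 SD of the combined pixel distribution onto the [0, 1] display range;
    out-of-range pixels are clipped and the clipped fraction returned.  The
    map is never rescaled per image beyond this rule, which would break the
    energy calibration.
    """
    a = np.asarray(scaled_cardinal, dtype=float)
    b = np.asarray(scaled_intercardinal, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"component shapes differ: {a.shape} vs {b.shape}")
    combo = (a - a.mean()) + (b - b.mean())
    sd = combo.std()
    if sd == 0:
        return np.full_like(combo, 0.5), 0.0
    scaled = 0.5 + combo * (0.5 / (3.0 * sd))
    clip_fraction = float(np.mean((scaled < 0) | (scaled > 1)))
    return np.clip(scaled, 0.0, 1.0), clip_fraction


def apply_aperture(
    image: np.ndarray,
    window_diameter_deg: float = WINDOW_DIAMETER_DEG,
    ppd: float = DEFAULT_PPD,
    background: float = 0.5,
) -> np.ndarray:
    """Center the image on the aperture canvas and apply the hard window.

    The canvas is the smallest square holding the aperture (314 px for a
    9.4-deg aperture at 33.33 px/deg); pixels outside the circular aperture
    are set to the background gray.
    """
    diameter_px = window_diameter_deg * ppd
    canvas_size = max(int(math.ceil(diameter_px)), image.shape[0])
    canvas = np.full((canvas_size, canvas_size), background, dtype=float)
    off = (canvas_size - image.shape[0]) // 2
    canvas[off : off + image.shape[0], off : off + image.shape[1]] = image
    yy, xx = np.indices((canvas_size, canvas_size))
    center = (canvas_size - 1) / 2.0
    outside = np.hypot(yy - center, xx - center) > diameter_px / 2.0
    canvas[outside] = background
    return canvas


def make_mask(
    hybrid_image: np.ndarray,
    seed: int | None = None,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Phase-scramble a hybrid by adding a white-noise phase spectrum.

    The noise is a seeded uniform-[0, 1] image of the hybrid's shape (or any
    real image passed as ``noise``); its phase spectrum is added to the
    hybrid's, leaving the amplitude spectrum untouched.  Because the noise is
    a real image, its phase is Hermitian-odd and the mask is real.
    """
    hybrid_image = np.asarray(hybrid_image, dtype=float)
    if noise is None:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0.0, 1.0, size=hybrid_image.shape)
    if noise.shape != hybrid_image.shape:
        raise ValueError("noise shape must match the hybrid image")
    h = np.fft.fft2(hybrid_image)
    phase = np.angle(h) + np.angle(np.fft.fft2(noise))
    mask = np.fft.ifft2(np.abs(h) * np.exp(1j * phase))
    scale = np.max(np.abs(mask.real)) or 1.0
    if np.max(np.abs(mask.imag)) > 1e-8 * scale:
        raise FloatingPointError("mask has non-negligible imaginary part")
    return mask.real


def make_hybrid(
    component_cardinal: np.ndarray | str | Path,
    component_intercardinal: np.ndarray | str | Path,
    spec: HybridSpec,
    wv: WindowOfVisibility | None = None,
    filt_cardinal: OrientationFilter | None = None,
    filt_intercardinal: OrientationFilter | None = None,
    target_size: int = CANVAS_SIZE,
) -> HybridStimulus:
    """Full pipeline: preprocess, filter, equate, compose, window, mask."""
    size = (target_size, target_size)
    wv = wv or build_wv(size, ppd=spec.ppd)
    filt_cardinal = filt_cardinal or cardinal_filter(size, ppd=spec.ppd)
    filt_intercardinal = filt_intercardinal or intercardinal_filter(size, ppd=spec.ppd)

    pre_c = preprocess_component(component_cardinal, target_size, pad=spec.pad)
    pre_i = preprocess_component(component_intercardinal, target_size, pad=spec.pad)
    filt_c = apply_filter(pre_c, filt_cardinal)
    filt_i = apply_filter(pre_i, filt_intercardinal)
    scaled_c, scaled_i, info = equate_components(filt_c, filt_i, spec, wv)
    image, clip_fraction = compose_hybrid(scaled_c, scaled_i, spec)
    mask = make_mask(image, seed=spec.seed)
    return HybridStimulus(
        image=image,
        mask=mask,
        display_image=apply_aperture(image, spec.window_diameter_deg, spec.ppd),
        display_mask=apply_aperture(mask, spec.window_diameter_deg, spec.ppd),
        cardinal_component=scaled_c,
        intercardinal_component=scaled_i,
        e_cardinal=info["e_cardinal"],
        e_intercardinal=info["e_intercardinal"],
        realized_log_ratio=math.log(info["e_cardinal"] / info["e_intercardinal"]),
        clip_fraction=clip_fraction,
        alpha_cardinal=info["alpha_cardinal"],
        alpha_intercardinal=info["alpha_intercardinal"],
        spec=spec,
    )
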