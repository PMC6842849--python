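"""Procedural component images and simulated observers.

This module is the test harness for the rest of the pipeline: it stands in
for photographic image sets and human participants.

Component textures come in two classes that emulate the spectral statistics
of the two stimulus families: *rectilinear* ("man-made-like") textures whose
power spectra are dominated by cardinal orientations, and *isotropic*
("natural-like") textures with orientation-uniform spectra.  Both start from
seeded noise shaped by a 1/f^beta power envelope (beta = 2, the canonical
natural-image slope); the rectilinear class superimposes axis-aligned
rectangles, with the mixing weight solved by bisection until the measured
cardinal-to-oblique power ratio matches the requested anisotropy factor.  The
anisotropy analyzer is thus the closed-loop oracle for the generator.

Simulated observers answer classification trials with choice probabilities
drawn from the same 4-parameter cumulative-normal psychometric function the
analysis fits, optionally with per-category preference offsets, enabling
end-to-end parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design_io import LOG_RATIO_LEVELS, TrialRecord
from .psychometrics import lr_test_bias, psychometric_function
from .visibility import cardinal_to_oblique_ratio

__all__ = [
    "TextureSpec",
    "ObserverModel",
    "generate_component",
    "simulate_trials",
    "simulate_binomial_counts",
    "lr_test_rejection_rate",
]


@dataclass(frozen=True)
class TextureSpec:
    """Spectral recipe for one procedural component image.

    kind: "rectilinear" (cardinal-dominated spectrum) or "isotropic".
    beta: exponent of the 1/f^beta power envelope (2.0 ~ natural images).
    anisotropy: target cardinal-to-oblique mean power ratio; must be 1 for
    isotropic textures and > 1 for rectilinear ones.
    """

    kind: str = "isotropic"
    beta: float = 2.0
    anisotropy: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("isotropic", "rectilinear"):
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if self.anisotropy < 1.0:
            raise ValueError("anisotropy factor must be >= 1")
        if self.kind == "rectilinear" and self.anisotropy <= 1.0:
            raise ValueError("rectilinear textures need anisotropy > 1")
        if self.kind == "isotropic" and self.anisotropy != 1.0:
            raise ValueError("isotropic textures must have anisotropy = 1")


def _pink_noise(size: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance noise with a 1/f^beta power spectrum."""
    white = rng.standard_normal((size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    envelope = np.zeros_like(f)
    envelope[f > 0] = f[f > 0] ** (-beta / 2.0)  # amplitude = sqrt(power)
    shaped = np.fft.ifft2(np.fft.fft2(white) * envelope).real
    shaped -= shaped.mean()
    return shaped / shaped.std()


def _rectangle_field(size: int, rng: np.random.Generator, n_rects: int = 40) -> np.ndarray:
    """Sum of random axis-aligned rectangles: carpentered spatial structure."""
    canvas = np.zeros((size, size))
    for _ in range(n_rects):
        h = rng.integers(size // 16, size // 2)
        w = rng.integers(size // 16, size // 2)
        top = rng.integers(0, size - h)
        left = rng.integers(0, size - w)
        canvas[top : top + h, left : left + w] += rng.uniform(-1.0, 1.0)
    canvas -= canvas.mean()
    sd = canvas.std()
    return canvas / sd if sd > 0 else canvas


def _cardinal_boost(size: int, strength: float, hwhh: float = 15.0) -> np.ndarray:
    """Spectral power gain 1 + strength * (wrapped lobes at 0/90 deg structure)."""
    from .orientation_filters import hwhh_to_sigma, structure_orientation_grid, wrapped_gaussian_gain

    theta = structure_orientation_grid((size, size))
    sigma = hwhh_to_sigma(hwhh)
    lobes = wrapped_gaussian_gain(theta, 0.0, sigma) + wrapped_gaussian_gain(theta, 90.0, sigma)
    gain = 1.0 + strength * lobes
    gain[0, 0] = 1.0
    return gain


def _render(
    base: np.ndarray,
    rects: np.ndarray | None = None,
    rect_weight: float = 0.0,
    boost: float = 0.0,
) -> np.ndarray:
    """Shape the noise spectrum, mix in rectangles, map to display range [0, 1]."""
    field_ = base
    if boost > 0:
        gain = _cardinal_boost(base.shape[0], boost)
        field_ = np.fft.ifft2(np.fft.fft2(base) * np.sqrt(gain)).real
        field_ = (field_ - field_.mean()) / field_.std()
    if rects is not None and rect_weight > 0:
        field_ = field_ + rect_weight * rects
    field_ = (field_ - field_.mean()) / field_.std()
    return np.clip(0.5 + 0.15 * field_, 0.0, 1.0)


def generate_component(spec: TextureSpec, size: int = 300) -> np.ndarray:
    """Generate one procedural component image in [0, 1].

    Rectilinear textures superimpose axis-aligned rectangles on the 1/f^beta
    noise and additionally boost spectral power at cardinal structure
    orientations; the boost strength is solved by bisection until the
    measured cardinal-to-oblique power ratio of the rendered image is within
    2% of ``spec.anisotropy`` (for targets below the rectangles' own
    anisotropy, the rectangle weight is bisected down instead).
    Deterministic given ``spec.seed``.
    """
    if size < 32:
        raise ValueError("size must be at least 32 pixels")
    rng = np.random.default_rng(spec.seed)
    base = _pink_noise(size, spec.beta, rng)
    if spec.kind == "isotropic":
        return _render(base)

    rects = _rectangle_field(size, rng)
    target = spec.anisotropy
    rect_weight = 0.75

    def solve(measure, lo, hi, render):
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            ratio = measure(mid)
            if abs(ratio - target) <= 0.02 * target:
                return render(mid)
            if ratio < target:
                lo = mid
            else:
                hi = mid
        return render(0.5 * (lo + hi))

    baseline = cardinal_to_oblique_ratio(_render(base, rects, rect_weight, 0.0))
    if baseline >= target:
        # rectangles alone overshoot the target: back their weight off
        return solve(
            lambda w: cardinal_to_oblique_ratio(_render(base, rects, w, 0.0)),
            0.0, rect_weight,
            lambda w: _render(base, rects, w, 0.0),
        )

    def measured(boost: float) -> float:
        return cardinal_to_oblique_ratio(_render(base, rects, rect_weight, boost))

    lo, hi = 0.0, 4.0
    for _ in range(30):
        if measured(hi) >= target:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise ValueError(f"anisotropy {target} unattainable with this seed")
    return solve(
        measured, lo, hi, lambda c: _render(base, rects, rect_weight, c)
    )


# --------------------------------------------------------------------------
# simulated observers


@dataclass(frozen=True)
class ObserverModel:
    """Generative observer: per-condition psychometric parameters.

    ``params`` maps condition name -> (mu, sigma, gamma, lambda); conditions
    not listed fall back to ``default_params``.  ``category_preference`` maps
    a category label to a preference offset in ln-energy units: a trial's
    effective mu is mu - pref(cardinal category) + pref(intercardinal
    category), so a positive preference makes that category dominate
    regardless of which filter band it occupies.
    """

    default_params: tuple[float, float, float, float] = (0.0, 0.8, 0.02, 0.02)
    params: dict = field(default_factory=dict)
    category_preference: dict = field(default_factory=dict)
    seed: int | None = None

    def trial_probability(self, trial: TrialRecord) -> float:
        mu, sigma, gamma, lam = self.params.get(trial.condition, self.default_params)
        mu_eff = (
            mu
            - self.category_preference.get(trial.cardinal_category, 0.0)
            + self.category_preference.get(trial.intercardinal_category, 0.0)
        )
        return float(
            psychometric_function(trial.log_ratio, mu_eff, sigma, gamma, lam)
        )


def simulate_trials(
    observer: ObserverModel,
    session: list[TrialRecord],
    seed: int | None = None,
) -> list[TrialRecord]:
    """Complete a session: each trial answered per the observer's model.

    The cardinal component is chosen with probability p(x); the response
    category is set to the chosen component's category, so the generated
    records are ready for response coding and fitting.  Seed precedence:
    explicit ``seed`` argument, else ``observer.seed``.
    """
    rng = np.random.default_rng(observer.seed if seed is None else seed)
    completed = []
    for trial in session:
        p = observer.trial_probability(trial)
        choose_cardinal = rng.random() < p
        response = (
            trial.cardinal_category if choose_cardinal else trial.intercardinal_category
        )
        completed.append(
            replace(
                trial,
                response_category=response,
                response_is_cardinal="cardinal" if choose_cardinal else "intercardinal",
            )
        )
    return completed


def simulate_binomial_counts(
    mu: float,
    sigma: float,
    gamma: float,
    lam: float,
    levels=LOG_RATIO_LEVELS,
    n_per_level: int = 8,
    rng: np.random.Generator | None = None,
):
    """Per-level cardinal-choice counts for one simulated condition.

    Equivalent to simulating ``n_per_level`` Bernoulli trials at each level
    and aggregating; used for fast calibration studies.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(levels, dtype=float)
    p = psychometric_function(x, mu, sigma, gamma, lam)
    n = np.full(x.shape, n_per_level)
    k = rng.binomial(n, p)
    return x, k, n


def lr_test_rejection_rate(
    n_observers: int = 1000,
    seed: int | None = None,
    mu: float = 0.0,
    sigma: float = 0.8,
    gamma: float = 0.02,
    lam: float = 0.02,
    levels=LOG_RATIO_LEVELS,
    n_per_level: int = 8,
    alpha: float = 0.05,
) -> float:
    """Fraction of simulated observers whose zero-bias test rejects.

    With mu = 0 this measures the empirical type-I error of the
    likelihood-ratio bias test under the session design (11 levels x
    ``n_per_level`` copies per condition); it should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_observers):
        x, k, n = simulate_binomial_counts(
            mu, sigma, gamma, lam, levels=levels, n_per_level=n_per_level, rng=rng
        )
        test = lr_test_bias(x, k, n, alpha=alpha)
        rejections += int(test.significant)
    return rejections / n_observers
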