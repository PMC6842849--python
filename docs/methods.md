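# Methods

This note documents the models, conventions and numerical choices behind
`hybridpsych`, and what the synthetic-data harness does and does not show
about real data.

## Orientation filters

Filters act on *image-structure* orientation: 0° means horizontal contours.
Because horizontal structure carries its power along the vertical spectral
axis, the gain map is evaluated at the spectral angle + 90°. Each filter is
a sum of unit-peak wrapped Gaussians on the 180°-periodic orientation
circle; the half-width at half height (default 23.6°) applies to a single
lobe, whose overlap with the orthogonal lobe at the peak (~4 × 10⁻⁵) is
ignored. The wrap sum uses k ∈ {−2, …, 2} after reducing the offset to its
principal value in [−90°, 90°), which is exact to well below 10⁻¹² for any
HWHH up to ~25°. Gains are evaluated at each spectral coordinate's exact
angle — no angular interpolation — and the DC gain is set to 1 so that mean
luminance passes unchanged (orientation is undefined at DC; the mean is
remapped at composition). The gain map is point-symmetric over the
two-sided DFT grid (zero frequency at the origin index), so filtered images
are real to machine precision.

A consequence of the two-lobe definition worth noting: structure exactly
45° from both cardinal lobes receives gain 2·exp(−45²/(2σ²)) ≈ 0.161, twice
the single-lobe value, because both lobes contribute equally there.

## Window of visibility and visible energy

The contract the pipeline relies on is only that visible energy is the dot
product of a power spectrum with a fixed nonnegative gain map whose DC gain
is zero. The shipped gain map is a pluggable default, not a claim about any
particular observer: a log-parabola contrast-sensitivity profile with unit
gain at 3 cycles/degree and a 2-octave full width at half amplitude,
multiplied by an oblique-attenuation term 1 − a·sin²(2θ) with a = 0.3 by
default (a = 0 gives an isotropic window). The map is normalized to unit
maximum. All parameters are exposed in `CSFParams` and recorded in exported
metadata.

Transform conventions are pinned: the unnormalized forward DFT
(`numpy.fft.fft2`). With a gain of 1 everywhere except DC, visible energy
equals the spatial-domain variance times the squared pixel count; the
energy constant S = 1.33 × 10⁸ is meaningful only relative to this
convention. The display mapping assumes 33.33 pixels/degree (1.8 arcmin per
pixel).

## Hybrid construction

Components are converted to grayscale (BT.601 luma weights), resized to the
300-px working canvas (a 9° image at 33.33 px/deg, matching the 300 × 300
mask noise), mean-removed, optionally zero-padded (the 50-px pad of the
second experiment variant), windowed by a radial raised-cosine with a 10%
taper, cropped back and re-meaned. With the pad, most of the taper falls
outside the crop, which keeps edges near the image boundary sharp.

Energy equating solves E_c = S·eʳ/(1+eʳ), E_i = S/(1+eʳ) and scales each
filtered component about its own mean by α = √(E_target/E_current); since
the window's DC gain is zero this realizes the target sum and ln-ratio to
machine precision. Composition sums the mean-removed components and maps
them affinely so the background mean sits at mid-gray and ±3 SD of the
combined pixel distribution spans the display range; out-of-range pixels are
clipped and the clipped fraction is reported, never silently rescaled
per-image (that would break the energy calibration; typical clip fractions
are below 1%). The composed image is centered on a 314-px canvas (the
smallest square holding the 9.4° aperture) and pixels outside the hard
circular aperture are set to background gray. Scaling about the mean versus
including DC is not observable in the energy targets (DC gain is zero); the
mean-removal choice keeps the display remap independent of the equating.

Masks add the phase spectrum of a seeded uniform-[0, 1] noise image to the
hybrid's phase spectrum, exactly preserving the amplitude spectrum; because
the noise is a real image its phase is Hermitian-odd and the mask is real.
The mask is computed from the composed (clipped) display-range hybrid, so
the spectrum match refers to the stimulus actually shown. Presentation
timing (0.10 s stimulus, 0.20 s mask) is metadata only; no display gamma
handling is attempted.

## Session designs and response coding

Both experiment presets use eight conditions and the 11-level ln-ratio set
(±3.66, ±2.20, ±1.39, ±0.41, ±0.20, 0). Each condition presents every level
exactly `copies` times (8 → 704 trials; 10 → 880), with the pooled trial
list shuffled by a single seeded generator per session. Experiment 1 fixes
one component's category and draws the other uniformly from the remaining
three, independently per trial; experiment 2 fixes both (four category
pairs × two filter assignments).

A response naming a category absent from the hybrid is coded "neither". The
default analysis keeps such trials in the binomial denominator as
non-successes, preserving trial counts; an "exclude" policy is selectable.
Nothing in the package generates "neither" responses, so the choice only
matters for real data, where the right policy is genuinely ambiguous.

## Psychometric fitting and tests

The binomial log-likelihood of p(x) = γ + (1−γ−λ)Φ((x−μ)/σ) is maximized
over a bounded box: σ ∈ [0.01, 20] ln-units and γ, λ ∈ [0, 0.25], which
keeps the fitted function strictly increasing. Optimization is a
deterministic multi-start: a coarse grid over data-driven μ and σ values
crossed with two asymptote levels is evaluated vectorized, and the best
three points are refined with L-BFGS-B — fits are exactly reproducible from
the data with no random state. Data with identical responses at every level
(all k = 0 or all k = n) leave μ unidentifiable; such fits are returned
flagged degenerate and unconverged rather than raising.

The zero-bias test refits with μ fixed at 0 and refers the deviance
−2 ln(L_constrained/L_unconstrained), floored at 0 against optimizer
jitter, to χ² with 1 degree of freedom. Under the 11-level × 8-copy design
with σ = 0.8 and 2% asymptote rates, the empirical type-I error over 1000
simulated unbiased observers lands within the binomial 95% band of the
nominal 0.05 (the acceptance script recomputes this each run). Confidence
intervals for μ use the profile likelihood (χ²₁ threshold, bisection +
Brent root-finding), truncated at the box bounds when unbracketed.

Categorical pooling re-expresses the stimulus axis as ln(E_category/E_other)
— trials with the category in the cardinal band keep x = r, trials with it
in the intercardinal band use x = −r — and refits with success defined as
"category chosen"; positive bias then favours the category irrespective of
filtering. Group inference is a two-tailed one-sample t-test with Cohen's
d = t/√n enforced as an exact identity. Repeated-measures ANOVAs and
pairwise comparisons are deliberately out of scope — they are standard
off-the-shelf statistics with no method-specific content.

## Synthetic data: what it does and does not emulate

The texture generator emulates one spectral property of the real image
sets: man-made categories' power spectra are dominated by cardinal
orientations while natural categories' are largely isotropic. Both classes
start from seeded Gaussian noise shaped to a 1/f² power envelope (the
canonical natural-image slope). The rectilinear class superimposes random
axis-aligned rectangles (fixed weight 0.75 in SD units) and additionally
boosts spectral power at cardinal structure orientations with 15°-HWHH
wrapped lobes; the boost strength is bisected until the rendered image's
measured cardinal-to-oblique power ratio is within 2% of the requested
anisotropy factor (for targets below what the rectangles alone produce, the
rectangle weight is bisected down instead). The analyzer is therefore the
generator's closed-loop oracle. These textures have no objects, semantics,
phase structure or real-world size — so passing tests demonstrate the
machinery (filtering, equating, fitting) is correct, not that any
particular bias exists in nature.

The anisotropy statistic classifies spectral coordinates within 22.5° of
the cardinal axes against the rest, restricted to the inscribed spectral
disc (≤ 0.5 cycles/pixel) so both classes sample matched radial
frequencies, and excluding radii below 4 cycles per image where angular
sampling is too coarse to assign an orientation (without the guard, the few
giant low-frequency coefficients of a 1/f² spectrum land at coarse angular
positions and distort the ratio by tens of percent). The orientation
histogram (`anisotropy_profile`) partitions the full non-DC power exactly
and also reports per-bin coordinate counts: on a square grid the corners
put more coordinates into oblique bins, so isotropy should be judged on
mean power per coordinate.

Simulated observers choose the cardinal component with probability given by
their condition's psychometric parameters (default σ = 0.8, γ = λ = 0.02 —
session-realistic values), with optional per-category preference offsets
added to the effective μ. Parameter recovery at the real per-condition
sample size (88 trials) carries a per-fit SD of about 0.2 ln-units on the
bias; recovery tests bound condition means accordingly (≈4 SE per
condition, 0.1 ln-units on the ensemble mean over conditions).

## Problem sizes and determinism

The test suite runs filters and windows mostly on 64–128-px grids, the
full-canvas checks on 300 px, and the calibration study at 1000 replicates;
the whole suite completes in well under a minute on one core. Every
stochastic operation takes an explicit seed; the acceptance script fans a
single root seed out to all of them via `numpy.random.default_rng`.

## Known limitations

- The window-of-visibility parameterization is a documented default, not a
  fit to any observer or a reconstruction of any published parameter set;
  visible energies are comparable only within a fixed parameterization and
  transform convention.
- Bounded ML is used for the psychometric fits; Bayesian priors (as in
  psignifit-style toolboxes) are not implemented, so estimates can differ
  from such toolboxes in small samples, particularly for γ and λ at their
  bounds.
- The deviance's χ²₁ reference is asymptotic; with 88 trials and nuisance
  asymptote parameters near their bounds the realized type-I error can sit
  slightly above nominal (measured ≈ 0.05–0.06 under the default design).
- Procedural textures capture orientation statistics only; no claim about
  recognizability or category semantics is possible with them.
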