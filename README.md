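# hybridpsych

Tools for building **ambiguous hybrid images** — superpositions of two
component images from different object categories, one carrying
near-cardinal (horizontal/vertical) orientation structure and the other
near-intercardinal (oblique) structure — and for analysing the
classification biases such stimuli elicit in psychophysical experiments.

The package is aimed at visual psychophysicists studying perceptual biases
in object classification. When both components of a briefly flashed hybrid
are equated for modelled visibility, the choice an observer makes reveals
which category their visual system expects; the analysis here quantifies
that expectation as a bias in log visible-energy units.

## The method

**Stimuli.** A component image is filtered in the Fourier domain by a gain
map built from two wrapped Gaussians in image-structure orientation (peaks
at 0°/90° for the cardinal filter, 45°/135° for the intercardinal one; each
lobe has a half-width at half height of 23.6°). The *notionally visible
energy* of an image is

    E = Σ_f |F(f)|² · WV(f)

the dot product of its power spectrum with a *window of visibility* WV — a
fixed nonnegative gain map modelling early contrast sensitivity (here a
log-parabola CSF peaking at 3 cycles/degree with an optional oblique
attenuation). Each component's amplitude spectrum is rescaled so the two
visible energies have a fixed sum, S = 1.33 × 10⁸, and a requested natural-log
ratio r = ln(E_c/E_i); the sum of the components is shown in a hard-edged
9.4°-diameter circular aperture, followed by a phase-scrambled mask with the
identical amplitude spectrum.

**Analysis.** Per condition, the probability of choosing the cardinal
component as a function of x = ln(E_c/E_i) is fitted by maximum likelihood
with a 4-parameter cumulative normal,

    p(x) = γ + (1 − γ − λ) Φ((x − μ)/σ),

and the **bias** is −μ (positive: the cardinal — or, after pooling, the
named-category — component dominates at equal visible energy). Each bias is
tested against zero with a generalized likelihood-ratio test (nested fit
with μ = 0, deviance referred to χ²₁), categorical biases pool the two
conditions in which a category occupied either filter band, and group-level
inference uses one-sample t-tests with Cohen's d = t/√n.

Procedural textures (cardinal-dominated "man-made-like" and isotropic
"natural-like" spectra) and simulated observers drawn from the same
psychometric model make the entire pipeline testable without photographs or
participants.

## Worked example

```python
from hybridpsych import (HybridSpec, TextureSpec, generate_component,
                         make_hybrid)

house_like  = generate_component(TextureSpec("rectilinear", anisotropy=4.0, seed=1), 300)
flower_like = generate_component(TextureSpec("isotropic", seed=2), 300)
stim = make_hybrid(house_like, flower_like, HybridSpec(log_ratio=0.41, seed=3))
print(stim.e_cardinal, stim.e_intercardinal, stim.realized_log_ratio)
```

prints

```
E_cardinal      = 7.99447e+07
E_intercardinal = 5.30553e+07
sum             = 1.33e+08
realized ln-ratio = 0.4100
clipped pixels    = 0.54%
```

— the two filtered components' visible energies sum to the configured
1.33 × 10⁸ exactly and realize the requested ln-ratio 0.41; about half a
percent of pixels clipped during the display remap. Fitting a simulated
observer (true μ = −0.5, i.e. bias +0.5) on a full 704-trial session:

```python
from hybridpsych import (ObserverModel, generate_experiment_session,
                         lr_test_bias, records_to_frame, simulate_trials)
from hybridpsych.psychometrics import aggregate_binomial

session  = generate_experiment_session(1, seed=10)
observer = ObserverModel(default_params=(-0.5, 0.8, 0.02, 0.02))
frame = records_to_frame(simulate_trials(observer, session, seed=11))
sub = frame[frame["condition"] == "CH"]
test = lr_test_bias(*aggregate_binomial(sub))
print(test.unconstrained.bias, test.p_value)
```

```
CH: bias = +0.915 (mu=-0.915, sigma=0.402), deviance = 22.12, p = 2.564e-06
```

Across this session's eight conditions the fitted biases were +0.34, +0.33,
+0.92, +0.59, +0.49, +0.27, +0.41 and +0.50 — scattered about the generating
+0.5 with the sampling spread expected from 88 trials per condition (each
single-condition estimate carries an SD of roughly 0.2).

The same operations are available from the shell:

```bash
hybridpsych make-session --experiment 1 --seed 0 --out session.csv
hybridpsych simulate --experiment 1 --observers 10 --seed 0 --out-dir sims/
hybridpsych fit --trials sims/obs00.csv --out fits.csv
hybridpsych group-stats --fits all_fits.csv --out table.csv
hybridpsych make-hybrid --component-c house.png --component-i flower.png \
    --log-ratio 0.41 --seed 3 --out stim
```

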