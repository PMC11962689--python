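# Methods

This document records the physical model, the conventions, the synthetic
data generators, and the numerical choices behind `cytomech`, together with
measured limitations of the tip-search procedure.

## 1. Contact model

A force curve records cantilever deflection against piezo extension. With
spring constant `k`, force is `F = k * deflection`, and tip–sample
deformation past the contact point `z_c` is

```
d = (z - z_c) - deflection
```

The fitted force law has an adhesion/surface term and a Hertz-like
indentation term:

```
F(d) = 4*pi*R*d*sigma * cos(arctan(2R/d))  +  (4/3) * gfac * E * sqrt(R) * d^1.5
```

- `sigma` (N/m) scales the surface term; `E` (Pa) is the elastic modulus.
- `gfac` is the Poisson-ratio factor. The default convention
  (`hertz_convention="as_printed"`) uses `gfac = 1 - gamma^2` as a
  multiplier with `gamma = 0.5`; `"divided"` gives the conventional
  `1 / (1 - gamma^2)`. Generator and fitter share one
  `ContactModelParams`, so round trips are always convention-consistent.
- Using `cos(arctan(x)) = 1/sqrt(1+x^2)`, the surface term is evaluated as
  `4*pi*R*d^2*sigma / sqrt(d^2 + 4R^2)`, which is well-behaved at `d -> 0`.

The **effective tip radius** is not constant; it depends on the local
sample slope and on deformation:

```
R(x, y, d) = r + a * dz/dx + b * dz/dy + c * d
```

with `(r, a, b, c)` the tip coefficients and `dz/dx`, `dz/dy` the
topography gradients at the pixel. Admissibility requires `R > 0` over the
curve's deformation range; pixels violating it are masked.

## 2. Per-curve fitting

For fixed tip coefficients and contact point, `F(d)` is linear in
`(sigma, E)`, so each curve is solved by least squares on the two basis
vectors `u(d) = 4*pi*R*d^2/sqrt(d^2+4R^2)` and
`v(d) = (4/3)*gfac*sqrt(R)*d^1.5`. Two numerical details matter:

- **Iterative refinement (2 passes).** For realistic values the sigma term
  is ~1e-6 of the total force, and a single `lstsq` solve recovers sigma
  only to ~4e-7 relative; two refinement passes on the residual bring it to
  ~1e-9 (the double-precision floor for this conditioning).
- **Collinearity guard.** The basis columns differ by ~6 orders of
  magnitude in scale, so the condition number is computed on
  unit-normalized columns (threshold 1e8). Well-posed curves measure ~16–44;
  a degenerate near-constant-`d` curve measures ~4e10.

The per-curve root-mean-square residual (`rms`) is the map-level quality
signal used by the tip search.

## 3. Contact detection and refinement

- **Threshold detection** (`detect_contact`): baseline and noise level are
  estimated from the first 30% of the approach; contact is the last
  crossing of baseline + 3 sigma before the setpoint. Exact to about one
  z-step on noiseless data; on 1%-noise data soft pixels detect the
  crossing ~200 nm late, which is fatal for modulus accuracy (measured
  median modulus error 179% — the free sigma term absorbs the distortion).
- **Changepoint refinement** (`refine_contact`): for each candidate `z_c`
  on a 5 nm grid in a window around the threshold estimate, the model is
  "zero force before contact, single-coefficient Hertz term after", and
  the total squared error over the window is minimized. The sigma basis is
  deliberately excluded: with sigma free, wrong contact points fit nearly
  as well and the estimator degenerates (measured p10 error −228 nm).
  With the true tip on 1%-noise data the refined contact has −0.1 nm
  median error, and the downstream median modulus error is 1.1%
  (p90 2.5%) on cell pixels.
- **The refinement needs a tip hypothesis and inherits its bias.**
  Refining under a wrong constant-radius tip shifts contacts coherently
  (measured +123 nm for r doubled). `process_map(fv, params, refine_tip=...)`
  makes the hypothesis explicit. Substrate pixels (GPa-stiff) refine
  ~22 nm early because the Hertz term cannot represent a rigid wall; they
  are excluded from summaries by the height-based substrate cutoff.

## 4. Topography

Per-pixel sample height is `z_max - z_c` (piezo range minus contact),
shifted so the minimum is zero. Gradients use second-order central
differences (`numpy.gradient`) scaled by the pixel pitch. Masked pixels
(no valid contact) propagate into the gradient mask.

## 5. Tip-coefficient search

`optimize_tip` is a seeded greedy Markov-chain search over `(r, a, b, c)`:
at each loop a Gaussian perturbation of the current state is evaluated and
accepted iff the objective does not increase. The objective is the
**variance over pixels of the per-curve rms residuals**: a correct `R(d)`
model fits every pixel equally well, so the spread of rms across the map is
minimized at the true coefficients. The trace records every proposal;
`best_so_far` is non-increasing by construction.

### Limitations (measured)

These are properties of the estimation problem, not of the implementation;
the numbers below are from seeded experiments reproducible with
`scripts/acceptance.py`.

1. **Noise floor of the variance objective.** With per-sample force noise
   `s` and `n` samples per curve, a correctly fitted curve has rms that
   fluctuates with standard deviation ~`s/sqrt(2n)`; the variance-of-rms
   objective therefore has a floor of ~`s^2/(2n)`. At 1% of a 1.5 nN
   setpoint (`s` = 15 pN, `n` ≈ 150) the floor is ~6.8e-25 N², and the
   measured objective at the true coefficients is exactly there. The
   objective at a 2x-perturbed initial radius is only ~1.8x the floor, so
   large relative objective reductions are impossible in this regime —
   most of the initial objective *is* noise.
2. **Tip identifiability at 1% noise.** Per-pixel `(sigma, E)` are free
   parameters, so a wrong `R(d)` is absorbed almost perfectly into
   rescaled coefficients; the residual systematic misfit must exceed
   ~0.34x the noise before the objective can register it. Measured: a
   1000-loop search can reach an objective *below* the true tip's value at
   coefficients whose refit modulus map has ~50% median error. At this
   noise level a low objective does not certify a correct tip.
3. **No alternating refinement.** Iterating contact refinement and tip
   search diverges: refining under a wrong tip biases contacts coherently,
   the free coefficients absorb the bias, and the objective anti-correlates
   with modulus accuracy (measured median error growing 0.34 → 4.5 over
   rounds). The pipeline refines contacts once, under the explicitly
   assumed tip.
4. **Noiseless regime.** Without noise the floor vanishes and the search
   behaves as expected: the objective at the true coefficients is ~1e-33 N²
   and strictly below random admissible perturbations, and a short greedy
   run reduces the initial objective by many orders of magnitude.

## 6. Line-scan modulus summary

`line_scan_summary` takes per-pixel moduli along a scan line, removes
substrate pixels (optional height cutoff/mask), applies Tukey IQR fences
(1.5x), and returns the mean of the survivors. At least 4 values must
survive (e.g. `[1, 2, 3, 4, 100] -> 2.5` after the fence removes 100).

## 7. Image quantification

- **Orientation histograms** use Gaussian-derivative gradients (sigma 1 px);
  each pixel votes for the structure orientation (gradient rotated 90°,
  folded to [-90°, 90°)) weighted by gradient energy. The alignment score
  is the population SD of the normalized bin weights: 0 for isotropic,
  maximal for a single spike.
- **Radial profiles** average intensity over integer-rounded-distance rings;
  the identity `sum(mean * count) = total intensity inside r_max` holds to
  machine precision.
- **Particle analysis**: optional 3x3 sharpening (undershoot clipped at 0),
  exact-value Otsu threshold, connected-component labelling, area filter at
  0.1 um². The exact Otsu splits the unique sample values and returns the
  midpoint of the separating gap; binned Otsu can return a bin centre below
  the background level on images with large empty intensity gaps.
- **Shape descriptors**: perimeter is measured by marching squares on a
  Gaussian-smoothed (sigma 1.5 px) 0/1 indicator, contoured at 0.5. Raw
  binary marching squares overestimates a disc's perimeter by ~5%
  (staircase); sigma 1.5 gives disc perimeter within 0.2%, square perimeter
  within 1.3%, and <2% circularity change under 2x nearest-neighbour
  resampling. Circularity is `4*pi*A/P^2`.
- **Intensity metrics**: corrected total fluorescence
  `IntDen - area * mean(background)`, positive-area fraction at a fixed
  threshold, and before/after area ratios (zero before-area raises
  `ZeroDivisionError`).

## 8. Statistics

Two-tailed Student's t-test, pooled variance by default ("type 2"),
Welch's form via `equal_var=False`, through `scipy.stats.ttest_ind`.
Both-groups-constant-and-equal raises `UndefinedStatisticError`;
constant-unequal returns infinite `t` with `p = 0`. Significance flags are
derived properties of `p`.

## 9. Synthetic data as study conditions

Generator defaults model the study system: a spherical-cap cell dome
(default 16x16 map, 6 um dome radius, 2.5 um height) on rigid substrate
(1 GPa), cytoplasm modulus field with optional lognormal jitter, tip truth
`r = 50 nm` with slope and depth coefficients, 1.5 nN setpoint, 10 nm
z-step. Filament images draw fibers with von-Mises-distributed axial
orientations (kappa controls alignment); particle images plant discs with
known areas either side of the 0.1 um² cutoff and emit a ground-truth
table.

## 10. Determinism

Every generator and the search take explicit seeds. The pipeline derives
per-replicate seeds from the master seed independently of the condition
index, so identically configured conditions produce identical cohorts
(t = 0, p = 1) — a built-in null check. `run_from_manifest` re-executes a
recorded run and reproduces its CSV outputs byte-for-byte.
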