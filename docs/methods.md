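# Methods

This note documents the models, numerical choices and limitations behind
`turbidslab`.  Units everywhere: lengths μm, times ps, c = 299.792458 μm/ps.

## Monte Carlo transport model

The solver is a weighted photon-packet random walk through a stack of
homogeneous layers, asymptotically exact for the scalar radiative transfer
equation:

- **Free paths** are exponential in each layer's scattering mean free path
  `l_s`; a step crossing a layer boundary carries its remaining optical
  depth into the next layer (so heterogeneous stacks are sampled without
  bias).
- **Scattering** uses the Henyey–Greenstein phase function with the layer's
  anisotropy `g`, sampled by its closed-form inverse CDF.  The phase
  function is a modelling choice: HG is the de-facto standard for
  tissue-like media and has exact first moment `g`.  The similarity-relation
  tests (thick-regime equivalence of `(l_s, g)` and `(l_t, 0)` walks) bound
  the sensitivity of the package's conclusions to this choice.
- **Absorption** is continuous weight attenuation `exp(−μ_a ℓ)` per path
  segment, not survival draws: lower variance, and `μ_a = 0` gives exactly
  zero absorbed weight.
- **Interfaces.**  Unpolarized Fresnel reflection/refraction is applied
  stochastically wherever adjacent refractive indices differ; total internal
  reflection is deterministic.  Layers that differ only in scatterer density
  share one index, so internal crossings are free.  The launch is a
  collimated pencil beam at the origin; `t = 0` is entry into the front
  face, and the specular entry reflection is excluded from the reflectance
  by default (`include_specular_entry=True` adds it as a deterministic
  weight split).  Arrival times accumulate `Σ ℓ_i n_i / c`.
- **Termination.**  Russian roulette below weight 1e−4 with survival
  probability 0.1 (the boost is entered into the per-packet ledger so the
  energy balance stays an identity), and a hard optical-path cap of 100 ps
  whose discarded weight is tracked in `unbinned_tail`.  For every run
  `ΣT + ΣR + A + tail = 1` holds to machine precision by construction — it
  is a bookkeeping identity, not a statistical statement.
- **RNG.**  Each packet owns a splitmix64 stream seeded by hashing
  `(seed, packet index)`.  Results are independent of execution order, and
  replaying the same seed across parameter values yields common random
  numbers (CRN), which the inversions rely on for a quasi-smooth objective.
- **Recording.**  Besides the T/R time histograms (default 0.05 ps bins on
  [0, 50] ps) and an (x, y, t) frame histogram on a coarser time axis, the
  solver accumulates exact per-time-bin moment sums (Σw, Σw², Σwx, Σwy,
  Σwρ²) of back-surface exits, so `w²(t)` is available without pixelation
  or finite-field truncation.

## Diffusion-approximation reference

Time-resolved total transmittance uses the image-source solution on the
extrapolated-boundary domain: the photon density vanishes on planes a
distance `z_e = (2/3) l_t (1+R_eff)/(1−R_eff)` outside the faces, with
`R_eff` the fluence/current angular moments of the unpolarized Fresnel
reflectance, `R_eff = (R_φ + R_j)/(2 − R_φ + R_j)` evaluated by adaptive
quadrature.  (The widely used polynomial fit in `n` corresponds to a
slightly different averaging and differs by up to ~0.045; it is exposed as
`effective_reflection_polynomial` for cross-checking.)  The isotropic
source sits at depth `z₀ = l_t` (configurable).  The image series is
truncated when the outermost image pair contributes < 1e−10 of the sum at
every requested time; the test suite verifies the series against a
finite-difference solution of the 1-D diffusion equation to < 0.5%.
Absorption factorizes exactly as `exp(−μ_a v t)`, which is the mathematical
root of the absorption artifact: the asymptotic decay rate
`1/τ = π² D / L_eff² + μ_a v` can be made arbitrarily fast by assuming
absorption, while at `μ_a = 0` it has a closed-form minimum over `l_t`
(at `2 z_e = L`) that a thin sample's measured decay can undercut.

## Observables and instrument emulation

- **Mean square width** is `Var(x) + Var(y)` of the background-subtracted
  intensity about its centroid (translation and amplitude invariant; a
  per-axis variant exists behind a flag).  Background is the median of the
  outer 2-pixel ring, with negatives clipped and the clipped fraction
  recorded.  Frames whose profile standard deviation exceeds one sixth of
  the field are excluded (truncation bias on the variance would exceed the
  percent level) and reported.
- **Instrument response** is the cross-correlation of two squared-hyperbolic
  -secant pulses computed numerically on a 1 fs grid; equal 112.8 fs pulses
  give the 174 fs response width used by all presets.  Trace convolution
  preserves area and, as the tests verify, leaves the asymptotic tail slope
  unchanged.
- **Detector emulation.**  The PMT channel scales the IRF-convolved
  transmittance to a peak of 1e5 expected counts (a choice recorded in the
  trace metadata; real peak count rates are instrument specific), applies
  Poisson draws, and truncates below an 8-decade dynamic range.  The camera
  channel gates the (x, y, t) histogram over one IRF-width window per frame
  delay, applies a Gaussian optical-resolution blur (FWHM = half the finest
  resolvable line-pair period; 11.3 lp/mm → σ ≈ 18.8 μm), scales to 1e3
  peak counts (per frame for the membrane scenario, emulating per-delay
  integration times; globally for the slab scenarios) and Poisson-averages
  over 100 disorder realizations.  Because synthetic frames inherit the
  generator's Monte Carlo sampling noise on top of the camera noise, every
  stack records a per-frame `mc_noise_scale` in its sidecar and all
  downstream uncertainties include it.
- **Cross-cuts.**  For the isotropically disordered samples the
  ensemble-averaged transverse profile is rotationally symmetric, so the
  default cross-cut estimator is the azimuthal average about the beam axis
  (the row-cut estimator is retained for single anisotropic frames).  This
  is what makes the thin-membrane inversion statistically feasible at
  realistic packet counts.

## Fit windows

Windows are the one genuinely arbitrary element of time-domain analysis, so
the package fixes them by convention and applies them uniformly:

- Tail fits start at twice the transmittance-peak time (the peak is located
  on a 0.55 ps boxcar-smoothed histogram, since a raw argmax jitters by
  several bins between seeds) and end at the last bin with ≥ 10 counts; the
  window must span ≥ 2 decades above that floor.
- Width-slope readings of `D` use the dataset's diffusive window: twice its
  peak time to the last camera delay (14 ps).
- Homogeneous-equivalent *matching* (decay-time- and slope-matched `l_t`
  for the layered stack) extracts slopes over the full camera window
  (2–14 ps) identically for the measured stack and every candidate, because
  `w²(t)` of a heterogeneous stack is not perfectly linear and only
  window-consistent slopes are comparable.
- DA fits run from the 50%-of-peak rising edge to the last bin with ≥ 10
  counts, with Poisson weights.

## Inversions

All Monte Carlo objectives are reduced chi-squares per dataset, summed with
equal weights; traces are compared after area normalization over the fit
window (the experiment has no absolute scale), `w²` series absolutely, and
cross-cuts each normalized to its own area.  The Monte Carlo noise of the
*model* curves is added in quadrature to the data uncertainties — omitting
it makes the objective fit the model's own noise realization, which at
common-random-number settings can favour wrong parameters.

- **One parameter (`l_t`).**  Log-spaced grid with CRN, local quadratic
  interpolation, Δχ² = 1 uncertainty.
- **Three parameters (symmetric 5-layer stack).**  Coarse brute-force grid,
  Nelder–Mead refinement from the four best corners (ties broken toward
  the smallest outer `l_t`), axis-wise Δχ² = 1 probes; flat directions are
  flagged.  Uncertainties are approximate: the CRN objective is not exactly
  a chi-square surface.
- **Two parameters (`g`, `l_s`), thin membrane.**  A coarse (g, l_s) grid
  locates the low-χ² valley (which tracks `l_t = l_s/(1−g)`); a refined
  stage re-grids locally in `(g, l_t)` coordinates at higher packet counts,
  re-centring if its minimum lands on a window edge, and the vertex of a
  weighted 2-D paraboloid over all refined nodes gives the estimate (far
  more noise-robust than argmin-and-neighbours).  A degeneracy guard
  rejects inputs whose objective is flat along constant `l_t` — in an
  optically thick sample that flatness *is* the similarity relation, and
  the guard advises trace-based fitting instead.
- DA-fit parameter uncertainties come from the least-squares covariance
  (lmfit); for the near-boundary `μ_a` these are approximate, and the
  boundary-pinned case is flagged.

## Synthetic-data scope and problem sizes

The generator's defaults are the study conditions: the three preset
scenarios carry exactly the printed sample parameters (203 μm / n 1.52 /
l_t 25.5 or 24.1 μm with l_a 12.0 mm; 22/60/26/60/22 μm with
l_t 11.0/21.5/3.5 μm; 85 μm / n 1.31 / g 0.7 / l_s 150 μm), the 174 fs
sech² IRF, Poisson counting noise and the quoted optical resolutions.  What
it does not emulate: speckle and interference, polarization, angular
acceptance of the upconversion crystal, laser drift, anisotropic in-plane
transport of real membranes (the elliptic wavefront), or deviations of real
phase functions from Henyey–Greenstein.  Passing tests therefore show the
*evaluation machinery* is correct and self-consistent under the stated
noise model, not that any particular real sample follows HG scattering.

Problem sizes are chosen per quantity: 10⁷ packets for the decay-time and
width-slope estimators of the homogeneous reference (the width-slope excess
is a ~4% effect whose estimator needs ~10⁷ packets for sub-point
precision), 10⁶ for absorbed fractions (binomial error < 0.03 points),
10⁶ + 8×10⁵-per-node scans for the layered equivalents, and a
2×10⁷-packet dataset with up to 10⁷-packet model runs for the membrane
inversion.  The test suite runs scaled-down versions of the same pipelines
with fixed seeds.

## Known limitations

- Δχ² = 1 intervals from CRN objectives underestimate the true seed-to-seed
  scatter of the Monte Carlo inversions; the acceptance pipeline quantifies
  accuracy by self-inversion error instead.
- The DA variant (source depth, boundary-coefficient averaging) matters at
  the few-percent level for DA-derived quantities; the Monte Carlo model is
  the ground truth throughout and absorbs those differences.
- The energy ledger admits transiently negative `unbinned_tail`
  contributions from roulette boosts; its expectation is ~0 and the balance
  identity is exact.
- The layered three-parameter objective has near-degenerate directions at
  small packet counts; the multi-start simplex mitigates but does not
  eliminate the risk of a secondary minimum.
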