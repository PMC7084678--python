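# Methods

This note documents the models, conventions and numerical choices behind
lamdiff, in the spirit of a package methods appendix: what is assumed,
what is fitted, and where the design was genuinely open.

## The forward model (`lamdiff.synthetic`)

The synthetic generator exists to make every downstream stage testable
against known ground truth. Its unit cell is the minimal centrosymmetric
parameterization of a fluid lamellar phase:

* a hydrocarbon slab of SLD `rho_CH` occupying `|z| < z_H`, with
  error-function edges of width `sigma_H` (the profile must be continuous
  and even);
* two Gaussian headgroup peaks of amplitude `rho_H − rho_CH` at `±z_H`,
  width `sigma_H`;
* a Gaussian methyl trough of amplitude `rho_CH3 − rho_CH` at the centre,
  width `sigma_CH3`;
* a water slab filling the rest of the cell, whose SLD is the linear
  H₂O/D₂O mix `x·ρ_D2O + (1−x)·ρ_H2O` with
  `ρ_H2O = −0.558×10⁻⁶ Å⁻²` and `ρ_D2O = +6.382×10⁻⁶ Å⁻²`, computed from
  the coherent scattering lengths (b_H = −3.739 fm, b_D = +6.671 fm,
  b_O = +5.803 fm) over a 30 Å³ water molecular volume. The mix crosses
  zero near 8% D₂O — the water contrast-match point, which is why the
  8% condition is the natural reference for reconstruction.

The profile is periodized over neighbouring cells. This is not a detail:
it makes the closed-form Fourier coefficients *exact* (the cell integral
of a periodized Gaussian equals the full-line transform of one Gaussian),
which is what lets the quadrature oracle test demand 10⁻⁶ relative
agreement rather than some hand-waved tolerance.

Defaults describe a diphytanyl-PC-like bilayer at full hydration:
`D = 50.4 Å`, `z_H = 18.7 Å` (so the true peak-to-peak thickness is
37.4 Å), `sigma_H = 2.5 Å`, `sigma_CH3 = 3.0 Å`, `rho_H = 1.8×10⁻⁶`,
`rho_CH = −0.4×10⁻⁶`, `rho_CH3 = −1.0×10⁻⁶ Å⁻²`. With these values the
first four form factors at 8% D₂O carry signs (−, −, +, −), the pattern
characteristic of PC bilayers at the water match point. The randomized
model sampler draws from ranges bracketing fluid PC-type multilayers
(D ∈ [42, 60] Å, z_H/D ∈ [0.30, 0.42], widths 2–3.5 Å, headgroup SLD
above and methyl SLD below the chain plateau).

Detection is modelled as a Gaussian line of width `peak_width = 0.004 Å⁻¹`
(sigma) at each `q_n = 2πn/D`, with integrated intensity
`scale · f_n² · q_n⁻ᵖ` (the generator applies the same Lorentz exponent
the correction later removes), a polynomial background, and Gaussian
counting noise of standard deviation `noise_scale · √I`. The line shape,
width and background are generator conventions — the real instrument's
line shape is not modelled, and no claim is made that these defaults
match it. What passing tests demonstrate is that the analysis chain is
correct and unbiased for data of this general character; they cannot
certify behaviour under instrument-specific artefacts (mosaic broadening,
detector nonuniformity, misalignment) that the generator does not emulate.

## Reduction (`lamdiff.reduction`)

Background: polynomial (constant / linear / degree-k) weighted
least-squares fit on points outside peak exclusion windows. Subtracted
intensities are deliberately not clipped at zero — clipping would bias
integrated intensities upward.

Peak fitting: `scipy.signal.find_peaks` detection with a prominence
threshold of 5× the median per-point uncertainty plus a relative floor of
10⁻⁴ of the strongest prominence (counting noise on the flanks of a
strong peak otherwise produces spurious candidates); each group of peaks
closer than three widths is co-fitted as a sum of Gaussians over a local
linear baseline by `scipy.optimize.curve_fit`. Integrated intensity is
`A·σ·√(2π)` with its standard error from the fit covariance (delta
method, including the A–σ covariance). Non-converged fits are excluded
with a warning; fitted peaks whose area is below 5 standard errors are
treated as noise spikes and likewise excluded with a warning
(`min_snr=0` disables this).

Indexing: hypotheses are tried in order of parsimony —

1. one lamellar series: candidate first-order positions from the lowest
   peak (divided by 1–3) and the median spacing; orders by rounding;
   accepted if every relative position residual is within the tolerance
   (default 1%); `D = 2π/slope` from a weighted least-squares line
   through the origin of `q` vs order, with the slope variance taken as
   the larger of the weight-based and residual-based estimates;
2. one hexagonal series: ratios from {1, √3, 2, √7}, requiring at least
   one genuinely non-integer ratio; the reported lattice constant is
   `a = 4π/(√3 q₁)`;
3. two coexisting lamellar series: seeded by pairs of low-q peaks,
   each lattice must explain at least two distinct orders and every peak
   must be explained;
4. otherwise `unindexed`.

A single peak is indexed as a first-order lamellar reflection and flagged
low-confidence. Classification depends only on position ratios, so it is
invariant under uniform rescaling of q.

## Phasing (`lamdiff.phasing`)

Lorentz correction: `|f_n| = √(I_n · q_nᵖ)`, default `p = +1`, the
standard correction for oriented multilayers. The literal reading of the
relation `I_n = |f_n|²·q_z` as a division is available as `p = −1`, and
`p = 0` disables the correction; the exponent is recorded in the output.
Negative (noise) intensities give zero amplitude with a flag.

Sign determination proceeds in two steps.

1. **Per-order linearity.** For each order, all `2^(c−1)` sign patterns
   over the `c` contrasts are scored by the weighted R² of a straight
   line of signed `f_n` vs `x_D2O`; the best pattern wins. For a
   centrosymmetric cell the signed structure factor is exactly affine in
   the water SLD, so the true pattern achieves R² = 1 on noiseless data.
   This step pins each order's sign *sequence* but leaves one flip per
   order undetermined — flipping all of an order's signs together
   preserves linearity, so linearity alone cannot relate different
   orders.
2. **Water-distribution orientation.** The slope of signed `f_n` vs
   `x_D2O` equals `(ρ_D2O − ρ_H2O)` times the cosine transform of the
   water volume-fraction distribution, which for a stack is a slab
   centred on the unit-cell boundary: transform
   `(−1)ⁿ (2/k_n) sin(k_n d/2) e^(−k_n²s²/2)` for width `d` and edge
   smoothing `s`. The slab parameters are fitted to the slope magnitudes
   (coarse grid plus Nelder-Mead refinement on slope values normalized to
   the largest, so the objective is well-scaled), and each order is
   flipped so its measured slope sign matches the fitted transform sign.
   Because heavy water has the higher SLD, the orientation is absolute,
   not merely relative. Near a node of the transform (`k_n d/2 ≈ π`, i.e.
   order ≈ D/D_w) the slope vanishes and contrast variation is
   fundamentally uninformative about that order's sign — a genuine
   physical limitation, which the ambiguity flags surface. On randomized
   noiseless models the procedure recovers all four analytic signs in
   ≳99.8% of draws; the residual failures sit exactly on the node.

The classic convention that the reconstructed reference-contrast profile
has its minimum at the bilayer centre (the terminal-methyl trough) is
retained: it fixes the global sign when no contrast dependence exists at
all, and otherwise acts as a consistency check (a warning is emitted if
it disagrees with the physical orientation, which does not happen for
bilayer-like data).

Ambiguity: orders whose best and runner-up pattern R² differ by less than
0.01 are flagged; they still receive the best-scoring sign.

## Reconstruction (`lamdiff.reconstruction`)

The profile is the exact truncated cosine series on a symmetric grid
(default step 0.1 Å, ≥250 points per 50 Å cell — far finer than the
four-order resolution). There is no zeroth-order term: profiles are
relative, zero-mean, in arbitrary units, matching how such data are
reported; no absolute normalization to Å⁻² is attempted, and amplitudes
are never compared across conditions. Evenness and periodicity are
asserted on every constructed profile. `truncation_error` returns the L2
distance between the centred model profile and its M-order partial sum
via Parseval (tail coefficient energy, reference series 256 orders —
the Gaussian-damped coefficients are numerically zero far earlier).

## Parameters (`lamdiff.parameters`)

`D_B` is the distance between the two headgroup maxima, each located by a
Gaussian (+ constant) fit over a window extending from the peak to the
nearest inflection points (symmetric: the smaller side is used for both).
The two peak positions must agree under reflection within 3 combined
standard errors (or one grid step); asymmetry raises an error. The chain

    D_w = D − D_B,  A = 2V_l/D_B,  2D_c = 2V_c/A,  n_w = A·D_w/(2V_w)

uses config-supplied molecular volumes. Defaults `V_l = 1400 Å³`,
`V_c = 1175 Å³` are documented approximations for a diphytanyl-PC-rich
mixture (chosen for internal consistency of the tabulated D_B, 2D_c and
n_w at full hydration); `V_w = 30 Å³`. The hydration number counts the
interbilayer water slab per lipid — headgroup-intercalated water is not
partitioned separately.

Errors propagate first-order from the two measured inputs (D, D_B),
including their correlation through the chain (e.g. A and D_w are both
functions of D_B); the standalone operation helpers treat their inputs as
independent, which is the right thing when the inputs genuinely are. A
Monte-Carlo mode (independent normal resampling of D and D_B) provides a
linearization-free cross-check; at the measured scale
(D ≈ 50.4 ± 0.1, D_B ≈ 37.4 ± 0.2 Å) the two agree to well under 1%.

## Pipeline and reproducibility (`lamdiff.pipeline`, `lamdiff.cli`)

A condition (one temperature/humidity state) holds one or more contrasts.
Conditions indexing as hexagonal or coexisting-lamellar, or with fewer
than two usable Bragg orders, are reported lattice-only with the reason
logged — parameters are never silently degraded to guesses. Contrasts
whose own lattice constant deviates from the reference contrast's by more
than twice the indexing tolerance are excluded from the structure-factor
table (again logged). Single-contrast conditions accept a user-supplied
phase vector, mirroring the practice of reconstructing a
reference-contrast profile with phases determined once from a full
series. All randomness flows from the config seed (per-contrast generator
seeds are derived deterministically), so identical config plus seed gives
identical outputs; the run log records version, config hash and seed.

## Problem sizes in the test suite

The suite exercises the chain at the scale the method is designed for:
q-grids of ~900 points, four Bragg orders, four contrasts; 200 replicates
for the peak-fit coverage property; 100 randomized models for phase-sign
recovery; 50 models × 8 orders for the quadrature oracle; 10⁵ draws for
the Monte-Carlo error cross-check. The end-to-end recovery test uses
counting noise scaled to a 1% relative standard error on the strongest
integrated Bragg intensity — the package's operational definition of a
"1%-noise" measurement; noise much larger than this begins to lose the
weakest order, exactly as in a real under-counted measurement.

## Known limitations

* The generator is 1D: rocking curves, mosaicity, absorption and
  detector-plane effects are out of scope, as is chamber-background
  subtraction (only smooth residual baselines are handled).
* Phase determination assumes centrosymmetry (real structure factors)
  and a single-slab interbilayer water distribution; orders at a node of
  the water transform are genuinely undeterminable from contrast
  variation alone and are only flagged, not guessed better.
* `D_B` from a 4-order synthesis carries a small systematic truncation
  shift (~0.5% for the default geometry); the quoted statistical errors
  do not include it, though the recovery tests bound it.
* Molecular volumes are inputs, not results: A, 2D_c and n_w inherit any
  error in V_l, V_c verbatim.
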