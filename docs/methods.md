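# Methods

## The calibration problem

Near-infrared spectra of powdered instant tea are cheap to acquire but
only indirectly related to the quantities of interest — moisture,
caffeine, tea polyphenol and tea polysaccharide content (all in % by
mass). `nircal` implements the full chemometric chain that turns a
spectra matrix plus wet-chemistry reference values into a calibrated,
validated prediction model:

1. **SNV pretreatment** of each spectrum,
2. **segment-level wavelength selection** by repeated binary particle
   swarm optimization (BPSO) with a frequency-consensus rule,
3. **calibration** by single-response partial least squares (PLS1) or
   linear epsilon-SVR,
4. **evaluation** by the six standard figures Rc, RMSEC, Rp, RMSEP,
   SEP and Bias.

Because no public instant-tea NIR dataset exists, the package ships a
synthetic generator with known ground truth; the end-to-end tests use
it to verify that the chain recovers what was planted.

## Pretreatment

SNV maps each spectrum x to (x − mean(x)) / sd(x), with the sample
(n−1) standard deviation by default (`snv_ddof` exposes the n
convention). This removes per-spectrum multiplicative gain and additive
offset exactly — the dominant particle-size and path-length artifacts
of diffuse reflectance. Replicate scans, when a replicate map is
present, are averaged *before* SNV so the averaged spectrum is the
analytical unit. Rows with zero variance are rejected by name rather
than silently producing NaNs.

## Segmentation and selection

The wavenumber axis (canonically descending, 10,000 → 4,000 cm⁻¹) is
partitioned into `n_segments` contiguous blocks (default 21). All
blocks share the width ⌊n_vars / n_segments⌋ and the division remainder
goes to the last block, so 6539 variables give twenty segments of 311
and a final segment of 319. One bit per segment defines the selection
search space.

BPSO maintains a swarm (default 20 particles) of bit vectors with
per-bit velocities updated as

    v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x),  r1, r2 ~ U(0,1)

clamped to ±v_max (default 6), after which bit d is resampled to 1 with
probability 1/(1+e^(−v_d)). Defaults follow the standard small-swarm
setting: c1 = c2 = 2, inertia weight 1.0, 100 generations. The clamp
keeps flip probabilities in roughly [0.25%, 99.75%], preserving
late-stage exploration. Personal/global bests update on strict
improvement only, so a run is a pure function of its seed. The velocity
update is carried out in floating point; positions are stored as bits.

A single run is stochastic, so the final selection is a consensus:
`n_runs` independent runs (seeds derived per run from the base seed via
`SeedSequence((base, index))`), counting per segment how many runs'
final best masks include it, and keeping segments whose count *strictly
exceeds* the threshold (default n_runs/2 — "more than half"). The
fitness of a mask is the tenfold cross-validated RMSE of the model
restricted to the mask's variables, evaluated on the calibration set
only; the empty mask scores +∞ so the selection can never be empty.

## Models

**PLS1** is implemented as NIPALS deflation on column-mean-centered
data, without unit-variance scaling of X (SNV has already normalized
the spectra). Because the NIPALS loading–weight matrix product P'W is
upper triangular, the rotation R = W(P'W)⁻¹ computed once at the
maximal component count yields the regression vector of *every*
truncated model, so the whole RMSECV-versus-components path costs one
deflation per fold. The latent count is chosen per variable subset as
the minimizer of pooled tenfold RMSECV over 1..max_latent (default cap
15), ties toward fewer components.

Inside the BPSO fitness loop the same path is evaluated in dual (Gram)
form: per-segment Gram matrices X_s X_sᵀ are precomputed once, a mask's
Gram is their sum, and a compiled kernel runs the deflation at O(n²)
per fold instead of O(n·p). The dual path is algebraically identical to
the primal one (the test suite checks agreement to 1e-9) and makes a
20-run consensus over 12,000 fitness evaluations a matter of seconds.

**SVR** is the linear epsilon-insensitive machine at fixed penalty
C = 1 (the conventional default when the study focus is variable
selection, not hyperparameter tuning). Columns of X and the response
are standardized before the solve; epsilon (default 0.1) therefore
lives on the standardized-y scale. The quadratic program is solved by
scikit-learn's libsvm backend; an independent SLSQP solution of the
dual on small instances serves as the oracle in tests, along with KKT
checks (points strictly inside the tube carry no dual weight).

**Cross-validation** uses max-balanced random fold assignment: with 118
samples and 10 folds, eight folds of 12 and two of 11, every sample
held out exactly once. RMSECV pools all out-of-fold residuals before
taking the root (this makes it the RMSEP definition applied to
out-of-fold predictions, and deterministic given the folds). The outer
evaluation holds out one designated fold (seeded, default fold 0) as
the prediction set; the remaining nine folds form the calibration set
on which everything else — inner CV, BPSO fitness, latent-count choice,
final fit — operates. Inner and outer splits use separate seeds.

## Evaluation metrics

With residuals e_i = predicted − reference:
Rc and Rp are Pearson correlations between predicted and measured
values on the calibration and prediction sets; RMSEC/RMSEP use the 1/n
denominator; SEP is the bias-corrected residual standard deviation with
1/(n−1); Bias is the mean signed residual. Under these conventions

    RMSEP² = SEP²·(n−1)/n + Bias²

holds exactly, and every emitted report is checked against it (1e-8).
Correlations undefined for degenerate inputs (e.g. a constant
predictor) are reported as NaN rather than failing the report.

## The synthetic generator

`default_tea_config` emulates a 118-sample instant-tea dataset:

* **Concentrations** are uniform over the published composition ranges
  (moisture 3.76–6.29%, caffeine 0.48–2.80%, polyphenols 18.70–22.40%,
  polysaccharides 18.00–24.50%); a truncated-normal option matching the
  published means/sds is config-selectable. Uniform is the least
  assumptive law reproducing the printed extremes.
* **Bands** are Gaussians in wavenumber, placed strictly inside the
  wavenumber regions reported informative for each component, each
  band inside the interior of a single segment of the default
  21-segment scheme (on both the full 6539-variable grid and the
  654-variable desk grid). Moisture and caffeine carry two strong
  bands each; polyphenols and polysaccharides carry four and six much
  weaker bands, several deliberately sharing segments with other
  components — this mirrors the reported region overlaps and makes
  those two the hard calibration targets.
* **The matrix** contributes (i) a fixed common absorbance envelope
  (broad bands rising toward low wavenumber plus fine structure at
  sub-segment scale, homogeneous along the axis) and (ii) per-sample
  smooth "matrix variability" — three Gaussian modes per segment,
  strictly segment-local, with N(0, matrix_sd) coefficients. The
  envelope dominates each spectrum's variance so the SNV divisor is
  insensitive to composition; its homogeneous fine structure means any
  single segment pins the divisor equally well, and segment-local
  modes mean no segment can correct another segment's nuisance. These
  three choices are what make "which segments carry information about
  component X" a well-posed question with the planted answer; without
  them, SNV's closure effect (the divisor is a function of the whole
  composition) makes almost every segment weakly informative about
  every component, and segment selection degenerates.
* **Scatter and noise**: per-sample gain U(0.8, 1.2), offset
  U(−0.1, 0.1), a random polynomial baseline of degree ≤ 2 (amplitude
  0.05), and iid Gaussian noise (sd 0.002 absorbance). The noise level
  was set so that planted-segment recovery succeeds with margin under
  the desk-scale optimizer budget; it is config-exposed, and raising it
  degrades selection before it degrades calibration.

What the generator does **not** emulate: instrument line-shape and
detector nonlinearity, wavelength-correlated (pink) noise, replicate-
scan drift, nonlinear detector saturation, and real band shapes
(Voigt/Lorentzian mixtures, hydrogen-bonding shifts). Passing the
end-to-end tests therefore demonstrates that the pipeline's logic is
sound — not that these settings transfer to any particular instrument.

## Scales and budgets

Two named profiles fix the optimizer scale: `full` (100 consensus runs
of 100 generations) and `ci` (20 runs of 30 generations). The end-to-end
tests and the acceptance script run the `ci` profile on a 654-variable
grid (the full 6539-variable grid divided by ten, preserving the
21-segment structure: twenty segments of 31 plus one of 34); these sizes
keep a complete four-component study within minutes on a single core
while leaving the selection problem nondegenerate. The `full` profile
on the full grid is a configuration change, not a code path change.

## Numerical and design notes

* Wavenumber grids are accepted ascending or descending and normalized
  to descending; grid matching across files uses a 1e-6 cm⁻¹ tolerance.
* CSV round trips write 17 significant digits; read(write(s))
  reproduces the matrix to < 1e-12.
* NIPALS stops early if the covariance X'y deflates to zero (the fit is
  exact at that point); requesting more components than min(n−1, p)
  is an error.
* Latent-count ties break toward the smaller count; pbest/gbest ties
  keep the incumbent — both for determinism.
* The Bias sign convention (predicted − reference) is fixed, not
  configurable, so reports are comparable across studies.
* Consensus counts are taken over each run's final global-best mask,
  not over all visited particles.
* An experiment cell (component × method) that fails aborts only that
  cell; the failure and its reason are recorded in the result and the
  log, and remaining cells proceed.

## Known limitations

* The epsilon-SVR epsilon is fixed rather than tuned; the study design
  deliberately avoids SVR hyperparameter search.
* Consensus selection is a frequency rule over best masks; stability-
  selection or bootstrap variants are out of scope.
* With a deterministic fitness and a well-converged optimizer, the
  consensus approaches the support of the global fitness optimum; on
  data whose informative regions genuinely overlap (here: polyphenols
  and polysaccharides), that support legitimately includes shared
  segments and omits redundant planted ones. The recovery guarantees in
  the tests are therefore stated for the two components with compact,
  dominant signatures (moisture, caffeine), matching what such data can
  support.
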