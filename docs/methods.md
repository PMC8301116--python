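# Methods

## Calibration model

Each property is calibrated independently with univariate partial least
squares (PLS1) via NIPALS. On mean-centered data, component `a` takes
the weight vector `w_a ∝ X_{a-1}ᵀ y_{a-1}` (unit norm), scores
`t_a = X_{a-1} w_a`, X-loading `p_a = X_{a-1}ᵀ t_a / t_aᵀ t_a` and
y-loading `q_a = y_{a-1}ᵀ t_a / t_aᵀ t_a`, after which both blocks are
deflated. For a single response this extraction is exact in one pass
(no inner iteration is needed; the classical iterative loop converges
immediately, which the test suite exploits as an independent oracle).
Predictions use `b = W (Pᵀ W)⁻¹ q`; `Pᵀ W` is unit-upper-triangular, so
the solve is well-posed whenever the components exist.

Assumptions inherited from the linear mixture premise: spectra respond
linearly to composition, samples are independent, and the property of
interest either shapes the spectrum directly (protein, fat, sugars,
polyphenols) or is strongly correlated with constituents that do
(elemental content, pH).

### Numerical choices

- Centering happens inside `fit_pls` with calibration means stored on
  the model; validation and unknown samples are always centered with
  those means. This is the same computation as a separate mean-centering
  stage, with no opportunity to use the wrong means.
- Component signs are fixed by making the largest-magnitude weight
  element positive; fits are bit-reproducible across runs and platforms.
- Rank exhaustion: extraction stops when the residual covariance
  `‖Xᵀy‖` falls below 1e-12 of its natural scale. `fit_pls` treats a
  request beyond the effective rank as an error; the pipeline instead
  caps the component count at the rank (with a logged warning), since
  fixed per-property defaults can legitimately exceed the rank of
  low-noise synthetic data.
- Leave-one-out cross-validation refits the scatter correction and the
  PLS model from scratch on every fold; the per-fold NIPALS run is
  shared across component counts (component `a` predictions reuse
  components `1..a-1`), which is algebraically identical to separate
  refits and is verified against one in the tests.

## Choosing the number of latent variables

RMSECV curves on 25-sample calibrations are shallow near their minimum,
and the bare argmin chronically overfits. `select_n_lv` therefore picks
the smallest count whose RMSECV is within a parsimony tolerance
(default 2%) of the curve minimum. The shipped per-property defaults
(`nmrcal/data/default_models.yaml`) fix the counts at the published
values (3–7 depending on property) rather than selecting automatically;
`n_lv: auto` enables the rule.

## Pretreatments

Order: ppm windowing → MSC or SNV (optional) → mean-centering.

- **SNV** scales each spectrum to zero mean and unit standard deviation
  (n−1 denominator).
- **MSC** regresses each spectrum on a reference (default: the mean
  calibration spectrum) and inverts the fitted affine distortion; the
  reference is stored so validation spectra are corrected against the
  calibration reference, never their own mean.
- **Windows** are closed `(high_ppm, low_ppm)` intervals; the only
  range fixed by default is 55–220 ppm for reducing sugars, which
  excludes the lipid-dominated aliphatic region. Other per-property
  ranges are configuration: range optimization was guided by VIP plots
  in the original workflow and its outcomes are not recoverable, so the
  package exposes ranges in the run config instead of hard-coding
  guesses.

Parameters with a data-dependent fit (MSC reference, centering means,
the split itself) are learned on the calibration set only.

## Sample splitting

The conventional partition for 35 samples is 25 calibration / 10
validation. `pca_coverage_split` implements a bootstrap-stabilized
Kennard–Stone selection in PCA score space (5 components, 200 bootstrap
resamples by default): each resample contributes one Kennard–Stone
maximin selection, samples chosen most often form the calibration set,
and the per-component extreme samples are forced into calibration so
validation is strictly interpolative. The procedure is deterministic
under its seed and invariant to row order (rows are canonicalized by
sample id). The published workflow combined bootstrapping with PCA score
plots without specifying an algorithm; this implementation is the
package's own documented realization of that intent, and exact
membership of the original 25/10 split is not reproducible.

## The synthetic data generator

No experimental spectra are deposited, so `synthetic_data` generates
studies with the statistical structure the analysis assumes:

- **Bases.** Five constituent bases (lipid, polysaccharide, protein,
  polyphenol, tannin) as sums of Lorentzian lines (HWHM 2–8 ppm,
  matching CPMAS broadening; Gaussian where a broad featureless band is
  wanted) at the chemical shifts where those constituents resonate.
  A sixth cellulose-like "matrix" basis represents the residual dry
  mass (crude fiber and other structural carbohydrate).
- **Mass closure.** Component loadings are mass shares that sum to
  100%: fat → lipid, reducing sugars → polysaccharide, protein →
  protein, TP (mg GAE/g, ~1% mass share) → polyphenol and a small
  tannin share, remainder → matrix. Closure matters: solid-state
  intensities carry no absolute concentration scale, and it is the
  closed composition shaping the *relative* spectrum that makes
  scatter-corrected calibration quantitative. Without it, row-normalized
  spectra underdetermine absolute content.
- **Specific intensities.** Per unit mass share, the lipid basis is
  weighted 7× the carbohydrate bases: long mobile (CH₂)ₙ chains
  concentrate many equivalent carbons into a few sharp lines, which is
  why the 36 ppm signal is the most intense feature of a whole-pollen
  spectrum although fat is only ~8–12% of the mass. The generated mean
  spectrum reproduces that appearance.
- **Compositions.** Drivers (TP, sugars, N, fat) are drawn from a
  multivariate normal fitted to the packaged 35-sample table and
  clipped to its ranges; protein is exactly 6.25 × N (Kjeldahl).
  Properties without a direct ¹³C signature (ABTS, NHCS, C, S, pH) are
  generated from regressions of the fixture table on the drivers plus
  jointly drawn residuals. ABTS depends on TP alone, with residual
  scatter that reproduces the observed TP–ABTS correlation of ≈0.84.
  The single knob `offspectral_residual` scales all these residuals:
  1 (default) matches the real table's scatter; 0 makes every property
  an exact function of the drivers, giving a perfect-recovery limit.
- **Noise and scatter.** Per-sample multiplicative slope
  (sd 0.10 about 1) and additive offset (sd 0.02 of the maximum mean
  intensity) give MSC/SNV something real to remove; white Gaussian
  noise (sd 0.028 of the maximum mean intensity) sets a moderate
  signal-to-noise ratio at which the first five principal components
  of a default study explain ≈75% of the spectral variance.

Defaults (35 samples, 3072 points over 220–0 ppm, the noise and scatter
levels above) are the package's standard study conditions; tests and the
acceptance script run at these sizes, which keep a full ten-property
calibration under a few seconds on one CPU.

What the generator does **not** emulate: spinning sidebands,
cross-polarization dynamics (per-carbon intensity distortions),
baseline roll, correlated (colored) noise, chemical-shift
miscalibration between samples, and any botanical-origin clustering
structure. Passing tests on synthetic data therefore demonstrate the
correctness and statistical behavior of the workflow under the linear
mixture model — not instrument-grade performance on real pollen. In the
same spirit, the generated calibration fits are cleaner than real ones
(calibration R ≈ 1.0 where experiments report ≈0.99), because the
generator's only imperfections are the injected noise and scatter.

The spectral "encoding" of pH and sulfur deserves a flag: physically
these properties influence ¹³C spectra only indirectly, and the
generator links them to composition by regression. Their recovery
quality in synthetic studies reflects that constructed correlation
strength, not an instrument truth.

## Perfect-data limit

With `noise_sd = scatter = offspectral_residual = 0` the spectra are an
exact linear mixture of four independent composition drivers (rank 4
after centering) and every property is an exact affine function of the
drivers. The pipeline's perfect-recovery check runs this limit with
pretreatment `none` and 4 latent variables: there is no scatter left to
correct, and row-wise MSC/SNV applied to noise-free closed mixtures
would introduce a small (~0.2–0.4% RSEP) nonlinearity of their own —
the limit isolates the modeling core, where calibration errors collapse
below 0.1%.

## Known limitations

- JCAMP-DX support covers the AFFN `(XY..XY)`/`XYPOINTS` point-table
  subset, not compressed (DIFDUP/SQZ) or vendor-specific encodings.
- The split procedure and the LV-parsimony rule are documented
  stand-ins for proprietary or unspecified steps in the original
  workflow; published per-property error values are consequently
  order-of-magnitude anchors, not reproduction targets.
- PLS2 (joint multi-property) modeling is intentionally absent; the
  workflow calibrates properties one at a time.
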