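# Methods

This note documents the statistical model behind `filafluct`, the estimators
it implements, the numerical conventions chosen where several are defensible,
and what the synthetic-data tests do and do not demonstrate about real data.

## Data model

The unit of analysis is a *filament*: an ordered chain of `L_f` cells with
fluorescence values `F(1..L_f)` (arbitrary units). A *run* is a set of
filaments recorded under one condition (strain, timepoint). Spatial
statistics treat the filament as a 1D lattice; filament orientation is
arbitrary, and every statistic in the package is invariant under reversal
of a filament (asserted by tests).

Filaments shorter than a minimum length are excluded before correlation
analysis. The default minimum is 8 cells; 7 is a supported alternative —
both conventions appear in practice for this kind of data, and the choice
is exposed as `min_length` rather than hidden.

## Noise and its decomposition

Expression noise is the squared coefficient of variation `σ²_p/μ²_p` over
all cells pooled, computed with the unbiased (ddof = 1) sample variance.
The decomposition reports

* `between` — CV² of the per-filament mean fluorescences,
* `within_avg` — the mean over filaments of each filament's own `σ²/μ²`,
* `ratio = between / within_avg`.

The ratio measures how much variability lives between whole filaments
rather than between cells of one filament. Note that `between` as
estimated from finite filaments is inflated by within-filament sampling:
`Var(F̄_f) ≈ cv²μ² + σ_w² κ_L / L`, where `κ_L = 1 + 2 Σ_n (1−n/L) ρ(n)`
inflates the variance of the mean when cells are spatially correlated.
The synthetic generator returns this *empirical* expectation as its ground
truth (and `filament_cv_for_ratio` inverts it), so recovery tests compare
like with like.

Intrinsic/extrinsic noise decomposition in the dual-reporter sense is
deliberately out of scope: it presumes independent cells, which spatial
correlation violates.

## Spatial autocorrelation and bias compensation

Per filament,

    g(n) = [1/(L_f − n)] Σ_{m=1}^{L_f−n} (F(n+m) − μ_f)(F(m) − μ_f) / σ_f² ,

and the run-level curve averages g(n) over filaments with equal weight
(length-weighted averaging is available as an option). `σ_f²` uses the
population (1/L) convention so that g(0) = 1 exactly; both conventions are
scale-free, so this choice only fixes the normalization identity.

Because `μ_f` is estimated from the same short series, g(n) is negatively
biased for n ≥ 1. For spatially independent cells the bias is exactly
−1/(L_f − 1) at every positive lag (conditional on the filament's values,
the average of (F(a)−μ̂)(F(b)−μ̂) over distinct position pairs equals
−σ̂²/(L−1), and the permuted estimator's variance is the same σ̂²).

Two compensations are implemented:

* **`method="permutation"`** (default). Cell positions are permuted
  independently within each filament, the filament-averaged curve of the
  permuted data is computed, and the mean over `n_permutations` rounds
  (default 10) is subtracted for n ≥ 1. By the identity above this removes
  the bias *exactly* for independent cells — the null-calibration test
  (50 × 100 filaments of 20 cells) confirms a corrected mean g(1)
  indistinguishable from 0 while the raw mean sits near −1/19. For
  *correlated* cells, however, the permuted curve still estimates only the
  iid bias; the raw estimator's actual bias is approximately
  −(κ_L/L)(1 − ρ(n))/(1 − κ_L/L) plus O(1/L²) terms that are substantial
  at L = 8–40, so a residual of order −(κ_L − 1)/L remains. Measured on
  MA(2) traces of length 8–40 the residual is ≈ −0.05 at n = 1 and
  ≈ −0.10 at n = 2 — several standard errors at 300 filaments. The
  permutation-corrected curve is therefore a *conservative* (attenuated)
  estimate of spatial correlation; comparisons between runs analysed the
  same way remain valid.

* **`method="surrogate"`.** Removes the correlation-dependent residual as
  well. Starting from the permutation-corrected curve, the estimator's
  full bias is measured on Gaussian surrogate filaments that share the
  observed lengths and carry the current autocovariance estimate (Toeplitz
  covariance, eigenvalue-floored to stay positive semi-definite; zero
  correlation assumed beyond `n_max`), and the curve is updated by the
  fixed point ρ = raw − bias(ρ) (12 iterations, 50 surrogate replicates
  per evaluation). Standard errors are propagated through the fixed point:
  d(corrected) = (I + J)⁻¹ d(raw) with J = ∂bias/∂ρ estimated by central
  differences, applied to the across-filament covariance of the raw curve.
  A 30-seed check at 300 filaments puts the residual bias of this method
  below 0.01 at every lag ≤ 5, with propagated standard errors matching
  the empirical seed-to-seed dispersion. The Gaussian marginal is a
  modeling assumption; for the right-skewed traces used here its effect is
  within the quoted errors. Use this method when the absolute correlation
  range is the quantity of interest.

The pooled nearest-neighbour Pearson coefficient is reported alongside
g(1). The two are close but not identical: the pooled estimator centres on
the global mean, so between-filament heterogeneity contributes to it while
per-filament centering removes that contribution from g(1). Both are
computed; neither is derived from the other.

## Histogram comparisons

For 1D histograms on *identical* bin edges with cumulative distributions
CDX, CDY:

* `EMD = Σ_i |CDX(i) − CDY(i)|` — the minimum total work to transform one
  normalized histogram into the other with unit cost per adjacent-bin move
  (verified against a brute-force transport LP to 1e−12); reported in bin
  units, so all strain-pair comparisons use shared fixed-width bins over
  the pooled range (width configurable, 1 a.u. in the demo).
* `D_KS = max_i |CDX(i) − CDY(i)|`, always ≤ EMD.
* `X² = (1/MN) Σ_i (M n_i − N m_i)²/(n_i + m_i)` for two *count*
  histograms with totals N, M, compared against χ² with b−1 degrees of
  freedom, where b counts bins with `n_i + m_i > 0` (empty bins carry no
  information and are skipped with the dof reduced). The difference form
  of the numerator is the only one that vanishes for identical histograms
  and is χ²-distributed under the null; a printed plus sign occasionally
  seen for this statistic is a typesetting artifact and is not
  implemented. Null calibration (multinomial pairs, b = 5, N = M = 200,
  2000 replicates) gives a type-I error of ≈ 0.046 at α = 0.05 and
  uniform p-values.

Bootstrap standard errors resample the underlying observations with
replacement — individual cells for fluorescence histograms, individual
clusters for cluster-size histograms — recompute the statistic, and report
the standard deviation over replicates (1000 by default; 10000 for
cluster-size EMDs). Replicates on which a statistic is undefined are
dropped and counted.

## Cluster analysis and the independent-cell null

Each run is binarized at the quantile threshold defining its upper 15% of
cells (linear-interpolation sample quantile; a cell is 1 iff *strictly*
above the threshold, so an all-equal run yields no high cells). Each run
is thresholded on its own pooled distribution. Cluster sizes are maximal
runs of contiguous 1s; runs touching filament ends count normally, and
clusters never merge across filament boundaries.

The null model is filaments of independent cells: Bernoulli(p) strings
(defaults p = 0.15, 1000 strings of 20 cells, matching the binarization
fraction). For finite strings the expected number of k-runs per string is

    E[#runs of size k] = (L−k−1) p^k (1−p)² + 2 p^k (1−p)   (k < L),
    E[#runs of size L] = p^L ,

which reduces to the geometric size law P(size=k) = (1−p)p^{k−1} as
L → ∞ (mean 1/(1−p) ≈ 1.176 at p = 0.15). The closed form is verified
against exhaustive 2^L enumeration at small L and serves as the
goodness-of-fit reference for the simulation. Observed cluster-size
histograms are compared to the simulated null by EMD on shared integer
bins, with bootstrap errors over resampled observed clusters (the
simulated histogram is held fixed).

## Segmentation

Cells are segmented from single-channel images by an adaptive-threshold
scheme: an initial global threshold, connected components, and iterative
local re-thresholding of any component larger than
`max_area_factor × typical_cell_area` (the threshold rises by 5% of the
local dynamic range per step, at most 20 steps) until merged cells
separate; components below `min_cell_area` are discarded. The initial
threshold defaults to robust background statistics (median + 3·1.4826·MAD),
which assumes the background majority of pixels; Otsu and percentile rules
are available, but Otsu systematically misses the dimmest cells when
foreground intensities span a wide range, which is the regime this scheme
exists for. Mean fluorescence is the raw mean pixel value per labelled
region — no background subtraction or flat-field correction is applied.

Ordering into filaments is automated: candidate edges join cells whose
centroids are within `neighbor_max_gap`; edges are accepted shortest-first
subject to degree ≤ 2 and acyclicity, so every connected structure is a
simple path, walked from a deterministic endpoint. Branch-adjacent cells
are flagged. On default rendered fixtures (non-overlapping cells, SNR ≥ 5)
this recovers ≥ 95% of ground-truth cells at IoU > 0.5 with correct order
up to reversal.

## Synthetic data

Traces: `F_f(n) = m_f · S(n)/E[S] + ε_n` with `S(n) = Σ_j w_j e_{n−j}`,
gamma innovations `e` (shape `innovation_shape`, default 4), lognormal
per-filament scale `m_f` (mean `baseline_mean` = 13 a.u., CV
`filament_cv` = 0.074), kernel `w` = (1,1,1), Gaussian cell noise
(sd 0.5 a.u.), lengths uniform on [8, 40], 100 filaments per run. These
defaults emulate the regime the package targets: right-skewed fluorescence
with total noise ≈ 0.09, spatial correlation extending 2–3 cells
(MA(2) autocorrelation 2/3, 1/3, 0, …), and ≈ 23% of the noise between
filaments. The kernel autocorrelation `ρ(n) = Σ_j w_j w_{j+n} / Σ_j w_j²`
and the expected noise decomposition are returned with the data as
analytic ground truth. Gamma/lognormal are conventions chosen for
positivity and right skew, not inferences from any particular dataset.

Images: each filament is a row of axis-aligned ellipses (semi-axes 5×3 px,
gap 3 px, optional sinusoidal bowing), intensity = trace value over a flat
background, Gaussian PSF blur, optional Poisson shot noise, Gaussian read
noise. Cells are non-overlapping by construction. The renderer omits
photobleaching, z-structure, autofluorescence and touching/overlapping
cells, so passing segmentation tests demonstrate correctness of the
algorithmic pipeline, not performance on hard real microscopy.

## Reproducibility

All randomness flows through numpy Generators seeded explicitly; the
pipeline spawns per-stage sub-seeds from one global seed via
`SeedSequence`, records them in `manifest.json`, and writes CSV/JSON with
fixed formatting — two runs with the same config and seed are
byte-identical in their numeric outputs. Plots are artifacts only and are
never read back.

## Known limitations

* The permutation compensation under-corrects correlated short filaments
  (quantified above); the surrogate method addresses this at the cost of a
  Gaussian surrogate assumption and ~1 s of computation per curve.
* Pearson-vs-g(1) equality holds only when between-filament heterogeneity
  is negligible.
* EMD values depend on the bin width; only comparisons made with shared
  bins are meaningful, and bin width must be reported with any EMD.
* The segmentation is validated against the package's own renderer, not
  against manually curated microscopy.
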