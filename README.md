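# filafluct

Noise and spatial-fluctuation statistics for gene expression along
one-dimensional cell filaments.

Filamentous cyanobacteria such as *Anabaena* grow as chains of cells that
exchange regulatory molecules through septal junctions. Fluctuations of a
regulator's expression (measured as per-cell fluorescence of a GFP fusion)
are therefore *coupled* between neighbouring cells, and the spatial range
of that coupling — typically two to three cells — carries information about
intercellular transport and feedback. This package provides the statistical
toolbox for such data, for microscopists and quantitative biologists who
have per-cell fluorescence values ordered along filaments (or just images):

* **Expression noise** `σ²_p/μ²_p` over all cells, and its decomposition into
  a between-filament share (CV² of per-filament means) versus the average
  within-filament noise.
* **Spatial autocorrelation** along filaments,

  `g(n) = ⟨ (1/(L_f−n)) Σ_m (F(n+m)−μ_f)(F(m)−μ_f) / σ_f² ⟩_filaments`,

  with compensation of the negative estimator bias that arises because
  `μ_f` is estimated from the same short series. Two compensations are
  available: subtraction of the mean curve of within-filament position
  permutations (exact for independent cells), and a surrogate-based
  fixed-point correction that also removes the correlation-dependent
  residual on short filaments (see `docs/methods.md`).
* **Histogram distances**: Earth Mover's Distance
  `EMD = Σ_i |CDX(i) − CDY(i)|` on shared-bin normalized histograms
  (reported in bin units), the Kolmogorov–Smirnov distance
  `D_KS = max_i |CDX(i) − CDY(i)|`, and the two-sample statistic
  `X² = (1/MN) Σ_i (M·n_i − N·m_i)²/(n_i+m_i)` with χ²_{b−1} p-values,
  plus bootstrap standard errors.
* **Cluster-size statistics**: binarize each filament at a population
  quantile threshold (default: upper 15th percentile), collect run lengths
  of contiguous high cells, and compare against the independent-cell null —
  Bernoulli(p) strings — via EMD, with the finite-string run-length law
  available in closed form.
* **Segmentation**: adaptive-threshold cell segmentation of single-channel
  TIFFs (robust background threshold, iterative local re-thresholding of
  oversized components) and automatic ordering of cells into filaments.
* **Synthetic data**: filament traces with controlled between-filament
  heterogeneity and a moving-average spatial kernel whose autocorrelation
  is known analytically, and microscopy-like renderings with ground-truth
  labels — so every stage is testable without external data.

## Worked example

Simulate a run of 100 filaments (8–40 cells each, mean fluorescence
13 a.u., MA(2) kernel with analytic autocorrelation 1, 2/3, 1/3, 0, …)
and analyse it:

```
$ filafluct simulate --n-filaments 100 --seed 1 --run-id wt --out wt.csv
wrote 2427 cells in 100 filaments to wt.csv (kernel autocorr [1.0, 0.667, 0.333])

$ filafluct stats --cells wt.csv --nmax 5 --method surrogate --seed 1 --out stats/
wrote statistics for 1 run(s) to stats
```

`stats/noise_report.json` then contains (values from this exact run):

```
population_noise        0.0892
between                 0.0177
within_avg              0.0725
between_within_ratio    0.2439
pearson_neighbors       0.6632
g_raw        [1.0, 0.519, 0.143, -0.230, -0.169, -0.139]
g_corrected  [1.0, 0.624, 0.276, -0.061, -0.035, -0.011]
```

Reading: total cell-to-cell noise is ≈ 0.09 (CV ≈ 30%), about 24% of which
sits between whole filaments; the raw autocorrelation is pulled far below
the generator's true curve (0.667, 0.333, 0, …) by the short-series
estimator bias, and the corrected curve recovers it within sampling error,
placing the correlation range at 2–3 cells. Comparing two runs and testing
clustering against independent cells:

```
$ filafluct compare --cells-a wt.csv --cells-b broad.csv --metric emd \
      --bins width:1.0 --boot 500 --seed 1 --out cmp.json
emd = 5.9270 -> cmp.json

$ filafluct clusters --cells wt.csv --percentile 0.15 --boot 1000 --seed 1 \
      --out clusters.json
# -> {"wt": {"threshold": 17.03, "n_clusters": 160,
#            "emd_vs_independent": 1.106, "emd_se": 0.137}}
```

An `emd_vs_independent` several standard errors above the
independent-vs-independent baseline says high-expressing cells cluster
spatially more than chance. `filafluct run` executes the whole pipeline
(simulate → render → segment → stats → compare → clusters → plots) from a
YAML config or the built-in demo; `filafluct validate cfg.yaml` checks a
config without running it.

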