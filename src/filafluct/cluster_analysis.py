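"""Threshold binarization, cluster-size statistics and the independent-cell null.

A two-point correlation function misses higher-order structure such as runs
of contiguous high-expressing cells.  Here each filament is binarized
against a population quantile threshold (default: the upper 15th percentile
of all pooled cells, bit = 1 iff strictly above), maximal runs of 1s are
collected as *cluster sizes*, and the observed cluster-size histogram is
compared against filaments of statistically independent cells: Bernoulli
strings with the same hit probability p.

For a finite string of length L with iid Bernoulli(p) cells the expected
number of runs of exactly k ones is available in closed form::

    E[#runs of size k] = (L-k-1) p^k (1-p)^2 + 2 p^k (1-p)   for k < L
    E[#runs of size L] = p^L

(interior runs need a 0 on both sides; runs touching one end need a single
0; the all-ones string is its own run).  In the infinite-string limit the
conditional size law is geometric, P(size=k) = (1-p) p^(k-1).  The closed
form serves as the oracle for the simulation and as the GOF reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import BinaryFilament, BinnedHistogram, ComparisonResult, FilamentSet
from .histogram_compare import bootstrap_se, emd

__all__ = [
    "BinarizationParams",
    "BernoulliSimParams",
    "binarize",
    "cluster_sizes",
    "cluster_size_histogram",
    "simulate_bernoulli_strings",
    "bernoulli_expected_run_counts",
    "bernoulli_size_pmf",
    "cluster_law_gof",
    "compare_to_independent",
]


@dataclass
class BinarizationParams:
    """How filaments are split into high/low expression bits.

    ``percentile`` is the upper-tail fraction defining "high" (default
    0.15: the threshold is the pooled 85th-percentile fluorescence, linear
    interpolation convention); a cell is 1 iff *strictly* above the
    threshold.  ``threshold_source='fixed_value'`` uses ``fixed_value``
    instead of the population quantile.
    """

    percentile: float = 0.15
    threshold_source: str = "population"
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must be in (0, 1)")
        if self.threshold_source not in ("population", "fixed_value"):
            raise ValueError("threshold_source must be 'population' or 'fixed_value'")
        if self.threshold_source == "fixed_value" and self.fixed_value is None:
            raise ValueError("fixed_value threshold requested but none given")


@dataclass
class BernoulliSimParams:
    """Independent-cell null model: iid Bernoulli(p) strings."""

    n_strings: int = 1000
    string_length: int = 20
    p: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.n_strings < 1 or self.string_length < 1:
            raise ValueError("n_strings and string_length must be >= 1")


def binarize(
    fset: FilamentSet, params: BinarizationParams = BinarizationParams()
) -> tuple[list[BinaryFilament], float]:
    """Binarize every filament against the set-level threshold.

    Returns the binary filaments and the threshold used.  The threshold is
    computed on the pooled cells of this set (each run/strain thresholded
    on its own distribution).
    """
    pooled = fset.pooled_values()
    if pooled.size < 1:
        raise ValueError("cannot binarize an empty filament set")
    if params.threshold_source == "fixed_value":
        thr = float(params.fixed_value)
    else:
        thr = float(np.quantile(pooled, 1.0 - params.percentile))
    bits = [
        BinaryFilament((t.values > thr).astype(np.int8), t.filament_id) for t in fset
    ]
    return bits, thr


def cluster_sizes(filament: BinaryFilament | np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of consecutive 1s (end-touching runs included)."""
    bits = filament.bits if isinstance(filament, BinaryFilament) else np.asarray(filament)
    if bits.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate(([0], bits.astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def cluster_size_histogram(
    sizes, max_size: int | None = None
) -> BinnedHistogram:
    """Counts per integer cluster size on bins [0.5, 1.5), [1.5, 2.5), ...

    ``sizes`` is an array of run lengths or an iterable of such arrays
    (pooling filaments = concatenating their size lists).  ``max_size``
    extends/limits the support so two histograms can share edges.
    """
    if isinstance(sizes, np.ndarray):
        pooled = sizes.astype(int)
    else:
        parts = [np.asarray(s, dtype=int) for s in sizes]
        pooled = np.concatenate(parts) if parts else np.empty(0, dtype=int)
    if pooled.size == 0:
        warnings.warn("empty cluster-size histogram", stacklevel=2)
        top = max_size if max_size is not None else 1
    else:
        top = max_size if max_size is not None else int(pooled.max())
    edges = np.arange(1, top + 2) - 0.5
    counts, _ = np.histogram(pooled, bins=edges)
    return BinnedHistogram(edges, counts)


def simulate_bernoulli_strings(params: BernoulliSimParams) -> list[BinaryFilament]:
    """Simulate iid Bernoulli(p) strings (the independent-cell null)."""
    rng = np.random.default_rng(params.seed)
    mat = (rng.random((params.n_strings, params.string_length)) < params.p)
    return [BinaryFilament(row.astype(np.int8), i) for i, row in enumerate(mat)]


def bernoulli_expected_run_counts(L: int, p: float) -> np.ndarray:
    """E[# runs of size k], k = 1..L, per Bernoulli(p) string of length L."""
    q = 1.0 - p
    k = np.arange(1, L + 1, dtype=float)
    interior = np.clip(L - k - 1, 0, None) * p ** k * q ** 2
    edge = 2.0 * p ** k * q
    out = interior + edge
    out[-1] = p ** L  # the all-ones string; edge/interior formulas need a 0
    return out


def bernoulli_size_pmf(L: int, p: float) -> np.ndarray:
    """Conditional cluster-size law P(size = k | a cluster), k = 1..L."""
    e = bernoulli_expected_run_counts(L, p)
    total = e.sum()
    if total == 0:
        raise ValueError("p = 0: no clusters, size law undefined")
    return e / total


def cluster_law_gof(
    sizes: np.ndarray, L: int, p: float, min_expected: float = 5.0
) -> ComparisonResult:
    """Chi-square goodness of fit of observed sizes to the finite-L law.

    Conditions on the observed number of clusters; tail sizes are merged
    into one bin until every expected count reaches ``min_expected``.
    """
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0:
        raise ValueError("no clusters observed")
    if sizes.max() > L:
        raise ValueError("observed cluster exceeds the string length L")
    pmf = bernoulli_size_pmf(L, p)
    obs = np.bincount(sizes, minlength=L + 1)[1:]
    exp = pmf * sizes.size
    # merge the tail upward until expected counts are adequate
    cut = L
    while cut > 1 and exp[cut - 1 :].sum() < min_expected:
        cut -= 1
    obs_m = np.concatenate([obs[: cut - 1], [obs[cut - 1 :].sum()]])
    exp_m = np.concatenate([exp[: cut - 1], [exp[cut - 1 :].sum()]])
    stat, pval = stats.chisquare(obs_m, f_exp=exp_m * obs_m.sum() / exp_m.sum())
    return ComparisonResult("chi2_gof", float(stat), p_value=float(pval),
                            dof=obs_m.size - 1)


def compare_to_independent(
    observed_sizes: np.ndarray,
    params: BernoulliSimParams,
    n_boot: int = 10000,
    seed=None,
) -> ComparisonResult:
    """EMD between observed and independent-cell cluster-size histograms.

    Simulates Bernoulli strings under ``params``, builds both normalized
    histograms on shared integer bins, and reports the EMD with a bootstrap
    standard error over resamples of the *observed* clusters (the simulated
    null histogram is held fixed).
    """
    observed_sizes = np.asarray(observed_sizes, dtype=int)
    if observed_sizes.size == 0:
        raise ValueError("observed cluster-size histogram is empty")
    if params.p == 0:
        raise ValueError("p = 0 yields an empty simulated histogram")
    sim = simulate_bernoulli_strings(params)
    sim_sizes = np.concatenate([cluster_sizes(s) for s in sim])
    top = int(max(observed_sizes.max(), sim_sizes.max()))
    h_sim = cluster_size_histogram(sim_sizes, max_size=top)

    def _emd_to_sim(obs: np.ndarray) -> float:
        h_obs = cluster_size_histogram(np.clip(obs, 1, top), max_size=top)
        return emd(h_obs, h_sim).statistic

    d = _emd_to_sim(observed_sizes)
    se = bootstrap_se(observed_sizes, _emd_to_sim, n_boot=n_boot, seed=seed)
    return ComparisonResult("emd", d, se=se)
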