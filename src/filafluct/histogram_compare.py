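"""Distribution-level comparisons between binned histograms.

Three distances between histograms on *shared* bin edges:

* Earth Mover's Distance, the total work to transform one normalized
  histogram into the other with unit cost between adjacent bins; for 1D
  histograms it reduces to ``EMD = sum_i |CDX(i) - CDY(i)|`` over the
  cumulative distributions, and is therefore reported in bin units.
* Kolmogorov-Smirnov distance, ``D_KS = max_i |CDX(i) - CDY(i)|`` — always
  <= EMD since it keeps only the largest of the non-negative terms.
* A two-sample chi-square statistic for count histograms,

      X^2 = (1/MN) * sum_i (M*n_i - N*m_i)^2 / (n_i + m_i),

  approximately chi^2_{b-1}-distributed under the null that both sets of
  counts come from one distribution (b = number of bins with events; bins
  with n_i + m_i = 0 carry no information and are skipped with the degrees
  of freedom reduced).  Note the *difference* in the numerator: the
  difference form is the one that vanishes for identical histograms and
  follows the chi-square law; a printed plus sign sometimes seen for this
  statistic is a typesetting artifact.

Bootstrap standard errors resample the underlying observations (cells for
fluorescence histograms, clusters for cluster-size histograms), recompute
the statistic and report the standard deviation over replicates.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .datatypes import BinnedHistogram, ComparisonResult

__all__ = [
    "build_histogram",
    "build_histogram_pair",
    "shared_edges",
    "emd",
    "ks_distance",
    "cluster_chi2",
    "bootstrap_se",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# building
# --------------------------------------------------------------------------

def shared_edges(
    *samples: np.ndarray, bin_width: float | None = None, n_bins: int | None = None
) -> np.ndarray:
    """Fixed-width bin edges covering the pooled range of all samples.

    Default width follows the Freedman-Diaconis rule on the pooled data
    (falling back to 10 bins for degenerate spreads).  Fixed-width shared
    bins keep EMD values comparable across pairs ("bin units").
    """
    pooled = np.concatenate([np.asarray(s, float).ravel() for s in samples])
    if pooled.size == 0:
        raise ValueError("cannot build edges from empty input")
    lo, hi = float(pooled.min()), float(pooled.max())
    if bin_width is None and n_bins is None:
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        bin_width = 2 * iqr / pooled.size ** (1 / 3) if iqr > 0 else 0.0
        if bin_width == 0:
            n_bins = 10
    if n_bins is not None:
        if hi == lo:
            hi = lo + 1.0
        return np.linspace(lo, hi, n_bins + 1)
    nb = max(1, int(np.ceil((hi - lo) / bin_width))) if hi > lo else 1
    return lo + bin_width * np.arange(nb + 1)


def build_histogram(values, bin_rule) -> BinnedHistogram:
    """Histogram of ``values`` under a binning rule.

    ``bin_rule`` is either an explicit array of edges, ``("width", w)`` for
    fixed-width bins over the data range, or ``"auto"`` (Freedman-Diaconis).
    The rightmost bin includes its upper edge (numpy convention).
    """
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("cannot histogram empty input")
    if isinstance(bin_rule, str):
        if bin_rule != "auto":
            raise ValueError(f"unknown bin rule {bin_rule!r}")
        edges = shared_edges(v)
    elif isinstance(bin_rule, tuple) and bin_rule and bin_rule[0] == "width":
        edges = shared_edges(v, bin_width=float(bin_rule[1]))
    else:
        edges = np.asarray(bin_rule, float)
    counts, edges = np.histogram(v, bins=edges)
    return BinnedHistogram(edges, counts)


def build_histogram_pair(
    a, b, bin_width: float | None = None, n_bins: int | None = None
) -> tuple[BinnedHistogram, BinnedHistogram]:
    """Two histograms on shared edges covering the pooled support."""
    edges = shared_edges(a, b, bin_width=bin_width, n_bins=n_bins)
    return build_histogram(a, edges), build_histogram(b, edges)


def _check_pair(x: BinnedHistogram, y: BinnedHistogram) -> None:
    if not x.same_edges(y):
        raise ValueError("histograms must share identical bin edges")
    if x.is_empty or y.is_empty:
        raise ValueError("cannot compare an empty histogram")


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

def emd(x: BinnedHistogram, y: BinnedHistogram) -> ComparisonResult:
    """Earth Mover's Distance between two shared-bin histograms (bin units)."""
    _check_pair(x, y)
    d = float(np.abs(x.cumulative() - y.cumulative()).sum())
    return ComparisonResult("emd", d)


def ks_distance(x: BinnedHistogram, y: BinnedHistogram) -> ComparisonResult:
    """Kolmogorov-Smirnov distance: max |CDX(i) - CDY(i)| over bins."""
    _check_pair(x, y)
    d = float(np.abs(x.cumulative() - y.cumulative()).max())
    return ComparisonResult("ks", d)


def _looks_normalized(h: BinnedHistogram) -> bool:
    c = h.counts
    return bool(np.isclose(c.sum(), 1.0) and np.any((c > 0) & (c < 1)))


def cluster_chi2(
    counts_n: BinnedHistogram, counts_m: BinnedHistogram
) -> ComparisonResult:
    """Two-sample chi-square comparison of count histograms.

    Returns the statistic, the p-value from chi^2_{b-1} (b = bins with
    n_i + m_i > 0) and the degrees of freedom.  Inputs must be raw counts,
    not normalized frequencies — the statistic's null distribution depends
    on the totals N and M.
    """
    _check_pair(counts_n, counts_m)
    if _looks_normalized(counts_n) or _looks_normalized(counts_m):
        raise ValueError("cluster_chi2 needs raw count histograms, not frequencies")
    n = counts_n.counts
    m = counts_m.counts
    N = counts_n.total
    M = counts_m.total
    occupied = (n + m) > 0
    b = int(occupied.sum())
    if b < 2:
        raise ValueError("need at least 2 occupied bins")
    ni, mi = n[occupied], m[occupied]
    x2 = float(np.sum((M * ni - N * mi) ** 2 / (ni + mi)) / (M * N))
    dof = b - 1
    p = float(stats.chi2.sf(x2, dof))
    return ComparisonResult("chi2", x2, p_value=p, dof=dof)


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def bootstrap_se(
    samples: Sequence[np.ndarray] | np.ndarray,
    statistic: Callable[..., float],
    n_boot: int = 1000,
    seed=None,
    ci: float | None = None,
):
    """Bootstrap standard error of ``statistic`` over resampled observations.

    ``samples`` is one array or a sequence of arrays; each replicate
    resamples every array independently with replacement and evaluates
    ``statistic(*resampled)``.  Replicates on which the statistic is
    undefined (raises or returns non-finite) are dropped and counted.

    Returns the se, or ``(se, (lo, hi))`` with a percentile confidence
    interval when ``ci`` (e.g. 0.95) is given.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if isinstance(samples, np.ndarray):
        samples = [samples]
    arrays = [np.asarray(s) for s in samples]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = []
    dropped = 0
    for _ in range(n_boot):
        res = [a[rng.integers(0, a.size, a.size)] for a in arrays]
        try:
            val = float(statistic(*res))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            dropped += 1
            continue
        if not np.isfinite(val):
            dropped += 1
            continue
        reps.append(val)
    if dropped:
        log.info("bootstrap: dropped %d/%d undefined replicates", dropped, n_boot)
    if len(reps) < 2:
        raise ValueError("statistic undefined on nearly all bootstrap replicates")
    reps = np.asarray(reps)
    se = float(reps.std(ddof=1))
    if ci is None:
        return se
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return se, (float(lo), float(hi))
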