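"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (brute force, enumeration, double loops)
and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def emd_transport(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum-cost transport between two normalized 1D histograms.

    Ground distance = |i - j| between bin indices; solved as an explicit
    linear program over the full flow matrix.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    b = x.size
    cost = np.abs(np.subtract.outer(np.arange(b), np.arange(b))).ravel()
    a_eq = []
    b_eq = []
    for i in range(b):  # row sums = x
        row = np.zeros((b, b))
        row[i, :] = 1
        a_eq.append(row.ravel())
        b_eq.append(x[i])
    for j in range(b):  # column sums = y
        col = np.zeros((b, b))
        col[:, j] = 1
        a_eq.append(col.ravel())
        b_eq.append(y[j])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun)


def autocorr_double_loop(values: np.ndarray, n_max: int) -> np.ndarray:
    """Spatial autocorrelation via explicit loops and population variance."""
    v = [float(x) for x in values]
    L = len(v)
    mu = sum(v) / L
    var = sum((x - mu) ** 2 for x in v) / L
    out = []
    for n in range(n_max + 1):
        total = 0.0
        for m in range(L - n):
            total += (v[n + m] - mu) * (v[m] - mu)
        out.append(total / (L - n) / var)
    return np.array(out)


def bernoulli_run_distribution_exact(L: int, p: float) -> np.ndarray:
    """E[# runs of exactly k ones], k = 1..L, by exhaustive enumeration.

    Sums over all 2^L strings weighted by their Bernoulli probability;
    feasible for L <= ~16.
    """
    q = 1.0 - p
    expected = np.zeros(L)
    for bits in itertools.product((0, 1), repeat=L):
        ones = sum(bits)
        w = p ** ones * q ** (L - ones)
        k = 0
        for bit in bits + (0,):
            if bit:
                k += 1
            elif k:
                expected[k - 1] += w
                k = 0
    return expected


def run_sizes_loop(bits) -> list[int]:
    """Run lengths of 1s via a plain scan."""
    sizes = []
    k = 0
    for b in list(bits) + [0]:
        if b:
            k += 1
        elif k:
            sizes.append(k)
            k = 0
    return sizes
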