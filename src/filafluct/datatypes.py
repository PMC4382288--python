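"""Core containers shared across the analysis stages.

A *filament* is an ordered one-dimensional chain of cells; every spatial
statistic in this package is defined on that lattice.  The containers here
deliberately stay thin: plain dataclasses wrapping numpy arrays, with just
enough validation to catch malformed inputs early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilamentTrace",
    "FilamentSet",
    "CorrelationCurve",
    "NoiseDecomposition",
    "NeighborPairs",
    "BinnedHistogram",
    "ComparisonResult",
    "BinaryFilament",
]


@dataclass
class FilamentTrace:
    """Ordered per-cell fluorescence values F(0..L-1) of one filament."""

    values: np.ndarray
    filament_id: int = 0
    run_id: str = "run0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("a filament trace must be a 1D array with >= 1 cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluorescence values must be finite")
        if np.any(self.values < 0):
            raise ValueError("fluorescence values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def reversed(self) -> "FilamentTrace":
        return FilamentTrace(self.values[::-1].copy(), self.filament_id, self.run_id)


@dataclass
class FilamentSet:
    """All filaments of one experimental run (one strain / timepoint)."""

    traces: list[FilamentTrace] = field(default_factory=list)
    run_id: str = "run0"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[FilamentTrace]:
        return iter(self.traces)

    @property
    def n_cells(self) -> int:
        return int(sum(len(t) for t in self.traces))

    def lengths(self) -> np.ndarray:
        return np.array([len(t) for t in self.traces], dtype=int)

    def pooled_values(self) -> np.ndarray:
        """All cell fluorescence values of the set, concatenated."""
        if not self.traces:
            return np.empty(0)
        return np.concatenate([t.values for t in self.traces])

    # ---- tabular round trip (CSV interface of the package) -------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.traces:
            for i, v in enumerate(t.values):
                rows.append((t.run_id, t.filament_id, i, v))
        return pd.DataFrame(
            rows, columns=["run_id", "filament_id", "cell_index", "fluorescence"]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, run_id: str | None = None) -> "FilamentSet":
        required = {"run_id", "filament_id", "cell_index", "fluorescence"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cells table missing columns: {sorted(missing)}")
        if run_id is not None:
            df = df[df["run_id"].astype(str) == str(run_id)]
        runs = df["run_id"].astype(str).unique()
        if len(runs) > 1:
            raise ValueError(
                "cells table contains several runs; pass run_id to select one"
            )
        rid = str(runs[0]) if len(runs) else (run_id or "run0")
        traces = []
        for fid, grp in df.groupby("filament_id", sort=True):
            grp = grp.sort_values("cell_index")
            idx = grp["cell_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise ValueError(
                    f"filament {fid}: cell_index must be consecutive from 0"
                )
            traces.append(FilamentTrace(grp["fluorescence"].to_numpy(), int(fid), rid))
        return cls(traces, run_id=rid)


@dataclass
class CorrelationCurve:
    """Spatial autocorrelation g(n) vs cell distance n, with standard errors.

    ``corrected`` flags whether the permutation bias compensation has been
    subtracted (n >= 1).  ``se`` is the standard error across filaments for a
    single-run curve, or across runs after aggregation.
    """

    distances: np.ndarray
    g: np.ndarray
    se: np.ndarray
    corrected: bool
    n_filaments_used: int
    run_id: str = "run0"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=int)
        self.g = np.asarray(self.g, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (self.distances.shape == self.g.shape == self.se.shape):
            raise ValueError("distances, g and se must have matching shapes")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.distances,
                "g": self.g,
                "se": self.se,
                "corrected": self.corrected,
            }
        )


@dataclass
class NoiseDecomposition:
    """Between-filament vs within-filament share of expression noise.

    ``between`` is sigma^2/mu^2 of the per-filament mean fluorescences;
    ``within_avg`` averages the per-filament noise sigma_f^2/mu_f^2 over
    filaments; ``ratio`` = between / within_avg (undefined -> None).
    """

    between: float
    within_avg: float
    ratio: float | None
    n_filaments: int


@dataclass
class NeighborPairs:
    """Pooled nearest-neighbour fluorescence pairs and their Pearson r."""

    f_n: np.ndarray
    f_n1: np.ndarray
    pearson_r: float
    p_value: float
    n_pairs: int


@dataclass
class BinnedHistogram:
    """Counts on ordered, shared bin edges.

    Both compared histograms of any distance computation must share
    identical ``bin_edges``.  ``counts`` are non-negative; the normalized
    form (frequencies summing to 1) is derived on demand.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("bin_edges and counts must be 1D")
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def b(self) -> int:
        """Number of bins."""
        return self.counts.size

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    def normalized(self) -> np.ndarray:
        """Frequencies x_i = counts_i / total (sums to 1)."""
        if self.is_empty:
            raise ValueError("cannot normalize an empty histogram")
        return self.counts / self.total

    def cumulative(self) -> np.ndarray:
        """Cumulative distribution CDX(i) = sum_{j<=i} x_j of the normalized form."""
        return np.cumsum(self.normalized())

    def same_edges(self, other: "BinnedHistogram", atol: float = 1e-9) -> bool:
        return self.bin_edges.size == other.bin_edges.size and np.allclose(
            self.bin_edges, other.bin_edges, atol=atol
        )


@dataclass
class ComparisonResult:
    """Outcome of a histogram comparison (EMD, D_KS or X^2)."""

    metric: str
    statistic: float
    p_value: float | None = None
    dof: int | None = None
    se: float | None = None

    def to_dict(self) -> dict:
        out = {"metric": self.metric, "statistic": self.statistic}
        if self.p_value is not None:
            out["p_value"] = self.p_value
        if self.dof is not None:
            out["dof"] = self.dof
        if self.se is not None:
            out["se"] = self.se
        return out


@dataclass
class BinaryFilament:
    """0/1 representation of a filament after thresholding."""

    bits: np.ndarray
    filament_id: int = 0

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 1:
            raise ValueError("bits must be 1D")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        self.bits = self.bits.astype(np.int8)

    def __len__(self) -> int:
        return self.bits.size
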