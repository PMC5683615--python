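"""Equal-width resistance clustering of phenotype scores by Sturges' rule.

Collections are partitioned into k = ceil(1 + log2(n)) clusters of
(nearly) equal width.  Because GI and SS are reported on a 0.01 grid, bins
are closed integer-grid ranges printed like ``0.01-0.12``, ``0.13-0.24``:
each bin spans ``ceil(n_cells / k)`` grid cells and consecutive bins abut
with a one-cell gap in printed notation, so ties at bin edges cannot
occur.  The last bin absorbs any remainder of the range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClusterAssignment",
    "sturges_k",
    "make_bins",
    "assign_clusters",
    "cross_classify",
    "SturgesBinner",
]


@dataclass(frozen=True)
class ClusterAssignment:
    entry_id: str
    cluster_index: int  # 1-based
    lo: float
    hi: float


def sturges_k(n: int) -> int:
    """Sturges' class count k = ceil(1 + log2 n); 8 for both n=74 and n=87."""
    if n < 1:
        raise ValueError("Sturges' rule requires n >= 1")
    return max(1, math.ceil(1.0 + math.log2(n)))


def _to_cells(values: np.ndarray, decimals: int) -> np.ndarray:
    """Map decimal-grid values to exact integer grid cells."""
    scale = 10**decimals
    cells = np.rint(np.asarray(values, dtype=float) * scale).astype(int)
    return cells


def make_bins(
    values, k: int, decimals: int = 2
) -> list[tuple[float, float]]:
    """Closed equal-width bin ranges on the ``10**-decimals`` grid.

    Each bin spans ``ceil(n_cells / k)`` grid cells, where ``n_cells`` is
    the number of grid points between min and max inclusive; the last bin
    is extended to cover the maximum.  Returns ``[(lo, hi), ...]`` with
    ``lo``/``hi`` both attainable data values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("make_bins requires at least one value")
    if k < 1:
        raise ValueError("k must be >= 1")
    cells = _to_cells(values, decimals)
    lo, hi = int(cells.min()), int(cells.max())
    scale = 10**decimals
    if lo == hi:
        if k > 1:
            warnings.warn(
                "all values identical: degenerate range, returning a single bin",
                stacklevel=2,
            )
        return [(lo / scale, hi / scale)]
    n_cells = hi - lo + 1
    width = math.ceil(n_cells / k)
    bins = []
    for i in range(k):
        b_lo = lo + i * width
        b_hi = b_lo + width - 1
        if i == k - 1:
            b_hi = max(b_hi, hi)
        bins.append((b_lo / scale, b_hi / scale))
    return bins


def assign_clusters(
    values_by_entry: dict[str, float],
    bins: list[tuple[float, float]],
    decimals: int = 2,
) -> tuple[list[ClusterAssignment], pd.Series]:
    """Assign each entry to its bin; returns assignments and per-bin counts."""
    edges = [(_to_cells(np.array([lo]), decimals)[0], _to_cells(np.array([hi]), decimals)[0])
             for lo, hi in bins]
    assignments = []
    counts = pd.Series(0, index=pd.RangeIndex(1, len(bins) + 1, name="cluster"))
    for entry_id, value in values_by_entry.items():
        cell = int(_to_cells(np.array([value]), decimals)[0])
        for i, (b_lo, b_hi) in enumerate(edges):
            if b_lo <= cell <= b_hi:
                lo, hi = bins[i]
                assignments.append(ClusterAssignment(entry_id, i + 1, lo, hi))
                counts[i + 1] += 1
                break
        else:
            raise ValueError(
                f"value {value} for entry {entry_id!r} falls outside all bins"
            )
    return assignments, counts


def cross_classify(
    gi_by_entry: dict[str, float],
    ss_by_entry: dict[str, float],
    gi_threshold: float,
    ss_threshold: float,
) -> dict[tuple[str, str], list[str]]:
    """2x2 low/high GI x low/high SS classification of the joint phenotype.

    'low' means value <= threshold.  Entries missing either phenotype are
    excluded.  Keys are (``'low_gi'|'high_gi'``, ``'low_ss'|'high_ss'``).
    """
    quadrants: dict[tuple[str, str], list[str]] = {
        (g, s): [] for g in ("low_gi", "high_gi") for s in ("low_ss", "high_ss")
    }
    for entry_id, gi in gi_by_entry.items():
        ss = ss_by_entry.get(entry_id)
        if ss is None or (isinstance(ss, float) and np.isnan(ss)) or np.isnan(gi):
            continue
        g = "low_gi" if gi <= gi_threshold else "high_gi"
        s = "low_ss" if ss <= ss_threshold else "high_ss"
        quadrants[(g, s)].append(entry_id)
    return quadrants


class SturgesBinner(TransformerMixin, BaseEstimator):
    """Discretize a phenotype into equal-width Sturges clusters.

    A KBinsDiscretizer-style transformer: ``fit`` learns the bin ranges
    from the training values (k from Sturges' rule unless ``n_bins`` is
    given), ``transform`` maps values to 1-based cluster indices.

    Parameters
    ----------
    n_bins : int or None
        Number of clusters; ``None`` (default) applies Sturges' rule to
        the number of fitted samples.
    decimals : int
        Reporting grid of the phenotype (2 for GI/SS as printed).

    Attributes
    ----------
    n_bins_ : int
        Number of clusters actually used.
    bin_ranges_ : list of (lo, hi)
        Closed cluster ranges on the decimal grid.
    """

    def __init__(self, n_bins: int | None = None, decimals: int = 2):
        self.n_bins = n_bins
        self.decimals = decimals

    def fit(self, X, y=None):
        X = self._check_values(X)
        k = self.n_bins if self.n_bins is not None else sturges_k(X.size)
        self.bin_ranges_ = make_bins(X, k, decimals=self.decimals)
        self.n_bins_ = len(self.bin_ranges_)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "bin_ranges_")
        X = self._check_values(X)
        cells = _to_cells(X, self.decimals)
        edges = np.array(
            [_to_cells(np.array(r), self.decimals) for r in self.bin_ranges_]
        )
        out = np.full(X.size, -1, dtype=int)
        for i, (lo, hi) in enumerate(edges):
            out[(cells >= lo) & (cells <= hi)] = i + 1
        if (out == -1).any():
            bad = X[out == -1]
            raise ValueError(f"values outside all fitted bins: {bad.tolist()}")
        return out

    @staticmethod
    def _check_values(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        if X.ndim != 1:
            raise ValueError("expected a 1-d array of phenotype values")
        if np.isnan(X).any():
            raise ValueError("missing values must be dropped before binning")
        return X
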