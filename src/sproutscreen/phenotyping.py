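"""Seed-dormancy phenotyping: germination index and spike sprouting.

The germination index (GI) is the day-weighted Walker-Simmons score of a
7-day Petri-dish germination assay,

    GI = (7*n1 + 6*n2 + ... + 1*n7) / (7 * TG),

where ``n_d`` is the number of seeds germinating on day ``d`` and ``TG`` is
the number of viable grains: seeds placed minus seeds that never germinated
within a 30-day viability window.  GI is 1 when every viable seed
germinates on day 1 (no dormancy) and approaches 1/7 as germination is
pushed to day 7; seeds germinating after day 7 but within the viability
window count in TG and contribute nothing to the numerator.

Spike sprouting (SS) is the fraction of grains visibly sprouted after a
3-day moist-chamber provocation of intact spikes: sprouted / total grains.

Both scores are proportions in [0, 1]; higher means faster germination,
lower dormancy, and greater pre-harvest sprouting susceptibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GerminationAssay",
    "SpikeAssay",
    "PhenotypeRecord",
    "MalformedAssayError",
    "viable_total",
    "germination_index",
    "entry_gi",
    "spike_sprouting",
    "germination_dynamics",
    "phenotype_table",
]

N_DAYS = 7


class MalformedAssayError(ValueError):
    """An assay violates its count invariants."""


@dataclass(frozen=True)
class GerminationAssay:
    """Daily germination counts for one replicate of one entry.

    ``daily_counts[d-1]`` is the number of seeds newly germinated on day d
    (d = 1..7).  ``n_nonviable`` is the number of seeds that never
    germinated within the 30-day viability window; seeds germinating on
    days 8-30 are the implicit remainder.
    """

    entry_id: str
    replicate: int
    daily_counts: tuple[int, ...]
    seeds_placed: int = 25
    n_nonviable: int = 0

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.daily_counts)
        object.__setattr__(self, "daily_counts", counts)
        if len(counts) != N_DAYS:
            raise MalformedAssayError(
                f"{self.entry_id}/rep{self.replicate}: expected {N_DAYS} "
                f"daily counts, got {len(counts)}"
            )
        if any(c < 0 for c in counts) or self.n_nonviable < 0:
            raise MalformedAssayError("counts must be non-negative")
        if self.seeds_placed <= 0:
            raise MalformedAssayError("seeds_placed must be positive")
        if sum(counts) + self.n_nonviable > self.seeds_placed:
            raise MalformedAssayError(
                f"{self.entry_id}/rep{self.replicate}: germinated + nonviable "
                f"exceeds seeds placed ({sum(counts)} + {self.n_nonviable} "
                f"> {self.seeds_placed})"
            )


@dataclass(frozen=True)
class SpikeAssay:
    """Sprouted vs total grain counts from the intact-spike assay."""

    entry_id: str
    n_sprouted: int
    n_total_grains: int

    def __post_init__(self) -> None:
        if self.n_total_grains <= 0:
            raise MalformedAssayError(
                f"{self.entry_id}: total grain count must be positive"
            )
        if not 0 <= self.n_sprouted <= self.n_total_grains:
            raise MalformedAssayError(
                f"{self.entry_id}: sprouted count {self.n_sprouted} outside "
                f"[0, {self.n_total_grains}]"
            )


@dataclass(frozen=True)
class PhenotypeRecord:
    entry_id: str
    gi: float
    ss: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gi <= 1.0:
            raise ValueError(f"GI outside [0,1]: {self.gi}")
        if self.ss is not None and not 0.0 <= self.ss <= 1.0:
            raise ValueError(f"SS outside [0,1]: {self.ss}")


def viable_total(assay: GerminationAssay) -> int:
    """Viable grain count TG = seeds placed minus never-germinating seeds."""
    tg = assay.seeds_placed - assay.n_nonviable
    if tg < 0:  # unreachable when invariants hold, kept as a guard
        raise MalformedAssayError("more nonviable seeds than seeds placed")
    return tg


def germination_index(daily_counts: Sequence[int], tg: int) -> float:
    """Day-weighted germination index of one count vector.

    Parameters
    ----------
    daily_counts : sequence of 7 ints
        Seeds newly germinated on days 1..7.
    tg : int
        Viable grain total; must be positive and at least ``sum(daily_counts)``.
    """
    counts = np.asarray(daily_counts, dtype=float)
    if counts.shape != (N_DAYS,):
        raise MalformedAssayError(f"expected {N_DAYS} daily counts")
    if tg <= 0:
        raise MalformedAssayError("germination index undefined for TG = 0")
    if counts.sum() > tg:
        raise MalformedAssayError("more germinated seeds than viable total")
    weights = np.arange(N_DAYS, 0, -1)  # 7, 6, ..., 1
    return float(weights @ counts / (N_DAYS * tg))


def entry_gi(assays: Iterable[GerminationAssay], method: str = "pool") -> float:
    """Aggregate replicate assays of one entry into a single GI.

    ``method="pool"`` (default) sums daily counts and viable totals across
    replicates before applying the index (ratio of sums), which is robust
    to replicates with unequal viable totals.  ``method="mean"`` averages
    the per-replicate indices instead.
    """
    assays = list(assays)
    if not assays:
        raise ValueError("entry_gi requires at least one replicate")
    if method == "pool":
        counts = np.sum([a.daily_counts for a in assays], axis=0)
        tg = sum(viable_total(a) for a in assays)
        return germination_index(counts, tg)
    if method == "mean":
        return float(
            np.mean([germination_index(a.daily_counts, viable_total(a)) for a in assays])
        )
    raise ValueError(f"unknown aggregation method: {method!r}")


def spike_sprouting(assay: SpikeAssay) -> float:
    """Fraction of grains sprouted in the intact-spike assay."""
    return assay.n_sprouted / assay.n_total_grains


def germination_dynamics(
    assays_by_entry: Mapping[str, Iterable[GerminationAssay]],
) -> dict[str, np.ndarray]:
    """Per-entry daily germination proportions n_d / TG, pooled over replicates.

    The returned 7-vectors sum to at most 1 (late germinators and
    nonviable seeds take up the remainder); resistant, low-GI entries show
    later, flatter peaks.
    """
    out: dict[str, np.ndarray] = {}
    for entry_id, assays in assays_by_entry.items():
        assays = list(assays)
        counts = np.sum([a.daily_counts for a in assays], axis=0, dtype=float)
        tg = sum(viable_total(a) for a in assays)
        if tg <= 0:
            raise MalformedAssayError(f"{entry_id}: no viable seeds")
        out[entry_id] = counts / tg
    return out


def phenotype_table(
    germination: pd.DataFrame,
    spikes: pd.DataFrame | None = None,
    method: str = "pool",
) -> pd.DataFrame:
    """Build the per-entry phenotype table from long-format count tables.

    ``germination`` columns: entry_id, replicate, day, n_germinated,
    seeds_placed, n_nonviable (seeds_placed/n_nonviable constant within a
    replicate).  ``spikes`` columns: entry_id, n_sprouted, n_total_grains.
    Returns a frame with columns entry_id, gi, ss (ss is NaN where the
    spike assay is missing).
    """
    days = germination["day"].to_numpy(dtype=int)
    if ((days < 1) | (days > N_DAYS)).any():
        bad = sorted(set(days[(days < 1) | (days > N_DAYS)]))
        raise MalformedAssayError(f"day values outside 1..{N_DAYS}: {bad}")
    wide = (
        germination.pivot_table(
            index=["entry_id", "replicate"],
            columns="day",
            values="n_germinated",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(columns=range(1, N_DAYS + 1), fill_value=0)
    )
    meta = germination.groupby(["entry_id", "replicate"], sort=False).agg(
        seeds_placed=("seeds_placed", "first"), n_nonviable=("n_nonviable", "first")
    )
    assays: dict[str, list[GerminationAssay]] = {}
    for (entry, rep), counts in zip(wide.index, wide.to_numpy(dtype=int)):
        assays.setdefault(str(entry), []).append(
            GerminationAssay(
                entry_id=str(entry),
                replicate=int(rep),
                daily_counts=tuple(counts),
                seeds_placed=int(meta.loc[(entry, rep), "seeds_placed"]),
                n_nonviable=int(meta.loc[(entry, rep), "n_nonviable"]),
            )
        )
    ss_map: dict[str, float] = {}
    if spikes is not None:
        for _, row in spikes.iterrows():
            a = SpikeAssay(
                str(row["entry_id"]), int(row["n_sprouted"]), int(row["n_total_grains"])
            )
            ss_map[a.entry_id] = spike_sprouting(a)
    records = [
        {"entry_id": e, "gi": entry_gi(a, method=method), "ss": ss_map.get(e, np.nan)}
        for e, a in assays.items()
    ]
    return pd.DataFrame.from_records(records, columns=["entry_id", "gi", "ss"])
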