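"""Two-marker haplotype calling for the wheatgrass Vp-1 orthologue (ThVp-1).

Two PCR markers interrogate the ThVp-1 region in a wheat background:

* ``Vp1BB4_HaeIII`` — a CAPS marker (PCR + HaeIII digestion) whose
  wheatgrass-diagnostic restriction fragments are ~600 bp or ~550 bp;
* ``Vivip`` — an STS marker whose wheatgrass-diagnostic amplicons are
  ~350 bp or ~370 bp.

The joint band state defines four haplotypes:

====================  ==============  ==========
Vp1BB4_HaeIII         Vivip           haplotype
====================  ==============  ==========
no specific fragment  no specific     ThVp-1a
~600 bp               no specific     ThVp-1b
~550 bp               ~370 bp         ThVp-1c
no specific fragment  ~350 bp         ThVp-1d
====================  ==============  ==========

The ~550 bp CAPS fragment and the ~370 bp STS fragment tag the same
allele, so they must co-occur; any other joint state is flagged
``inconsistent`` rather than called.  Entries whose plants disagree are
flagged ``heterogeneous`` and excluded from association analysis.

The wheat TaVp-1B allele (marker Vp-1B3) is handled as a categorical
label (``Vp-1Ba``/``Vp-1Bc``/``hz``/``hg``) rather than called from
fragment sizes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "MarkerObservation",
    "MarkerProfile",
    "HaplotypeCall",
    "AmbiguousBandError",
    "UnsupportedMarkerError",
    "CAPS_MARKER",
    "STS_MARKER",
    "HAPLOTYPES",
    "WHEAT_ALLELES",
    "BANDS_FOR_HAPLOTYPE",
    "call_band_state",
    "call_haplotype",
    "entry_consensus",
    "haplotype_distribution",
    "wheat_allele_distribution",
    "linkage_report",
    "HaplotypeCaller",
]

CAPS_MARKER = "Vp1BB4_HaeIII"
STS_MARKER = "Vivip"
WHEAT_MARKER = "Vp-1B3"

# diagnostic (non-wheat) reference fragment sizes, bp
_REFERENCE_SIZES = {
    CAPS_MARKER: {600: "f600", 550: "f550"},
    STS_MARKER: {370: "f370", 350: "f350"},
}

HAPLOTYPES = ("ThVp-1a", "ThVp-1b", "ThVp-1c", "ThVp-1d")
WHEAT_ALLELES = ("Vp-1Ba", "Vp-1Bc", "hz", "hg")

# joint band state -> haplotype (the four observed marker-result rows)
_HAPLOTYPE_TABLE = {
    ("absent", "absent"): "ThVp-1a",
    ("f600", "absent"): "ThVp-1b",
    ("f550", "f370"): "ThVp-1c",
    ("absent", "f350"): "ThVp-1d",
}

# inverse map: diagnostic band sizes expected for each haplotype
BANDS_FOR_HAPLOTYPE: dict[str, dict[str, tuple[float, ...]]] = {
    "ThVp-1a": {CAPS_MARKER: (), STS_MARKER: ()},
    "ThVp-1b": {CAPS_MARKER: (600.0,), STS_MARKER: ()},
    "ThVp-1c": {CAPS_MARKER: (550.0,), STS_MARKER: (370.0,)},
    "ThVp-1d": {CAPS_MARKER: (), STS_MARKER: (350.0,)},
}


class AmbiguousBandError(ValueError):
    """A fragment pattern cannot be resolved to a single band state."""

    def __init__(self, marker: str, message: str):
        self.marker = marker
        super().__init__(f"{marker}: {message}")


class UnsupportedMarkerError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerObservation:
    """Diagnostic fragment sizes seen for one marker in one plant."""

    entry_id: str
    plant_id: str
    marker: str
    fragment_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.marker not in (CAPS_MARKER, STS_MARKER, WHEAT_MARKER):
            raise UnsupportedMarkerError(f"unknown marker {self.marker!r}")
        sizes = tuple(float(s) for s in self.fragment_sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError("fragment sizes must be positive")
        object.__setattr__(self, "fragment_sizes", sizes)


@dataclass(frozen=True)
class MarkerProfile:
    """Joint band state of the two wheatgrass markers."""

    caps_state: str
    sts_state: str

    def __post_init__(self) -> None:
        if self.caps_state not in ("absent", "f600", "f550", "ambiguous"):
            raise ValueError(f"invalid CAPS state {self.caps_state!r}")
        if self.sts_state not in ("absent", "f350", "f370", "ambiguous"):
            raise ValueError(f"invalid STS state {self.sts_state!r}")


@dataclass(frozen=True)
class HaplotypeCall:
    entry_id: str
    haplotype: str | None
    flag: str  # ok | heterogeneous | inconsistent

    def __post_init__(self) -> None:
        if self.flag not in ("ok", "heterogeneous", "inconsistent"):
            raise ValueError(f"invalid flag {self.flag!r}")
        if (self.haplotype is not None) != (self.flag == "ok"):
            raise ValueError("haplotype must be present exactly when flag is ok")


def call_band_state(obs: MarkerObservation, tolerance_bp: float = 15.0) -> str:
    """Map observed fragment sizes to a band state for one wheatgrass marker.

    Each size is assigned to the nearest reference size within
    ``tolerance_bp``.  No diagnostic fragment gives ``absent``; a size
    matching no reference, or sizes matching both references of the same
    marker, give ``ambiguous``.
    """
    if obs.marker not in _REFERENCE_SIZES:
        raise UnsupportedMarkerError(
            f"band-state calling supports only the wheatgrass markers, "
            f"not {obs.marker!r}"
        )
    refs = _REFERENCE_SIZES[obs.marker]
    matched: set[str] = set()
    for size in obs.fragment_sizes:
        deltas = {state: abs(size - ref) for ref, state in refs.items()}
        state, delta = min(deltas.items(), key=lambda kv: kv[1])
        if delta > tolerance_bp:
            return "ambiguous"
        matched.add(state)
    if not matched:
        return "absent"
    if len(matched) > 1:
        return "ambiguous"
    return matched.pop()


def call_haplotype(profile: MarkerProfile, entry_id: str = "") -> HaplotypeCall:
    """Call a ThVp-1 haplotype from a joint marker profile.

    Only the four observed joint states are callable; every other
    combination (for example a ~550 bp CAPS fragment without the linked
    ~370 bp STS fragment) is flagged inconsistent.
    """
    for state, name in ((profile.caps_state, CAPS_MARKER), (profile.sts_state, STS_MARKER)):
        if state == "ambiguous":
            raise AmbiguousBandError(name, f"ambiguous band state for {entry_id!r}")
    haplotype = _HAPLOTYPE_TABLE.get((profile.caps_state, profile.sts_state))
    if haplotype is None:
        return HaplotypeCall(entry_id, None, "inconsistent")
    return HaplotypeCall(entry_id, haplotype, "ok")


def entry_consensus(calls: Sequence[HaplotypeCall]) -> HaplotypeCall:
    """Combine per-plant calls of one entry into a consensus call.

    All plants agreeing on one haplotype gives that haplotype; any
    disagreement marks the entry heterogeneous (excluded downstream); any
    inconsistent plant call propagates.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("entry_consensus requires at least one plant call")
    entry_id = calls[0].entry_id
    if any(c.flag == "inconsistent" for c in calls):
        return HaplotypeCall(entry_id, None, "inconsistent")
    haplotypes = {c.haplotype for c in calls}
    if len(haplotypes) > 1:
        return HaplotypeCall(entry_id, None, "heterogeneous")
    return HaplotypeCall(entry_id, haplotypes.pop(), "ok")


def haplotype_distribution(calls: Iterable[HaplotypeCall]) -> pd.DataFrame:
    """Per-haplotype counts and integer percentages over the collection.

    Heterogeneous entries are tallied under ``hg``; percentages are of
    all tallied entries, rounded to the nearest integer.
    """
    labels = []
    for c in calls:
        if c.flag == "ok":
            labels.append(c.haplotype)
        elif c.flag == "heterogeneous":
            labels.append("hg")
        else:
            labels.append("inconsistent")
    counter = Counter(labels)
    total = sum(counter.values())
    if total == 0:
        raise ValueError("no haplotype calls to summarize")
    rows = []
    for h in (*HAPLOTYPES, "hg", "inconsistent"):
        n = counter.get(h, 0)
        if h == "inconsistent" and n == 0:
            continue
        rows.append({"haplotype": h, "n": n, "percent": round(100.0 * n / total)})
    return pd.DataFrame(rows)


def wheat_allele_distribution(alleles: Iterable[str]) -> pd.DataFrame:
    """Counts and integer percentages of the wheat TaVp-1B allele labels.

    ``hz`` (heterozygote) and ``hg`` (heterogeneous entry) rows are
    flagged for downstream exclusion from association analysis.
    """
    alleles = list(alleles)
    unknown = set(alleles) - set(WHEAT_ALLELES)
    if unknown:
        raise ValueError(f"unknown wheat allele labels: {sorted(unknown)}")
    counter = Counter(alleles)
    total = len(alleles)
    rows = [
        {
            "allele": a,
            "n": counter.get(a, 0),
            "percent": round(100.0 * counter.get(a, 0) / total),
            "excluded_from_association": a in ("hz", "hg"),
        }
        for a in WHEAT_ALLELES
    ]
    return pd.DataFrame(rows)


def linkage_report(profiles: dict[str, MarkerProfile]) -> pd.DataFrame:
    """Validate the f550/f370 linkage across entries.

    The ~550 bp CAPS and ~370 bp STS fragments tag the same allele and
    must co-occur; returns the entries violating that linkage (empty frame
    on a consistent dataset).
    """
    rows = [
        {"entry_id": e, "caps_state": p.caps_state, "sts_state": p.sts_state}
        for e, p in profiles.items()
        if (p.caps_state == "f550") != (p.sts_state == "f370")
    ]
    return pd.DataFrame(rows, columns=["entry_id", "caps_state", "sts_state"])


def bands_from_labels(
    labels: pd.DataFrame,
    hg_pair: tuple[str, str] = ("ThVp-1a", "ThVp-1c"),
) -> pd.DataFrame:
    """Reconstruct a marker band table from haplotype labels.

    The inverse of the calling logic: each labelled entry gets one plant
    carrying the reference diagnostic fragments of its haplotype; entries
    labelled ``hg`` (heterogeneous) get two plants with discordant
    haplotypes (``hg_pair``), so the consensus caller re-flags them.
    ``labels`` needs columns ``entry_id`` and a haplotype-label column
    (the second column).
    """
    label_col = [c for c in labels.columns if c != "entry_id"][0]
    rows = []
    for _, rec in labels.iterrows():
        entry_id = str(rec["entry_id"])
        label = rec[label_col]
        plant_haps = hg_pair if label == "hg" else (label,)
        for p, hap in enumerate(plant_haps, start=1):
            if hap not in BANDS_FOR_HAPLOTYPE:
                raise ValueError(f"unknown haplotype label {hap!r} for {entry_id!r}")
            for marker in (CAPS_MARKER, STS_MARKER):
                rows.append(
                    {
                        "entry_id": entry_id,
                        "plant_id": f"p{p}",
                        "marker": marker,
                        "fragment_sizes": tuple(BANDS_FOR_HAPLOTYPE[hap][marker]),
                    }
                )
    return pd.DataFrame(rows)


class HaplotypeCaller(ClassifierMixin, BaseEstimator):
    """Rule-based ThVp-1 haplotype caller over marker band tables.

    A stateless classifier in the sklearn idiom: ``fit`` only validates
    parameters (the decision table is fixed by the marker design), and
    ``predict`` maps a long-format band table — columns ``entry_id``,
    ``plant_id``, ``marker``, ``fragment_sizes`` (sequence of bp sizes) —
    to one consensus :class:`HaplotypeCall` per entry.

    Parameters
    ----------
    tolerance_bp : float
        Half-width of the size-matching window around each reference
        fragment.  The default 15 bp separates both reference pairs
        (600/550: gap 50; 370/350: gap 20) without double assignment.
    """

    def __init__(self, tolerance_bp: float = 15.0):
        self.tolerance_bp = tolerance_bp

    def fit(self, X=None, y=None):
        if not 0 < self.tolerance_bp <= 20:
            raise ValueError(
                "tolerance_bp must be in (0, 20] to keep the 350/370 bp "
                "references separable"
            )
        self.classes_ = np.array(HAPLOTYPES)
        return self

    def predict(self, X: pd.DataFrame) -> list[HaplotypeCall]:
        if not hasattr(self, "classes_"):
            self.fit()
        calls: list[HaplotypeCall] = []
        for entry_id, per_entry in X.groupby("entry_id", sort=False):
            plant_calls = []
            for plant_id, per_plant in per_entry.groupby("plant_id", sort=False):
                states = {CAPS_MARKER: "absent", STS_MARKER: "absent"}
                for _, row in per_plant.iterrows():
                    obs = MarkerObservation(
                        str(entry_id), str(plant_id), row["marker"],
                        tuple(row["fragment_sizes"]),
                    )
                    states[obs.marker] = call_band_state(obs, self.tolerance_bp)
                profile = MarkerProfile(states[CAPS_MARKER], states[STS_MARKER])
                plant_calls.append(call_haplotype(profile, str(entry_id)))
            calls.append(entry_consensus(plant_calls))
        return calls

    def predict_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """predict() as a tidy frame with columns entry_id, haplotype, flag."""
        return pd.DataFrame(
            [
                {"entry_id": c.entry_id, "haplotype": c.haplotype, "flag": c.flag}
                for c in self.predict(X)
            ]
        )
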