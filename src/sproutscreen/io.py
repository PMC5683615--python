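"""Packaged collection data, tabular readers/writers, and the end-to-end run.

The package ships the published characterization of the 87-entry
wheat-wheatgrass hybrid collection (entry identifiers, ThVp-1 haplotype,
wheat TaVp-1B allele label, GI, SS, and spike/grain morphology) as a
plain TSV asset, checksummed on load.  All external tables are delimited
text with a header row; decimal commas are normalized to points on read
with a warning, and missing values are empty fields, never zeros.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

log = logging.getLogger("sproutscreen")

__all__ = [
    "Entry",
    "CorruptedFixtureError",
    "load_fixture",
    "read_table",
    "write_table",
    "GERMINATION_SCHEMA",
    "SPIKE_SCHEMA",
    "BAND_SCHEMA",
    "PHENOTYPE_SCHEMA",
    "reproduce",
]

_FIXTURE_NAME = "collection_87.tsv"
_FIXTURE_SHA256 = "2b30133f92e867d9dbb80a898b33edf66a648716b8c76863a6a3ef0f7efa1fce"

GRAIN_COLORS = {"light red", "dark red", "blue"}
GLUME_COLORS = {"white", "red"}
AWN_STATES = {"present", "absent", "small"}
THRESHABILITY = {"easy", "hard"}
_THVP1_LABELS = {"ThVp-1a", "ThVp-1b", "ThVp-1c", "ThVp-1d", "hg"}
_TAVP1B_LABELS = {"Vp-1Ba", "Vp-1Bc", "hz", "hg"}

# column name -> dtype ("str" | "int" | "float" | "sizes")
GERMINATION_SCHEMA = {
    "entry_id": "str",
    "replicate": "int",
    "day": "int",
    "n_germinated": "int",
    "seeds_placed": "int",
    "n_nonviable": "int",
}
SPIKE_SCHEMA = {"entry_id": "str", "n_sprouted": "int", "n_total_grains": "int"}
BAND_SCHEMA = {
    "entry_id": "str",
    "plant_id": "str",
    "marker": "str",
    "fragment_sizes": "sizes",
}
PHENOTYPE_SCHEMA = {"entry_id": "str", "gi": "float", "ss": "float"}


class CorruptedFixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class Entry:
    """One germplasm accession of the packaged collection."""

    entry_id: str
    thvp1: str
    tavp1b: str
    gi: float
    ss: float | None
    grain_color: str | None
    glume_color: str | None
    awns: str
    threshability: str


def load_fixture(as_records: bool = False):
    """Load and validate the packaged 87-entry collection table.

    Returns a DataFrame by default, or a list of :class:`Entry` records
    with ``as_records=True``.  Validates the checksum, the entry count
    (87, of which 74 carry a spike-sprouting value) and every categorical
    against its closed label set.
    """
    ref = resources.files("sproutscreen.data").joinpath(_FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise CorruptedFixtureError(
            f"fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", dtype={"entry_id": str})
    if len(df) != 87:
        raise CorruptedFixtureError(f"expected 87 entries, found {len(df)}")
    if int(df["ss"].notna().sum()) != 74:
        raise CorruptedFixtureError("expected 74 entries with a spike-sprouting value")
    checks = [
        ("thvp1", _THVP1_LABELS, False),
        ("tavp1b", _TAVP1B_LABELS, False),
        ("grain_color", GRAIN_COLORS, True),
        ("glume_color", GLUME_COLORS, True),
        ("awns", AWN_STATES, False),
        ("threshability", THRESHABILITY, False),
    ]
    for col, allowed, nullable in checks:
        values = df[col]
        bad = set(values.dropna()) - allowed
        if bad or (not nullable and values.isna().any()):
            raise CorruptedFixtureError(f"invalid {col} labels: {sorted(map(str, bad))}")
    if not df["gi"].between(0, 1).all() or not df["ss"].dropna().between(0, 1).all():
        raise CorruptedFixtureError("phenotype values outside [0, 1]")
    if df["entry_id"].duplicated().any():
        raise CorruptedFixtureError("duplicate entry identifiers")
    if not as_records:
        return df
    return [
        Entry(
            entry_id=r.entry_id,
            thvp1=r.thvp1,
            tavp1b=r.tavp1b,
            gi=float(r.gi),
            ss=None if pd.isna(r.ss) else float(r.ss),
            grain_color=None if pd.isna(r.grain_color) else r.grain_color,
            glume_color=None if pd.isna(r.glume_color) else r.glume_color,
            awns=r.awns,
            threshability=r.threshability,
        )
        for r in df.itertuples(index=False)
    ]


def _parse_sizes(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return ()
    return tuple(float(tok) for tok in str(cell).split(";") if tok.strip())


def read_table(path, schema: dict[str, str], sep: str | None = None) -> pd.DataFrame:
    """Read a delimited table and validate it against a column schema.

    The delimiter is sniffed (comma or tab) unless given.  Decimal commas
    in numeric columns are normalized to decimal points with a warning.
    Missing values come back as NaN (numeric) or empty tuples (size
    lists), never as zeros.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        series = df[col]
        if kind == "str":
            out[col] = series.astype(str)
            continue
        if kind == "sizes":
            out[col] = series.map(_parse_sizes)
            continue
        if series.str.contains(",", na=False).any():
            warnings.warn(
                f"{path}: decimal commas in column {col!r} normalized to points",
                stacklevel=2,
            )
            series = series.str.replace(",", ".", regex=False)
        try:
            numeric = pd.to_numeric(series)
        except (ValueError, TypeError) as exc:
            bad = series[pd.to_numeric(series, errors="coerce").isna() & series.notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {row}"
            ) from exc
        if kind == "int":
            if numeric.isna().any():
                raise ValueError(f"{path}: missing value in integer column {col!r}")
            out[col] = numeric.astype(int)
        else:
            out[col] = numeric.astype(float)
    return out


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a table as delimited text; missing values become empty fields."""
    df = df.copy()
    for col in df.columns:
        if df[col].map(lambda v: isinstance(v, tuple)).any():
            df[col] = df[col].map(lambda t: ";".join(f"{s:g}" for s in t))
    df.to_csv(path, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# end-to-end regeneration of the published summary tables from the fixture

#: published values the end-to-end run checks itself against:
#: (name, expected, absolute tolerance)
REPRODUCTION_TARGETS = [
    ("gi_anova_f", 4.635, 0.05),
    ("gi_mean_ThVp-1a", 0.78, 0.01),
    ("gi_mean_ThVp-1b", 0.74, 0.01),
    ("gi_mean_ThVp-1c", 0.82, 0.01),
    ("gi_mean_ThVp-1d", 0.64, 0.01),
    ("ss_anova_f", 2.13, 0.05),
    ("ss_back_mean_ThVp-1d", 0.29, 0.01),
    ("gi_allele_anova_f", 0.003, 0.02),
    ("ss_allele_anova_f", 0.21376, 0.05),
    ("haplotype_pct_ThVp-1a", 41, 0),
    ("haplotype_pct_ThVp-1b", 13, 0),
    ("haplotype_pct_ThVp-1c", 29, 0),
    ("haplotype_pct_ThVp-1d", 15, 0),
    ("allele_pct_Vp-1Ba", 51, 0),
    ("allele_pct_Vp-1Bc", 31, 0),
    ("ss_cluster1_n", 11, 0),
    ("gi_clusters_5_to_8_pct", 92, 0),
]


def reproduce(outdir) -> list[str]:
    """Regenerate every summary analysis from the packaged fixture.

    Writes cluster tables, the haplotype and wheat-allele distributions
    and the four association reports to ``outdir``, recomputes the
    published headline numbers and returns the names of any that fall
    outside their tolerance (empty list = full agreement).

    Note: the spike-sprouting x wheat-allele F statistic is a known,
    documented failure — it is not recoverable from the 2-decimal
    phenotype values the collection table reports (see docs/methods.md).
    """
    from pathlib import Path

    from .association import associate
    from .binning import SturgesBinner
    from .haplotyping import (
        HaplotypeCaller,
        haplotype_distribution,
        wheat_allele_distribution,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = load_fixture()
    computed: dict[str, float] = {}

    # resistance clustering
    for metric in ("ss", "gi"):
        values = df[["entry_id", metric]].dropna()
        binner = SturgesBinner().fit(values[metric])
        clusters = binner.transform(values[metric])
        table = pd.DataFrame(
            {
                "entry_id": values["entry_id"].to_numpy(),
                metric: values[metric].to_numpy(),
                "cluster": clusters,
                "lo": [binner.bin_ranges_[c - 1][0] for c in clusters],
                "hi": [binner.bin_ranges_[c - 1][1] for c in clusters],
            }
        )
        write_table(table, outdir / f"clusters_{metric}.tsv")
        if metric == "ss":
            computed["ss_cluster1_n"] = int((clusters == 1).sum())
        else:
            computed["gi_clusters_5_to_8_pct"] = round(
                100.0 * (clusters >= 5).sum() / len(clusters)
            )

    # marker-based composition (band states reconstructed from the haplotype
    # labels; heterogeneous entries as two discordant plants)
    from .haplotyping import bands_from_labels

    bands = bands_from_labels(df[["entry_id", "thvp1"]])
    calls = HaplotypeCaller().fit().predict(bands)
    hap_dist = haplotype_distribution(calls)
    write_table(hap_dist, outdir / "haplotype_distribution.tsv")
    for _, row in hap_dist.iterrows():
        if row["haplotype"] in _THVP1_LABELS:
            computed[f"haplotype_pct_{row['haplotype']}"] = row["percent"]
    allele_dist = wheat_allele_distribution(df["tavp1b"])
    write_table(allele_dist, outdir / "wheat_allele_distribution.tsv")
    for _, row in allele_dist.iterrows():
        computed[f"allele_pct_{row['allele']}"] = row["percent"]

    # association reports
    reports = {
        "gi_by_haplotype": associate(df["gi"], df["thvp1"], "gi"),
        "ss_by_haplotype": associate(df["ss"], df["thvp1"], "ss", transform="arcsin_sqrt"),
        "gi_by_allele": associate(df["gi"], df["tavp1b"], "gi"),
        "ss_by_allele": associate(df["ss"], df["tavp1b"], "ss", transform="arcsin_sqrt"),
    }
    for name, report in reports.items():
        frame = report.to_frame()
        write_table(frame, outdir / f"association_{name}.tsv")
        with open(outdir / f"association_{name}.txt", "w") as fh:
            fh.write(frame.to_string(index=False))
            fh.write(
                f"\n\nF_observed = {report.anova.f_observed:.4f}, "
                f"F_critical = {report.anova.f_critical:.4f}, "
                f"p = {report.anova.p_value:.4f}, n = {report.n_used}\n"
            )
            for note in report.notes:
                fh.write(f"note: {note}\n")
    computed["gi_anova_f"] = reports["gi_by_haplotype"].anova.f_observed
    for s in reports["gi_by_haplotype"].summaries:
        computed[f"gi_mean_{s.group}"] = s.mean
    computed["ss_anova_f"] = reports["ss_by_haplotype"].anova.f_observed
    for s in reports["ss_by_haplotype"].summaries:
        if s.group == "ThVp-1d":
            computed["ss_back_mean_ThVp-1d"] = s.mean_back_transformed
    computed["gi_allele_anova_f"] = reports["gi_by_allele"].anova.f_observed
    computed["ss_allele_anova_f"] = reports["ss_by_allele"].anova.f_observed

    failures = []
    lines = []
    for name, expected, tol in REPRODUCTION_TARGETS:
        value = computed.get(name)
        ok = value is not None and abs(value - expected) <= tol + 1e-9
        lines.append(
            f"{'PASS' if ok else 'FAIL'}  {name}: computed={value!r} "
            f"expected={expected} tol={tol}"
        )
        if not ok:
            failures.append(name)
    (outdir / "reproduction_report.txt").write_text("\n".join(lines) + "\n")
    for line in lines:
        log.info(line)
    return failures
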