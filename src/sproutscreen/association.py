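"""Haplotype-phenotype association: one-way ANOVA with Fisher's LSD.

Proportion phenotypes (spike sprouting) are variance-stabilized with the
arcsine square-root transform before the ANOVA; group means are reported
both on the transformed scale and back-transformed (sin^2).  Pairwise
differences are tested with Fisher's protected least significant
difference using the pooled within-group mean square, and summarized as a
compact letter display (groups sharing a letter do not differ at alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "LsdResult",
    "AssociationReport",
    "arcsin_sqrt",
    "reverse_transform",
    "group_summaries",
    "one_way_anova",
    "f_critical",
    "lsd_test",
    "compact_letter_display",
    "associate",
]


def arcsin_sqrt(x):
    """Variance-stabilizing arcsin(sqrt(x)) transform for proportions.

    Maps [0, 1] monotonically onto [0, pi/2] radians.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("arcsin_sqrt requires values in [0, 1]")
    out = np.arcsin(np.sqrt(x))
    return float(out) if out.ndim == 0 else out


def reverse_transform(m):
    """Back-transform sin(m)^2, the exact inverse of arcsin_sqrt on [0, pi/2]."""
    m = np.asarray(m, dtype=float)
    if np.any((m < 0) | (m > np.pi / 2 + 1e-12)):
        raise ValueError("reverse_transform requires values in [0, pi/2]")
    out = np.sin(m) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float  # sample SD, n-1 denominator
    min: float
    max: float
    # populated when the analysis ran on transformed values
    mean_back_transformed: float | None = None
    raw_min: float | None = None
    raw_max: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    f_observed: float
    df_between: int
    df_within: int
    p_value: float
    f_critical: float
    ms_within: float
    ms_between: float
    alpha: float
    infinite_f: bool = False  # MS_within == 0 with group differences


@dataclass(frozen=True)
class LsdResult:
    """Pairwise Fisher-LSD decisions and the equivalent letter display."""

    groups: tuple[str, ...]
    significant: pd.DataFrame  # boolean, groups x groups
    letters: dict[str, str]
    lsd_thresholds: pd.DataFrame


@dataclass(frozen=True)
class AssociationReport:
    phenotype: str
    factor: str
    transform: str  # "none" | "arcsin_sqrt"
    alpha: float
    summaries: tuple[GroupSummary, ...]
    anova: AnovaResult
    lsd: LsdResult
    n_used: int
    n_excluded_missing: int
    n_excluded_factor: int
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout of the per-group summary with LSD letters."""
        rows = []
        for s in self.summaries:
            row = {
                "group": s.group,
                "n": s.n,
                "mean": round(s.mean, 2),
                "letters": self.lsd.letters.get(s.group, ""),
                "sd": round(s.sd, 2),
            }
            if self.transform == "arcsin_sqrt":
                row["mean_back_transformed"] = round(s.mean_back_transformed, 2)
                row["range_raw"] = f"{s.raw_min:.2f}-{s.raw_max:.2f}"
            else:
                row["range"] = f"{s.min:.2f}-{s.max:.2f}"
            rows.append(row)
        return pd.DataFrame(rows)


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    return {g: values[groups == g] for g in sorted(map(str, np.unique(groups)))}


def group_summaries(values, groups) -> list[GroupSummary]:
    """Per-group n, mean, sample SD and range."""
    out = []
    for g, v in _group_arrays(values, groups).items():
        out.append(
            GroupSummary(
                group=g,
                n=v.size,
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                min=float(v.min()),
                max=float(v.max()),
            )
        )
    return out


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-alpha quantile of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def one_way_anova(values, groups, alpha: float = 0.05) -> AnovaResult:
    """Fixed-effects one-way ANOVA between/within decomposition.

    Computed directly (rather than via ``scipy.stats.f_oneway``) because
    the LSD stage needs the within-group mean square and its degrees of
    freedom; the F and p agree with scipy on the same data.
    """
    by_group = _group_arrays(values, groups)
    k = len(by_group)
    n_total = sum(v.size for v in by_group.values())
    if k < 2:
        raise ValueError("one-way ANOVA requires at least two groups")
    if n_total <= k:
        raise ValueError("ANOVA requires more observations than groups")
    grand = np.concatenate(list(by_group.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in by_group.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        infinite = ms_between > 0
        return AnovaResult(
            f_observed=float("inf") if infinite else 0.0,
            df_between=df_between,
            df_within=df_within,
            p_value=0.0 if infinite else 1.0,
            f_critical=f_critical(alpha, df_between, df_within),
            ms_within=0.0,
            ms_between=float(ms_between),
            alpha=alpha,
            infinite_f=infinite,
        )
    f_obs = ms_between / ms_within
    return AnovaResult(
        f_observed=float(f_obs),
        df_between=df_between,
        df_within=df_within,
        p_value=float(stats.f.sf(f_obs, df_between, df_within)),
        f_critical=f_critical(alpha, df_between, df_within),
        ms_within=float(ms_within),
        ms_between=float(ms_between),
        alpha=alpha,
    )


def compact_letter_display(
    groups: list[str], significant: pd.DataFrame, means: dict[str, float]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from a single letter shared by all groups; every significant
    pair splits each letter set containing both; letter sets that become
    subsets of another are absorbed.  Letters are ordered so that 'a'
    attaches to the lowest-mean groups.  The result encodes the pairwise
    matrix exactly: two groups share a letter iff not significantly
    different.
    """
    columns: list[set[str]] = [set(groups)]
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            if not significant.loc[gi, gj]:
                continue
            for col in [c for c in columns if gi in c and gj in c]:
                columns.remove(col)
                columns.extend([col - {gi}, col - {gj}])
            # absorb: drop any set contained in another
            columns = [
                c
                for c in columns
                if c and not any(c < other for other in columns if other is not c)
            ]
            # drop duplicates
            unique: list[set[str]] = []
            for c in columns:
                if c not in unique:
                    unique.append(c)
            columns = unique
    columns.sort(key=lambda c: min(means[g] for g in c))
    letters = {g: "" for g in groups}
    for idx, col in enumerate(columns):
        letter = chr(ord("a") + idx)
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def lsd_test(values, groups, anova: AnovaResult, alpha: float = 0.05) -> LsdResult:
    """Fisher's least significant difference over all group pairs.

    A pair differs when |mean_i - mean_j| exceeds
    t_{1-alpha/2, df_within} * sqrt(MS_within * (1/n_i + 1/n_j)).
    The design is protected in the classical sense (run after the omnibus
    ANOVA) but the decisions are reported regardless of the omnibus
    outcome, with the caller deciding how to interpret that situation.
    """
    by_group = _group_arrays(values, groups)
    names = list(by_group)
    if len(names) < 2:
        return LsdResult(
            tuple(names),
            pd.DataFrame(False, index=names, columns=names),
            {n: "a" for n in names},
            pd.DataFrame(np.nan, index=names, columns=names),
        )
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, anova.df_within)
    sig = pd.DataFrame(False, index=names, columns=names)
    thresholds = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = by_group[a], by_group[b]
            lsd = t_crit * np.sqrt(anova.ms_within * (1 / va.size + 1 / vb.size))
            diff = abs(va.mean() - vb.mean())
            decision = bool(diff > lsd) if anova.ms_within > 0 else bool(diff > 0)
            sig.loc[a, b] = sig.loc[b, a] = decision
            thresholds.loc[a, b] = thresholds.loc[b, a] = lsd
    means = {g: float(v.mean()) for g, v in by_group.items()}
    letters = compact_letter_display(names, sig, means)
    return LsdResult(tuple(names), sig, letters, thresholds)


EXCLUDED_FACTOR_LEVELS = ("hg", "hz")


def associate(
    phenotypes: pd.Series,
    factor: pd.Series,
    phenotype_name: str = "phenotype",
    transform: str = "none",
    alpha: float = 0.05,
    exclude_levels: tuple[str, ...] = EXCLUDED_FACTOR_LEVELS,
) -> AssociationReport:
    """Full association report of a phenotype against a categorical factor.

    Entries with a missing phenotype, or with a factor level in
    ``exclude_levels`` (heterogeneous ``hg`` / heterozygous ``hz`` calls),
    are dropped and counted.  With ``transform="arcsin_sqrt"`` each
    observation is transformed before the ANOVA and the group means are
    additionally reported back-transformed; ranges stay on the raw scale.
    """
    if transform not in ("none", "arcsin_sqrt"):
        raise ValueError(f"unknown transform {transform!r}")
    df = pd.DataFrame({"y": phenotypes, "g": factor.astype(str)})
    n_excluded_factor = int(df["g"].isin(exclude_levels).sum())
    df = df[~df["g"].isin(exclude_levels)]
    n_excluded_missing = int(df["y"].isna().sum())
    df = df.dropna(subset=["y"])
    if df["g"].nunique() < 2:
        raise ValueError("fewer than two usable factor levels after exclusions")

    raw = df["y"].to_numpy(dtype=float)
    y = arcsin_sqrt(raw) if transform == "arcsin_sqrt" else raw
    g = df["g"].to_numpy()

    anova = one_way_anova(y, g, alpha=alpha)
    lsd = lsd_test(y, g, anova, alpha=alpha)
    summaries = []
    for s in group_summaries(y, g):
        mask = g == s.group
        if transform == "arcsin_sqrt":
            s = GroupSummary(
                group=s.group,
                n=s.n,
                mean=s.mean,
                sd=s.sd,
                min=s.min,
                max=s.max,
                mean_back_transformed=reverse_transform(s.mean),
                raw_min=float(raw[mask].min()),
                raw_max=float(raw[mask].max()),
            )
        summaries.append(s)

    notes = []
    if anova.f_observed <= anova.f_critical and lsd.significant.to_numpy().any():
        notes.append(
            "omnibus F is non-significant but LSD flags pairwise differences; "
            "interpret the pairwise letters with caution"
        )
    return AssociationReport(
        phenotype=phenotype_name,
        factor=str(factor.name or "factor"),
        transform=transform,
        alpha=alpha,
        summaries=tuple(summaries),
        anova=anova,
        lsd=lsd,
        n_used=len(df),
        n_excluded_missing=n_excluded_missing,
        n_excluded_factor=n_excluded_factor,
        notes=tuple(notes),
    )
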