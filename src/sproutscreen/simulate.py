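"""Synthetic germplasm collections with haplotype-dependent dormancy.

The generator emulates the three raw inputs of the screening pipeline —
daily germination counts, spike sprouting counts, and marker band
observations — from a latent per-entry dormancy score, so that the full
pipeline (phenotyping, haplotype calling, association) can be exercised
and its operating characteristics (type-I error, power, recovery bias)
measured without any real plant material.

Model
-----
Per entry: a ThVp-1 haplotype is drawn from the collection frequencies; a
latent germination index GI* is drawn from a normal with the haplotype's
mean, truncated to the attainable range [1/7, 1].  The 7-day germination
schedule is ``day = 1 + Binomial(6, q)`` with ``q`` chosen in closed form
so that the expected day-weighted index equals GI*; replicate counts are
multinomial over the seven days plus a never-germinating (nonviable)
class.  Spike sprouting is binomial with success probability linked to
GI* on the logit scale (dormant entries sprout less in the spike too).
Marker bands are the haplotype's reference fragment sizes plus Gaussian
size-reading noise.

Everything is driven by one ``numpy.random.default_rng`` (PCG64) seed;
identical parameters and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .haplotyping import BANDS_FOR_HAPLOTYPE, CAPS_MARKER, STS_MARKER, HAPLOTYPES
from .phenotyping import N_DAYS

__all__ = [
    "SimulationParams",
    "SimulatedCollection",
    "day_distribution_for_gi",
    "simulate_collection",
    "power_study",
]

GI_FLOOR = 1.0 / N_DAYS  # lowest index attainable within the 7-day window


@dataclass(frozen=True)
class SimulationParams:
    """Study-design and effect-size parameters of the generator.

    Defaults mirror the 87-entry hybrid collection: haplotype frequencies
    0.41/0.13/0.29/0.15 (normalized to sum 1), per-haplotype mean GI
    0.78/0.74/0.82/0.64, 25 seeds x 4 replicates per entry, and a spike
    set of ~150 grains.
    """

    n_entries: int = 87
    haplotype_freqs: tuple[float, float, float, float] = (0.41, 0.13, 0.29, 0.15)
    gi_means: tuple[float, float, float, float] = (0.78, 0.74, 0.82, 0.64)
    gi_sd: float = 0.15
    ss_link: tuple[float, float] = (5.0, -4.1)  # (slope, intercept) on logit scale
    n_replicates: int = 4
    seeds_per_replicate: int = 25
    grains_per_spike_set: int = 150
    nonviable_rate: float = 0.05
    band_noise_sd: float = 5.0
    n_plants: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.haplotype_freqs, dtype=float)
        if freqs.size != len(HAPLOTYPES) or (freqs < 0).any():
            raise ValueError("haplotype_freqs must be 4 non-negative numbers")
        total = freqs.sum()
        if not np.isclose(total, 1.0, atol=0.05):
            raise ValueError("haplotype_freqs must sum to ~1")
        object.__setattr__(self, "haplotype_freqs", tuple(freqs / total))
        if not 0.0 <= self.nonviable_rate < 1.0:
            raise ValueError("nonviable_rate must be in [0, 1)")
        for m in self.gi_means:
            if not 0.0 < m <= 1.0:
                raise ValueError("gi_means must lie in (0, 1]")
        if self.n_entries < 1 or self.n_replicates < 1 or self.seeds_per_replicate < 1:
            raise ValueError("design sizes must be positive")


@dataclass(frozen=True)
class SimulatedCollection:
    """Bundle of generated input tables plus the generating truth."""

    germination: pd.DataFrame  # entry_id, replicate, day, n_germinated, seeds_placed, n_nonviable
    spikes: pd.DataFrame  # entry_id, n_sprouted, n_total_grains
    bands: pd.DataFrame  # entry_id, plant_id, marker, fragment_sizes
    truth: pd.DataFrame  # entry_id, haplotype, gi_latent, ss_prob
    params: SimulationParams = field(repr=False, default=None)


def day_distribution_for_gi(target_gi: float) -> np.ndarray:
    """Germination-day probabilities whose expected index equals target_gi.

    Uses the one-parameter family ``day = 1 + Binomial(6, q)``.  The
    day-weighted index is linear in the mean day, E[GI] = (8 - E[day])/7,
    so ``q = 7 (1 - target) / 6`` hits the target exactly.  The family is
    unimodal and its peak day moves later, one day at a time, as the
    target decreases — fast-germinating entries peak on day 1-2, dormant
    ones late in the week.
    """
    if not GI_FLOOR - 1e-12 <= target_gi <= 1.0 + 1e-12:
        raise ValueError(
            f"target GI {target_gi} outside the attainable range "
            f"[{GI_FLOOR:.4f}, 1]"
        )
    q = np.clip(7.0 * (1.0 - target_gi) / 6.0, 0.0, 1.0)
    p = stats.binom.pmf(np.arange(N_DAYS), N_DAYS - 1, q)
    return p / p.sum()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_collection(params: SimulationParams) -> SimulatedCollection:
    """Generate one synthetic collection, reproducible from ``rng_seed``."""
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_entries
    hap_idx = rng.choice(len(HAPLOTYPES), size=n, p=params.haplotype_freqs)
    means = np.asarray(params.gi_means)[hap_idx]

    if params.gi_sd > 0:
        a = (GI_FLOOR - means) / params.gi_sd
        b = (1.0 - means) / params.gi_sd
        gi_latent = stats.truncnorm.rvs(
            a, b, loc=means, scale=params.gi_sd, random_state=rng
        )
    else:
        gi_latent = np.clip(means, GI_FLOOR, 1.0)

    slope, intercept = params.ss_link
    ss_prob = _sigmoid(intercept + slope * gi_latent)

    entry_ids = [f"sim-{i + 1:04d}" for i in range(n)]
    germ_rows, spike_rows, band_rows, truth_rows = [], [], [], []
    for i, entry_id in enumerate(entry_ids):
        day_p = day_distribution_for_gi(gi_latent[i])
        cell_p = np.append(day_p * (1.0 - params.nonviable_rate), params.nonviable_rate)
        for rep in range(1, params.n_replicates + 1):
            counts = rng.multinomial(params.seeds_per_replicate, cell_p)
            for day in range(1, N_DAYS + 1):
                germ_rows.append(
                    {
                        "entry_id": entry_id,
                        "replicate": rep,
                        "day": day,
                        "n_germinated": int(counts[day - 1]),
                        "seeds_placed": params.seeds_per_replicate,
                        "n_nonviable": int(counts[-1]),
                    }
                )
        n_sprouted = int(rng.binomial(params.grains_per_spike_set, ss_prob[i]))
        spike_rows.append(
            {
                "entry_id": entry_id,
                "n_sprouted": n_sprouted,
                "n_total_grains": params.grains_per_spike_set,
            }
        )
        haplotype = HAPLOTYPES[hap_idx[i]]
        for plant in range(1, params.n_plants + 1):
            for marker in (CAPS_MARKER, STS_MARKER):
                refs = BANDS_FOR_HAPLOTYPE[haplotype][marker]
                sizes = tuple(
                    float(np.round(s + rng.normal(0.0, params.band_noise_sd), 1))
                    for s in refs
                )
                band_rows.append(
                    {
                        "entry_id": entry_id,
                        "plant_id": f"p{plant}",
                        "marker": marker,
                        "fragment_sizes": sizes,
                    }
                )
        truth_rows.append(
            {
                "entry_id": entry_id,
                "haplotype": haplotype,
                "gi_latent": float(gi_latent[i]),
                "ss_prob": float(ss_prob[i]),
            }
        )

    return SimulatedCollection(
        germination=pd.DataFrame(germ_rows),
        spikes=pd.DataFrame(spike_rows),
        bands=pd.DataFrame(band_rows),
        truth=pd.DataFrame(truth_rows),
        params=params,
    )


def power_study(
    params: SimulationParams,
    effect_grid,
    n_reps: int = 100,
    alpha: float = 0.05,
    baseline_gi: float = 0.78,
) -> pd.DataFrame:
    """ANOVA rejection rate as a function of the ThVp-1d dormancy effect.

    For each effect size e the three common haplotypes share
    ``baseline_gi`` while the ThVp-1d mean is lowered by e; ``n_reps``
    collections are simulated, the per-entry GI recomputed from the
    generated counts, and the fraction of collections with omnibus
    p < alpha reported.  Effect 0 estimates the type-I error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    from .phenotyping import phenotype_table

    rows = []
    seed_stream = np.random.SeedSequence(params.rng_seed)
    for effect in effect_grid:
        means = (baseline_gi, baseline_gi, baseline_gi, baseline_gi - effect)
        rejections = 0
        child_seeds = seed_stream.spawn(n_reps)
        for rep_seed in child_seeds:
            seed = int(rep_seed.generate_state(1)[0] % (2**31))
            p = replace(params, gi_means=means, rng_seed=seed)
            coll = simulate_collection(p)
            pheno = phenotype_table(coll.germination)
            merged = pheno.merge(coll.truth[["entry_id", "haplotype"]], on="entry_id")
            if merged["haplotype"].nunique() < 2:
                continue
            from .association import one_way_anova

            res = one_way_anova(merged["gi"], merged["haplotype"], alpha=alpha)
            if res.p_value < alpha:
                rejections += 1
        rows.append(
            {"effect": float(effect), "n_reps": n_reps, "power": rejections / n_reps}
        )
    return pd.DataFrame(rows)
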