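# Methods

## Phenotype definitions

The germination index is the day-weighted score
GI = Σ_{d=1..7} (8−d)·n_d / (7·TG), with n_d the seeds newly germinated
on day d and TG the viable total. Three decisions close gaps the assay
description leaves open:

* **Viability filter.** TG = seeds placed − seeds that never germinate
  within the 30-day window. Seeds germinating on days 8–30 are viable:
  they stay in TG but contribute nothing to the numerator (the weights
  stop at day 7). Only the never-germinating class is excluded.
* **Replicate aggregation.** The default pools daily counts and viable
  totals across replicates and applies the index once (ratio of sums).
  This weights replicates by their viable totals and is well-defined
  even when a replicate loses most seeds to the viability filter. The
  alternative mean-of-ratios is exposed (`entry_gi(..., method="mean")`);
  for the balanced four-replicate design the two differ negligibly.
* **Missing spike assays** are explicit missing values end to end
  (empty fields in tables, NaN in frames), never zeros — 13 of the 87
  packaged entries lack SS.

GI and SS are reported to 2 decimals in output tables mirroring the
published collection table; all internal computation is full precision.

## Sturges clustering

k = ⌈1 + log₂ n⌉ (8 for both n = 74 and n = 87). Because phenotypes are
reported on a 0.01 grid, bins are closed grid ranges: the span from min
to max covers `n_cells` grid points, each bin spans ⌈n_cells/k⌉ points,
consecutive bins abut (printed as 0.01–0.12, 0.13–0.24, …), and the last
bin absorbs any remainder. Ties at edges are impossible by construction.
The published SS table follows exactly this rule; the published GI table
has irregular widths (alternating 10/11 cells) that no single rule
generates, so the uniform rule is used there too — the cluster
memberships this package reports for GI differ from the printed ones
only for values adjacent to those irregular edges, and none of the
summary statistics depend on them.

The 2×2 low/high GI × SS cross-classification requires explicit
thresholds ("low" = value ≤ threshold). On the packaged collection the
low-GI/high-SS quadrant — dormant seeds that nevertheless sprout in the
spike — is empty for any GI threshold ≤ 0.46 once "high SS" means
above the resistant spike-sprouting range (threshold ≥ 0.20, the
maximum SS among low-GI entries).

## Haplotype calling

Band states are called per marker by nearest-reference matching within
±`tolerance_bp` (default 15 bp). The default is the largest window that
cannot double-assign the 350/370 bp STS pair; it is a matching window,
not a guarantee band: exact recovery of a known haplotype is guaranteed
only while size error stays below half the smallest reference spacing
(10 bp), because larger errors land nearer the other reference. Band
intensity is ignored; presence is binary per reference size.

Only the four observed joint states are callable. Unobserved
combinations (e.g. ~600 bp with ~350 bp) may be real alleles or
artifacts — undecidable from two presence/absence markers — so they are
flagged `inconsistent`, never called. Per-plant calls are combined by
unanimity; any disagreement flags the entry `heterogeneous`. Both flags
exclude an entry from association analysis. A linkage validation report
lists entries violating the f550↔f370 co-occurrence.

Wheat *TaVp-1B* genotypes are accepted as categorical labels
(`Vp-1Ba`, `Vp-1Bc`, `hz`, `hg`) rather than called from fragment
sizes; heterozygous and heterogeneous labels are likewise excluded from
association.

## Association analysis

Fixed-effects one-way ANOVA with the standard between/within
decomposition; F compared to the upper-α F quantile and p from the
survival function. The decomposition is computed directly because
Fisher's LSD needs MS_within and its degrees of freedom; agreement with
`scipy.stats.f_oneway` is enforced by a test. Group SDs use the n−1
denominator. Spike-sprouting proportions are transformed arcsin√x per
observation (not per group mean) before the ANOVA; group means are
additionally reported back-transformed (sin²m), which is the exact
inverse. Note the back-transformed mean of transformed values is not
the arithmetic mean of the raw proportions (0.29 vs 0.33 for the
dormant haplotype group in the packaged collection); both are available
and labelled distinctly.

Fisher's LSD declares groups i, j different when
|ȳ_i − ȳ_j| > t_{1−α/2, df_within}·√(MS_within·(1/n_i + 1/n_j)),
all two-sided at α = 0.05, with no further multiplicity correction
beyond the protected (ANOVA-first) design. The report attaches a note
when the omnibus F is non-significant while LSD pairs are — the
situation in the spike-sprouting × haplotype analysis, where the letter
display is suggestive rather than confirmatory. Letters come from the
insert-and-absorb algorithm (start with one letter set holding all
groups; each significant pair splits every set containing both; absorb
subset sets), ordered so `a` attaches to the lowest-mean groups; a test
verifies the display reconstructs the pairwise matrix exactly.

## Synthetic collections

The generator draws, per entry: a haplotype from the collection
frequencies (default 0.41/0.13/0.29/0.15, normalized); a latent index
GI\* ~ Normal(μ_h, σ) truncated to the attainable [1/7, 1], with
defaults μ = 0.78/0.74/0.82/0.64 and σ = 0.15 — the between-entry
spread of the real collection; a germination-day distribution
day = 1 + Binomial(6, q). Because the index is linear in the mean day,
E[GI] = (8 − E[day])/7, setting q = 7(1 − GI\*)/6 meets the target
exactly; the family is unimodal and its peak slides smoothly from day 1
(GI\* → 1) to day 7 (GI\* → 1/7), matching the observed dynamics where
resistant entries peak late and faintly. Replicate counts are
multinomial over the seven days plus a never-germinating class
(default rate 0.05 — the assay description reports no rate; this is a
modelling choice). Spike sprouting is Binomial(grains, p) with
logit p = −4.1 + 5.0·GI\*, chosen so the default group means map to
spike-sprouting means near the observed ones (GI 0.78 → SS ≈ 0.45,
GI 0.64 → SS ≈ 0.29); linking SS to the same latent dormancy reflects
the concordant haplotype effects seen in both assays. Marker bands are
the haplotype's reference sizes plus Gaussian noise (default σ = 5 bp).

All randomness flows from one `numpy.random.default_rng` (PCG64) seed;
the generator algorithm is part of the public contract, so identical
parameters and seed give byte-identical outputs across runs and
platforms.

What the generator does *not* emulate: within-entry genetic
substructure (each entry is one latent dormancy value), environmental
or harvest-date effects, overdispersion beyond multinomial/binomial
sampling, spike-architecture variation independent of dormancy, and
gel artifacts other than additive size noise. Pipeline tests passing on
synthetic data therefore demonstrate internal consistency and
statistical calibration, not field validity.

Power and calibration studies rerun the full pipeline (counts →
pooled GI → ANOVA) on each simulated collection. Defaults use
87-entry collections; the packaged calibration check uses 500 null
collections (type-I error within ±3 binomial SE of 0.05) and 100
collections per effect size for the power curve — sizes chosen to keep
Monte-Carlo error below the assertion margins.

## Known limitations

* The published spike-sprouting × wheat-allele F statistic (0.21376)
  cannot be recovered from the collection table: the phenotypes there
  are rounded to 2 decimals, and the rounded values yield F = 0.024
  with group means differing by 0.01. All other published headline
  numbers — both haplotype ANOVAs, every group mean/SD/range, both
  critical values, cluster counts and composition percentages — are
  recovered within printing precision. The corresponding check is left
  failing (in `tests/test_acceptance.py` and the `reproduce` report)
  rather than loosened, since it documents a genuine limit of the
  published inputs. The same table also prints F_critical = 1.74 where
  the α = 0.05 quantile at (1, 61) df is ≈ 4.00; the package reports
  the correct quantile.
* The packaged qualitative 2×2 classification of joint GI/SS resistance
  is threshold-based; the published grouping it emulates is not
  reproducible by any single pair of thresholds and is not treated as a
  target.
* ANOVA assumes homoscedastic normal errors; with 2-decimal proportions
  and group sizes down to 11 this is an approximation, mitigated but
  not removed by the arcsin√ transform.
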