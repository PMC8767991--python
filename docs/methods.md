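# Methods

## Data model

A dataset is a table of visits, one row per visit: unique `visit_id`,
`patient_id`, ISO date, modality (`face_to_face` / `telemedicine`),
specialty (`general_medicine` / `nursing` / `pediatrics` / `other`), sex,
integer age, and a `;`-joined list of ICD-10 codes (possibly empty).
Diagnostic coding is optional in primary-care records, so the first
analysis step restricts to *coded* visits (≥ 1 code); the fraction of
uncoded visits is reported per date partition rather than silently
dropped.

## ICD-10 aggregation

Codes are normalized (uppercased, dots and whitespace removed) and
truncated to the 3-character category stem; suffixed codes such as
`E11.9` are rolled into their category `E11` at the finest level. Three
aggregation levels are supported: chapter (level 1), block (level 2), and
category (level 3). The embedded chapter/block tables follow the
ICD-10-CM arrangement (`C00-D49` and `D50-D89` as separate chapters) and
include the special-purpose chapter `U00-U85` (toggleable), since
pandemic-era data use `U07` for COVID-19.

Category ordering is positional: the leading letter compares
lexicographically, each remaining character compares with digits before
letters, so `O9A` falls inside `O00-O9A`. Chapter ranges must be pairwise
disjoint and each block must nest inside exactly one chapter; the loader
validates user-supplied override tables against the same invariants. The
official CM listing prints three letter-suffixed singleton blocks (`C7A`,
`C7B`, `D3A`) whose ranges interleave with digit blocks; the embedded
table splits the neighbouring ranges (e.g. `C76-C80` into `C76-C79`,
`C7A`, `C7B`, `C80`) so disjointness holds without changing any category's
chapter. Categories outside every range map to an explicit `UNMAPPED`
bucket that participates in all totals, so counts are conserved across
levels by construction.

## Frequency matrices and variation statistics

The term-frequency matrix counts code *occurrences* by (partition,
group): a visit with k codes contributes k occurrences, and duplicate
identical codes on one visit count separately by default (a
`dedupe_per_visit` toggle exists). Date partitions are user-specified,
closed-open, pairwise-disjoint intervals; the calendar years 2019/2020
are the shipped default. Visits dated outside all partitions are excluded
and counted in the matrix's `n_outside` field. Optional strata (modality,
specialty, age group, sex) restrict the visits before counting; stratum
matrices therefore sum cellwise to the unstratified matrix.

From a two-partition matrix the variation table reports, per group: both
period counts and within-period shares, the pooled share, the interannual
variation `iav = 100·(n_late − n_early)/n_early`, and the variation index
`VI = |Δ| / Σ|Δ|`. Two conventions matter and are fixed here:

* **VI scope.** The denominator `Σ|Δ|` runs over exactly the groups of
  the matrix being reported, i.e. within the current level and stratum.
  Recomputing the published chapter table under this convention
  reproduces its printed index column (e.g. 0.127 → 0.13 for `I00-I99`).
* **Undefined values.** A zero baseline makes `iav` undefined; it is kept
  as NaN internally and rendered as `NA`, never as 0, and such rows still
  contribute their `Δ` to the VI denominator. When *all* deltas are zero
  the VI itself is undefined (NaN), never 0/0.

Both statistics are invariant under scaling all counts by a common
factor. Sorting is by pooled count or by index, descending, with ties
broken lexicographically by group label; rounding (2 decimals by default)
is purely a rendering concern — computation is full precision.

## Age groups

Six bins partition the non-negative integers: 0–5, 6–11, 12–18, 19–26,
27–59, ≥ 60. The published footnotes print overlapping adolescent/youth
bounds (12–18 vs 14–26) and leave age 60 ambiguous; the disjoint bins
above are used so that every age maps to exactly one group and shares sum
to 100%.

## Synthetic cohorts

The generator emulates the marginal structure of the reference two-year
cohort; all defaults are read from the packaged published tables:

| parameter | default (2019 / 2020) | source |
|---|---|---|
| visits per year | 1,421,779 / 1,402,406 | published totals |
| uncoded fraction | 0.1846 / 0.2250 | published missingness |
| codes per coded visit | mean 1.38, P(>3) = 0.035 | published moments |
| face-to-face share | 0.8530 / 0.4520 | published modality mix |
| specialty, sex, age mixes | published within-year shares | descriptor table |
| chapter vectors | published per-year chapter counts, normalized | chapter table |

Codes per coded visit follow a zero-inflated shifted geometric:
`N = 1 + G`, where `G = 0` with probability `w`, else a geometric failure
count with success probability `q`. Only the mean and the `P(N > 3)` tail
are published, and a plain shifted geometric cannot match both, so
`(w, q)` are solved from those two moments at configuration time
(`w ≈ 0.400`, `q ≈ 0.612`). Each code draws a chapter from the period's
chapter vector, then a concrete category uniformly within the chapter's
blocks (user-overridable vectors); block- and category-level structure in
generated data is therefore uniform-within-chapter, not realistic.
Patients are drawn uniformly from a finite pool (default 290,000, chosen
so that at full scale the expected distinct patients per year ≈ 288,000
as published); visit dates are uniform within each year.

What the generator deliberately does **not** model: disease co-occurrence
within a visit, per-patient visit overdispersion or longitudinal care
pathways, calendar seasonality, any correlation between codes and
modality/specialty/age/sex, and the `U00-U85` chapter (the published
chapter vectors carry no U mass). Passing pipeline tests on synthetic
cohorts therefore validates counting, aggregation and index algebra —
not clinical realism.

`expected_counts` gives the closed-form expectation
`E[n(c,t)] = n_visits(t) · (1 − missingness(t)) · E[codes per coded visit]
· p(c,t)` at any level, and serves as the oracle for parameter-recovery
tests: on a seeded ~100,000-visit cohort (~110,000 codes) the empirical
chapter shares sit within 3 binomial standard errors of the configured
vectors, and the empirical VI vector matches the expected-delta VI within
tolerances propagated from multinomial sampling noise.

## Numerical and reproducibility choices

* All randomness flows through one `numpy` `default_rng(seed)`; generation
  is byte-reproducible for a fixed seed, and the report pipeline writes a
  manifest (version, seed, config hash, row counts) alongside tables whose
  bytes depend only on the configuration.
* Table rendering uses fixed column order, stable mergesort for ties,
  fixed-precision floats, and the `NA` sentinel for undefined values.
* Test and example runs use scaled-down cohorts (0.035 % to 3.5 % of the
  full visit totals), chosen as the sizes at which the binomial error
  bounds above are already tight enough to be informative; the full-scale
  defaults remain available through `SyntheticConfig` unchanged.

## Known limitations

* The published reference tables are desk inputs, not raw data; stratified
  reference matrices contain only the five printed rows per stratum, so
  indices recomputed from them normalize over those five groups only. One
  printed telemedicine row (`A00-B99`, 2020) is internally inconsistent in
  the source and is shipped verbatim but excluded from golden checks.
* Block tables cover ICD-10-CM block gaps as `UNMAPPED` at level 2; WHO
  ICD-10 dialect layouts would need a user-supplied override table.
* No inferential statistics: the variation statistics are descriptive, and
  the package intentionally computes no confidence intervals or tests.
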