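"""Seeded synthetic primary-care visit cohorts.

The real visit registry behind the reference tables is not publicly
available, so this module generates visit-level datasets with the same
statistical structure: per-period visit totals, a fraction of visits
without any diagnosis, a calibrated codes-per-coded-visit law, per-period
modality / specialty / sex / age mixtures, and per-period chapter
probability vectors for the diagnosis codes. Every default is read from
the packaged reference tables (see :mod:`icdvar.reference`), so a large
generated cohort reproduces the published marginal structure up to
sampling noise.

Codes-per-coded-visit law
-------------------------
Only two moments of the count law are published: the mean (1.38 codes per
coded visit) and the tail P(more than 3 codes) = 0.035. A plain shifted
geometric cannot match both, so the generator uses a two-parameter
zero-inflated shifted geometric: N = 1 + G, where G = 0 with probability w
and otherwise G is a geometric failure count with success probability q.
(w, q) are solved from the two published moments at config-build time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import reference
from .frequency import FrequencyMatrix, PartitionSpec, StratumFilter
from .hierarchy import ICDHierarchy, load_hierarchy
from .visits import AGE_GROUPS, COLUMNS, MODALITIES, SEXES, SPECIALTIES

__all__ = [
    "PeriodConfig",
    "SyntheticConfig",
    "default_config",
    "generate",
    "expected_counts",
]


class ConfigError(ValueError):
    """Raised for invalid generator configurations before any generation."""


def _check_mixture(name: str, mix: dict[str, float]) -> None:
    probs = np.array(list(mix.values()), dtype=float)
    if (probs < 0).any() or (probs > 1).any():
        raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ConfigError(f"{name}: mixture sums to {probs.sum():.6f}, not 1")


@dataclass(frozen=True)
class PeriodConfig:
    """Generator parameters for one date partition.

    ``chapter_probs`` maps chapter keys (e.g. ``"Z00-Z99"``) to the
    probability that a drawn code falls in that chapter.
    """

    name: str
    start: str
    end: str
    n_visits: int
    coding_missingness: float
    modality_mix: dict[str, float]
    specialty_mix: dict[str, float]
    sex_mix: dict[str, float]
    age_group_mix: dict[str, float]
    chapter_probs: dict[str, float]

    def validate(self) -> None:
        if self.n_visits < 0:
            raise ConfigError(f"{self.name}: n_visits must be >= 0")
        if not 0.0 <= self.coding_missingness <= 1.0:
            raise ConfigError(f"{self.name}: coding_missingness outside [0, 1]")
        _check_mixture(f"{self.name}.modality_mix", self.modality_mix)
        _check_mixture(f"{self.name}.specialty_mix", self.specialty_mix)
        _check_mixture(f"{self.name}.sex_mix", self.sex_mix)
        _check_mixture(f"{self.name}.age_group_mix", self.age_group_mix)
        _check_mixture(f"{self.name}.chapter_probs", self.chapter_probs)
        if set(self.modality_mix) - set(MODALITIES):
            raise ConfigError(f"{self.name}: unknown modality in mixture")
        if set(self.specialty_mix) - set(SPECIALTIES):
            raise ConfigError(f"{self.name}: unknown specialty in mixture")
        if set(self.sex_mix) - set(SEXES):
            raise ConfigError(f"{self.name}: unknown sex in mixture")
        if set(self.age_group_mix) - set(AGE_GROUPS):
            raise ConfigError(f"{self.name}: unknown age group in mixture")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration (all rates, mixtures and the seed)."""

    periods: tuple[PeriodConfig, ...]
    codes_per_visit_mean: float = 1.38
    codes_per_visit_tail: float = 0.035  # P(> 3 codes | coded visit)
    patient_pool_size: int = 290_000
    seed: int = 0
    #: Optional override of the within-chapter category allocation:
    #: chapter key -> {category: probability}. Default is uniform over the
    #: categories enumerated from the chapter's blocks.
    category_probs: dict[str, dict[str, float]] | None = None

    def validate(self) -> None:
        if not self.periods:
            raise ConfigError("at least one period is required")
        for period in self.periods:
            period.validate()
        if self.patient_pool_size < 1:
            raise ConfigError("patient_pool_size must be >= 1")
        if not self.codes_per_visit_mean > 1.0:
            raise ConfigError("codes_per_visit_mean must exceed 1")
        _solve_count_law(self.codes_per_visit_mean, self.codes_per_visit_tail)
        if self.category_probs is not None:
            for chapter, probs in self.category_probs.items():
                _check_mixture(f"category_probs[{chapter}]", probs)

    def partitions(self) -> PartitionSpec:
        from .frequency import Partition

        return PartitionSpec(tuple(
            Partition(p.name, pd.Timestamp(p.start), pd.Timestamp(p.end))
            for p in self.periods
        ))

    def scaled(self, factor: float) -> "SyntheticConfig":
        """Copy with visit totals and patient pool scaled by ``factor``.

        All rates, mixtures and probability vectors are left untouched, so
        a scaled cohort has the same expected structure at a smaller size.
        """
        periods = tuple(
            replace(p, n_visits=int(round(p.n_visits * factor))) for p in self.periods
        )
        return replace(self, periods=periods,
                       patient_pool_size=max(1, int(round(self.patient_pool_size * factor))))


def _solve_count_law(mean: float, tail: float) -> tuple[float, float]:
    """Solve the zero-inflated shifted-geometric parameters (w, q).

    With N = 1 + G, G = 0 w.p. w else Geometric(q) failures, and r = 1 - q,
    a = 1 - w:  E[N] - 1 = a r / (1 - r)  and  P(N > 3) = a r^3, so r solves
    r^2 (1 - r) = tail / (mean - 1).
    """
    m, t = mean - 1.0, tail
    if t <= 0 or m <= 0:
        raise ConfigError("count law needs mean > 1 and tail > 0")
    ratio = t / m
    # r^2(1-r) peaks at 4/27 on (0,1); solve on the increasing branch.
    if ratio >= 4.0 / 27.0:
        raise ConfigError("codes-per-visit tail too heavy for the count law")
    r = brentq(lambda x: x * x * (1 - x) - ratio, 1e-9, 2.0 / 3.0, xtol=1e-12)
    a = t / r**3
    if not 0.0 < a <= 1.0:
        raise ConfigError("codes-per-visit moments are inconsistent")
    return 1.0 - a, 1.0 - r


def default_config(seed: int = 0, scale: float = 1.0) -> SyntheticConfig:
    """Generator defaults calibrated to the published reference tables.

    Per-period visit totals, coding missingness, modality / specialty /
    sex / age mixtures and the chapter probability vectors are all read
    from the packaged 2019/2020 tables:

    * visit totals 1,421,779 / 1,402,406 and missingness 18.46% / 22.50%;
    * modality 85.30/14.70 (2019) vs 45.20/54.80 (2020);
    * chapter vectors = the printed per-year chapter counts, normalized.

    ``scale`` shrinks the cohort (see :meth:`SyntheticConfig.scaled`) for
    desk-scale runs.
    """
    summary = reference.visit_summary()
    chapters = reference.chapter_counts()

    def mix(rows: dict[str, str], col: str) -> dict[str, float]:
        probs = {k: float(summary.loc[row, col]) for k, row in rows.items()}
        total = sum(probs.values())
        return {k: v / total for k, v in probs.items()}

    def period(name: str, start: str, end: str, n_visits: int, uncoded: int,
               col: str) -> PeriodConfig:
        chap = chapters[f"n_{name[1:]}"].astype(float)
        return PeriodConfig(
            name=name, start=start, end=end, n_visits=n_visits,
            coding_missingness=uncoded / n_visits,
            modality_mix=mix({"face_to_face": "visits_face_to_face",
                              "telemedicine": "visits_telemedicine"}, col),
            specialty_mix=mix({"general_medicine": "visits_general_medicine",
                               "nursing": "visits_nursing",
                               "pediatrics": "visits_pediatrics"}, col),
            sex_mix=mix({"male": "visits_male", "female": "visits_female"}, col),
            age_group_mix=mix({g: f"visits_{g}" for g in AGE_GROUPS}, col),
            chapter_probs=(chap / chap.sum()).to_dict(),
        )

    config = SyntheticConfig(
        periods=(
            period("Y2019", "2019-01-01", "2020-01-01",
                   reference.VISITS_EARLY, reference.UNCODED_EARLY, "pct_2019"),
            period("Y2020", "2020-01-01", "2021-01-01",
                   reference.VISITS_LATE, reference.UNCODED_LATE, "pct_2020"),
        ),
        seed=seed,
    )
    if scale != 1.0:
        config = config.scaled(scale)
    config.validate()
    return config


def _category_table(
    config: SyntheticConfig, hierarchy: ICDHierarchy
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per chapter: (categories, allocation probabilities)."""
    out: dict[str, tuple[list[str], np.ndarray]] = {}
    chapter_keys = {key for p in config.periods for key in p.chapter_probs}
    for chapter in hierarchy.chapters:
        if chapter.key not in chapter_keys:
            continue
        if config.category_probs and chapter.key in config.category_probs:
            probs = config.category_probs[chapter.key]
            cats = list(probs)
            weights = np.array([probs[c] for c in cats], dtype=float)
        else:
            cats = sorted({
                c for b in hierarchy.blocks if b.start in chapter
                for c in b.categories()
            })
            weights = np.full(len(cats), 1.0 / len(cats))
        out[chapter.key] = (cats, weights)
    missing = chapter_keys - set(out)
    if missing:
        raise ConfigError(f"chapters with no category table: {sorted(missing)}")
    return out


def _generate_period(
    period: PeriodConfig,
    config: SyntheticConfig,
    cat_table: dict[str, tuple[list[str], np.ndarray]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = period.n_visits
    start, end = pd.Timestamp(period.start), pd.Timestamp(period.end)
    n_days = (end - start).days
    dates = start + pd.to_timedelta(rng.integers(0, n_days, size=n), unit="D")

    def draw(mix: dict[str, float]) -> np.ndarray:
        keys = np.array(list(mix), dtype=object)
        return keys[rng.choice(len(keys), size=n, p=list(mix.values()))]

    modality = draw(period.modality_mix)
    specialty = draw(period.specialty_mix)
    sex = draw(period.sex_mix)
    group = draw(period.age_group_mix)
    low = np.array([AGE_GROUPS[g][0] for g in group])
    high = np.array([min(AGE_GROUPS[g][1], 99) for g in group])
    age = rng.integers(low, high + 1)

    patients = rng.integers(0, config.patient_pool_size, size=n)

    coded = rng.random(n) >= period.coding_missingness
    w, q = _solve_count_law(config.codes_per_visit_mean, config.codes_per_visit_tail)
    extra = np.where(rng.random(n) < w, 0, rng.geometric(q, size=n) - 1)
    n_codes = np.where(coded, 1 + extra, 0)

    total_codes = int(n_codes.sum())
    chapter_keys = list(period.chapter_probs)
    chapter_idx = rng.choice(len(chapter_keys), size=total_codes,
                             p=list(period.chapter_probs.values()))
    codes = np.empty(total_codes, dtype=object)
    for i, key in enumerate(chapter_keys):
        sel = chapter_idx == i
        cats, weights = cat_table[key]
        codes[sel] = np.array(cats, dtype=object)[
            rng.choice(len(cats), size=int(sel.sum()), p=weights)
        ]

    owner = np.repeat(np.arange(n), n_codes)
    joined = np.full(n, "", dtype=object)
    if total_codes:
        per_visit = pd.Series(codes).groupby(owner).agg(";".join)
        joined[per_visit.index.to_numpy()] = per_visit.to_numpy()

    return pd.DataFrame({
        "visit_id": [f"{period.name}-{i:08d}" for i in range(n)],
        "patient_id": [f"P{p:06d}" for p in patients],
        "date": dates,
        "modality": modality,
        "specialty": specialty,
        "sex": sex,
        "age": age.astype(int),
        "codes": joined,
    })


def generate(config: SyntheticConfig, hierarchy: ICDHierarchy | None = None) -> pd.DataFrame:
    """Generate a visit-level dataset from a validated configuration.

    Byte-reproducible for a fixed seed. Visit dates are uniform within each
    period; a ``coding_missingness`` fraction of visits carries no codes;
    each code on a coded visit draws a chapter from the period's chapter
    vector and then a concrete 3-character category within it.
    """
    config.validate()
    hierarchy = hierarchy or load_hierarchy()
    cat_table = _category_table(config, hierarchy)
    rng = np.random.default_rng(config.seed)
    frames = [_generate_period(p, config, cat_table, rng) for p in config.periods]
    out = pd.concat(frames, ignore_index=True)
    return out.loc[:, list(COLUMNS)]


def expected_counts(
    config: SyntheticConfig, level: int, hierarchy: ICDHierarchy | None = None
) -> FrequencyMatrix:
    """Closed-form expected frequency matrix under a configuration.

    ``E[n(c, t)] = n_visits(t) * (1 - missingness(t)) * E[codes per coded
    visit] * p(c, t)``, with the chapter mass spread over blocks/categories
    by the configured (default uniform) within-chapter allocation. Serves
    as the oracle for parameter-recovery checks; cells are floats.
    """
    config.validate()
    hierarchy = hierarchy or load_hierarchy()
    cat_table = _category_table(config, hierarchy)
    rows = {}
    for period in config.periods:
        n_coded = period.n_visits * (1.0 - period.coding_missingness)
        total = n_coded * config.codes_per_visit_mean
        cell: dict[str, float] = {}
        for chapter_key, p_chapter in period.chapter_probs.items():
            cats, weights = cat_table[chapter_key]
            for cat, weight in zip(cats, weights):
                mass = total * p_chapter * weight
                key = hierarchy.group_key(cat, level)
                cell[key] = cell.get(key, 0.0) + mass
        rows[period.name] = cell
    counts = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    counts = counts.loc[[p.name for p in config.periods]]
    counts.index.name = "partition"
    return FrequencyMatrix.from_counts(counts, level, StratumFilter())
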