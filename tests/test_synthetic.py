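"""The synthetic cohort generator: calibration to the published margins,
seeded determinism, validation, and closed-form expected counts."""

import numpy as np
import pandas as pd
import pytest

from icdvar import (
    build_matrix,
    expected_counts,
    filter_coded,
    generate,
    interannual_variation,
)
from icdvar.synthetic import (
    ConfigError,
    SyntheticConfig,
    _solve_count_law,
    default_config,
)
from icdvar.visits import code_counts
from icdvar import reference

from dataclasses import replace


class TestDefaultConfig:
    def test_mixtures_match_published_shares(self):
        cfg = default_config()
        early, late = cfg.periods
        assert early.modality_mix["face_to_face"] == pytest.approx(0.8530, abs=0.0005)
        assert late.modality_mix["telemedicine"] == pytest.approx(0.5480, abs=0.0005)
        assert early.coding_missingness == pytest.approx(0.1846, abs=0.0001)
        assert late.coding_missingness == pytest.approx(0.2250, abs=0.0001)
        assert early.n_visits == reference.VISITS_EARLY

    def test_all_mixtures_sum_to_one(self):
        for period in default_config().periods:
            for mix in (period.modality_mix, period.specialty_mix,
                        period.sex_mix, period.age_group_mix, period.chapter_probs):
                assert sum(mix.values()) == pytest.approx(1.0)

    def test_chapter_vector_matches_published_share(self):
        cfg = default_config()
        assert cfg.periods[0].chapter_probs["Z00-Z99"] == pytest.approx(
            186_604 / 2_059_441)

    def test_count_law_hits_published_moments(self):
        w, q = _solve_count_law(1.38, 0.035)
        a, r = 1 - w, 1 - q
        assert 1 + a * r / (1 - r) == pytest.approx(1.38)
        assert a * r**3 == pytest.approx(0.035)

    def test_invalid_configs_rejected_before_generation(self):
        cfg = default_config(scale=0.001)
        bad = replace(cfg, periods=(replace(cfg.periods[0],
                                            modality_mix={"face_to_face": 0.7}),))
        with pytest.raises(ConfigError, match="mixture"):
            generate(bad)
        with pytest.raises(ConfigError, match="n_visits"):
            replace(cfg.periods[0], n_visits=-1).validate()

    def test_inconsistent_count_moments_rejected(self):
        with pytest.raises(ConfigError):
            _solve_count_law(1.01, 0.2)


class TestGenerate:
    def test_seeded_determinism(self):
        cfg = default_config(seed=7, scale=0.001)
        a = generate(cfg)
        b = generate(cfg)
        pd.testing.assert_frame_equal(a, b)
        c = generate(default_config(seed=8, scale=0.001))
        assert not a["codes"].equals(c["codes"])

    def test_output_passes_visit_validation(self, cohort_1k, tmp_path):
        from icdvar import read_visits, write_visits

        path = tmp_path / "cohort.csv"
        write_visits(cohort_1k, path)
        back = read_visits(path)  # raises on any invalid row
        assert len(back) == len(cohort_1k)

    def test_zero_code_fraction_matches_missingness(self, cohort_100k,
                                                    cohort_100k_config, years):
        for period in cohort_100k_config.periods:
            mask = years.mask(cohort_100k["date"], period.name)
            frac = (code_counts(cohort_100k[mask]) == 0).mean()
            n = int(mask.sum())
            se = np.sqrt(period.coding_missingness
                         * (1 - period.coding_missingness) / n)
            assert abs(frac - period.coding_missingness) < 3 * se

    def test_codes_per_visit_moments(self, cohort_100k):
        counts = code_counts(cohort_100k)
        coded = counts[counts > 0]
        assert coded.mean() == pytest.approx(1.38, abs=0.01)
        assert (coded > 3).mean() == pytest.approx(0.035, abs=0.004)

    def test_chapter_shares_within_3_binomial_se(self, cohort_100k,
                                                 cohort_100k_config,
                                                 hierarchy, years):
        """Empirical level-1 shares track the configured chapter vectors."""
        coded, _ = filter_coded(cohort_100k)
        matrix = build_matrix(coded, 1, years, hierarchy)
        for period in cohort_100k_config.periods:
            row = matrix.counts.loc[period.name]
            m = row.sum()
            for chapter, p in period.chapter_probs.items():
                se = np.sqrt(p * (1 - p) / m)
                emp = row.get(chapter, 0) / m
                assert abs(emp - p) < 3 * se, (period.name, chapter)

    def test_dates_confined_to_periods(self, cohort_1k):
        years_seen = pd.to_datetime(cohort_1k["date"]).dt.year
        assert set(years_seen) <= {2019, 2020}


class TestExpectedCounts:
    def test_single_chapter_gets_all_mass(self):
        cfg = default_config(scale=0.001)
        period = replace(cfg.periods[0], chapter_probs={"I00-I99": 1.0})
        cfg = replace(cfg, periods=(period,))
        exp = expected_counts(cfg, 1)
        assert exp.counts.loc[period.name].drop("I00-I99").sum() == 0
        assert exp.counts.loc[period.name, "I00-I99"] > 0

    def test_total_mass_is_visits_times_mean_codes(self):
        cfg = default_config(scale=0.01)
        exp = expected_counts(cfg, 1)
        for period in cfg.periods:
            want = period.n_visits * (1 - period.coding_missingness) * 1.38
            assert exp.counts.loc[period.name].sum() == pytest.approx(want)

    def test_level_consistency_of_expectations(self):
        cfg = default_config(scale=0.001)
        e1 = expected_counts(cfg, 1)
        e2 = expected_counts(cfg, 2)
        e3 = expected_counts(cfg, 3)
        for e in (e2, e3):
            assert e.counts.to_numpy().sum() == pytest.approx(
                e1.counts.to_numpy().sum())

    def test_zero_visits_zero_matrix(self):
        cfg = default_config(scale=0.001)
        cfg = replace(cfg, periods=tuple(replace(p, n_visits=0) for p in cfg.periods))
        exp = expected_counts(cfg, 1)
        assert (exp.counts.to_numpy() == 0).all()

    def test_expected_iav_reproduces_configured_shift(self):
        """The iav implied by the two configured chapter shares and period
        sizes falls out of the expected matrix by algebra."""
        cfg = default_config()
        exp = expected_counts(cfg, 1)
        early, late = cfg.periods
        for chapter in ("Z00-Z99", "I00-I99"):
            n0 = early.n_visits * (1 - early.coding_missingness) * 1.38 \
                * early.chapter_probs[chapter]
            n1 = late.n_visits * (1 - late.coding_missingness) * 1.38 \
                * late.chapter_probs[chapter]
            got = interannual_variation(exp.counts.loc["Y2019", chapter],
                                        exp.counts.loc["Y2020", chapter])
            assert got == pytest.approx(interannual_variation(n0, n1))
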