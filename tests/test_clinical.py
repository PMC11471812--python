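"""Clinical layer: BED10, Kaplan-Meier from aggregate life tables,
log-rank against an independent row-level implementation, Fisher exact,
summary-statistics z/power, and the cohort report."""

import math

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from fedstats import ring as R
from fedstats.clinical import (ContingencyTable2x2, DoseScheme, GroupSummary,
                               bed, bed_reported, cohort_report, fisher_2x2,
                               km, life_table_median, logrank,
                               power_two_sample, survival_rate, two_sample_z)
from fedstats.dictionary import default_dictionary
from fedstats.stats import SecureStats, SurvivalTableAgg
from fedstats.table import ingest_csv


def expand(tab: SurvivalTableAgg):
    """Row-level (time, event) expansion of a monthly table — feeds the
    independent lifelines cross-check."""
    T, E = [], []
    for m, (d, c) in enumerate(zip(tab.events, tab.censored)):
        T += [m] * (d + c)
        E += [1] * d + [0] * c
    return np.array(T), np.array(E)


def monthly_table(times, events) -> SurvivalTableAgg:
    months = np.floor(times).astype(int)
    M = int(months.max())
    return SurvivalTableAgg(
        events=[int(((months == m) & (events == 1)).sum()) for m in range(M + 1)],
        censored=[int(((months == m) & (events == 0)).sum()) for m in range(M + 1)],
    )


class TestBED:
    @pytest.mark.parametrize("dose,n,reported", [
        (40.5, 3, 95),   # printed 3-fraction median scheme
        (40.0, 5, 72),   # printed 5-fraction median scheme
        (50.0, 5, 100),  # printed 5-fraction range top
        (24.0, 3, 43),   # printed 3-fraction range bottom
    ])
    def test_printed_scheme_pairs(self, dose, n, reported):
        assert bed_reported(DoseScheme(dose, n)) == reported

    def test_exact_value_is_rational(self):
        assert float(bed(DoseScheme(40.5, 3))) == 95.175

    def test_zero_dose_limit(self):
        assert bed(DoseScheme(0.0, 3)) == 0

    def test_invalid_fraction_count(self):
        with pytest.raises(ValueError):
            DoseScheme(40.0, 0)


class TestKaplanMeier:
    def test_all_censored_curve_is_flat(self):
        c = km(SurvivalTableAgg(events=[0, 0, 0], censored=[1, 2, 1]))
        assert all(s == 1.0 for s in c.surv)
        assert c.median is None

    def test_hand_product_limit_toy(self):
        tab = SurvivalTableAgg(events=[0, 0, 2, 0, 0, 1, 0, 0],
                               censored=[0, 0, 0, 0, 0, 0, 0, 1])
        c = km(tab)
        assert c.surv[2] == 0.5 and c.surv[5] == 0.25
        assert c.median == 2
        assert survival_rate(c, 0) == 1.0
        assert survival_rate(c, 3) == 0.5

    def test_matches_lifelines_on_expanded_data(self, rng):
        t = rng.exponential(10, 300)
        cns = rng.uniform(0, 25, 300)
        fu = np.minimum(t, cns)
        ev = (t <= cns).astype(int)
        tab = monthly_table(fu, ev)
        ours = km(tab)
        T, E = expand(tab)
        kmf = KaplanMeierFitter().fit(T, E)
        for m in ours.months:
            assert ours.surv[m] == pytest.approx(
                float(kmf.survival_function_at_times(m).iloc[0]), abs=1e-12)

    def test_rate_beyond_follow_up_undefined(self):
        c = km(SurvivalTableAgg(events=[1], censored=[1]))
        with pytest.raises(ValueError):
            survival_rate(c, 5.0)

    def test_exponential_limit_median(self):
        """KM median from month-grouped data converges to scale * ln 2."""
        rng = np.random.default_rng(2718)
        scale = 19 / math.log(2)
        t = rng.exponential(scale, 10_000)
        cns = rng.uniform(0, 27, 10_000)
        tab = monthly_table(np.minimum(t, cns), (t <= cns).astype(int))
        med = life_table_median(tab)
        assert med == pytest.approx(19.0, rel=0.05)

    def test_survival_rate_near_closed_form(self):
        rng = np.random.default_rng(31415)
        scale = 19 / math.log(2)
        t = rng.exponential(scale, 5000)
        cns = rng.uniform(0, 27, 5000)
        tab = monthly_table(np.minimum(t, cns), (t <= cns).astype(int))
        c = km(tab)
        # S(12) estimates exp(-12 ln2 / 19) = 0.645; grouped curve at month
        # 12 covers events up to month 13, bracket accordingly
        lo = math.exp(-13 * math.log(2) / 19)
        hi = math.exp(-12 * math.log(2) / 19)
        assert lo - 0.03 <= survival_rate(c, 12) <= hi + 0.03


class TestLogRank:
    def test_identical_tables_give_null(self):
        tab = SurvivalTableAgg(events=[1, 2, 0], censored=[0, 1, 2])
        res = logrank(tab, tab)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_cross_implementation_oracle(self, rng):
        """Agrees with lifelines' row-level Mantel-Cox on random tables."""
        for _ in range(10):
            ta = monthly_table(rng.exponential(8, 40), rng.integers(0, 2, 40))
            tb = monthly_table(rng.exponential(12, 35), rng.integers(0, 2, 35))
            ours = logrank(ta, tb)
            Ta, Ea = expand(ta)
            Tb, Eb = expand(tb)
            ref = logrank_test(Ta, Tb, Ea, Eb)
            assert ours.statistic == pytest.approx(ref.test_statistic,
                                                   abs=1e-9)
            assert ours.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_empty_group_rejected(self):
        tab = SurvivalTableAgg(events=[1], censored=[0])
        with pytest.raises(ValueError):
            logrank(tab, SurvivalTableAgg(events=[0], censored=[0]))

    def test_power_increases_with_hazard_ratio(self):
        """Rejection rate under HR = 2.5 clearly exceeds the null rate."""
        rng = np.random.default_rng(404)

        def rejection_rate(hr, sims=150, n=60):
            rej = 0
            for _ in range(sims):
                ta = monthly_table(*_sim(rng, n, 1 / 15))
                tb = monthly_table(*_sim(rng, n, hr / 15))
                if logrank(ta, tb).p_value < 0.05:
                    rej += 1
            return rej / sims

        def _sim(rng, n, h):
            t = rng.exponential(1 / h, n)
            c = rng.uniform(0, 27, n)
            return np.minimum(t, c), (t <= c).astype(int)

        assert rejection_rate(2.5) > rejection_rate(1.0) + 0.3


class TestFisher:
    def test_printed_remission_table(self):
        res = fisher_2x2(ContingencyTable2x2(5, 5, 5, 31))
        assert round(res.p_value, 3) == 0.027

    def test_degenerate_margin(self):
        assert fisher_2x2(ContingencyTable2x2(0, 10, 0, 36)).p_value == 1.0

    def test_exact_rational_enumeration(self):
        res = fisher_2x2(ContingencyTable2x2(3, 1, 1, 3))
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_transposition_invariance(self):
        # simultaneous row and column transposition maps (a,b;c,d)->(d,c;b,a)
        a = fisher_2x2(ContingencyTable2x2(5, 5, 5, 31)).p_value
        swapped = fisher_2x2(ContingencyTable2x2(31, 5, 5, 5)).p_value
        assert a == pytest.approx(swapped, abs=1e-12)

    def test_doubling_convention_differs_but_valid(self):
        p_sum = fisher_2x2(ContingencyTable2x2(5, 5, 5, 31)).p_value
        p_dbl = fisher_2x2(ContingencyTable2x2(5, 5, 5, 31),
                           convention="doubling").p_value
        assert 0 <= p_dbl <= 1 and p_dbl >= p_sum

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestSummaryStatistics:
    ECOG01 = GroupSummary(mean=20.4, n=40, ci95=(15.9, 24.8))
    ECOG2 = GroupSummary(mean=9.2, n=8, ci95=(6.6, 11.8))

    def test_ecog_groups_highly_significant(self):
        res = two_sample_z(self.ECOG01, self.ECOG2)
        assert res.p_value < 1e-4

    def test_ecog_power_close_to_one(self):
        assert power_two_sample(self.ECOG01, self.ECOG2) > 0.95

    def test_zero_effect_rejection_is_alpha(self):
        g = GroupSummary(mean=10.0, n=20, se=1.0)
        assert power_two_sample(g, g, alpha=0.05) == pytest.approx(0.05,
                                                                   abs=1e-9)

    def test_ci_and_se_are_interchangeable(self):
        from_ci = GroupSummary(mean=20.4, n=40, ci95=(15.9, 24.8)).std_error
        assert from_ci == pytest.approx((24.8 - 15.9) / 2 / 1.96, rel=1e-3)
        with pytest.raises(ValueError):
            GroupSummary(mean=1.0, n=5, se=-0.1)


class TestCohortReport:
    def test_gender_row_with_percentages(self, rng, engine):
        from conftest import make_categorical_column
        from fedstats.table import (ColumnSpec, DataDictionary, PrivateTable,
                                    CATEGORICAL)
        d = DataDictionary(columns=(
            ColumnSpec("gender", CATEGORICAL, ("male", "female")),))
        col = make_categorical_column([0] * 16 + [1] * 8, ("male", "female"),
                                      rng, "gender")
        t = PrivateTable(columns={"gender": col}, site_label="m", n_rows=24,
                         dictionary=d)
        report = cohort_report(t, engine)
        assert "| gender | male | 16 (67%) |" in report
        assert "| gender | female | 8 (33%) |" in report

    def test_report_redacts_under_sdc(self, rng, store, site_csvs):
        t = ingest_csv(site_csvs[0], default_dictionary(), rng=rng)
        engine = SecureStats(store, sdc_threshold=100)  # above cohort size
        report = cohort_report(t, engine)
        assert "redacted" in report
        assert "%" not in report  # no count/percentage cell survives
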