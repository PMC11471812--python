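"""Secure statistics engine: oracle equivalence, printed-session
conformance, SDC gating and the survival-table invariants."""

import numpy as np
import pytest

from fedstats import ring as R
from fedstats.stats import (ALLOWED, REFUSED, QuantileSummary, SecureStats,
                            SurvivalTableAgg, oblivious_sort, sdc_guard)
from fedstats.table import SchemaMismatchError, SelectionMask

from conftest import (CONFORMANCE_AGES, make_categorical_column,
                      make_metric_column)


def bit_mask(bits, rng, desc="mask"):
    sv = R.share(np.asarray(bits, dtype=np.int64), rng, kind=R.INT)
    return SelectionMask(bits=sv.with_kind(R.BIT), source="t", description=desc)


class TestObliviousSort:
    def test_matches_plaintext_sort(self, rng, store):
        for n in (1, 2, 5, 8, 13, 24):
            x = rng.uniform(-50, 400, n)
            sv = R.share(x, rng, kind=R.FIXED)
            out = R.reconstruct_fixed(oblivious_sort(sv, store))
            grid = np.round(x * 65536) / 65536
            assert np.array_equal(out, np.sort(grid)), n

    def test_handles_duplicates(self, rng, store):
        x = np.array([3.0, 1.0, 3.0, 1.0, 2.0])
        out = R.reconstruct_fixed(oblivious_sort(R.share(x, rng, kind=R.FIXED),
                                                 store))
        assert np.array_equal(out, np.sort(x))


class TestFrequencies:
    def test_printed_gender_composition(self, rng, engine):
        col = make_categorical_column([0] * 16 + [1] * 8, ("male", "female"),
                                      rng, "gender")
        assert engine.freq(col).payload == {"male": 16, "female": 8}

    def test_zero_count_categories_reported(self, rng, engine):
        col = make_categorical_column([0, 0, 2], ("a", "b", "c"), rng)
        assert engine.freq(col).payload == {"a": 2, "b": 0, "c": 1}

    def test_counts_match_plaintext_oracle(self, engine):
        master = np.random.default_rng(99)
        for _ in range(25):
            rng = np.random.default_rng(master.integers(2**31))
            n = int(rng.integers(1, 30))
            codes = rng.integers(0, 4, n)
            col = make_categorical_column(codes, ("a", "b", "c", "d"), rng)
            got = engine.freq(col).payload
            assert got == {lab: int((codes == k).sum())
                           for k, lab in enumerate(("a", "b", "c", "d"))}
            assert sum(got.values()) == n

    def test_metric_column_rejected(self, rng, engine):
        with pytest.raises(SchemaMismatchError):
            engine.freq(make_metric_column([1.0], rng))


class TestMean:
    def test_constant_vector(self, rng, engine):
        assert engine.mean(make_metric_column([5.0] * 7, rng)).payload == 5.0

    def test_grid_exact(self, rng, engine):
        assert engine.mean(make_metric_column([1, 2, 3, 4], rng)).payload == 2.5

    def test_masked_mean_oracle(self, engine):
        master = np.random.default_rng(7)
        for _ in range(20):
            rng = np.random.default_rng(master.integers(2**31))
            n = int(rng.integers(2, 25))
            x = rng.uniform(-40, 120, n)
            sel = rng.integers(0, 2, n)
            if sel.sum() == 0:
                sel[0] = 1
            col = make_metric_column(x, rng)
            res = engine.mean(col, bit_mask(sel, rng))
            grid = np.round(x * 65536) / 65536
            assert res.payload == pytest.approx(grid[sel == 1].mean(),
                                                abs=2**-10)

    def test_empty_selection_refused(self, rng, engine):
        col = make_metric_column([1.0, 2.0], rng)
        res = engine.mean(col, bit_mask([0, 0], rng))
        assert res.sdc_status == REFUSED and res.payload is None


class TestQuantiles:
    def test_conformance_vector_matches_printed_summary(self, rng, engine):
        col = make_metric_column(CONFORMANCE_AGES, rng, "age", "years")
        q = engine.quantile(col).payload
        assert q.as_tuple() == (38.0, 62.5, 66.0, 72.25, 91.0)

    def test_constant_vector(self, rng, engine):
        q = engine.quantile(make_metric_column([4.25] * 9, rng)).payload
        assert q.as_tuple() == (4.25,) * 5

    def test_random_vectors_match_numpy_oracle(self, engine):
        master = np.random.default_rng(31)
        for _ in range(20):
            rng = np.random.default_rng(master.integers(2**31))
            n = int(rng.integers(1, 40))
            x = np.round(rng.uniform(0, 300, n) * 65536) / 65536
            col = make_metric_column(x, rng)
            got = np.array(engine.quantile(col).payload.as_tuple())
            want = np.quantile(x, [0, 0.25, 0.5, 0.75, 1.0],
                               method="linear")
            assert np.max(np.abs(got - want)) <= 2**-10

    def test_ordering_invariant(self, rng, engine):
        x = rng.uniform(0, 10, 17)
        q = engine.quantile(make_metric_column(x, rng)).payload
        v = q.as_tuple()
        assert all(a <= b for a, b in zip(v, v[1:]))

    def test_median_is_middle_element(self, rng, engine):
        col = make_metric_column(CONFORMANCE_AGES, rng)
        assert engine.median(col).payload == 66.0

    def test_summary_rejects_disorder(self):
        with pytest.raises(ValueError):
            QuantileSummary(1, 0, 2, 3, 4)


class TestSurvivalTable:
    def test_hand_counted_toy(self, rng, engine):
        tcol = make_metric_column([2.4, 2.9, 5.1, 7.0], rng, "follow_up",
                                  "months", min_value=0.0)
        ecol = make_categorical_column([1, 1, 1, 0], ("0", "1"), rng,
                                       "event_death")
        tab = engine.survival_table(tcol, ecol).payload
        assert tab.events[2] == 2 and tab.events[5] == 1
        assert tab.censored[7] == 1
        assert tab.at_risk[0] == 4

    def test_empty_selection_refused(self, rng, engine):
        tcol = make_metric_column([1.0, 2.0], rng)
        ecol = make_categorical_column([1, 0], ("0", "1"), rng)
        res = engine.survival_table(tcol, ecol, bit_mask([0, 0], rng))
        assert res.sdc_status == REFUSED

    def test_conservation_on_random_cohorts(self, engine):
        """n_0 equals the (masked) cohort size and every subject is
        accounted for, for arbitrary cohorts and selections."""
        master = np.random.default_rng(55)
        for _ in range(15):
            rng = np.random.default_rng(master.integers(2**31))
            n = int(rng.integers(2, 30))
            t = rng.uniform(0, 20, n)
            e = rng.integers(0, 2, n)
            sel = rng.integers(0, 2, n)
            if sel.sum() == 0:
                sel[0] = 1
            tcol = make_metric_column(t, rng)
            ecol = make_categorical_column(e, ("0", "1"), rng)
            tab = engine.survival_table(tcol, ecol, bit_mask(sel, rng)).payload
            tab.validate()
            assert tab.n_total == sel.sum()
            months = np.floor(np.round(t * 65536) / 65536).astype(int)
            for m in range(len(tab.events)):
                inm = (months == m) & (sel == 1)
                assert tab.events[m] == int((inm & (e == 1)).sum())
                assert tab.censored[m] == int((inm & (e == 0)).sum())

    def test_csv_roundtrip(self):
        tab = SurvivalTableAgg(events=[0, 2, 1], censored=[1, 0, 3])
        again = SurvivalTableAgg.from_csv(tab.to_csv())
        assert again.events == tab.events and again.censored == tab.censored
        assert again.at_risk == tab.at_risk

    def test_invariant_violation_detected(self):
        with pytest.raises(ValueError):
            SurvivalTableAgg(events=[5], censored=[-1])


class TestDisclosureControl:
    def test_guard_truth_table(self):
        assert sdc_guard(4, 5) == REFUSED
        assert sdc_guard(5, 5) == ALLOWED
        assert sdc_guard(0, 5) == ALLOWED    # empty: nothing to disclose
        assert sdc_guard(1, 0) == ALLOWED    # k=0: session-reproduction mode

    def test_small_subgroup_freq_refused(self, rng, store):
        engine = SecureStats(store, sdc_threshold=5)
        col = make_categorical_column([0, 1, 0, 1, 0, 1], ("a", "b"), rng)
        res = engine.freq(col, bit_mask([1, 1, 1, 0, 0, 0], rng))
        assert res.sdc_status == REFUSED and res.payload is None
        assert "3" in res.reason

    def test_refusal_serializes_without_payload(self, rng, store):
        engine = SecureStats(store, sdc_threshold=5)
        col = make_metric_column([1.0, 2.0, 3.0], rng)
        d = engine.mean(col, bit_mask([1, 1, 0], rng)).to_dict()
        assert d["sdc_status"] == REFUSED and d["payload"] is None
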