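"""First-use construction, censoring, and the product-limit estimator."""

import datetime as dt
import math

import numpy as np
import pytest

from acrotrend import (ReuseCohortConfig, ReuseRecord, build_reuse_records,
                       generate_reuse_cohorts, km_curve,
                       reuse_fraction_within, t10_by_cohort)

from conftest import make_record


def brute_force_product_limit(times, events):
    """Independent Kaplan–Meier oracle: walk distinct event times in
    order, multiplying survival by (1 - deaths/at-risk)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = {}
    s = 1.0
    for t in sorted(set(times[events])):
        at_risk = int((times >= t).sum())
        deaths = int(((times == t) & events).sum())
        s *= 1.0 - deaths / at_risk
        out[t] = s
    return out


def rr(surface, time, event, year=2000, length=None, journal="J"):
    return ReuseRecord(
        surface=surface, journal_id=journal,
        first_use_date=dt.date(year, 1, 1), first_use_year=year,
        time_to_event=time, event=event,
        acronym_length=length or len(surface))


class TestBuildReuseRecords:
    def test_event_time(self):
        recs = [
            make_record(paper_id="A", year=2000, month=1, day=1,
                        journal="J", title="the XYZ study here"),
            make_record(paper_id="B", year=2000, month=7, day=1,
                        journal="J", title="more about XYZ today"),
        ]
        (r,) = build_reuse_records(recs)
        assert r.surface == "XYZ" and r.event
        assert r.time_to_event == pytest.approx(182 / 365.25, abs=1e-6)

    def test_censored_at_last_issue(self):
        recs = [
            make_record(paper_id="A", year=2000, month=1, day=1,
                        journal="J", title="the QQZ study here"),
            make_record(paper_id="B", year=2001, month=1, day=1,
                        journal="J", title="nothing relevant at all"),
        ]
        (r,) = build_reuse_records(recs)
        assert not r.event
        assert r.time_to_event == pytest.approx(366 / 365.25, abs=1e-6)

    def test_same_surface_two_journals_independent(self):
        recs = [
            make_record(paper_id="A", year=2000, journal="J",
                        title="the ZZT study here"),
            make_record(paper_id="B", year=2001, journal="K",
                        title="another ZZT study there"),
        ]
        out = build_reuse_records(recs)
        assert sorted(r.journal_id for r in out) == ["J", "K"]
        assert all(not r.event for r in out)

    def test_reuse_within_same_paper_does_not_count(self):
        recs = [
            make_record(paper_id="A", year=2000, journal="J",
                        title="the ABC study", abstract="more ABC context"),
        ]
        (r,) = build_reuse_records(recs)
        assert not r.event
        assert r.time_to_event == 0.0

    def test_first_use_on_last_date_censored_at_zero(self):
        recs = [
            make_record(paper_id="A", year=2000, journal="J",
                        title="plain words only here"),
            make_record(paper_id="B", year=2000, journal="J",
                        title="a late NEW acronym"),
        ]
        (r,) = build_reuse_records(recs)
        assert (r.event, r.time_to_event) == (False, 0.0)

    def test_undated_record_rejected(self):
        rec = make_record(paper_id="A", year=None)
        with pytest.raises(ValueError, match="no date"):
            build_reuse_records([rec])

    def test_censoring_consistency(self):
        """Extending the journal's last issue can only lengthen censor
        times or convert censored records to events."""
        base = [
            make_record(paper_id="A", year=2000, month=1, day=1, journal="J",
                        title="the QQZ study here"),
            make_record(paper_id="B", year=2001, month=1, day=1, journal="J",
                        title="filler words only here"),
        ]
        extended = base + [
            make_record(paper_id="C", year=2003, month=1, day=1, journal="J",
                        title="late QQZ revival piece")]
        (before,) = build_reuse_records(base)
        (after,) = [r for r in build_reuse_records(extended)
                    if r.surface == "QQZ"]
        assert not before.event and after.event
        assert after.time_to_event >= before.time_to_event


class TestReuseFraction:
    def test_simple_fraction(self):
        records = [rr("AA", 0.5, True)] + \
            [rr(f"B{i}", 1.5, False) for i in range(9)]
        assert reuse_fraction_within(records, 1.0) == pytest.approx(0.10)

    def test_all_censored_before_window_is_missing(self):
        records = [rr(f"B{i}", 0.4, False) for i in range(5)]
        assert reuse_fraction_within(records, 1.0) is None

    def test_event_after_window_in_denominator_only(self):
        records = [rr("AA", 2.0, True), rr("BB", 0.5, True)]
        assert reuse_fraction_within(records, 1.0) == pytest.approx(0.5)

    def test_empty_input_missing(self):
        assert reuse_fraction_within([], 1.0) is None

    def test_bad_window(self):
        with pytest.raises(ValueError):
            reuse_fraction_within([], 0.0)

    def test_length_hazard_ordering_recovered(self):
        """Cohorts simulated with re-use hazards ordered 2 > 3 > 4 > 5+
        show the same ordering in estimated one-year fractions."""
        rng = np.random.default_rng(42)
        hazards = {2: 0.30, 3: 0.20, 4: 0.12, 6: 0.05}
        records = []
        for length, lam in hazards.items():
            times = rng.exponential(1.0 / lam, size=600)
            for i, t in enumerate(times):
                records.append(rr(f"L{length}N{i}", min(t, 5.0), t <= 5.0,
                                  length=length))
        frac = reuse_fraction_within(records, 1.0, by_length=True)
        assert frac[2] > frac[3] > frac[4] > frac["5+"]


class TestKMCurve:
    def test_single_event_curve(self):
        records = [rr("AA", 2.0, True)] + \
            [rr(f"C{i}", 3.0, False) for i in range(9)]
        curve = km_curve(records)
        assert curve.t10 == pytest.approx(2.0)
        assert curve.survival[0] == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_no_events_t10_missing(self):
        records = [rr(f"C{i}", 3.0, False) for i in range(5)]
        curve = km_curve(records)
        assert curve.t10 is None

    def test_no_censoring_matches_ecdf(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(2.0, size=50).round(3)
        records = [rr(f"S{i}", t, True) for i, t in enumerate(times)]
        curve = km_curve(records)
        for t, s in zip(curve.times[1:], curve.survival[1:]):
            assert s == pytest.approx(1.0 - (times <= t).mean())

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        """KM survival equals the brute-force product-limit computation on
        random instances of <= 20 records with ties and censoring."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        times = rng.integers(1, 8, size=n).astype(float)  # forces ties
        events = rng.random(n) < 0.6
        if not events.any():
            events[0] = True
        records = [rr(f"S{i}", t, bool(e), length=3)
                   for i, (t, e) in enumerate(zip(times, events))]
        curve = km_curve(records)
        oracle = brute_force_product_limit(times, events)
        got = dict(zip(curve.times, curve.survival))
        for t, s in oracle.items():
            assert got[t] == pytest.approx(s, abs=1e-12)

    def test_ci_brackets_t10(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(1.0, size=200)
        records = [rr(f"S{i}", t, True) for i, t in enumerate(times)]
        curve = km_curve(records)
        assert curve.t10_ci_low <= curve.t10 <= curve.t10_ci_high

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="cohort"):
            km_curve([rr("AA", 1.0, True)], cohort_year=1990)


class TestT10Cohorts:
    def test_hazard_ordering_across_cohorts(self):
        """Lower re-use hazard means longer time to 10% re-use."""
        cfg = ReuseCohortConfig(
            seed=9, hazard_by_cohort={1990: 0.4, 2000: 0.1},
            n_per_cohort=400, journal_end=dt.date(2060, 12, 31))
        records, truth = generate_reuse_cohorts(cfg)
        reuse = build_reuse_records(records)
        table = t10_by_cohort(reuse).set_index("cohort_year")
        assert table.loc[1990, "t10"] < table.loc[2000, "t10"]

    def test_cohort_of_one_censored_missing(self):
        records = [rr("AA", 1.0, False, year=1999)]
        table = t10_by_cohort(records)
        assert math.isnan(table.iloc[0].t10)

    def test_identical_cohorts_equal_t10(self):
        a = [rr(f"A{i}", t, True, year=1990)
             for i, t in enumerate([0.5, 1.0, 2.0, 3.0, 4.0,
                                    5.0, 6.0, 7.0, 8.0, 9.0])]
        b = [rr(f"B{i}", r.time_to_event, r.event, year=1991)
             for i, r in enumerate(a)]
        table = t10_by_cohort(a + b).set_index("cohort_year")
        assert table.loc[1990, "t10"] == table.loc[1991, "t10"]

    def test_all_censored_at_coining(self):
        cfg = ReuseCohortConfig(
            seed=2, hazard_by_cohort={2000: 0.5}, n_per_cohort=20,
            n_journals=2, journal_end=dt.date(2000, 12, 31))
        records, _ = generate_reuse_cohorts(cfg)
        reuse = build_reuse_records(records)
        # journals end within the coining year: nearly everything censors
        # early; any event observed must fall before the journal end
        for r in reuse:
            assert r.time_to_event <= 1.01
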