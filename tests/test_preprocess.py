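"""SG correction, reproductive states, exclusion rules, span filter,
covariate encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rnherit as rh
from rnherit.preprocess import parse_clock_time


class TestSGCorrection:
    @pytest.mark.parametrize("raw,sg,pop,expected", [
        (10.0, 1.04, 1.02, 5.0),
        (7.0, 1.02, 1.02, 7.0),
        (3.0, 1.01, 1.02, 6.0),
    ])
    def test_formula(self, raw, sg, pop, expected):
        assert rh.sg_correct(raw, sg, pop) == pytest.approx(expected)

    def test_degenerate_sg_rejected(self):
        with pytest.raises(ValueError):
            rh.sg_correct(5.0, 1.0, 1.02)
        with pytest.raises(ValueError):
            rh.sg_correct(5.0, 1.02, 0.99)

    @given(raw=st.floats(0.01, 1e3), scale=st.floats(0.01, 100.0),
           sg=st.floats(1.001, 1.05), pop=st.floats(1.001, 1.05))
    def test_homogeneous_in_concentration(self, raw, scale, sg, pop):
        a = rh.sg_correct(raw * scale, sg, pop)
        b = rh.sg_correct(raw, sg, pop) * scale
        assert a == pytest.approx(b, rel=1e-9)


class TestReproductiveState:
    EVENTS = pd.DataFrame({"mother": ["f"], "offspring": ["kid"],
                           "birth_date": [pd.Timestamp("2010-06-01")]})

    @pytest.mark.parametrize("offset,state", [
        (-100, "pregnant"),       # inside the 240-day gestation window
        (+500, "lactating"),      # inside the 1095-day window
        (+1200, "cycling"),       # past lactation, no pending birth
        (-300, "cycling"),        # before conception
    ])
    def test_windows(self, offset, state):
        date = pd.Timestamp("2010-06-01") + pd.Timedelta(days=offset)
        assert rh.assign_reproductive_state("f", date, self.EVENTS) == state

    def test_pregnancy_precedes_lactation_on_overlap(self):
        ev = pd.DataFrame({
            "mother": ["f", "f"],
            "offspring": ["k1", "k2"],
            "birth_date": [pd.Timestamp("2010-06-01"),
                           pd.Timestamp("2012-06-01")],
        })
        # 2012-03-01 is within 1095 d of k1's birth AND 240 d before k2's
        assert rh.assign_reproductive_state(
            "f", pd.Timestamp("2012-03-01"), ev) == "pregnant"


def _sample(ind, date, time="08:00", sex="female", age=20.0, sick=0,
            cort=50.0, sg=1.02, **kw):
    row = {"sample_id": kw.pop("sid", f"{ind}-{date}-{time}"),
           "individual": ind, "group": "g1", "project": "p1", "date": date,
           "time": time, "cortisol_raw": cort, "specific_gravity": sg,
           "lcms_method": "new", "sex": sex, "age_years": age,
           "group_size": 10, "sex_ratio": 0.5, "sick_flag": sick}
    row.update(kw)
    return row


class TestExclusions:
    def fixture_10(self):
        ev = pd.DataFrame({
            "mother": ["mom", "mom", "eva", "eva"],
            "offspring": ["kid", "kid2", "x1", "orphan"],
            "birth_date": ["2015-06-01", "2010-01-01", "2008-01-01",
                           "2008-06-01"],
            "mother_death_date": [None, None, None, "2015-01-01"],
        })
        rows = [
            # 2 pregnant samples (mom, 100 and 10 days before kid's birth)
            _sample("mom", "2015-02-21", sid="pg1"),
            _sample("mom", "2015-05-22", sid="pg2"),
            # 1 sick-day sample
            _sample("eva", "2016-01-10", sick=1, sid="sick1"),
            # 1 immature sample after maternal loss (orphan, age 7.6)
            _sample("orphan", "2016-02-01", age=7.6, sid="ml1"),
            # retained: orphan sampled before the mother's death
            _sample("orphan", "2014-06-01", age=6.0, sid="keep1"),
            # retained: lactating mom well after birth
            _sample("mom", "2016-06-01", sid="keep2"),
            # retained: cycling female
            _sample("eva", "2016-03-01", sid="keep3"),
            # retained: adult male (no state needed)
            _sample("al", "2016-03-01", sex="male", sid="keep4"),
            # retained: immature male with living mother
            _sample("kid2", "2016-03-01", sex="male", age=6.2, sid="keep5"),
            # retained: immature female (x1, mother alive)
            _sample("x1", "2016-03-01", age=8.2, sid="keep6"),
        ]
        return pd.DataFrame(rows), ev

    def test_counts_on_constructed_fixture(self):
        samples, ev = self.fixture_10()
        kept, log = rh.apply_exclusions(samples, ev)
        assert len(kept) == 6
        assert log["pregnant"] == 2
        assert log["sick"] == 1
        assert log["maternal_loss"] == 1
        assert set(kept["sample_id"]) == {
            "keep1", "keep2", "keep3", "keep4", "keep5", "keep6"}

    def test_mature_orphan_always_retained(self):
        ev = pd.DataFrame({
            "mother": ["m"], "offspring": ["ad"],
            "birth_date": ["1990-01-01"],
            "mother_death_date": ["1999-01-01"],  # lost mother at age 9
        })
        samples = pd.DataFrame(
            [_sample("ad", "2016-01-01", sex="male", age=26.0)])
        kept, log = rh.apply_exclusions(samples, ev)
        assert len(kept) == 1 and log["maternal_loss"] == 0

    def test_unassignable_adult_female_excluded(self):
        samples = pd.DataFrame([_sample("nohist", "2016-01-01")])
        kept, log = rh.apply_exclusions(samples, None)
        assert len(kept) == 0 and log["state_unassignable"] == 1

    def test_filters_commute(self, tiny_sim):
        # exclusion rules and the span rule are independent predicates:
        # applying them in either order (and on shuffled rows) yields
        # the same retained set
        samples, ev = self.fixture_10()
        a, _ = rh.apply_exclusions(samples, ev)
        a = rh.sampling_span_filter(a)
        b = rh.sampling_span_filter(samples)
        b, _ = rh.apply_exclusions(b, ev)
        shuffled = samples.sample(frac=1.0, random_state=1)
        c, _ = rh.apply_exclusions(shuffled, ev)
        c = rh.sampling_span_filter(c)
        assert set(a["sample_id"]) == set(b["sample_id"])
        assert set(a["sample_id"]) == set(c["sample_id"])


class TestSamplingSpan:
    def year(self, times, ind="a"):
        return pd.DataFrame([
            _sample(ind, "2016-05-01", time=t, sex="male", age=20.0)
            for t in times])

    def test_spanning_day_retained(self):
        kept = rh.sampling_span_filter(self.year(["07:00", "10:00", "14:00"]))
        assert len(kept) == 3

    def test_short_span_dropped(self):
        kept = rh.sampling_span_filter(self.year(["07:00", "08:00", "12:30"]))
        assert len(kept) == 0

    def test_no_afternoon_dropped(self):
        kept = rh.sampling_span_filter(self.year(["06:00", "07:00", "11:00"]))
        assert len(kept) == 0

    def test_evaluated_per_individual_year(self):
        good = self.year(["07:00", "10:00", "14:00"])
        bad = pd.DataFrame([
            _sample("a", "2017-05-01", time=t, sex="male", age=21.0)
            for t in ["07:00", "08:00"]])
        kept = rh.sampling_span_filter(pd.concat([good, bad]))
        assert set(pd.to_datetime(kept["date"]).dt.year) == {2016}


class TestEncoding:
    def test_clock_time_parsing(self):
        assert parse_clock_time("06:45") == pytest.approx(6.75)
        assert parse_clock_time(13.5) == pytest.approx(13.5)
        with pytest.raises(ValueError):
            parse_clock_time("25:00")

    def test_quarter_period_seasonality(self):
        day = int(round(365.25 / 4))
        samples = pd.DataFrame([
            _sample("a", f"2015-01-01", time=t, sex="male", age=20)
            for t in ["07:00", "09:00", "14:00"]])
        samples.loc[0, "date"] = (
            pd.Timestamp("2015-01-01") + pd.Timedelta(days=day - 1))
        prep = rh.encode_covariates(samples)
        row = prep.data.iloc[0]
        assert row["season_sin"] == pytest.approx(1.0, abs=0.02)
        assert row["season_cos"] == pytest.approx(0.0, abs=0.02)

    def test_id_year_levels_split_by_year(self):
        samples = pd.DataFrame([
            _sample("a", "2004-05-01", time="08:00", sex="male", age=20),
            _sample("a", "2005-05-01", time="09:00", sex="male", age=21),
        ])
        prep = rh.encode_covariates(samples)
        assert prep.data["id_year"].nunique() == 2
        assert prep.data["individual"].nunique() == 1

    def test_reencoding_with_reference_stats_is_idempotent(self, tiny_sim):
        prep1 = rh.prepare(tiny_sim.samples, tiny_sim.events)
        prep2 = rh.prepare(tiny_sim.samples, tiny_sim.events,
                           reference_stats=prep1.reference_stats,
                           sg_population_mean=prep1.sg_population_mean)
        for col in ("y", "t", "t2", "age_z", "groupsize_z", "sexratio_z"):
            assert np.allclose(prep1.data[col], prep2.data[col])

    def test_zscored_columns_standardized(self, tiny_prep):
        for col in ("t", "age_z"):
            assert tiny_prep.data[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert tiny_prep.data[col].std(ddof=0) == pytest.approx(1.0,
                                                                    rel=1e-9)

    def test_unknown_mothers_get_singleton_levels(self, tiny_prep):
        singletons = tiny_prep.data["mother"].str.startswith("mother_of_")
        assert singletons.any()
        per_level = tiny_prep.data[singletons].groupby("mother")[
            "individual"].nunique()
        assert (per_level == 1).all()
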