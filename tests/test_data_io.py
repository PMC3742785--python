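import numpy as np
import pandas as pd
import pytest

import dielmetab as dm
from dielmetab.types import SondeFormatError


@pytest.fixture()
def sonde_csv(tmp_path):
    p = tmp_path / "sonde.csv"
    p.write_text(
        "timestamp, do_mgL, temp_C\n"
        "2007-09-01 00:00, 3.2, 29.5\n"
        "2007-09-01 00:30, 3.1, 29.4\n"
        "2007-09-01 01:00, 3.0, 29.3\n"
    )
    return p


class TestReadSonde:
    def test_direct_parse(self, sonde_csv):
        s = dm.read_sonde(sonde_csv)
        assert len(s) == 3
        assert s.data["do_mgL"].iloc[0] == 3.2
        assert s.data["temp_C"].iloc[0] == 29.5
        assert s.rejects.empty

    def test_missing_do_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("timestamp, temp_C\n2007-09-01 00:00, 29.5\n")
        with pytest.raises(SondeFormatError):
            dm.read_sonde(p)

    def test_bad_rows_go_to_rejects(self, tmp_path):
        p = tmp_path / "mixed.csv"
        p.write_text(
            "timestamp, do_mgL, temp_C\n"
            "2007-09-01 00:00, 3.2, 29.5\n"
            "not-a-time, 3.2, 29.5\n"
            "2007-09-01 00:30, 3.1, 29.5\n"
            "2007-09-01 01:00, -1.0, 29.5\n"
            "2007-09-01 01:30, 3.0, 29.4\n"
            "2007-09-01 02:00, 3.0, 99.0\n"
            "2007-09-01 02:30, 3.0, 29.3\n"
            "2007-09-01 02:30, 3.0, 29.3\n"
            "2007-09-01 03:00, 3.0, 29.2\n"
            "2007-09-01 03:30, 3.0, 29.2\n"
        )
        s = dm.read_sonde(p)
        assert len(s) == 6
        reasons = set(s.rejects["reason"])
        assert reasons == {"unparseable timestamp", "negative DO",
                           "temperature out of range", "duplicate timestamp"}

    def test_synthetic_day_roundtrip(self, tmp_path, small_campaign):
        """48-step synthetic day survives write -> read with no rejects and
        values preserved to the printed precision."""
        _, series, _, _ = small_campaign
        sub = dm.SondeSeries(site_id="ck", data=series.data.iloc[:48])
        out = tmp_path / "rt.csv"
        dm.write_sonde(sub, out)
        back = dm.read_sonde(out)
        assert len(back) == 48
        assert back.rejects.empty
        np.testing.assert_allclose(back.data["do_mgL"], sub.data["do_mgL"],
                                   atol=5e-5)
        np.testing.assert_allclose(back.data["temp_C"], sub.data["temp_C"],
                                   atol=5e-5)

    def test_cadence_mismatch_rejected(self):
        idx = pd.date_range("2007-09-01", periods=10, freq="17min")
        data = pd.DataFrame({"do_mgL": 5.0, "temp_C": 29.0}, index=idx)
        with pytest.raises(SondeFormatError):
            dm.SondeSeries(site_id="x", data=data)


def test_read_wind(tmp_path):
    p = tmp_path / "wind.csv"
    p.write_text("date, u10_ms\n2007-09-01, 4.5\n2007-09-02, 0.0\n")
    recs = dm.read_wind(p)
    assert len(recs) == 2
    assert recs[0].u10_ms == 4.5
    with pytest.raises(SondeFormatError):
        bad = tmp_path / "badwind.csv"
        bad.write_text("day, speed\n2007-09-01, 4.5\n")
        dm.read_wind(bad)


class TestSegmentDays:
    def test_three_days_give_two_full_segments(self, site):
        spec = dm.tonle_sap_preset("balanced", n_days=2, seed=1)
        series, _, _ = dm.simulate_campaign(spec)
        # trim to exactly 3 calendar days starting at midnight
        sub = dm.SondeSeries(site_id="ck", data=series.data.iloc[:3 * 48])
        segs = dm.segment_days(sub, site)
        assert len(segs) == 2
        assert all(s.n_steps == 48 for s in segs)

    def test_too_short_series_is_empty(self, site):
        spec = dm.tonle_sap_preset("balanced", n_days=2, seed=1)
        series, _, _ = dm.simulate_campaign(spec)
        sub = dm.SondeSeries(site_id="ck", data=series.data.iloc[:10])
        assert dm.segment_days(sub, site) == []

    def test_servicing_gap_flags_day_unusable(self, site, small_campaign):
        _, series, _, _ = small_campaign
        data = series.data.copy()
        # carve a 4-h hole in the second full day
        hole = slice(60, 68)
        data = data.drop(data.index[hole])
        segs = dm.segment_days(dm.SondeSeries(site_id="ck", data=data), site)
        flagged = [s for s in segs if not s.usable]
        assert len(flagged) >= 1
        assert any("gap" in f for s in flagged for f in s.flags)

    def test_first_step_is_sunrise_crossing(self, site, small_campaign):
        """Each segment starts at the slot where solar elevation first
        crosses zero from below."""
        _, series, _, _ = small_campaign
        segs = dm.segment_days(series, site)
        for s in segs:
            t = s.times[0]
            assert dm.solar_elevation(site, t) >= 0
            before = t - pd.Timedelta(minutes=30)
            assert dm.solar_elevation(site, before) < 0

    def test_segments_tile_the_record(self, site, small_campaign):
        """Union of consecutive segments covers sunrise-to-sunrise spans
        with no overlap and no holes."""
        _, series, _, _ = small_campaign
        segs = dm.segment_days(series, site)
        for a, b in zip(segs, segs[1:]):
            assert a.times[-1] + pd.Timedelta(minutes=30) == b.times[0]

    def test_missing_do_stays_missing(self, site, small_campaign):
        _, series, _, _ = small_campaign
        data = series.data.copy()
        drop = data.index[100:103]
        data = data.drop(drop)
        segs = dm.segment_days(dm.SondeSeries(site_id="ck", data=data), site)
        all_missing = sum(s.n_missing for s in segs)
        assert all_missing >= 3
        for s in segs:
            assert not np.isnan(s.temp).any()  # drivers gap-filled


class TestAttachK20Prior:
    def test_no_wind_gives_uniform_prior(self, site, small_campaign):
        _, series, _, _ = small_campaign
        seg = dm.segment_days(series, site)[0]
        seg = dm.attach_k20_prior(seg, None, site)
        assert seg.k20_prior == dm.Prior.uniform(0.0, 4.0)

    def test_zero_wind_mean_zero_with_floor_sd(self, site, small_campaign):
        _, series, _, _ = small_campaign
        seg = dm.segment_days(series, site)[0]
        seg = dm.attach_k20_prior(seg, {seg.date: 0.0}, site)
        assert seg.k20_prior.kind == "normal"
        assert seg.k20_prior.a == 0.0
        assert seg.k20_prior.b == 0.02

    def test_reference_wind_prior_mean(self, site, small_campaign):
        """u10 = 5 m/s over a 0.5-m mixed layer gives a 0.133 1/h prior mean."""
        _, series, _, _ = small_campaign
        seg = dm.segment_days(series, site)[0]
        seg = dm.attach_k20_prior(seg, {seg.date: 5.0}, site)
        assert seg.k20_prior.a == pytest.approx(0.133)
        assert seg.k20_prior.b == pytest.approx(0.3 * 0.133)
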