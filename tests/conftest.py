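import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dielmetab as dm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def site():
    """Tropical lake site (Tonle Sap, Chong Khneas), UTC+7, 0.5 m mixing depth."""
    return dm.SiteMeta(latitude_dd=13.2429, longitude_dd=103.8229,
                       utc_offset_h=7.0, mixing_depth_m=0.5, site_id="ck")


@pytest.fixture(scope="session")
def small_campaign(site):
    """5-day net-heterotrophic synthetic campaign with truth table."""
    spec = dm.tonle_sap_preset("net_heterotrophic", n_days=5, seed=3)
    series, winds, truth = dm.simulate_campaign(spec)
    return spec, series, winds, truth


@pytest.fixture(scope="session")
def fitted_day(site, small_campaign):
    """One usable day fitted with the reduced chain protocol."""
    _, series, winds, truth = small_campaign
    segs = dm.segment_days(series, site)
    wind_map = {w.date: w.u10_ms for w in winds}
    segs = [dm.attach_k20_prior(s, wind_map, site) for s in segs if s.usable]
    seg = segs[1]
    day = dm.StateSpaceDay.from_segment(seg)
    post = dm.fit_day(day, mcmc=dm.FAST_CHAINS, seed=11)
    return day, post, truth.loc[seg.date]


def make_simple_day(n=48, do=None, temp=30.0, qp=None, k20_prior=None):
    """Hand-built StateSpaceDay helper used across test modules."""
    if qp is None:
        qp = np.zeros(n)
        qp[10:34] = 1000.0
    if do is None:
        do = np.full(n, 5.0)
    temp_arr = np.full(n, float(temp)) if np.isscalar(temp) else np.asarray(temp)
    kwargs = {}
    if k20_prior is not None:
        kwargs["k20_prior"] = k20_prior
    return dm.StateSpaceDay(y=np.asarray(do, dtype=float), qp=np.asarray(qp, dtype=float),
                            temp=temp_arr, **kwargs)
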