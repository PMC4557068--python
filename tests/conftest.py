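import numpy as np
import pytest

from sedfire import AgeDepthModel, CharcoalRecord, SiteMeta
from sedfire.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def simple_record():
    """3 one-cm slices, 10 yr per cm, concentrations 10/0/30."""
    meta = SiteMeta(site_id="lake_a", lat=48.0, lon=-70.0, zone="boreal_mixedwood")
    model = AgeDepthModel(depths=[0.0, 3.0], ages=[0.0, 30.0])
    return CharcoalRecord(
        meta=meta,
        depth_top=[0.0, 1.0, 2.0],
        depth_bottom=[1.0, 2.0, 3.0],
        concentration=[10.0, 0.0, 30.0],
        age_model=model,
    )


def random_record(rng, site_id="site", zone="temperate", n=40):
    depths = np.sort(rng.uniform(0, 200, size=6))
    depths[0] = 0.0
    ages = np.cumsum(rng.uniform(50, 400, size=6))
    model = AgeDepthModel(depths=depths, ages=ages)
    spacing = (depths[-1] - depths[0]) / (n + 1)
    top = depths[0] + spacing * np.arange(n)
    bottom = top + spacing * rng.uniform(0.3, 0.9, size=n)
    conc = rng.gamma(1.0, 10.0, size=n)
    meta = SiteMeta(site_id=site_id, lat=45.0, lon=-72.0, zone=zone)
    return CharcoalRecord(meta=meta, depth_top=top, depth_bottom=bottom,
                          concentration=conc, age_model=model)


@pytest.fixture
def small_cfg():
    """A light synthetic configuration for fast generator tests."""
    return SynthConfig(
        seed=7,
        n_sites_per_zone=4,
        n_modern=25,
        record_depth_cm=160.0,
        control_spacing_cm=32.0,
        sed_rate_yr_per_cm=50.0,
        grid_res_deg=0.1,
        n_fossil_sites_per_zone=2,
        fossil_sample_spacing_yr=250.0,
    )
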