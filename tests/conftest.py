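import numpy as np
import pandas as pd
import pytest

import paleodark as pdk
from paleodark.synthetic import ChannelConfig, Scenario, TaxonHyperparams


@pytest.fixture(scope="session")
def stage_bins():
    return pdk.palaeozoic_stages()


@pytest.fixture(scope="session")
def subperiod_bins():
    return pdk.palaeozoic_subperiods()


@pytest.fixture(scope="session")
def small_scenario():
    """A quick scenario: 30 taxa, moderate sampling."""
    return Scenario(n_taxa=30)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    occ, spec, truth = pdk.simulate(small_scenario, seed=11)
    return occ, spec, truth


@pytest.fixture(scope="session")
def small_partition(small_dataset, stage_bins):
    occ, _, _ = small_dataset
    binned = pdk.assign_bins(occ, stage_bins)
    return pdk.partition(binned)


def make_occurrences(rows):
    """Build a canonical occurrence table from terse row dicts."""
    defaults = dict(species="", genus="", family="", rank="genus",
                    lon=0.0, lat=0.0, plon=0.0, plat=0.0,
                    max_ma=330.0, min_ma=320.0,
                    lithology="unknown", grainsize="unknown",
                    country_found="US", country_housed="US",
                    n_specimens=1, in_dark=False, in_published=True,
                    in_pbdb=False,
                    # pre-binned defaults so per-bin metrics run on fixtures
                    bin="Mississippian", bin_max_ma=358.9, bin_min_ma=323.2,
                    bin_mid_ma=(358.9 + 323.2) / 2)
    recs = []
    for i, r in enumerate(rows):
        rec = dict(defaults, occurrence_id=f"o{i}", collection_id=f"c{i}")
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def make_occ():
    return make_occurrences
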