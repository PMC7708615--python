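import dataclasses

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from diazoload import config, rates
from diazoload.monitoring_io import CANONICAL_COLUMNS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cfg():
    """Default Baltic station/basin/load configuration."""
    return config.load_config()


@pytest.fixture(scope="session")
def genus_rates():
    return rates.default_rates()


def make_samples(rows):
    """Tidy samples frame from (station, date, taxon, biovolume[, carbon, group])."""
    recs = []
    for row in rows:
        station, date, taxon, biovolume = row[:4]
        carbon = row[4] if len(row) > 4 else None
        group = row[5] if len(row) > 5 else None
        recs.append(
            dict(station=station, date=pd.Timestamp(date), depth_top=0.0,
                 depth_bottom=10.0, taxon=taxon, biovolume=biovolume,
                 carbon=carbon, group=group)
        )
    return pd.DataFrame(recs, columns=CANONICAL_COLUMNS)


def silence(params):
    """Noise-free copy of BloomParams."""
    return dataclasses.replace(params, noise_sigma=0.0, zero_inflation=0.0)


def silence_scenario(scenario):
    return dataclasses.replace(
        scenario,
        blooms={s: {g: silence(p) for g, p in d.items()} for s, d in scenario.blooms.items()},
        others={s: {g: silence(p) for g, p in d.items()} for s, d in scenario.others.items()},
    )
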