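import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cherisk.data_model import (CountryProfile, HealthService, IncomeGroup,
                                DiseaseGroup, InputBundle, OopShare,
                                OopShareTable, UtilizationEntry,
                                UtilizationTable, load_countries,
                                load_services, packaged_fixture_path)
from cherisk.synth import make_fixture_bundle

settings.register_profile(
    "suite", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_countries():
    return load_countries(packaged_fixture_path("table1_countries"))


@pytest.fixture(scope="session")
def service_catalog():
    return load_services(packaged_fixture_path("table3_services"))


@pytest.fixture(scope="session")
def fixture_bundle():
    """Packaged country/service tables with a seeded synthetic fill."""
    return make_fixture_bundle(seed=7)


def build_mini_bundle(oop_share_a=0.5, oop_share_b=0.8,
                      util_s1=(0.4, 0.5, 0.6, 0.7, 0.8),
                      util_s2=(0.3, 0.3, 0.3, 0.3, 0.3)):
    """Tiny hand-built two-country, two-service bundle for engine tests."""
    countries = {
        "AAA": CountryProfile("AAA", "Alphaland", IncomeGroup.LI, "West",
                              2015, 1000.0, 0.5),
        "BBB": CountryProfile("BBB", "Betaland", IncomeGroup.LMI, "East",
                              2014, 1500.0, 0.35),
    }
    services = {
        "S1": HealthService("S1", "costly care", "disease_a",
                            DiseaseGroup.ncd, 120.0, 150.0),
        "S2": HealthService("S2", "cheap care", "disease_b",
                            DiseaseGroup.childhood, 0.5, 0.8),
    }
    oop = OopShareTable({(c, "disease_a"): OopShare(oop_share_a)
                         for c in countries}
                        | {(c, "disease_b"): OopShare(oop_share_b)
                           for c in countries})
    util = UtilizationTable({(c, "S1"): UtilizationEntry(u=util_s1)
                             for c in countries}
                            | {(c, "S2"): UtilizationEntry(u=util_s2)
                               for c in countries})
    return InputBundle(countries, services, oop, util).validate()


@pytest.fixture()
def mini_bundle():
    return build_mini_bundle()
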