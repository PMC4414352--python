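import pytest
from hypothesis import HealthCheck, settings

import isoprov as ip

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def harappa_study():
    """Synthetic urban-site study: 13 fauna (9 local + 4 imports), 17
    all-immigrant individuals with sex-structured natal catchments."""
    return ip.simulate_study(ip.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def harappa_report(harappa_study):
    return ip.estimate_local_range(
        harappa_study["fauna"], site="Harappa", seed=7)


@pytest.fixture(scope="session")
def farmana_study():
    """Synthetic sediment-augmented site: 8 neighbouring-site fauna, 3
    sediment leachates, 17 migrants from a low-radiogenic Pb source."""
    return ip.simulate_study(ip.farmana_like_config(7))


@pytest.fixture(scope="session")
def farmana_range(farmana_study):
    rep = ip.estimate_local_range(
        farmana_study["fauna"], site="Rakhigarhi", seed=7)
    members = [s for s in rep.normalized.samples
               if s.sample_id in set(rep.local.member_ids)]
    return ip.pool_baseline(
        [members, farmana_study["sediments"]],
        source="Farmana: sediments + neighbouring local cluster")
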