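import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from microsearch import (
    Database,
    FeatureSpace,
    Profile,
    SimConfig,
    build_index,
    simulate_database,
)


def make_database(space: str, n_samples: int = 60, seed: int = 1, **kwargs):
    """A small clustered synthetic database plus its Database and index."""
    cfg = SimConfig(
        n_samples=n_samples,
        n_features=kwargs.pop("n_features", 120),
        seed=seed,
        feature_space=FeatureSpace(space),
        **kwargs,
    )
    synth = simulate_database(cfg)
    db = Database(
        synth.profiles, tree=synth.tree, lineages=synth.lineages, ko_map=synth.ko_map
    )
    index = build_index(
        synth.profiles, lineages=synth.lineages, ko_map=synth.ko_map
    )
    return synth, db, index


@pytest.fixture(scope="session")
def otu_db():
    return make_database("otu")


@pytest.fixture(scope="session")
def species_db():
    return make_database("species")


@pytest.fixture(scope="session")
def ko_db():
    return make_database("ko")


@pytest.fixture(scope="session", params=["otu", "species", "ko"])
def any_db(request, otu_db, species_db, ko_db):
    return {"otu": otu_db, "species": species_db, "ko": ko_db}[request.param]


@pytest.fixture
def ko_pair():
    a = Profile(FeatureSpace.KO, {"K00001": 0.7, "K00002": 0.3})
    b = Profile(FeatureSpace.KO, {"K00001": 0.5, "K00002": 0.5})
    return a, b
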