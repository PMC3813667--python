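import numpy as np
import pytest

from metaprox import (
    CommunitySpec,
    EnzymeProfile,
    ProfileCollection,
    kolenbrander_fixture,
    make_community,
)


@pytest.fixture(scope="session")
def fixture_model():
    return kolenbrander_fixture()


@pytest.fixture(scope="session")
def planted_community(fixture_model):
    """A planted-gradient community attached to the packaged biofilm map."""
    collection, model = make_community(CommunitySpec(seed=42), model=fixture_model)
    return collection, model


@pytest.fixture()
def tiny_collection():
    """Three small hand-written profiles with known pairwise overlaps."""
    return ProfileCollection(
        [
            EnzymeProfile("A", frozenset({"e1", "e2", "e3"})),
            EnzymeProfile("B", frozenset({"e2", "e3", "e4"})),
            EnzymeProfile("C", frozenset({"e5", "e6"})),
        ]
    )


def random_collection(n_organisms, n_features=30, p=0.4, seed=0, prefix="O"):
    """Independent random binary profiles (test helper)."""
    rng = np.random.default_rng(seed)
    feats = [f"f{i}" for i in range(n_features)]
    profiles = []
    for i in range(n_organisms):
        mask = rng.random(n_features) < p
        if not mask.any():
            mask[rng.integers(n_features)] = True
        profiles.append(
            EnzymeProfile(f"{prefix}{i}", frozenset(f for f, m in zip(feats, mask) if m))
        )
    return ProfileCollection(profiles)
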