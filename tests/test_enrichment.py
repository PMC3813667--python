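"""Layer profiles and pathway-by-layer enrichment."""

from fractions import Fraction

import numpy as np
import pytest

from metaprox import (
    BiofilmModel,
    CommunitySpec,
    EnzymeProfile,
    LayerProfile,
    PathwayMap,
    ProfileCollection,
    gsea_layer_enrichment,
    layer_profile,
    make_community,
    make_pathway_map,
    read_pathway_map,
    write_pathway_map,
)


@pytest.fixture()
def small_model():
    return BiofilmModel(
        layers=(frozenset({"A1", "A2", "A3"}), frozenset({"B1", "B2", "B3", "B4"}))
    )


@pytest.fixture()
def small_collection(small_model):
    feats = {
        "A1": {"e1", "e2", "s"},
        "A2": {"e1", "s"},
        "A3": {"e1", "e3", "s"},
        "B1": {"e4", "s"},
        "B2": {"e4", "e5", "s"},
        "B3": {"e4", "s"},
        "B4": {"e1", "s"},
    }
    return ProfileCollection(
        [EnzymeProfile(o, frozenset(f)) for o, f in feats.items()]
    )


class TestLayerProfile:
    def test_fractions_are_exact(self, small_model, small_collection):
        lp = layer_profile(small_model, small_collection, 1)
        assert lp.values["e1"] == Fraction(3, 3)
        assert lp.values["e2"] == Fraction(1, 3)
        assert lp.values["e4"] == Fraction(0)
        assert all(isinstance(v, Fraction) for v in lp.values.values())

    def test_one_of_four(self, small_model, small_collection):
        lp = layer_profile(small_model, small_collection, 2)
        assert lp.values["e5"] == Fraction(1, 4)
        assert lp.values["e1"] == Fraction(1, 4)

    def test_unknown_layer(self, small_model, small_collection):
        with pytest.raises(KeyError):
            layer_profile(small_model, small_collection, 5)

    def test_covers_full_universe(self, small_model, small_collection):
        lp = layer_profile(small_model, small_collection, 1)
        assert set(lp.values) == set(small_collection.universe)


class TestPathwayMapIO:
    def test_round_trip(self, tmp_path):
        pmap = PathwayMap({"P1": {"e1", "e2"}, "P2": {"e2", "e3", "e4"}})
        path = tmp_path / "pathways.tsv"
        write_pathway_map(pmap, path)
        back = read_pathway_map(path)
        assert dict(back.items()) == dict(pmap.items())

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            PathwayMap({"P1": set()})

    def test_malformed_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("P1\te1\nP2\n")
        with pytest.raises(ValueError, match=":2"):
            read_pathway_map(path)


def planted_setup(seed=0):
    """Community with a gradient plus one pathway planted in layer 2
    (purity 1: every planted enzyme is private to layer-2 organisms)."""
    spec = CommunitySpec(layer_sizes=(3, 3, 3), universe_size=300, seed=seed)
    coll, model = make_community(spec)
    planted = {"PW001": 2}
    pmap = make_pathway_map(
        coll.universe, n_pathways=10, planted=planted, model=model,
        collection=coll, seed=seed, planted_purity=1.0,
    )
    profiles = [layer_profile(model, coll, x) for x in (1, 2, 3)]
    return coll, model, pmap, profiles


class TestGSEA:
    def test_planted_pathway_recovered_in_its_layer_only(self):
        _, _, pmap, profiles = planted_setup(seed=1)
        res = gsea_layer_enrichment(profiles, pmap, n_perm=500, seed=3)
        t = res.table.set_index(["pathway", "layer"])
        assert bool(t.loc[("PW001", 2), "flag"])
        assert not t.loc[("PW001", 1), "flag"]
        assert not t.loc[("PW001", 3), "flag"]

    def test_constant_ranking_statistic_is_error(self):
        profiles = [
            LayerProfile(
                layer_index=x,
                values={f"e{i}": Fraction(1, 2) for i in range(10)},
                layer_size=2,
            )
            for x in (1, 2)
        ]
        pmap = PathwayMap({"P1": {f"e{i}" for i in range(5)}})
        with pytest.raises(ValueError, match="constant"):
            gsea_layer_enrichment(profiles, pmap, n_perm=100, seed=0)

    def test_small_pathway_excluded_with_warning(self):
        _, _, _, profiles = planted_setup(seed=2)
        pmap = PathwayMap({"tiny": {"E00001", "E00002"},
                           "ok": {f"E{i:05d}" for i in range(10)}})
        with pytest.warns(UserWarning, match="tiny"):
            res = gsea_layer_enrichment(profiles, pmap, n_perm=100, seed=0)
        assert set(res.table["pathway"]) == {"ok"}

    def test_duplicating_an_organism_leaves_scores_unchanged(self):
        """Adding a copy of a singleton layer's organism leaves B^(x) —
        and hence every enrichment score — unchanged."""
        spec = CommunitySpec(layer_sizes=(3, 1, 3), universe_size=300, seed=3)
        coll, model = make_community(spec)
        pmap = make_pathway_map(coll.universe, n_pathways=8, seed=3)
        profiles = [layer_profile(model, coll, x) for x in (1, 2, 3)]
        member = next(iter(model.layers[1]))
        dup = EnzymeProfile("DUP", coll[member].features)
        coll2 = ProfileCollection(list(coll) + [dup])
        layers2 = tuple(
            layer | {"DUP"} if i == 1 else layer
            for i, layer in enumerate(model.layers)
        )
        model2 = BiofilmModel(layers=layers2)
        profiles2 = [layer_profile(model2, coll2, x) for x in (1, 2, 3)]
        assert profiles2[1].values == profiles[1].values
        r1 = gsea_layer_enrichment(profiles, pmap, n_perm=100, seed=5)
        r2 = gsea_layer_enrichment(profiles2, pmap, n_perm=100, seed=5)
        np.testing.assert_allclose(r1.table["es"], r2.table["es"])

    def test_deterministic_under_seed(self):
        _, _, pmap, profiles = planted_setup(seed=4)
        r1 = gsea_layer_enrichment(profiles, pmap, n_perm=200, seed=7)
        r2 = gsea_layer_enrichment(profiles, pmap, n_perm=200, seed=7)
        assert r1.table.equals(r2.table)

    def test_flag_thresholds(self):
        _, _, pmap, profiles = planted_setup(seed=5)
        res = gsea_layer_enrichment(profiles, pmap, n_perm=200, seed=1)
        t = res.table
        assert ((t["pvalue"] <= 0.05) & (t["qvalue"] < 0.25)).equals(t["flag"])
        assert t["pvalue"].between(0, 1).all()
        assert t["qvalue"].between(0, 1).all()


def test_null_calibration_nominal_rate():
    """With no planted structure, ~5% of pathway x layer tests reach
    nominal p <= 0.05 (averaged over many simulated communities)."""
    rejects = 0
    total = 0
    for seed in range(300):
        spec = CommunitySpec(
            layer_sizes=(2, 2), universe_size=80, gradient=0.4, seed=seed
        )
        coll, model = make_community(spec)
        pmap = make_pathway_map(coll.universe, n_pathways=4, seed=seed + 1,
                                size_range=(4, 8))
        profiles = [layer_profile(model, coll, x) for x in (1, 2)]
        res = gsea_layer_enrichment(profiles, pmap, n_perm=150, seed=seed + 2,
                                    min_pathway_size=3)
        rejects += int((res.table["pvalue"] <= 0.05).sum())
        total += len(res.table)
    rate = rejects / total
    assert 0.025 <= rate <= 0.075
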