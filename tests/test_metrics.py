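import numpy as np
import pytest

from foodwebs.core import FoodWebError, SpeciesRecord, web_from_links
from foodwebs.metrics import (
    METRIC_NAMES,
    chain_lengths,
    compute_all,
    degree_stats,
    foundation_importance,
    graph_metrics,
    guild_fractions,
    max_similarity,
    metrics_table,
    similarity_matrix,
    trophic_fractions,
    trophic_levels,
)
from foodwebs.synth import niche_model_web

from conftest import random_web
from oracles import (
    bf_clustering,
    bf_compartmentalization,
    bf_max_similarity,
    bf_path_length,
    bf_similarity_matrix,
)

# hand-computed expectations for the two toy webs
W3_EXPECTED = {
    "species_number": 3, "link_density": 2 / 3, "connectance": 2 / 9,
    "vulnerability": 2 / 3, "generality": 2 / 3, "links": 4 / 3,
    "top_fraction": 1 / 3, "intermediate_fraction": 1 / 3, "basal_fraction": 1 / 3,
    "herbivore_fraction": 1 / 3, "omnivore_fraction": 0.0, "carnivore_fraction": 1 / 3,
    "cannibal_fraction": 0.0, "chain_length": 1.0, "trophic_level": 2.0,
    "max_similarity": 0.0, "clustering": 0.0, "path_length": 4 / 3,
    "compartmentalization": 1 / 3,
}
W4_EXPECTED = {
    "species_number": 3, "link_density": 4 / 3, "connectance": 4 / 9,
    "vulnerability": 1.0, "generality": 4 / 3, "links": 7 / 3,
    "top_fraction": 1 / 3, "intermediate_fraction": 1 / 3, "basal_fraction": 1 / 3,
    "herbivore_fraction": 1 / 3, "omnivore_fraction": 1 / 3, "carnivore_fraction": 0.0,
    "cannibal_fraction": 1 / 3, "chain_length": 2 / 3, "trophic_level": 11 / 6,
}


class TestToyWebs:
    @pytest.mark.parametrize("name,expected", sorted(W3_EXPECTED.items()))
    def test_chain_metrics(self, w3, name, expected):
        assert getattr(compute_all(w3), name) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("name,expected", sorted(W4_EXPECTED.items()))
    def test_omnivore_cannibal_metrics(self, w4, name, expected):
        assert getattr(compute_all(w4), name) == pytest.approx(expected, abs=1e-12)

    def test_w4_self_link_conventions(self, w4):
        # O's only predator is itself, so O counts as a top species,
        # while the self-link still shows up in L, C and generality.
        tf = trophic_fractions(w4)
        assert tf["top"] == pytest.approx(1 / 3)
        d = degree_stats(w4)
        assert d["L"] == 4 and d["generality"] == pytest.approx(4 / 3)

    def test_fully_connected_no_self(self):
        ids = list("ABCD")
        web = web_from_links([(a, b) for a in ids for b in ids if a != b])
        assert degree_stats(web)["connectance"] == pytest.approx(12 / 16)

    def test_star_fractions(self):
        web = web_from_links([("P", "H1"), ("P", "H2")])
        tf = trophic_fractions(web)
        assert tf == {"top": 2 / 3, "intermediate": 0.0, "basal": 1 / 3}

    def test_all_consumers_on_one_basal(self):
        web = web_from_links([("B", f"c{k}") for k in range(5)])
        _, mean = chain_lengths(web)
        assert mean == pytest.approx(5 / 6)  # (S-1)/S

    def test_triangle_graph_metrics(self):
        web = web_from_links([("A", "B"), ("B", "C"), ("A", "C")])
        gm = graph_metrics(web)
        assert gm["clustering"] == 1.0 and gm["path_length"] == 1.0


class TestErrors:
    def test_empty_web(self):
        web = web_from_links([], species=["A"], allow_isolated=True)
        empty = web_from_links([])
        with pytest.raises(FoodWebError):
            degree_stats(empty)

    def test_consumer_loop_without_basal(self):
        web = web_from_links([("H1", "H2"), ("H2", "H1")])
        with pytest.raises(FoodWebError, match="H1"):
            trophic_levels(web)
        with pytest.raises(FoodWebError):
            chain_lengths(web)

    def test_similarity_needs_two_species(self):
        web = web_from_links([("A", "A")])
        with pytest.raises(FoodWebError):
            max_similarity(web)


class TestOracles:
    """Brute-force enumeration oracles on random webs with S <= 8."""

    @pytest.mark.parametrize("seed", range(4))
    def test_structural_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            web = random_web(rng)
            gm = graph_metrics(web)
            assert gm["path_length"] == pytest.approx(bf_path_length(web))
            assert gm["compartmentalization"] == pytest.approx(bf_compartmentalization(web))
            assert gm["clustering"] == pytest.approx(bf_clustering(web))
            assert max_similarity(web) == pytest.approx(bf_max_similarity(web))

    def test_similarity_symmetric_unit_interval(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            web = random_web(rng)
            mat = similarity_matrix(web)
            ref = bf_similarity_matrix(web)
            assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
            assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()
            for (a, b), v in ref.items():
                assert mat.loc[a, b] == pytest.approx(v)

    def test_identical_consumers_have_similarity_one(self):
        web = web_from_links(
            [("P", "C1"), ("P", "C2"), ("C1", "T"), ("C2", "T")]
        )
        assert similarity_matrix(web).loc["C1", "C2"] == 1.0


class TestIdentities:
    @pytest.mark.parametrize("seed", range(3))
    def test_partition_and_degree_identities(self, seed):
        for k in range(30):
            web = niche_model_web(15, 0.15, seed=seed * 1000 + k)
            tf = trophic_fractions(web)
            gf = guild_fractions(web)
            d = degree_stats(web)
            n_self = sum(1 for a, b in web.links if a == b)
            assert tf["top"] + tf["intermediate"] + tf["basal"] == pytest.approx(1, abs=1e-12)
            assert gf["herbivore"] + gf["omnivore"] + gf["carnivore"] == pytest.approx(
                1 - tf["basal"], abs=1e-12
            )
            assert d["generality"] == pytest.approx(d["link_density"])
            assert d["vulnerability"] == pytest.approx((d["L"] - n_self) / d["S"])
            assert d["connectance"] == pytest.approx(d["link_density"] / d["S"])

    def test_consumer_trophic_level_at_least_two(self):
        web = niche_model_web(20, 0.15, seed=5)
        levels, mean = trophic_levels(web)
        assert mean >= 1
        for sid, tl in levels.items():
            if web.prey_of(sid, include_self=False):
                assert tl >= 2 - 1e-9
            else:
                assert tl == pytest.approx(1)

    def test_relabelling_invariance(self):
        web = niche_model_web(12, 0.2, seed=3)
        mapping = {s: f"new_{i}" for i, s in enumerate(reversed(web.species_ids))}
        relabelled = web_from_links(
            [(mapping[a], mapping[b]) for a, b in web.links]
        )
        a = compute_all(web).as_dict()
        b = compute_all(relabelled).as_dict()
        for name in METRIC_NAMES:
            assert a[name] == pytest.approx(b[name]), name

    def test_compute_all_matches_components(self, w4):
        vec = compute_all(w4)
        assert vec.connectance == degree_stats(w4)["connectance"]
        assert vec.max_similarity == max_similarity(w4)
        assert vec.clustering == graph_metrics(w4)["clustering"]


class TestFoundationImportance:
    def test_ratio_example(self):
        # foundation F has 1 predator; other three species average 2
        sp = [SpeciesRecord("F", is_foundation=True)] + [SpeciesRecord(s) for s in "ABC"]
        links = [("F", "A"), ("A", "B"), ("A", "C"), ("B", "C"), ("B", "A"), ("C", "B"), ("C", "A")]
        web = web_from_links(links, species=sp)
        imp = foundation_importance(web)
        assert imp["fs_vulnerability"] / imp["other_mean_vulnerability"] == pytest.approx(0.5)

    def test_missing_foundation_errors(self, w3):
        with pytest.raises(FoodWebError):
            foundation_importance(w3)

    def test_single_species_errors(self):
        sp = [SpeciesRecord("F", is_foundation=True)]
        web = web_from_links([("F", "F")], species=sp)
        with pytest.raises(FoodWebError):
            foundation_importance(web)

    def test_basal_comparison_reported(self):
        sp = [SpeciesRecord("F", is_foundation=True), SpeciesRecord("B2"),
              SpeciesRecord("C1"), SpeciesRecord("C2")]
        links = [("F", "C1"), ("B2", "C1"), ("B2", "C2"), ("C1", "C2")]
        web = web_from_links(links, species=sp)
        imp = foundation_importance(web)
        assert imp["fs_basal_links"] == 1.0
        assert imp["other_basal_mean_links"] == 2.0


def test_metrics_table_shape(w3, w4):
    t = metrics_table([w3.with_meta(ecosystem="e", replicate="1"),
                       w4.with_meta(ecosystem="e", web_type="BA", replicate="1")])
    assert list(t.columns[:3]) == ["ecosystem", "web_type", "replicate"]
    assert t.shape == (2, 3 + 19)
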