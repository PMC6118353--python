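import numpy as np
import pytest

from foodwebs.core import FoodWebError
from foodwebs.metrics import chain_lengths, foundation_importance, trophic_levels
from foodwebs.synth import (
    SynthConfig,
    generate_study,
    make_ecosystem_pair,
    niche_model_web,
    simulate_isotopes,
)


class TestNicheModel:
    def test_connectance_calibration(self):
        cs = [
            niche_model_web(25, 0.15, seed=s).n_links / 25**2 for s in range(150)
        ]
        assert np.mean(cs) == pytest.approx(0.15, abs=0.02)

    def test_constructive_guarantees(self):
        for s in range(30):
            web = niche_model_web(20, 0.12, seed=s)
            basal = [x for x in web.species_ids if not web.prey_of(x, include_self=False)]
            assert basal
            linked = {x for l in web.links for x in l}
            assert linked == set(web.species_ids)
            chain_lengths(web)  # every species rooted in a basal resource
            trophic_levels(web)

    def test_seed_determinism(self):
        assert niche_model_web(15, 0.2, seed=9).links == niche_model_web(15, 0.2, seed=9).links

    def test_invalid_parameters(self):
        with pytest.raises(FoodWebError):
            niche_model_web(2, 0.2)
        with pytest.raises(FoodWebError):
            niche_model_web(10, 0.6)


@pytest.fixture(scope="module")
def pair():
    return make_ecosystem_pair(SynthConfig(seed=1), 0, seed=0)


class TestEcosystemPair:
    def test_paired_replicates(self, pair):
        fs, ba, diets = pair
        assert len(fs) == len(ba)
        assert 3 <= len(fs) <= 6

    def test_ba_subset_of_fs(self, pair):
        fs, ba, _ = pair
        for f, b in zip(fs, ba):
            assert set(b.species_ids) <= set(f.species_ids)
            kept = set(b.species_ids)
            assert b.links == {(x, y) for x, y in f.links if x in kept and y in kept}
            assert b.web_type == "BA" and f.web_type == "FS"

    def test_foundation_basal_and_weakly_linked(self, pair):
        fs, ba, _ = pair
        for f, b in zip(fs, ba):
            fnd = f.foundation
            assert fnd is not None
            assert not f.prey_of(fnd.id, include_self=False)  # basal
            # the foundation species never occurs in its paired bare area
            assert fnd.id not in set(b.species_ids)

    def test_foundation_links_below_average(self):
        # weakly linked by construction: below the network mean in nearly
        # every draw (mirrors the ~half link budget of the generator)
        hits = 0
        n = 60
        for k in range(n):
            fs, _, _ = make_ecosystem_pair(
                SynthConfig(seed=100 + k, reps_per_ecosystem=(1,), n_ecosystems=1), 0, seed=0
            )
            imp = foundation_importance(fs[0])
            hits += imp["fs_links"] < imp["other_mean_links"]
        assert hits / n > 0.95

    def test_counts_present_with_rare_tail(self, pair):
        fs, _, _ = pair
        counts = [sp.count for f in fs for sp in f.species]
        assert all(c is not None and c >= 0 for c in counts)
        assert any(c < 3 for c in counts)  # some rare species exist


class TestIsotopes:
    def test_single_prey_consumer_exact_enrichment(self):
        from foodwebs.core import web_from_links

        cfg = SynthConfig(seed=0, noise_sd=0.0, n_samples=2)
        web = web_from_links([("B", "C")])
        out, diets = simulate_isotopes(web, cfg, seed=4)
        b = out.species_by_id("B")
        c = out.species_by_id("C")
        assert c.d13C[0] == pytest.approx(b.d13C[0] + cfg.tef.delta_d13C, abs=1e-3)
        assert c.d15N[0] == pytest.approx(b.d15N[0] + cfg.tef.delta_d15N, abs=1e-3)
        assert set(diets) == {"C"}
        assert diets["C"]["B"] == pytest.approx(1.0)

    def test_true_diets_on_simplex(self):
        web = niche_model_web(20, 0.15, seed=2)
        _, diets = simulate_isotopes(web, SynthConfig(seed=0), seed=1)
        for consumer, props in diets.items():
            assert sum(props.values()) == pytest.approx(1.0)
            assert all(0 <= v <= 1 for v in props.values())
            assert set(props) == web.prey_of(consumer, include_self=False)

    def test_d15n_increases_with_trophic_level(self):
        cfg = SynthConfig(seed=0, noise_sd=0.1)
        slopes = []
        for s in range(10):
            web = niche_model_web(25, 0.15, seed=200 + s)
            out, _ = simulate_isotopes(web, cfg, seed=s)
            levels, _ = trophic_levels(out)
            tl = np.array([levels[x] for x in out.species_ids])
            n15 = np.array([np.mean(out.species_by_id(x).d15N) for x in out.species_ids])
            slopes.append(np.polyfit(tl, n15, 1)[0])
        assert np.mean(slopes) == pytest.approx(cfg.tef.delta_d15N, abs=0.5)


class TestGenerateStudy:
    def test_count_contract(self):
        study = generate_study(SynthConfig(seed=3, reps_per_ecosystem=(5, 4, 4, 4, 4, 4, 4)))
        assert len(study.design.webs("FS")) == 29
        assert len(study.design.webs("BA")) == 29
        assert len(study.design.ecosystems) == 7

    def test_mean_fs_richness_near_target(self):
        sizes = []
        for s in range(8):
            study = generate_study(SynthConfig(seed=s, n_ecosystems=2))
            sizes += [w.n_species for w in study.design.webs("FS")]
        assert np.mean(sizes) == pytest.approx(25, abs=2)

    def test_deterministic_per_seed(self):
        a = generate_study(SynthConfig(seed=5, n_ecosystems=2))
        b = generate_study(SynthConfig(seed=5, n_ecosystems=2))
        for wa, wb in zip(a.design.webs(), b.design.webs()):
            assert wa.links == wb.links and wa.species == wb.species
        assert a.true_diets == b.true_diets

    def test_targeted_mode_shifts_guild_composition(self):
        from foodwebs.metrics import metrics_table

        rnd = generate_study(SynthConfig(seed=4, n_ecosystems=3, facilitation_mode="random"))
        tgt = generate_study(SynthConfig(seed=4, n_ecosystems=3, facilitation_mode="targeted"))
        mr = metrics_table(rnd.design.webs("BA"))
        mt = metrics_table(tgt.design.webs("BA"))
        # facilitation weights: basal weakly facilitated (retained in bare),
        # carnivores strongly facilitated (lost from bare)
        assert mt["basal_fraction"].mean() > mr["basal_fraction"].mean()
        assert mt["carnivore_fraction"].mean() < mr["carnivore_fraction"].mean()
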