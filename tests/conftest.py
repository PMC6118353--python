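import pytest

from foodwebs.core import SpeciesRecord, web_from_links


@pytest.fixture
def w3():
    """Three-species chain A -> B -> C."""
    return web_from_links([("A", "B"), ("B", "C")])


@pytest.fixture
def w4():
    """Basal plant P, herbivore H, cannibalistic omnivore O."""
    return web_from_links([("P", "H"), ("P", "O"), ("H", "O"), ("O", "O")])


@pytest.fixture
def counted_chain():
    """Chain with abundance counts for the rare-species filter."""
    species = [
        SpeciesRecord("A", count=10),
        SpeciesRecord("B", count=2),
        SpeciesRecord("C", count=5),
    ]
    return web_from_links([("A", "B"), ("B", "C")], species=species)


def random_web(rng, s_max=8, p=0.3, allow_self=True):
    """Small random directed web for oracle comparisons (>=1 link)."""
    while True:
        S = int(rng.integers(3, s_max + 1))
        ids = [f"x{k}" for k in range(S)]
        links = [
            (a, b)
            for a in ids
            for b in ids
            if (a != b or allow_self) and rng.random() < p
        ]
        if links and len({s for l in links for s in l}) >= 2:
            return web_from_links(links)
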