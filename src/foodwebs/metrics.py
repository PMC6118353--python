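"""The 19-metric food-web topology suite.

All metrics operate on a dichotomous web (see :mod:`foodwebs.core`) and
follow the standard conventions of the empirical food-web literature
(Williams & Martinez / Dunne style):

* ``L`` counts every link including self-links (cannibalism), so
  connectance is ``L / S**2`` and generality (mean prey per species)
  equals link density exactly.
* Self-links are excluded from vulnerability, the top/intermediate/basal
  partition, feeding-guild classification, trophic levels, chain lengths,
  trophic similarity and the undirected graph metrics; they are what the
  cannibal fraction counts.
* Basal species are defined purely topologically: no prey once self-links
  are ignored.  The foundation species receives no special treatment.

Per-species intermediates (trophic levels, chain lengths, similarity
matrix) are exposed so they can be tested against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import FoodWeb, FoodWebError

__all__ = [
    "MetricVector",
    "METRIC_NAMES",
    "degree_stats",
    "trophic_fractions",
    "guild_fractions",
    "trophic_levels",
    "chain_lengths",
    "max_similarity",
    "similarity_matrix",
    "graph_metrics",
    "compute_all",
    "foundation_importance",
    "metrics_table",
]


@dataclass(frozen=True)
class MetricVector:
    """The 19 topology metrics of one web, in conventional report order."""

    species_number: float
    link_density: float
    connectance: float
    vulnerability: float
    generality: float
    links: float
    top_fraction: float
    intermediate_fraction: float
    basal_fraction: float
    herbivore_fraction: float
    omnivore_fraction: float
    carnivore_fraction: float
    cannibal_fraction: float
    chain_length: float
    trophic_level: float
    max_similarity: float
    clustering: float
    path_length: float
    compartmentalization: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


METRIC_NAMES: tuple[str, ...] = tuple(f.name for f in dc_fields(MetricVector))


def _check_nonempty(web: FoodWeb) -> None:
    if web.n_species == 0:
        raise FoodWebError("metric undefined on an empty web")


def _basal_set(web: FoodWeb) -> set[str]:
    return {sid for sid in web.species_ids if not web.prey_of(sid, include_self=False)}


def degree_stats(web: FoodWeb) -> dict[str, float]:
    """Size, link density, connectance and the three degree means.

    Generality is the mean in-degree (prey per species) with self-links
    counted, hence exactly ``L/S``; vulnerability is the mean out-degree
    (predators per species) with self-links excluded; ``links`` is the
    mean number of distinct links a species participates in, a self-link
    touching its species once.
    """
    _check_nonempty(web)
    S = web.n_species
    L = web.n_links
    n_self = sum(1 for a, b in web.links if a == b)
    return {
        "S": S,
        "L": L,
        "link_density": L / S,
        "connectance": L / S**2,
        "generality": L / S,
        "vulnerability": (L - n_self) / S,
        "links": (2 * L - n_self) / S,
    }


def trophic_fractions(web: FoodWeb) -> dict[str, float]:
    """Fractions of top, intermediate and basal species (self-links ignored)."""
    _check_nonempty(web)
    S = web.n_species
    basal = top = inter = 0
    for sid in web.species_ids:
        has_prey = bool(web.prey_of(sid, include_self=False))
        has_pred = bool(web.predators_of(sid, include_self=False))
        if not has_prey:
            basal += 1
        elif has_pred:
            inter += 1
        else:
            top += 1
    return {"top": top / S, "intermediate": inter / S, "basal": basal / S}


def guild_fractions(web: FoodWeb) -> dict[str, float]:
    """Feeding-guild fractions among all species (self-links ignored).

    Consumers (non-basal species) split into herbivores (all prey basal),
    carnivores (no prey basal) and omnivores (both); the cannibal fraction
    is the share of species with a self-link.
    """
    _check_nonempty(web)
    S = web.n_species
    basal = _basal_set(web)
    herb = omn = carn = 0
    for sid in web.species_ids:
        prey = web.prey_of(sid, include_self=False)
        if not prey:
            continue
        n_basal_prey = len(prey & basal)
        if n_basal_prey == len(prey):
            herb += 1
        elif n_basal_prey == 0:
            carn += 1
        else:
            omn += 1
    cannibals = sum(1 for a, b in web.links if a == b)
    return {
        "herbivore": herb / S,
        "omnivore": omn / S,
        "carnivore": carn / S,
        "cannibal": cannibals / S,
    }


def trophic_levels(web: FoodWeb) -> tuple[dict[str, float], float]:
    """Prey-averaged trophic levels, solved exactly.

    ``TL = 1`` for basal species; for consumers ``TL_i = 1 + mean(TL of
    prey of i)`` with self-links excluded, solved simultaneously as a
    linear system so that feeding loops are handled.  Returns the
    per-species levels and their mean.
    """
    _check_nonempty(web)
    ids = list(web.species_ids)
    idx = {s: k for k, s in enumerate(ids)}
    S = len(ids)
    A = np.eye(S)
    for i, sid in enumerate(ids):
        prey = web.prey_of(sid, include_self=False)
        if prey:
            for p in prey:
                A[i, idx[p]] -= 1.0 / len(prey)
    b = np.ones(S)
    try:
        tl = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        tl = np.full(S, np.nan)
    if not np.all(np.isfinite(tl)) or np.max(np.abs(A @ tl - b)) > 1e-8:
        comp = _unsupported_component(web)
        raise FoodWebError(
            "trophic levels undefined: consumer cycle with no basal input "
            f"involving species {sorted(comp)}"
        )
    levels = {sid: float(tl[idx[sid]]) for sid in ids}
    return levels, float(tl.mean())


def _unsupported_component(web: FoodWeb) -> set[str]:
    """A strongly connected consumer cycle with no directed path from basal."""
    g = nx.DiGraph()
    g.add_nodes_from(web.species_ids)
    g.add_edges_from((a, b) for a, b in web.links if a != b)
    basal = _basal_set(web)
    reachable = set(basal)
    for b in basal:
        reachable |= nx.descendants(g, b)
    bad = set(web.species_ids) - reachable
    for scc in nx.strongly_connected_components(g.subgraph(bad)):
        if len(scc) > 1:
            return set(scc)
    return bad


def chain_lengths(web: FoodWeb) -> tuple[dict[str, float], float]:
    """Shortest chain (number of feeding links) from each species down to
    a basal species; basal species score 0.  Multi-source BFS upward from
    the basal set along prey->predator links, self-links ignored.
    """
    _check_nonempty(web)
    basal = _basal_set(web)
    up: dict[str, set[str]] = {s: set() for s in web.species_ids}  # prey -> predators
    for a, b in web.links:
        if a != b:
            up[a].add(b)
    dist = {s: 0 for s in basal}
    frontier = list(basal)
    while frontier:
        nxt = []
        for s in frontier:
            for t in up[s]:
                if t not in dist:
                    dist[t] = dist[s] + 1
                    nxt.append(t)
        frontier = nxt
    missing = set(web.species_ids) - set(dist)
    if missing:
        raise FoodWebError(
            f"no path to a basal species for {sorted(missing)}; chain length undefined"
        )
    chains = {s: float(dist[s]) for s in web.species_ids}
    return chains, float(np.mean(list(chains.values())))


def similarity_matrix(web: FoodWeb) -> pd.DataFrame:
    """Pairwise trophic similarity ``s_ij`` (self-links excluded).

    ``s_ij`` = (shared prey + shared predators) / (distinct prey +
    distinct predators of the pair); 0 when the pair has no partners.
    """
    ids = list(web.species_ids)
    prey = {s: web.prey_of(s, include_self=False) for s in ids}
    pred = {s: web.predators_of(s, include_self=False) for s in ids}
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            denom = len(prey[a] | prey[b]) + len(pred[a] | pred[b])
            num = len(prey[a] & prey[b]) + len(pred[a] & pred[b])
            s = num / denom if denom else 0.0
            mat.loc[a, b] = mat.loc[b, a] = s
        mat.loc[a, a] = 1.0
    return mat


def max_similarity(web: FoodWeb) -> float:
    """Mean over species of the maximum trophic similarity to any other."""
    if web.n_species < 2:
        raise FoodWebError("max_similarity needs at least 2 species")
    mat = similarity_matrix(web).to_numpy(copy=True)
    np.fill_diagonal(mat, -np.inf)
    return float(mat.max(axis=1).mean())


def _undirected(web: FoodWeb) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(web.species_ids)
    g.add_edges_from((a, b) for a, b in web.links if a != b)
    return g


def graph_metrics(web: FoodWeb) -> dict[str, float]:
    """Clustering, mean path length and compartmentalization.

    Computed on the undirected simple projection with self-links dropped.
    Path length averages shortest paths over connected ordered pairs only,
    so it stays finite on fragmented webs.  Compartmentalization is the
    mean over unordered species pairs of the Jaccard overlap of their
    neighbour sets, the focal pair removed from both sets; pairs with an
    empty union contribute 0.
    """
    if web.n_species < 2:
        raise FoodWebError("graph metrics need at least 2 species")
    g = _undirected(web)
    clustering = float(np.mean(list(nx.clustering(g).values())))
    dists = []
    for src, dd in nx.all_pairs_shortest_path_length(g):
        dists.extend(d for tgt, d in dd.items() if tgt != src)
    path_length = float(np.mean(dists)) if dists else 0.0
    nodes = list(g.nodes)
    overlaps = []
    for i, a in enumerate(nodes):
        na = set(g[a])
        for b in nodes[i + 1 :]:
            nb = set(g[b])
            ua = na - {a, b}
            ub = nb - {a, b}
            union = ua | ub
            overlaps.append(len(ua & ub) / len(union) if union else 0.0)
    return {
        "clustering": clustering,
        "path_length": path_length,
        "compartmentalization": float(np.mean(overlaps)),
    }


def compute_all(web: FoodWeb) -> MetricVector:
    """Compute the full 19-metric panel for one web."""
    try:
        deg = degree_stats(web)
        tf = trophic_fractions(web)
        gf = guild_fractions(web)
        _, mean_chain = chain_lengths(web)
        _, mean_tl = trophic_levels(web)
        msim = max_similarity(web)
        gm = graph_metrics(web)
    except FoodWebError:
        raise
    return MetricVector(
        species_number=float(deg["S"]),
        link_density=deg["link_density"],
        connectance=deg["connectance"],
        vulnerability=deg["vulnerability"],
        generality=deg["generality"],
        links=deg["links"],
        top_fraction=tf["top"],
        intermediate_fraction=tf["intermediate"],
        basal_fraction=tf["basal"],
        herbivore_fraction=gf["herbivore"],
        omnivore_fraction=gf["omnivore"],
        carnivore_fraction=gf["carnivore"],
        cannibal_fraction=gf["cannibal"],
        chain_length=mean_chain,
        trophic_level=mean_tl,
        max_similarity=msim,
        clustering=gm["clustering"],
        path_length=gm["path_length"],
        compartmentalization=gm["compartmentalization"],
    )


def foundation_importance(web: FoodWeb) -> dict[str, float]:
    """Trophic importance of the foundation species relative to the rest.

    Reports the foundation species' vulnerability (number of predators,
    self-links excluded) and total link count against the means over all
    other species, and — when the foundation species is basal — its link
    count against the mean over the other basal species (for basal
    species the link count equals vulnerability).
    """
    fs = web.foundation
    if fs is None:
        raise FoodWebError("web has no foundation species flagged")
    others = [sid for sid in web.species_ids if sid != fs.id]
    if not others:
        raise FoodWebError("no other species to compare the foundation species against")

    def vuln(sid: str) -> int:
        return len(web.predators_of(sid, include_self=False))

    def nlinks(sid: str) -> int:
        return sum(1 for a, b in web.links if sid in (a, b))

    out = {
        "fs_vulnerability": float(vuln(fs.id)),
        "other_mean_vulnerability": float(np.mean([vuln(s) for s in others])),
        "fs_links": float(nlinks(fs.id)),
        "other_mean_links": float(np.mean([nlinks(s) for s in others])),
        "fs_basal_links": np.nan,
        "other_basal_mean_links": np.nan,
    }
    basal = _basal_set(web)
    other_basal = [s for s in basal if s != fs.id]
    if fs.id in basal:
        out["fs_basal_links"] = float(nlinks(fs.id))
        if other_basal:
            out["other_basal_mean_links"] = float(np.mean([nlinks(s) for s in other_basal]))
    return out


def metrics_table(webs: Sequence[FoodWeb]) -> pd.DataFrame:
    """One row per web: ecosystem, web_type, replicate plus the 19 metrics."""
    rows = []
    for w in webs:
        row = {"ecosystem": w.ecosystem, "web_type": w.web_type, "replicate": w.replicate}
        row.update(compute_all(w).as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["ecosystem", "web_type", "replicate", *METRIC_NAMES])
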