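"""Brute-force reference implementations used only to check the package.

These deliberately re-derive each quantity from its definition with
plain loops and no graph library, so they stay independent of the code
paths they validate.
"""

from itertools import combinations


def undirected_neighbours(web):
    nb = {s: set() for s in web.species_ids}
    for a, b in web.links:
        if a != b:
            nb[a].add(b)
            nb[b].add(a)
    return nb


def bf_path_length(web):
    """Mean shortest path over connected ordered pairs (undirected, no self)."""
    nb = undirected_neighbours(web)
    dists = []
    for src in web.species_ids:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in nb[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        dists.extend(d for t, d in dist.items() if t != src)
    return sum(dists) / len(dists) if dists else 0.0


def bf_compartmentalization(web):
    """Mean pairwise neighbour overlap, focal pair excluded from both sets."""
    nb = undirected_neighbours(web)
    vals = []
    for a, b in combinations(web.species_ids, 2):
        na = nb[a] - {a, b}
        nbb = nb[b] - {a, b}
        union = na | nbb
        vals.append(len(na & nbb) / len(union) if union else 0.0)
    return sum(vals) / len(vals)


def bf_similarity_matrix(web):
    """Pairwise trophic similarity from its set definition."""
    prey = {s: {a for a, b in web.links if b == s and a != s} for s in web.species_ids}
    pred = {s: {b for a, b in web.links if a == s and b != s} for s in web.species_ids}
    out = {}
    for a, b in combinations(web.species_ids, 2):
        denom = len(prey[a] | prey[b]) + len(pred[a] | pred[b])
        num = len(prey[a] & prey[b]) + len(pred[a] & pred[b])
        out[(a, b)] = num / denom if denom else 0.0
    return out


def bf_max_similarity(web):
    mat = bf_similarity_matrix(web)
    best = {s: 0.0 for s in web.species_ids}
    for (a, b), v in mat.items():
        best[a] = max(best[a], v)
        best[b] = max(best[b], v)
    return sum(best.values()) / len(best)


def bf_clustering(web):
    """Mean local clustering coefficient; degree < 2 contributes 0."""
    nb = undirected_neighbours(web)
    vals = []
    for s, ns in nb.items():
        k = len(ns)
        if k < 2:
            vals.append(0.0)
            continue
        closed = sum(1 for u, v in combinations(ns, 2) if v in nb[u])
        vals.append(closed / (k * (k - 1) / 2))
    return sum(vals) / len(vals)
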