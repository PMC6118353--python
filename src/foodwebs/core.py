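"""Food-web data model, validation, and file I/O.

A food web is stored as a *dichotomous* (unweighted, directed) trophic
network: a set of species plus a set of directed links oriented
prey -> predator.  Self-links (cannibalism) are allowed.  Species carry
the metadata the downstream stages need: abundance counts for the
rare-species filter, a foundation-species flag, and replicate stable
isotope measurements (delta-13C / delta-15N, in permil) for the diet
mixing model.

File formats (all plain CSV, comma-separated, UTF-8, with header):

* edge list       -- header ``prey,predator``, one link per row;
* adjacency       -- first row and first column hold species ids; cell
                     (row i, column j) = 1 means species j eats species i;
* species table   -- header ``id,name,count,is_foundation,d13C,d15N``;
                     isotope fields hold semicolon-separated replicate
                     values or are empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SpeciesRecord",
    "FoodWeb",
    "StudyDesign",
    "FoodWebError",
    "load_web",
    "save_web",
    "load_species",
    "save_species",
    "induced_subweb",
    "web_from_links",
]

WEB_TYPES = ("FS", "BA", "RR")


class FoodWebError(ValueError):
    """Raised for invalid webs, unparseable files or broken invariants."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One species of a web.

    Parameters
    ----------
    id:
        Short unique token (case-sensitive, no commas).
    name:
        Free-text name; defaults to the id.
    count:
        Number of individuals observed (drives the rare-species filter).
        ``None`` when abundance was not recorded.
    is_foundation:
        Whether this species is the habitat-forming foundation species of
        its ecosystem.  At most one per web.
    d13C, d15N:
        Replicate tissue isotope values in permil (may be empty).
    """

    id: str
    name: str = ""
    count: int | None = None
    is_foundation: bool = False
    d13C: tuple[float, ...] = ()
    d15N: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.id or "," in self.id:
            raise FoodWebError(f"invalid species id {self.id!r}")
        if self.count is not None and self.count < 0:
            raise FoodWebError(f"negative count for species {self.id!r}")


@dataclass(frozen=True)
class FoodWeb:
    """A dichotomous trophic network with species metadata.

    ``links`` is a frozenset of ``(prey_id, predator_id)`` pairs; the
    orientation follows energy flow (prey -> predator).
    """

    species: tuple[SpeciesRecord, ...]
    links: frozenset[tuple[str, str]]
    ecosystem: str = ""
    web_type: str = "FS"
    replicate: str = ""

    def __post_init__(self):
        ids = [sp.id for sp in self.species]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FoodWebError(f"duplicate species ids: {dup}")
        if self.web_type not in WEB_TYPES:
            raise FoodWebError(
                f"web_type must be one of {WEB_TYPES}, got {self.web_type!r}"
            )
        idset = set(ids)
        for prey, pred in self.links:
            if prey not in idset or pred not in idset:
                raise FoodWebError(f"link ({prey!r}, {pred!r}) references unknown species")
        nfound = sum(sp.is_foundation for sp in self.species)
        if nfound > 1:
            raise FoodWebError("more than one foundation species flagged")

    # -- basic accessors -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(sp.id for sp in self.species)

    def species_by_id(self, sid: str) -> SpeciesRecord:
        for sp in self.species:
            if sp.id == sid:
                return sp
        raise KeyError(sid)

    @property
    def foundation(self) -> SpeciesRecord | None:
        for sp in self.species:
            if sp.is_foundation:
                return sp
        return None

    def prey_of(self, sid: str, include_self: bool = True) -> set[str]:
        """Species eaten by ``sid``."""
        out = {prey for prey, pred in self.links if pred == sid}
        if not include_self:
            out.discard(sid)
        return out

    def predators_of(self, sid: str, include_self: bool = True) -> set[str]:
        """Species that eat ``sid``."""
        out = {pred for prey, pred in self.links if prey == sid}
        if not include_self:
            out.discard(sid)
        return out

    def adjacency(self) -> pd.DataFrame:
        """0/1 matrix with rows = prey, columns = predators."""
        ids = list(self.species_ids)
        mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
        for prey, pred in self.links:
            mat.loc[prey, pred] = 1
        return mat

    def with_meta(self, **kwargs) -> "FoodWeb":
        return replace(self, **kwargs)


@dataclass
class StudyDesign:
    """Pairing of foundation-dominated (FS) and bare (BA) replicate webs.

    ``pairs`` maps an ecosystem label to ``{"FS": [webs], "BA": [webs]}``.
    Each ecosystem needs at least one web of each type; two or more BA
    webs are required before a bare-richness confidence interval can be
    formed by the null model.
    """

    pairs: dict[str, dict[str, list[FoodWeb]]] = field(default_factory=dict)

    def __post_init__(self):
        for eco, d in self.pairs.items():
            if not d.get("FS") or not d.get("BA"):
                raise FoodWebError(f"ecosystem {eco!r} lacks FS or BA webs")

    @property
    def ecosystems(self) -> list[str]:
        return list(self.pairs)

    def webs(self, web_type: str | None = None) -> list[FoodWeb]:
        out = []
        for d in self.pairs.values():
            for wt, webs in d.items():
                if web_type is None or wt == web_type:
                    out.extend(webs)
        return out


# ---------------------------------------------------------------------------
# construction helpers


def web_from_links(
    links: Iterable[tuple[str, str]],
    species: Sequence[SpeciesRecord] | Sequence[str] | None = None,
    allow_isolated: bool = False,
    **meta,
) -> FoodWeb:
    """Build a validated web from an iterable of (prey, predator) pairs.

    When ``species`` is omitted, species records are inferred from link
    endpoints (in first-seen order).  Species listed but not participating
    in any link are rejected unless ``allow_isolated``.
    """
    links = list(links)
    if len(set(links)) != len(links):
        dup = sorted({l for l in links if links.count(l) > 1})
        raise FoodWebError(f"duplicate links: {dup}")
    seen: dict[str, None] = {}
    for prey, pred in links:
        seen.setdefault(prey)
        seen.setdefault(pred)
    if species is None:
        recs = tuple(SpeciesRecord(id=s) for s in seen)
    else:
        recs = tuple(
            sp if isinstance(sp, SpeciesRecord) else SpeciesRecord(id=sp)
            for sp in species
        )
        linked = set(seen)
        listed = {sp.id for sp in recs}
        missing = linked - listed
        if missing:
            raise FoodWebError(f"link species missing from species table: {sorted(missing)}")
        isolated = listed - linked
        if isolated and not allow_isolated:
            raise FoodWebError(
                f"isolated species not allowed: {sorted(isolated)} "
                "(pass allow_isolated=True to keep them)"
            )
    return FoodWeb(species=recs, links=frozenset(links), **meta)


def induced_subweb(web: FoodWeb, keep: Iterable[str]) -> FoodWeb:
    """Restrict ``web`` to the species in ``keep``.

    Keeps exactly the species in ``keep`` (preserving order and metadata)
    and the links with both endpoints kept.
    """
    keep = set(keep)
    unknown = keep - set(web.species_ids)
    if unknown:
        raise FoodWebError(f"unknown species in keep set: {sorted(unknown)}")
    return FoodWeb(
        species=tuple(sp for sp in web.species if sp.id in keep),
        links=frozenset((a, b) for a, b in web.links if a in keep and b in keep),
        ecosystem=web.ecosystem,
        web_type=web.web_type,
        replicate=web.replicate,
    )


# ---------------------------------------------------------------------------
# file I/O


def _parse_isotopes(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(float(x) for x in str(cell).split(";") if x != "")


def load_species(path: str | Path) -> list[SpeciesRecord]:
    """Read a species table CSV (``id,name,count,is_foundation,d13C,d15N``)."""
    df = pd.read_csv(path, dtype={"id": str, "name": str})
    required = {"id", "name", "count", "is_foundation", "d13C", "d15N"}
    missing = required - set(df.columns)
    if missing:
        raise FoodWebError(f"species table {path} missing columns {sorted(missing)}")
    recs = []
    for _, row in df.iterrows():
        count = None if pd.isna(row["count"]) else int(row["count"])
        recs.append(
            SpeciesRecord(
                id=str(row["id"]),
                name="" if pd.isna(row["name"]) else str(row["name"]),
                count=count,
                is_foundation=bool(row["is_foundation"]),
                d13C=_parse_isotopes(row["d13C"]),
                d15N=_parse_isotopes(row["d15N"]),
            )
        )
    return recs


def save_species(species: Sequence[SpeciesRecord], path: str | Path) -> None:
    rows = [
        {
            "id": sp.id,
            "name": sp.name,
            "count": sp.count,
            "is_foundation": sp.is_foundation,
            "d13C": ";".join(repr(float(v)) for v in sp.d13C),
            "d15N": ";".join(repr(float(v)) for v in sp.d15N),
        }
        for sp in species
    ]
    pd.DataFrame(rows, columns=["id", "name", "count", "is_foundation", "d13C", "d15N"]).to_csv(
        path, index=False
    )


def load_web(
    path: str | Path,
    format: str = "edge_list",
    species_path: str | Path | None = None,
    allow_isolated: bool = False,
    **meta,
) -> FoodWeb:
    """Load a web from an edge-list or adjacency CSV.

    ``species_path`` optionally points to a species table supplying
    metadata; every link endpoint must appear in it.
    """
    path = Path(path)
    species = load_species(species_path) if species_path is not None else None
    if format == "edge_list":
        df = pd.read_csv(path, dtype=str)
        if list(df.columns[:2]) != ["prey", "predator"]:
            raise FoodWebError(f"{path}: expected header 'prey,predator'")
        links = []
        for i, row in df.iterrows():
            prey, pred = row["prey"], row["predator"]
            if pd.isna(prey) or pd.isna(pred):
                raise FoodWebError(f"{path}: malformed link on data row {i + 1}")
            if (prey, pred) in links:
                raise FoodWebError(f"{path}: duplicate link on data row {i + 1}: {prey}->{pred}")
            links.append((prey, pred))
    elif format == "adjacency":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise FoodWebError(f"{path}: adjacency row and column ids differ")
        links = [
            (prey, pred)
            for prey in df.index
            for pred in df.columns
            if int(df.loc[prey, pred]) == 1
        ]
        if species is None:
            # keep every species of the matrix, not just linked ones
            species = [SpeciesRecord(id=s) for s in df.index]
    else:
        raise FoodWebError(f"unknown format {format!r}")
    try:
        return web_from_links(links, species=species, allow_isolated=allow_isolated, **meta)
    except FoodWebError as exc:
        raise FoodWebError(f"{path}: {exc}") from exc


def save_web(web: FoodWeb, path: str | Path, format: str = "edge_list") -> None:
    """Write a web as an edge-list or adjacency CSV (see module docstring)."""
    path = Path(path)
    order = {sid: k for k, sid in enumerate(web.species_ids)}
    links = sorted(web.links, key=lambda l: (order[l[0]], order[l[1]]))
    if format == "edge_list":
        pd.DataFrame(links, columns=["prey", "predator"]).to_csv(path, index=False)
    elif format == "adjacency":
        web.adjacency().to_csv(path)
    else:
        raise FoodWebError(f"unknown format {format!r}")
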