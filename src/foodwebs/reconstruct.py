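"""Constrain a maximized literature-based candidate web to the final web.

The reconstruction pipeline applies, in order:

1. rare-species filter — species observed fewer than ``min_count`` times
   (default 3, strict ``<``) are dropped with all their links;
2. forbidden-link removal — expert-judged implausible interactions
   (e.g. predator/prey size discrepancies) supplied as an explicit list;
3. diet filter — for every consumer with two or more (non-self) prey, a
   Bayesian isotope mixing model estimates diet proportions and links
   contributing less than the threshold (default 5%) are removed;
4. species left without any link are dropped.

Every removal is recorded in a provenance log so the link/species deltas
between the maximized and final web are fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FoodWeb, FoodWebError, SpeciesRecord, induced_subweb
from .mixing import (
    DietPosterior,
    SourceSignature,
    TrophicEnrichment,
    diet_filter,
    fit_mixing_model,
)

__all__ = [
    "ForbiddenLinkList",
    "ReconstructionResult",
    "rare_species_filter",
    "apply_forbidden",
    "reconstruct_web",
    "load_forbidden",
]

LOG_COLUMNS = ["stage", "kind", "prey", "predator", "species", "detail"]


@dataclass(frozen=True)
class ForbiddenLinkList:
    """Expert-flagged implausible (prey, predator) pairs with reasons."""

    pairs: frozenset[tuple[str, str]]
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)

    def __len__(self):
        return len(self.pairs)


def load_forbidden(path) -> ForbiddenLinkList:
    """Read a forbidden-link CSV with header ``prey,predator,reason``."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["prey", "predator"]:
        raise FoodWebError(f"{path}: expected header 'prey,predator[,reason]'")
    pairs = set()
    reasons = {}
    for _, row in df.iterrows():
        pair = (row["prey"], row["predator"])
        pairs.add(pair)
        if "reason" in df.columns and not pd.isna(row.get("reason")):
            reasons[pair] = str(row["reason"])
    return ForbiddenLinkList(pairs=frozenset(pairs), reasons=reasons)


@dataclass
class ReconstructionResult:
    web: FoodWeb
    log: pd.DataFrame  # columns LOG_COLUMNS
    posteriors: list[DietPosterior]


def rare_species_filter(web: FoodWeb, min_count: int = 3) -> FoodWeb:
    """Drop species observed fewer than ``min_count`` times (strict <)."""
    missing = [sp.id for sp in web.species if sp.count is None]
    if missing:
        raise FoodWebError(f"species without abundance counts: {missing}")
    keep = {sp.id for sp in web.species if sp.count >= min_count}
    return induced_subweb(web, keep)


def apply_forbidden(web: FoodWeb, forbidden: ForbiddenLinkList) -> FoodWeb:
    """Remove every listed link that is present; absent ones are ignored."""
    return FoodWeb(
        species=web.species,
        links=frozenset(web.links - forbidden.pairs),
        ecosystem=web.ecosystem,
        web_type=web.web_type,
        replicate=web.replicate,
    )


def _source_signature(sp: SpeciesRecord) -> SourceSignature:
    if not sp.d13C or not sp.d15N:
        raise FoodWebError(f"species {sp.id!r} lacks isotope data needed as a diet source")
    return SourceSignature(
        id=sp.id,
        mean_d13C=float(np.mean(sp.d13C)),
        mean_d15N=float(np.mean(sp.d15N)),
        sd_d13C=float(np.std(sp.d13C, ddof=0)),
        sd_d15N=float(np.std(sp.d15N, ddof=0)),
    )


def fit_consumer_posteriors(
    web: FoodWeb,
    tef: TrophicEnrichment | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
) -> list[DietPosterior]:
    """Fit the mixing model for every consumer with >= 2 non-self prey.

    Per-consumer seeds are derived deterministically from ``seed`` so
    adding or removing consumers never perturbs the others.
    """
    posteriors = []
    ss = np.random.SeedSequence(seed)
    for sid in web.species_ids:
        prey = sorted(web.prey_of(sid, include_self=False))
        if len(prey) < 2:
            continue
        sp = web.species_by_id(sid)
        if not sp.d13C or not sp.d15N:
            raise FoodWebError(f"consumer {sid!r} lacks isotope samples")
        samples = list(zip(sp.d13C, sp.d15N))
        sources = [_source_signature(web.species_by_id(p)) for p in prey]
        child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        post = fit_mixing_model(samples, sources, tef=tef, n_iter=n_iter, seed=child_seed)
        post.consumer = sid
        posteriors.append(post)
    return posteriors


def reconstruct_web(
    maximized: FoodWeb,
    forbidden: ForbiddenLinkList | None = None,
    tef: TrophicEnrichment | None = None,
    threshold: float = 0.05,
    min_count: int = 3,
    n_iter: int = 10_000,
    seed: int = 0,
) -> ReconstructionResult:
    """Run the full three-step constraint pipeline on a maximized web.

    Returns the final web plus a provenance log with one row per removed
    link or species, tagged by stage.  Deterministic given ``seed``.
    """
    forbidden = forbidden or ForbiddenLinkList(pairs=frozenset())
    log_rows: list[dict] = []

    def log(stage, kind, prey="", predator="", species="", detail=""):
        log_rows.append(
            {"stage": stage, "kind": kind, "prey": prey, "predator": predator,
             "species": species, "detail": detail}
        )

    # 1. rare species
    after_rare = rare_species_filter(maximized, min_count=min_count)
    removed = set(maximized.species_ids) - set(after_rare.species_ids)
    for sid in sorted(removed):
        log("rare", "species", species=sid,
            detail=f"count {maximized.species_by_id(sid).count} < {min_count}")
    for a, b in sorted(maximized.links - after_rare.links):
        log("rare", "link", prey=a, predator=b, detail="endpoint removed as rare")

    # 2. forbidden links
    after_forbidden = apply_forbidden(after_rare, forbidden)
    for a, b in sorted(after_rare.links - after_forbidden.links):
        log("forbidden", "link", prey=a, predator=b,
            detail=forbidden.reasons.get((a, b), "expert judgement"))

    # 3. diet filter on multi-prey consumers
    n_multi = sum(
        1 for sid in after_forbidden.species_ids
        if len(after_forbidden.prey_of(sid, include_self=False)) >= 2
    )
    if n_multi:
        posteriors = fit_consumer_posteriors(
            after_forbidden, tef=tef, n_iter=n_iter, seed=seed
        )
        after_diet = diet_filter(after_forbidden, posteriors, threshold=threshold)
        for a, b in sorted(after_forbidden.links - after_diet.links):
            post = next(p for p in posteriors if p.consumer == b)
            log("diet", "link", prey=a, predator=b,
                detail=f"posterior mean {post.mean[a]:.4f} < {threshold}")
    else:
        posteriors = []
        after_diet = after_forbidden

    # 4. drop species left without any link
    linked = {s for l in after_diet.links for s in l}
    isolated = set(after_diet.species_ids) - linked
    final = induced_subweb(after_diet, linked) if isolated else after_diet
    for sid in sorted(isolated):
        log("isolation", "species", species=sid, detail="isolated after reconstruction")

    return ReconstructionResult(
        web=final,
        log=pd.DataFrame(log_rows, columns=LOG_COLUMNS),
        posteriors=posteriors,
    )
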