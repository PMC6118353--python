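"""Random-removal null model for foundation-species food webs.

Foundation-dominated (FS) webs are pruned by removing uniformly random
species — cascading away species that become trophically isolated (zero
remaining links) — until the surviving species count falls within the
95% confidence interval of the mean species richness of the paired bare
(BA) webs of the same ecosystem.  If the cascade overshoots below the
interval the replicate restarts from the intact web with a fresh stream
of the seeded generator.

The resulting random-removal (RR) webs form the null ensemble: if the
foundation species facilitates species at random throughout the trophic
network, the RR webs should be statistically indistinguishable from the
real bare webs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .core import FoodWeb, FoodWebError, StudyDesign, induced_subweb
from .metrics import chain_lengths, metrics_table

__all__ = ["TargetInterval", "RemovalResult", "bare_ci", "random_removal", "null_ensemble"]


@dataclass(frozen=True)
class TargetInterval:
    """t-based confidence interval for bare-web species richness."""

    lo: float
    hi: float
    ecosystem: str
    n_bare: int
    mean: float
    se: float

    def __post_init__(self):
        if not (self.lo <= self.mean <= self.hi):
            raise FoodWebError("interval must bracket its mean")


@dataclass
class RemovalResult:
    """One pruned web plus the removal trace that produced it."""

    web: FoodWeb
    trace: list[tuple[str, str]]  # (species id, "random" | "isolated")
    seed: int
    restarts: int


def bare_ci(bare_webs: list[FoodWeb], level: float = 0.95) -> TargetInterval:
    """CI = mean +/- t(1-alpha/2, n-1) * sd/sqrt(n) over bare species counts."""
    if len(bare_webs) < 2:
        raise FoodWebError("need >= 2 bare webs for a confidence interval")
    counts = np.array([w.n_species for w in bare_webs], dtype=float)
    n = len(counts)
    mean = counts.mean()
    se = counts.std(ddof=1) / np.sqrt(n)
    tcrit = st.t.ppf(0.5 + level / 2, df=n - 1)
    half = tcrit * se
    eco = bare_webs[0].ecosystem
    return TargetInterval(lo=mean - half, hi=mean + half, ecosystem=eco,
                          n_bare=n, mean=mean, se=se)


def _cascade(links: set[tuple[str, str]], alive: set[str]) -> list[str]:
    """Remove species with zero remaining links; returns removal order."""
    removed = []
    while True:
        degree = {s: 0 for s in alive}
        for a, b in links:
            degree[a] += 1
            degree[b] += 1
        dead = [s for s in alive if degree[s] == 0]
        if not dead:
            return removed
        for s in dead:
            alive.discard(s)
            removed.append(s)
        # links cannot reference dead species (they had none), loop re-checks


def random_removal(
    fs_web: FoodWeb,
    target: TargetInterval,
    seed: int = 0,
    max_restarts: int = 100,
    exempt_foundation: bool = False,
) -> RemovalResult:
    """Prune ``fs_web`` until its richness falls inside ``target``.

    One uniformly random species is removed at a time, followed by the
    isolation cascade.  The per-replicate stopping richness is drawn from
    the bare-web richness distribution (Normal(mean, sd) clipped to the
    interval), so the pruned ensemble matches bare richness rather than
    piling up at the upper CI bound.  An undershoot below ``target.lo``
    restarts the replicate (fresh draws from the same seeded generator).
    The foundation species is eligible for removal unless
    ``exempt_foundation``.
    """
    if fs_web.n_species <= target.hi:
        return RemovalResult(
            web=fs_web.with_meta(web_type="RR"), trace=[], seed=seed, restarts=0
        )
    rng = np.random.default_rng(seed)
    fs_id = fs_web.foundation.id if (exempt_foundation and fs_web.foundation) else None
    sd_bare = target.se * np.sqrt(target.n_bare)
    for restart in range(max_restarts):
        stop_at = float(np.clip(round(rng.normal(target.mean, sd_bare)), target.lo, target.hi))
        alive = set(fs_web.species_ids)
        links = set(fs_web.links)
        trace: list[tuple[str, str]] = []
        while len(alive) > stop_at:
            candidates = sorted(alive - {fs_id} if fs_id else alive)
            if not candidates:
                break
            victim = candidates[rng.integers(len(candidates))]
            alive.discard(victim)
            links = {(a, b) for a, b in links if a in alive and b in alive}
            trace.append((victim, "random"))
            for s in _cascade(links, alive):
                trace.append((s, "isolated"))
        if len(alive) >= target.lo:
            pruned = induced_subweb(fs_web, alive).with_meta(web_type="RR")
            return RemovalResult(web=pruned, trace=trace, seed=seed, restarts=restart)
    raise FoodWebError(
        f"random_removal: exhausted {max_restarts} restarts without landing in "
        f"[{target.lo:.2f}, {target.hi:.2f}] (web S={fs_web.n_species})"
    )


def null_ensemble(
    design: StudyDesign,
    reps_per_fs_web: int = 1,
    seed: int = 0,
    max_restarts: int = 100,
    exempt_foundation: bool = False,
) -> tuple[pd.DataFrame, list[RemovalResult]]:
    """Generate the RR ensemble for a whole study.

    For every FS web, ``reps_per_fs_web`` pruned replicates are produced
    with deterministically derived sub-seeds.  Returns the metric table
    of all RR webs plus the raw removal results.

    Pruned webs on which the metric suite is undefined (a surviving
    feeding loop with no basal support, or fewer than 2 species) are
    redrawn with the next derived sub-seed; the metric panel assumes
    every species is rooted in a basal resource.
    """
    rows = []
    results = []
    ss = np.random.SeedSequence(seed)
    for eco in design.ecosystems:
        target = bare_ci(design.pairs[eco]["BA"])
        for fs_web in design.pairs[eco]["FS"]:
            for rep in range(reps_per_fs_web):
                res = None
                for _attempt in range(50):
                    sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                    cand = random_removal(
                        fs_web, target, seed=sub, max_restarts=max_restarts,
                        exempt_foundation=exempt_foundation,
                    )
                    if cand.web.n_species >= 2 and _metric_safe(cand.web):
                        res = cand
                        break
                if res is None:
                    raise FoodWebError(
                        f"null_ensemble: no metric-computable pruning of FS web "
                        f"{fs_web.ecosystem}/{fs_web.replicate} after 50 attempts"
                    )
                res.web = res.web.with_meta(
                    replicate=f"{fs_web.replicate}-rr{rep}"
                )
                results.append(res)
                rows.append(res.web)
    table = metrics_table(rows)
    return table, results


def _metric_safe(web: FoodWeb) -> bool:
    try:
        chain_lengths(web)
    except FoodWebError:
        return False
    return True
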