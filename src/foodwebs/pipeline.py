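"""End-to-end orchestration: study I/O, metrics, null model, statistics.

A *study directory* is the on-disk form of a study:

    design.csv                  ecosystem, web_type, replicate, edges, species
    webs/<eco>_<type>_<rep>_edges.csv
    webs/<eco>_<type>_<rep>_species.csv
    ground_truth.json           (synthetic studies only: true diet proportions)

``run_study`` takes a :class:`RunConfig` (either a synthetic generator
config or a study directory), computes the 19-metric table for all FS
and BA webs, generates the random-removal ensemble, fits the per-metric
mixed models and the PCA/PC1 contrast, and writes a reproducible result
bundle (CSV/JSON only).  Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import FoodWeb, FoodWebError, StudyDesign, load_web, save_species, save_web
from .metrics import metrics_table
from .nullmodel import null_ensemble
from .stats import lme_summary_table, pc1_contrast, pca_metrics
from .synth import SynthConfig, SynthStudy, generate_study

__all__ = ["RunConfig", "RunResult", "run_study", "save_study", "load_study"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Inputs and knobs of one full analysis run."""

    synth: SynthConfig | None = None
    study_dir: str | None = None
    rr_reps: int = 1
    ci_level: float = 0.95
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if (self.synth is None) == (self.study_dir is None):
            raise FoodWebError("provide exactly one of synth config or study_dir")
        if self.rr_reps < 1:
            raise FoodWebError("rr_reps must be >= 1")


@dataclass
class RunResult:
    metrics: pd.DataFrame  # FS + BA + RR rows
    summary: pd.DataFrame  # per-metric means, F, stars, letters
    pca_scores: pd.DataFrame
    pca_loadings: pd.DataFrame
    pc1: object  # LmeResult
    manifest: dict


# ---------------------------------------------------------------------------
# study directory I/O


def save_study(study: SynthStudy | StudyDesign, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "webs").mkdir(parents=True, exist_ok=True)
    design = study.design if isinstance(study, SynthStudy) else study
    rows = []
    for eco in design.ecosystems:
        for wt, webs in design.pairs[eco].items():
            for w in webs:
                stem = f"{eco}_{wt}_{w.replicate}"
                save_web(w, out / "webs" / f"{stem}_edges.csv")
                save_species(w.species, out / "webs" / f"{stem}_species.csv")
                rows.append(
                    {
                        "ecosystem": eco,
                        "web_type": wt,
                        "replicate": w.replicate,
                        "edges": f"webs/{stem}_edges.csv",
                        "species": f"webs/{stem}_species.csv",
                    }
                )
    pd.DataFrame(rows).to_csv(out / "design.csv", index=False)
    if isinstance(study, SynthStudy):
        truth = {
            f"{eco}|{rep}": diets for (eco, rep), diets in study.true_diets.items()
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def load_study(study_dir: str | Path) -> StudyDesign:
    root = Path(study_dir)
    df = pd.read_csv(root / "design.csv", dtype=str)
    pairs: dict[str, dict[str, list[FoodWeb]]] = {}
    for _, row in df.iterrows():
        web = load_web(
            root / row["edges"],
            format="edge_list",
            species_path=root / row["species"],
            ecosystem=row["ecosystem"],
            web_type=row["web_type"],
            replicate=row["replicate"],
        )
        pairs.setdefault(row["ecosystem"], {}).setdefault(row["web_type"], []).append(web)
    return StudyDesign(pairs=pairs)


# ---------------------------------------------------------------------------


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    d = asdict(cfg)
    d.pop("out_dir", None)  # the hash identifies the analysis, not its destination
    blob = json.dumps(d, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_study(config: RunConfig) -> RunResult:
    """Run metrics -> null model -> statistics on a study and bundle results."""
    if config.synth is not None:
        design = generate_study(config.synth).design
    else:
        design = load_study(config.study_dir)

    real = metrics_table(design.webs())
    rr_table, rr_results = null_ensemble(
        design, reps_per_fs_web=config.rr_reps, seed=config.seed
    )
    table = pd.concat([real, rr_table], ignore_index=True)

    summary = lme_summary_table(table)
    pca = pca_metrics(table)
    pc1 = pc1_contrast(pca, table)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "rr_reps": config.rr_reps,
        "config_hash": _config_hash(config),
        "n_webs": {wt: int((table["web_type"] == wt).sum()) for wt in ("FS", "BA", "RR")},
        "pca_total_variation": float(pca.total_variation),
        "pca_axis1_pct": float(pca.variance_pct[0]),
        "pc1_f": float(pc1.fstat),
        "pc1_p": float(pc1.pvalue),
        "rr_restarts": int(sum(r.restarts for r in rr_results)),
    }

    result = RunResult(
        metrics=table,
        summary=summary,
        pca_scores=pca.scores,
        pca_loadings=pca.loadings,
        pc1=pc1,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "metrics.csv", index=False, float_format=_FLOAT_FMT)
    result.summary.to_csv(out / "summary.csv", index=False, float_format=_FLOAT_FMT)
    result.pca_scores.to_csv(out / "pca_scores.csv", float_format=_FLOAT_FMT)
    result.pca_loadings.to_csv(out / "pca_loadings.csv", float_format=_FLOAT_FMT)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
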