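"""End-to-end run configuration and report assembly.

A run reads the genotype panel, annotation and monitoring table named in
a YAML config, scores every candidate population and every n-population
source set, ranks the sets by GD:GL, places the chosen set on the
percentile scale, computes per-site evolvability and survivorship, and
writes a ranked-set TSV, an evolvability TSV, a survivorship TSV and a
JSON report. All randomness flows from the single seed in the config, so
identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import optimize as opt
from . import popgen
from .evolvability import (
    DEFAULT_H2,
    EvolvabilityResult,
    POOLED_LABEL,
    evolvability_table,
    fold_gain,
    survivorship_summary,
)
from .io import read_annotation, read_genotypes, read_traits


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    vcf: Path
    popmap: Path
    annotation: Path
    traits: Path
    n_sources: int = 4
    chosen_set: list[str] | None = None
    include: list[str] = field(default_factory=list)
    exclude: list[str] = field(default_factory=list)
    h2: float = DEFAULT_H2
    boot_n: int = 200
    boot_reps: int = 1000
    iqr_multiplier: float = 1.5
    saturation: tuple[int, int] | None = None
    cap: int = opt.DEFAULT_ENUMERATION_CAP
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
        if self.boot_n < 1 or self.boot_reps < 1:
            raise ValueError("bootstrap N and reps must be >= 1")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent
        kwargs = dict(raw)
        for key in ("vcf", "popmap", "annotation", "traits"):
            if key not in kwargs:
                raise ValueError(f"run config is missing required path {key!r}")
            kwargs[key] = base / kwargs[key]
        if kwargs.get("saturation") is not None:
            kwargs["saturation"] = tuple(kwargs["saturation"])
        return cls(**kwargs)


def _round3(x: float) -> float:
    return float(np.round(x, 3))


def _sets_frame(ranked: list[opt.RankedSet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "populations": ["+".join(r.populations) for r in ranked],
            "GD": [_round3(r.score.gd) for r in ranked],
            "GL": [_round3(r.score.gl) for r in ranked],
            "GD_GL": [_round3(r.score.ratio) for r in ranked],
            "rank": [r.rank for r in ranked],
            "percentile": [_round3(r.percentile) for r in ranked],
        }
    )


def _evolvability_frame(tables: dict[str, list[EvolvabilityResult]]) -> pd.DataFrame:
    rows = []
    for site, results in tables.items():
        for r in results:
            rows.append(
                {
                    "site": site,
                    "source": r.label,
                    "mean_cm": _round3(r.mean),
                    "V_P": _round3(r.v_p),
                    "V_G": _round3(r.v_g),
                    "CV_G": _round3(r.cv_g),
                    "boot_sd": "" if r.boot_sd is None else _round3(r.boot_sd),
                    "n_used": r.n_used,
                    "n_removed": r.n_removed,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute score -> optimize -> evolvability and write all outputs.

    Returns the report dict (also written to report.json with full
    precision; TSVs are rounded to 3 decimals for reading).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    gm = stage("read_genotypes", read_genotypes, cfg.vcf, cfg.popmap)
    ann = stage("read_annotation", read_annotation, cfg.annotation)
    traits = stage("read_traits", read_traits, cfg.traits)

    pops = [p for p in gm.populations if p not in set(cfg.exclude)]
    if cfg.include:
        pops = [p for p in pops if p in set(cfg.include)]
    if cfg.n_sources > len(pops):
        raise PipelineError(
            f"stage 'optimize' failed: n_sources={cfg.n_sources} exceeds the "
            f"{len(pops)} candidate populations"
        )

    pop_scores = stage("score", popgen.score_populations, gm, ann, pops)
    sets = stage("enumerate", opt.enumerate_sets, pops, cfg.n_sources)
    scored = stage("score_sets", opt.score_sets, gm, ann, sets)
    ranked = stage("rank", opt.rank_sets, scored)

    chosen = tuple(sorted(cfg.chosen_set)) if cfg.chosen_set else ranked[0].populations
    rank, percentile = stage("percentile", opt.rank_and_percentile, scored, chosen)

    saturation = None
    if cfg.saturation is not None:
        n_min, n_max = cfg.saturation
        saturation = stage(
            "saturation", opt.saturation_curve, gm, ann, n_min, n_max,
            populations=pops, cap=cfg.cap,
        )

    evo_tables = stage(
        "evolvability", evolvability_table, traits,
        h2=cfg.h2, iqr_multiplier=cfg.iqr_multiplier,
        boot_n=cfg.boot_n, boot_reps=cfg.boot_reps, seed=cfg.seed,
    )
    per_plot, per_source = stage("survivorship", survivorship_summary, traits)

    sets_df = _sets_frame(ranked)
    sets_df.to_csv(out_dir / "ranked_sets.tsv", sep="\t", index=False)
    evo_df = _evolvability_frame(evo_tables)
    evo_df.to_csv(out_dir / "evolvability.tsv", sep="\t", index=False)
    surv = per_plot.merge(per_source, on=["site", "source"])
    surv.round(3).to_csv(out_dir / "survivorship.tsv", sep="\t", index=False)
    if saturation is not None:
        pd.DataFrame(
            {
                "n": [p.n for p in saturation],
                "best_GD_GL": [_round3(p.best_ratio) for p in saturation],
                "mean_GD_GL": [_round3(p.mean_ratio) for p in saturation],
                "n_sets": [p.n_sets for p in saturation],
            }
        ).to_csv(out_dir / "saturation.tsv", sep="\t", index=False)

    report = {
        "config": {
            "n_sources": cfg.n_sources,
            "h2": cfg.h2,
            "boot_n": cfg.boot_n,
            "boot_reps": cfg.boot_reps,
            "iqr_multiplier": cfg.iqr_multiplier,
            "seed": cfg.seed,
            "populations": pops,
        },
        "population_scores": {
            p: {"GD": s.gd, "GL": s.gl, "GD_GL": s.ratio, "Pn": s.pn, "Ps": s.ps}
            for p, s in pop_scores.items()
        },
        "sets": {
            "n_sets": len(ranked),
            "best": {
                "populations": list(ranked[0].populations),
                "GD": ranked[0].score.gd,
                "GL": ranked[0].score.gl,
                "GD_GL": ranked[0].score.ratio,
            },
            "top10": [
                {"populations": list(r.populations), "GD_GL": r.score.ratio,
                 "rank": r.rank, "percentile": r.percentile}
                for r in ranked[:10]
            ],
        },
        "chosen_set": list(chosen),
        "chosen_rank": rank,
        "chosen_percentile": percentile,
        "evolvability": {
            site: [
                {
                    "source": r.label, "mean_cm": r.mean, "V_P": r.v_p,
                    "V_G": r.v_g, "CV_G": r.cv_g, "boot_sd": r.boot_sd,
                    "n_used": r.n_used, "n_removed": r.n_removed,
                }
                for r in results
            ]
            for site, results in evo_tables.items()
        },
        "fold_gain": {
            site: fold_gain(
                next(r.cv_g for r in results if r.label == POOLED_LABEL),
                [r.cv_g for r in results if r.label != POOLED_LABEL],
            )
            for site, results in evo_tables.items()
        },
        "survivorship": {
            "per_plot": per_plot.to_dict(orient="records"),
            "per_source_site": per_source.to_dict(orient="records"),
        },
    }
    if saturation is not None:
        report["saturation"] = [
            {"n": p.n, "best_GD_GL": p.best_ratio, "mean_GD_GL": p.mean_ratio,
             "n_sets": p.n_sets}
            for p in saturation
        ]
    with (out_dir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
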