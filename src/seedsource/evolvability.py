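"""Trait evolvability and survivorship summaries from seedling monitoring data.

Evolvability is measured as the genetic coefficient of variation
CV_G = sqrt(V_G) / mean, a scale-free index of a trait's capacity to
respond to selection. With unknown pedigree, the genetic variance is
obtained by scaling the phenotypic variance with an externally estimated
broad-sense heritability: V_G = H^2 * V_P. Heights are cleaned with a
Tukey interquartile-range outlier filter before any variance is taken.
Pooled (multi-source) CV_G is bootstrapped at a fixed resample size so
it is comparable with single-source values despite the larger pooled n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Broad-sense heritability of one-year seedling height used throughout
#: (estimated externally from a common-garden experiment).
DEFAULT_H2 = 0.3962

POOLED_LABEL = "Pooled"


@dataclass
class EvolvabilityResult:
    """One row of the evolvability table (a single source or the pool)."""

    label: str
    mean: float  # trait mean X-bar, cm
    v_p: float  # phenotypic variance, cm^2
    v_g: float  # genetic variance = H^2 * V_P, cm^2
    cv_g: float  # sqrt(V_G) / mean, dimensionless
    boot_sd: float | None = None  # bootstrap SD, pooled rows only
    n_used: int = 0
    n_removed: int = 0


def tukey_filter(
    values: Sequence[float], multiplier: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Tukey IQR outlier filter.

    Removes values outside [Q1 - m*IQR, Q3 + m*IQR], with quartiles by
    linear interpolation. Returns (kept, removed), both preserving input
    order. Not idempotent: re-filtering the kept values recomputes the
    fences and may remove more.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError(f"need at least 4 finite values, got {x.size}")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], x[~keep]


def genetic_variance(v_p: float, h2: float) -> float:
    """V_G = H^2 * V_P (broad-sense heritability scaling)."""
    if v_p < 0:
        raise ValueError(f"phenotypic variance must be >= 0, got {v_p}")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"heritability must lie in [0, 1], got {h2}")
    return h2 * v_p


def evolvability(v_g: float, mean: float) -> float:
    """Genetic coefficient of variation CV_G = sqrt(V_G) / mean."""
    if mean <= 0:
        raise ValueError(f"trait mean must be positive, got {mean}")
    if v_g < 0:
        raise ValueError(f"genetic variance must be >= 0, got {v_g}")
    return float(np.sqrt(v_g) / mean)


def bootstrap_pooled_cvg(
    heights: Sequence[float],
    h2: float,
    n: int = 200,
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bootstrap CV_G of a pooled height sample at a fixed resample size.

    Each of ``reps`` replicates draws ``n`` heights with replacement,
    computes V_P (denominator n-1), V_G = h2 * V_P and
    CV_G = sqrt(V_G)/mean. Returns the mean and standard deviation of
    CV_G over replicates. Outlier filtering is the caller's job.
    """
    x = np.asarray(heights, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite heights to bootstrap")
    if n < 2:
        raise ValueError("resample size n must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.integers(0, x.size, size=(reps, n))
    samples = x[draws]
    means = samples.mean(axis=1)
    v_p = samples.var(axis=1, ddof=1)
    cvg = np.sqrt(h2 * v_p) / means
    return float(cvg.mean()), float(cvg.std(ddof=1))


def fold_gain(pooled_cvg: float, single_cvgs: Sequence[float]) -> float:
    """Maximum evolvability gain of the pool over any single source.

    fold = pooled CV_G / min positive single-source CV_G, to 1 decimal
    place — the "up to X times higher" summary.
    """
    singles = [c for c in single_cvgs if c > 0]
    if any(c < 0 for c in single_cvgs) or pooled_cvg < 0:
        raise ValueError("CV_G values must be >= 0")
    if not singles:
        raise ValueError("no single source with positive CV_G")
    return round(pooled_cvg / min(singles), 1)


def _plugin_row(
    label: str, heights: np.ndarray, h2: float, n_removed: int
) -> EvolvabilityResult:
    mean = float(heights.mean())
    v_p = float(heights.var(ddof=1))
    v_g = genetic_variance(v_p, h2)
    return EvolvabilityResult(
        label=label,
        mean=mean,
        v_p=v_p,
        v_g=v_g,
        cv_g=evolvability(v_g, mean),
        n_used=heights.size,
        n_removed=n_removed,
    )


def evolvability_table(
    traits: pd.DataFrame,
    h2: float = DEFAULT_H2,
    iqr_multiplier: float = 1.5,
    boot_n: int = 200,
    boot_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, list[EvolvabilityResult]]:
    """Per-site evolvability of seedling height, by source and pooled.

    For each site, heights of alive seedlings are outlier-filtered per
    source (Tukey IQR), then each source gets a plug-in CV_G and the
    union of the filtered single-source heights gets a bootstrapped
    pooled CV_G (mean +/- SD over replicates).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, list[EvolvabilityResult]] = {}
    for site in sorted(traits["site"].unique()):
        site_rows = traits[(traits["site"] == site) & traits["alive"]]
        results = []
        pooled_heights = []
        for source in sorted(site_rows["source"].unique()):
            h = site_rows.loc[site_rows["source"] == source, "height_cm"].to_numpy()
            kept, removed = tukey_filter(h, iqr_multiplier)
            pooled_heights.append(kept)
            results.append(_plugin_row(source, kept, h2, removed.size))
        pooled = np.concatenate(pooled_heights)
        row = _plugin_row(POOLED_LABEL, pooled, h2, 0)
        boot_mean, boot_sd = bootstrap_pooled_cvg(
            pooled, h2, n=boot_n, reps=boot_reps, seed=rng
        )
        row.cv_g = boot_mean  # pooled CV_G is the bootstrap mean
        row.boot_sd = boot_sd
        results.append(row)
        out[site] = results
    return out


def survivorship_summary(
    traits: pd.DataFrame, n_planted: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot and per-source-by-site survivorship proportions.

    Each monitoring record is one planted seedling, so a plot's planted
    count is its record count unless ``n_planted`` overrides it (the
    trial design plants 40 per plot). Returns (per_plot, per_source_site)
    DataFrames; the latter averages plot proportions within source x site.
    """
    grouped = traits.groupby(["site", "source", "plot"], sort=True)
    per_plot = grouped.agg(
        n_alive=("alive", "sum"), n_recorded=("alive", "size")
    ).reset_index()
    per_plot["n_planted"] = n_planted if n_planted is not None else per_plot["n_recorded"]
    if (per_plot["n_alive"] > per_plot["n_planted"]).any():
        bad = per_plot[per_plot["n_alive"] > per_plot["n_planted"]].iloc[0]
        raise ValueError(
            f"plot {bad['plot']!r}: {bad['n_alive']} alive exceeds "
            f"{bad['n_planted']} planted"
        )
    per_plot["proportion"] = per_plot["n_alive"] / per_plot["n_planted"]
    per_source = (
        per_plot.groupby(["site", "source"], sort=True)["proportion"]
        .mean()
        .reset_index()
        .rename(columns={"proportion": "mean_proportion"})
    )
    return per_plot.drop(columns="n_recorded"), per_source
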