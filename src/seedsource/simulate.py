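"""Synthetic genotype panels and field-trial trait tables.

The generator emulates the statistical structure the seed-sourcing
analysis assumes, so every stage of the pipeline is testable without any
external download:

* Genotypes follow the Balding-Nichols model: each locus has an
  ancestral frequency drawn from a Beta distribution, each population
  draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with a
  population-specific drift parameter F, and individuals carry
  Binomial(2, p_pop) alternate-allele dosages. The model has closed-form
  moments (E[2p(1-p)] = (1-F) * E[2p_anc(1-p_anc)]), which the tests use
  as an analytic oracle.
* Genetic load differences are induced minimally: nonsynonymous loci in
  population i have their frequency inflated by a factor lambda_i >= 1,
  capped at 0.5, so GL as defined (class-wise counts x mean frequencies)
  responds directly and populations remain rankable by lambda. The update
  never decreases a frequency, so lambda = 1 is exactly the identity.
* Seedling trials place single-source plots within sites; a seedling
  survives with a per-source probability, and surviving heights are
  mu_source + g + e with g ~ N(0, V_G), e ~ N(0, V_E) and
  V_G/(V_G + V_E) equal to the target broad-sense heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .evolvability import DEFAULT_H2
from .io import (
    MISSING,
    GenotypeMatrix,
    SnpFunctionalTable,
    write_annotation,
    write_genotypes_vcf,
    write_population_map,
    write_traits,
)

NONSYN_EFFECT = "missense_variant"
SYN_EFFECT = "synonymous_variant"
OTHER_EFFECT = "intergenic_region"


@dataclass
class GenomeSimConfig:
    """Parameters of the Balding-Nichols genotype simulation.

    Defaults emulate the candidate panel the analysis was designed for:
    23 candidate populations of 6 individuals genotyped on a biallelic
    SNP panel partitioned into nonsynonymous/synonymous/other classes,
    with population-specific drift (F spread over 0.05-0.35) and
    deleterious-frequency inflation (lambda spread over 1.0-1.4).
    """

    k: int = 23
    n_individuals: int = 6
    l_syn: int = 1200
    l_nonsyn: int = 1200
    l_other: int = 600
    beta_a: float = 0.5
    beta_b: float = 0.5
    fst: float | Sequence[float] = ()
    lam: float | Sequence[float] = ()
    missing_rate: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.k, self.n_individuals, self.l_syn, self.l_nonsyn, self.l_other) < 1:
            raise ValueError("all counts must be >= 1")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if isinstance(self.fst, (int, float)):
            self.fst = np.full(self.k, float(self.fst))
        elif len(self.fst) == 0:
            self.fst = np.linspace(0.05, 0.35, self.k)
        else:
            self.fst = np.asarray(self.fst, dtype=float)
        if isinstance(self.lam, (int, float)):
            self.lam = np.full(self.k, float(self.lam))
        elif len(self.lam) == 0:
            self.lam = np.linspace(1.0, 1.4, self.k)
        else:
            self.lam = np.asarray(self.lam, dtype=float)
        if len(self.fst) != self.k or len(self.lam) != self.k:
            raise ValueError("fst and lam must have one value per population")
        if np.any((self.fst <= 0) | (self.fst >= 1)):
            raise ValueError("drift F must lie in (0, 1)")
        if np.any(self.lam < 1):
            raise ValueError("load inflation lambda must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must lie in [0, 1)")

    @property
    def n_loci(self) -> int:
        return self.l_syn + self.l_nonsyn + self.l_other

    def population_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.k)]


def inflate_frequency(p: np.ndarray, lam: float) -> np.ndarray:
    """Deleterious-frequency inflation: p -> max(p, min(lam*p, 0.5)).

    Monotone in lam, exactly the identity at lam = 1, and never pushes an
    inflated frequency past 0.5 (drift load stays at intermediate
    frequency rather than fixing).
    """
    return np.maximum(p, np.minimum(lam * p, 0.5))


def simulate_genotypes(
    cfg: GenomeSimConfig,
    rng: np.random.Generator | None = None,
    return_frequencies: bool = False,
):
    """Draw a genotype panel under the Balding-Nichols model.

    Returns ``(GenotypeMatrix, SnpFunctionalTable, population_map)``;
    with ``return_frequencies=True`` a fourth element exposes the true
    simulated frequencies (``p_anc`` of shape (L,), ``p_pop`` of shape
    (k, L)) for calibration checks.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    pops = cfg.population_ids()

    # locus order mixes the functional classes along the chromosome
    effects = np.array(
        [NONSYN_EFFECT] * cfg.l_nonsyn
        + [SYN_EFFECT] * cfg.l_syn
        + [OTHER_EFFECT] * cfg.l_other
    )
    effects = effects[rng.permutation(L)]
    nonsyn_mask = effects == NONSYN_EFFECT

    refs = np.array(list("ACGT"))[rng.integers(0, 4, L)]
    alts = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
    )
    snp_ids = [f"1:{pos + 1}:{refs[pos]}:{alts[pos]}" for pos in range(L)]

    p_anc = np.clip(rng.beta(cfg.beta_a, cfg.beta_b, L), 1e-6, 1 - 1e-6)

    individual_ids: list[str] = []
    population_of: dict[str, str] = {}
    blocks = []
    pop_freqs = np.empty((cfg.k, L))
    for i, pop in enumerate(pops):
        f = cfg.fst[i]
        shape = (1.0 - f) / f
        p_pop = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        p_pop = np.clip(p_pop, 0.0, 1.0)
        p_pop[nonsyn_mask] = inflate_frequency(p_pop[nonsyn_mask], cfg.lam[i])
        pop_freqs[i] = p_pop
        dos = rng.binomial(2, p_pop, size=(cfg.n_individuals, L)).astype(np.int8)
        if cfg.missing_rate > 0:
            dos[rng.random(dos.shape) < cfg.missing_rate] = MISSING
        blocks.append(dos)
        for j in range(cfg.n_individuals):
            ind = f"{pop}_i{j + 1}"
            individual_ids.append(ind)
            population_of[ind] = pop

    ann = SnpFunctionalTable()
    for snp_id, eff in zip(snp_ids, effects):
        ann.add(snp_id, eff)

    gm = GenotypeMatrix(
        individual_ids=individual_ids,
        population_of=population_of,
        snp_ids=snp_ids,
        dosages=np.vstack(blocks),
    )
    if return_frequencies:
        return gm, ann, population_of, {"p_anc": p_anc, "p_pop": pop_freqs}
    return gm, ann, population_of


@dataclass
class TrialSimConfig:
    """Parameters of the seedling field-trial simulation.

    Mirrors the monitoring design: single-source plots of
    ``seedlings_per_plot`` seedlings, ``plots_per_source`` replicate
    plots per source within each site. Heights decompose into a
    per-source mean, a genetic deviation with variance V_G and a residual
    with variance ``residual_variance``, with
    V_G = H^2/(1-H^2) * residual_variance so V_G/V_P equals the target
    heritability exactly in expectation.
    """

    sites: Mapping[str, Sequence[str]] = field(default_factory=dict)
    plots_per_source: int = 5
    seedlings_per_plot: int = 40
    mu: Mapping[str, float] = field(default_factory=dict)
    h2: float = DEFAULT_H2
    residual_variance: float = 1.3
    survival: Mapping[str, float] | float = 0.85
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("at least one site with sources is required")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
        if self.h2 >= 1.0 and self.residual_variance > 0:
            raise ValueError("H^2 = 1 requires zero residual variance")
        if self.residual_variance < 0:
            raise ValueError("residual variance must be >= 0")
        sources = sorted({s for ss in self.sites.values() for s in ss})
        if not self.mu:
            self.mu = {s: 23.0 + 5.0 * i / max(len(sources) - 1, 1)
                       for i, s in enumerate(sources)}
        missing = [s for s in sources if s not in self.mu]
        if missing:
            raise ValueError(f"no trait mean for source(s) {missing}")
        if any(self.mu[s] <= 0 for s in sources):
            raise ValueError("trait means must be positive")
        if isinstance(self.survival, (int, float)):
            self.survival = {s: float(self.survival) for s in sources}
        bad = [s for s in sources
               if not 0.0 <= self.survival.get(s, -1.0) <= 1.0]
        if bad:
            raise ValueError(f"survival probability outside [0, 1] for {bad}")

    @property
    def genetic_variance(self) -> float:
        if self.h2 >= 1.0:
            return 0.0
        return self.h2 / (1.0 - self.h2) * self.residual_variance


def simulate_trial(
    cfg: TrialSimConfig,
    rng: np.random.Generator | None = None,
    keep_genetic_values: bool = False,
) -> pd.DataFrame:
    """Simulate a plot-structured seedling monitoring table.

    Returns a DataFrame with columns site, source, plot, height_cm,
    alive (dead seedlings have missing height). With
    ``keep_genetic_values=True`` a ``genetic_value`` column exposes the
    simulated genetic deviations for variance-recovery checks.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    v_g = cfg.genetic_variance
    v_e = cfg.residual_variance
    rows: list[dict] = []
    for site in cfg.sites:
        for source in cfg.sites[site]:
            for j in range(cfg.plots_per_source):
                plot = f"{site}-{source}-p{j + 1}"
                m = cfg.seedlings_per_plot
                alive = rng.random(m) < cfg.survival[source]
                g = rng.normal(0.0, np.sqrt(v_g), m) if v_g > 0 else np.zeros(m)
                e = rng.normal(0.0, np.sqrt(v_e), m) if v_e > 0 else np.zeros(m)
                h = cfg.mu[source] + g + e
                for s in range(m):
                    rec = {
                        "site": site,
                        "source": source,
                        "plot": plot,
                        "height_cm": h[s] if alive[s] else np.nan,
                        "alive": bool(alive[s]),
                    }
                    if keep_genetic_values:
                        rec["genetic_value"] = g[s]
                    rows.append(rec)
    return pd.DataFrame(rows)


def _preset_configs(
    preset: str, seed: int | None
) -> tuple[GenomeSimConfig, TrialSimConfig]:
    if preset == "tiny":
        genome = GenomeSimConfig(
            k=4, n_individuals=3, l_syn=30, l_nonsyn=30, l_other=15,
            missing_rate=0.05, seed=seed,
        )
        trial = TrialSimConfig(
            sites={"S1": ["P01", "P02"]},
            plots_per_source=2,
            seedlings_per_plot=10,
            seed=seed,
        )
    elif preset == "paper_like":
        genome = GenomeSimConfig(seed=seed)  # 23 populations x 6 individuals
        pops = genome.population_ids()
        trial = TrialSimConfig(
            sites={
                "MD": pops[0:3],
                "WV": pops[0:4],
                "VA": [pops[2], pops[3], pops[6], pops[10]],
            },
            # scrambled 22-28 cm spread so each site's sources differ in
            # mean height about as much as monitored sources do
            mu={p: 22.0 + 6.0 * ((7 * i) % 23) / 22.0
                for i, p in enumerate(pops)},
            survival={p: s for p, s in zip(
                pops, np.linspace(0.75, 0.95, len(pops)))},
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {preset!r}; use 'tiny' or 'paper_like'")
    return genome, trial


def _config_to_plain(cfg) -> dict:
    out = {}
    for key, val in asdict(cfg).items():
        if isinstance(val, np.ndarray):
            val = [float(v) for v in val]
        elif isinstance(val, Mapping):
            val = {k: (float(v) if isinstance(v, (int, float, np.floating)) else list(v))
                   for k, v in val.items()}
        out[key] = val
    return out


def write_fixture(
    out_dir: str | Path,
    preset: str = "tiny",
    seed: int | None = 0,
    force: bool = False,
) -> dict[str, Path]:
    """Generate a complete on-disk input set for one preset.

    Writes genotypes.vcf, annotation.tsv, popmap.tsv, traits.csv and the
    config used (config.yaml) into ``out_dir``. Output is byte-stable for
    a fixed seed. Refuses a non-empty directory unless ``force``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} is not empty; pass force=True to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    genome_cfg, trial_cfg = _preset_configs(preset, seed)
    gm, ann, popmap = simulate_genotypes(genome_cfg)
    traits = simulate_trial(trial_cfg)

    paths = {
        "vcf": out_dir / "genotypes.vcf",
        "annotation": out_dir / "annotation.tsv",
        "popmap": out_dir / "popmap.tsv",
        "traits": out_dir / "traits.csv",
        "config": out_dir / "config.yaml",
    }
    write_genotypes_vcf(gm, paths["vcf"])
    write_annotation(ann, paths["annotation"])
    write_population_map(popmap, paths["popmap"])
    write_traits(traits, paths["traits"])
    with paths["config"].open("w") as fh:
        yaml.safe_dump(
            {
                "preset": preset,
                "seed": seed,
                "genome": _config_to_plain(genome_cfg),
                "trial": _config_to_plain(trial_cfg),
            },
            fh,
            sort_keys=True,
        )
    return paths
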