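"""Genetic diversity and genetic load for arbitrary pools of individuals.

Genetic diversity (GD) is the mean expected heterozygosity He = 2p(1-p)
across the SNP panel, computed from pooled allele frequencies. Genetic
load (GL) is a drift-load proxy: the count of segregating nonsynonymous
SNPs weighted by their mean frequency, over the same quantity for
synonymous SNPs, GL = (Pn*fn)/(Ps*fs). The selection score is the ratio
GD:GL — diversity per unit deleterious burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .io import MISSING, FunctionalClass, GenotypeMatrix, SnpFunctionalTable


class UndefinedLoadError(ValueError):
    """Raised when GL is undefined (no segregating synonymous SNPs)."""


@dataclass
class FrequencyVector:
    """Per-SNP alternate-allele frequencies for a pool of individuals.

    ``p`` is NaN for SNPs with zero called alleles in the pool; such SNPs
    are excluded from all downstream means. ``n_called_alleles`` is twice
    the number of individuals with a called genotype at each SNP.
    """

    snp_ids: list[str]
    p: np.ndarray
    n_called_alleles: np.ndarray

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of SNPs with at least one called allele."""
        return self.n_called_alleles > 0


class LoadComponents(NamedTuple):
    gl: float
    pn: int
    ps: int
    fn: float
    fs: float


@dataclass
class DiversityLoadScore:
    """GD, GL and their ratio for one pool, plus the counts behind them."""

    gd: float
    gl: float
    ratio: float
    n_snps_used: int
    pn: int
    ps: int


def allele_frequencies(
    gm: GenotypeMatrix, individuals: Sequence[str] | None = None
) -> FrequencyVector:
    """Alternate-allele frequencies over a subset of individuals.

    Missing genotypes are excluded per SNP from the denominator:
    p = (sum of called dosages) / (2 x number of called individuals).
    ``individuals=None`` uses every individual in the matrix.
    """
    if individuals is None:
        rows = np.arange(gm.n_individuals)
    else:
        individuals = list(individuals)
        if not individuals:
            raise ValueError("empty individual subset")
        rows = gm.row_indices(individuals)
    d = gm.dosages[rows, :]
    called = d != MISSING
    n_called_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called_alleles > 0, alt / np.maximum(n_called_alleles, 1), np.nan)
    return FrequencyVector(
        snp_ids=list(gm.snp_ids),
        p=p.astype(float),
        n_called_alleles=n_called_alleles.astype(np.int64),
    )


def expected_heterozygosity(freqs: FrequencyVector) -> float:
    """Mean He = 2p(1-p) over all usable SNPs (monomorphic sites included).

    GD is a per-genotyped-site average over the whole SNP panel, so pools
    scored on the same panel are directly comparable. No small-sample
    correction is applied.
    """
    usable = freqs.usable
    if not usable.any():
        raise ValueError("no SNP has a called allele in this pool")
    p = freqs.p[usable]
    return float(np.mean(2.0 * p * (1.0 - p)))


def genetic_load(freqs: FrequencyVector, ann: SnpFunctionalTable) -> LoadComponents:
    """Genetic load GL = (Pn*fn)/(Ps*fs) for a pool.

    Pn and Ps count SNPs of the nonsynonymous and synonymous classes that
    segregate in the pool (0 < p < 1); fn and fs are the mean
    alternate-allele frequencies over those SNPs, so Pn*fn is simply the
    summed frequency of the class. OTHER-class SNPs are ignored.

    Raises
    ------
    UndefinedLoadError
        If no synonymous SNP segregates in the pool (Ps = 0 or fs = 0).
    """
    classes = ann.classes_for(freqs.snp_ids)
    usable = freqs.usable
    p = freqs.p
    seg = usable & (p > 0.0) & (p < 1.0)

    nonsyn = seg & (classes == FunctionalClass.NONSYNONYMOUS)
    syn = seg & (classes == FunctionalClass.SYNONYMOUS)
    pn, ps = int(nonsyn.sum()), int(syn.sum())
    if ps == 0:
        raise UndefinedLoadError(
            "genetic load undefined: no segregating synonymous SNP in pool"
        )
    fn = float(p[nonsyn].mean()) if pn else 0.0
    fs = float(p[syn].mean())
    if fs == 0.0:
        raise UndefinedLoadError("genetic load undefined: fs = 0")
    return LoadComponents(gl=(pn * fn) / (ps * fs), pn=pn, ps=ps, fn=fn, fs=fs)


def gd_gl_ratio(gd: float, gl: float) -> float:
    """The selection score GD:GL; requires GL > 0."""
    if gl <= 0:
        raise ValueError(f"GD:GL undefined for GL = {gl}")
    return gd / gl


def score_pool(
    gm: GenotypeMatrix,
    ann: SnpFunctionalTable,
    individuals: Sequence[str] | None = None,
) -> DiversityLoadScore:
    """GD, GL and GD:GL for a pool of individuals (default: all)."""
    freqs = allele_frequencies(gm, individuals)
    gd = expected_heterozygosity(freqs)
    load = genetic_load(freqs, ann)
    return DiversityLoadScore(
        gd=gd,
        gl=load.gl,
        ratio=gd_gl_ratio(gd, load.gl),
        n_snps_used=int(freqs.usable.sum()),
        pn=load.pn,
        ps=load.ps,
    )


def score_populations(
    gm: GenotypeMatrix, ann: SnpFunctionalTable, populations: Iterable[str] | None = None
) -> dict[str, DiversityLoadScore]:
    """Per-population GD/GL/ratio scores."""
    pops = list(populations) if populations is not None else gm.populations
    return {pop: score_pool(gm, ann, gm.individuals_of([pop])) for pop in pops}
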