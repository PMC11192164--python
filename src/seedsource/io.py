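"""Readers and writers for the formats the seed-sourcing pipeline touches.

Genotypes come in as VCF (biallelic SNPs with a GT field), functional
annotations as a SnpEff-style tab-separated effect table, and seedling
monitoring records as CSV. Genotypes are held in memory as an
individuals x SNPs alternate-allele dosage matrix (0/1/2, ``MISSING`` = -1)
with a population label per individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype in the dosage matrix.
MISSING: int = -1

_BASES = frozenset("ACGT")


class FunctionalClass(Enum):
    """Functional consequence class of a SNP, collapsed from SnpEff labels."""

    NONSYNONYMOUS = "NONSYNONYMOUS"
    SYNONYMOUS = "SYNONYMOUS"
    OTHER = "OTHER"


#: SnpEff effect categories treated as nonsynonymous (amino-acid changing
#: or otherwise protein-disruptive) in the genetic-load calculation.
NONSYNONYMOUS_EFFECTS = frozenset(
    {
        "missense_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "start_lost",
        "stop_gained",
        "stop_lost",
    }
)

SYNONYMOUS_EFFECTS = frozenset({"synonymous_variant"})

#: Worst-consequence precedence used when several effect labels annotate
#: the same SNP.
_CLASS_PRECEDENCE = {
    FunctionalClass.NONSYNONYMOUS: 0,
    FunctionalClass.SYNONYMOUS: 1,
    FunctionalClass.OTHER: 2,
}


def classify_effect(effect: str) -> FunctionalClass:
    """Map a raw SnpEff effect label to a :class:`FunctionalClass`.

    Matching is case-insensitive and accepts both space- and
    underscore-delimited forms; unknown labels map to ``OTHER``.
    """
    norm = effect.strip().lower().replace(" ", "_")
    if norm in NONSYNONYMOUS_EFFECTS:
        return FunctionalClass.NONSYNONYMOUS
    if norm in SYNONYMOUS_EFFECTS:
        return FunctionalClass.SYNONYMOUS
    return FunctionalClass.OTHER


@dataclass
class SnpFunctionalTable:
    """Per-SNP functional class lookup keyed by ``chrom:pos:ref:alt``."""

    effect_of: dict[str, str] = field(default_factory=dict)
    class_of: dict[str, FunctionalClass] = field(default_factory=dict)

    def add(self, snp_id: str, effect: str) -> None:
        cls = classify_effect(effect)
        if snp_id in self.class_of:
            # worst-consequence precedence: NONSYN beats SYN beats OTHER
            if _CLASS_PRECEDENCE[cls] < _CLASS_PRECEDENCE[self.class_of[snp_id]]:
                self.effect_of[snp_id] = effect
                self.class_of[snp_id] = cls
        else:
            self.effect_of[snp_id] = effect
            self.class_of[snp_id] = cls

    def functional_class(self, snp_id: str) -> FunctionalClass:
        """Class of ``snp_id``; SNPs absent from the table are ``OTHER``."""
        return self.class_of.get(snp_id, FunctionalClass.OTHER)

    def classes_for(self, snp_ids: Iterable[str]) -> np.ndarray:
        """Array of :class:`FunctionalClass` for each SNP id, in order."""
        return np.array([self.functional_class(s) for s in snp_ids], dtype=object)

    def __len__(self) -> int:
        return len(self.class_of)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele dosages with population labels.

    Attributes
    ----------
    individual_ids
        Sample names, in matrix row order.
    population_of
        Individual -> population ID; every individual must be labelled.
    snp_ids
        ``chrom:pos:ref:alt`` keys, in matrix column order, unique.
    dosages
        ``(n_individuals, n_snps)`` int8 array with values in
        {0, 1, 2, MISSING}.
    n_skipped_records
        Count of non-biallelic-SNP records dropped by the reader.
    """

    individual_ids: list[str]
    population_of: dict[str, str]
    snp_ids: list[str]
    dosages: np.ndarray
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n_ind, n_snp = self.dosages.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.snp_ids) != n_snp:
            raise ValueError("snp_ids length does not match dosage columns")
        if len(set(self.snp_ids)) != n_snp:
            raise ValueError("snp_ids are not unique")
        unlabelled = [i for i in self.individual_ids if i not in self.population_of]
        if unlabelled:
            raise ValueError(
                f"individuals without a population label: {unlabelled[:5]}"
            )
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def populations(self) -> list[str]:
        """Distinct population IDs, sorted."""
        return sorted(set(self.population_of[i] for i in self.individual_ids))

    def individuals_of(self, populations: Iterable[str]) -> list[str]:
        """Individuals belonging to any of the given populations."""
        wanted = set(populations)
        return [i for i in self.individual_ids if self.population_of[i] in wanted]

    def row_indices(self, individuals: Iterable[str]) -> np.ndarray:
        index = {ind: r for r, ind in enumerate(self.individual_ids)}
        try:
            return np.array([index[i] for i in individuals], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown individual {exc.args[0]!r}") from None


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``individual<TAB>population`` into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "population"],
                     dtype=str, comment="#")
    if df["individual"].duplicated().any():
        dup = df.loc[df["individual"].duplicated(), "individual"].iloc[0]
        raise ValueError(f"individual {dup!r} listed twice in population map")
    return dict(zip(df["individual"], df["population"]))


def read_genotypes(
    vcf_path: str | Path, population_map: Mapping[str, str] | str | Path
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNP records (indels, symbolic alleles) are
    skipped; the skip count is logged and stored on the returned matrix.

    Parameters
    ----------
    vcf_path
        Path to a VCF v4.x file with a GT field.
    population_map
        Individual -> population mapping, or path to a two-column TSV.

    Raises
    ------
    ValueError
        If a VCF sample is absent from the population map, or no sample
        in the VCF intersects the map.
    """
    from cyvcf2 import VCF

    if not isinstance(population_map, Mapping):
        population_map = read_population_map(population_map)

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")
    missing_pop = [s for s in samples if s not in population_map]
    if len(missing_pop) == len(samples):
        raise ValueError("no VCF sample appears in the population map")
    if missing_pop:
        raise ValueError(
            f"individual {missing_pop[0]!r} in VCF is absent from the population map"
        )

    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        alts = variant.ALT
        if (
            len(alts) != 1
            or len(variant.REF) != 1
            or len(alts[0]) != 1
            or variant.REF.upper() not in _BASES
            or alts[0].upper() not in _BASES
        ):
            n_skipped += 1
            continue
        snp_ids.append(f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alts[0]}")
        # with gts012=True: 0/1/2 = alt dosage, 3 = uncalled
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()

    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records", n_skipped)
    dosages = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        individual_ids=samples,
        population_of={s: population_map[s] for s in samples},
        snp_ids=snp_ids,
        dosages=dosages,
        n_skipped_records=n_skipped,
    )


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal VCF 4.2 file.

    SNP ids are parsed back into CHROM/POS/REF/ALT; genotypes are emitted
    unphased (het as 0/1), so a write/read round trip preserves dosages
    exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen: dict[str, None] = {}
        for snp_id in gm.snp_ids:
            seen.setdefault(snp_id.rsplit(":", 3)[0], None)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        for j, snp_id in enumerate(gm.snp_ids):
            chrom, pos, ref, alt = snp_id.rsplit(":", 3)
            gts = "\t".join(_GT_STRING[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{chrom}\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_population_map(population_of: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for ind, pop in population_of.items():
            fh.write(f"{ind}\t{pop}\n")


_ANNOTATION_COLUMNS = ("chrom", "pos", "ref", "alt", "effect")


def read_annotation(path: str | Path) -> SnpFunctionalTable:
    """Read a tab-separated SnpEff-style effect table.

    Requires columns ``chrom pos ref alt effect``. Effects in the
    nonsynonymous category list become ``NONSYNONYMOUS``,
    ``synonymous_variant`` becomes ``SYNONYMOUS``, everything else
    ``OTHER``. When several rows annotate one SNP the worst consequence
    wins (NONSYNONYMOUS > SYNONYMOUS > OTHER).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annotation table is missing required column {col!r}")
    table = SnpFunctionalTable()
    for chrom, pos, ref, alt, effect in df[list(_ANNOTATION_COLUMNS)].itertuples(
        index=False
    ):
        table.add(f"{chrom}:{pos}:{ref}:{alt}", effect)
    return table


def write_annotation(table: SnpFunctionalTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("chrom\tpos\tref\talt\teffect\n")
        for snp_id, effect in table.effect_of.items():
            chrom, pos, ref, alt = snp_id.rsplit(":", 3)
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{effect}\n")


TRAIT_COLUMNS = ("site", "source", "plot", "height_cm", "alive")

_TRUTHY = {"1", "true"}
_FALSY = {"0", "false"}


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a seedling monitoring table.

    CSV with header ``site,source,plot,height_cm,alive``. ``alive`` accepts
    0/1/true/false (case-insensitive). Dead seedlings carry a missing
    height; an alive seedling must have a positive height.

    Returns a DataFrame with columns site, source, plot (str),
    height_cm (float, NaN for dead) and alive (bool).
    """
    df = pd.read_csv(path, dtype={"site": str, "source": str, "plot": str})
    for col in TRAIT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trait table is missing required column {col!r}")

    alive_raw = df["alive"].astype(str).str.strip().str.lower()
    unknown = ~alive_raw.isin(_TRUTHY | _FALSY)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"unparseable alive flag at row {row}")
    alive = alive_raw.isin(_TRUTHY)

    height = pd.to_numeric(df["height_cm"], errors="coerce")
    bad = alive & ~(height > 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"alive seedling with non-positive height at row {row}")
    height = height.where(alive)  # dead seedlings get missing height

    out = df[["site", "source", "plot"]].copy()
    out["height_cm"] = height.astype(float)
    out["alive"] = alive.to_numpy()
    # each plot must sit inside exactly one site and hold a single source
    plot_span = out.groupby("plot")[["site", "source"]].nunique()
    multi = plot_span[(plot_span["site"] > 1) | (plot_span["source"] > 1)]
    if len(multi):
        raise ValueError(
            f"plot {multi.index[0]!r} spans multiple sites or sources"
        )
    return out


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    out = traits.copy()
    out["alive"] = out["alive"].astype(int)
    out.to_csv(path, index=False, float_format="%.2f", columns=list(TRAIT_COLUMNS))
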