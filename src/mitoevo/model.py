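"""Shared domain types: genotypes, circumstances, and the genome model."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

BASES = ("A", "C", "G", "T")

#: default nuclear/mitochondrial background identifiers
DEFAULT_BACKGROUNDS = ("N", "D", "Y")

#: the seven mitonuclear genotype labels of the reference design
DEFAULT_GENOTYPES = ("NN", "ND", "DN", "DD", "DY", "YD", "YY")

#: carbon-source media: fermentable and nonfermentable
DEFAULT_MEDIA = ("FF", "NF")


@dataclass(frozen=True)
class MitonuclearGenotype:
    """A nuclear background paired with a mitochondrial background.

    The two-character ``label`` lists the nuclear background first and the
    mitochondrial background second (e.g. ``"ND"`` = N nucleus, D mito).
    """

    nuclear: str
    mitochondrial: str

    def __post_init__(self) -> None:
        if not self.nuclear or not self.mitochondrial:
            raise ValueError("nuclear and mitochondrial backgrounds must be non-empty")

    @property
    def label(self) -> str:
        return f"{self.nuclear}{self.mitochondrial}"

    @classmethod
    def from_label(cls, label: str) -> "MitonuclearGenotype":
        if len(label) != 2:
            raise ValueError(f"genotype label must have 2 characters, got {label!r}")
        return cls(nuclear=label[0], mitochondrial=label[1])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class EvolutionCircumstance:
    """One combination of mitonuclear genotype and evolution medium."""

    genotype: MitonuclearGenotype
    medium: str

    @property
    def label(self) -> str:
        return f"{self.genotype.label}:{self.medium}"

    @classmethod
    def from_label(cls, label: str) -> "EvolutionCircumstance":
        geno, _, medium = label.partition(":")
        if not medium:
            raise ValueError(f"circumstance label must look like 'NN:FF', got {label!r}")
        return cls(MitonuclearGenotype.from_label(geno), medium)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def circumstance_label(genotype: str, medium: str) -> str:
    """Canonical label for a (genotype, medium) pair, e.g. ``"NN:FF"``."""
    return f"{genotype}:{medium}"


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genomic interval with a label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(1-based inclusive, start <= end required)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes plus the mitochondrial chromosome and its coding intervals.

    Coordinates are 1-based inclusive throughout.
    """

    chrom_sizes: Mapping[str, int]
    mito_chrom: str = "chrM"
    mito_coding: Sequence[Interval] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size < 1:
                raise ValueError(f"chromosome {chrom} has non-positive size {size}")
        for iv in self.mito_coding:
            if iv.chrom != self.mito_chrom:
                raise ValueError(f"mito coding interval {iv} is not on {self.mito_chrom}")
            if iv.end > self.chrom_sizes.get(self.mito_chrom, 0):
                raise ValueError(f"mito coding interval {iv} exceeds {self.mito_chrom} size")

    @property
    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.chrom_sizes if c != self.mito_chrom]

    @property
    def total_size(self) -> int:
        return int(sum(self.chrom_sizes.values()))


def reference_base(chrom: str, pos: int) -> str:
    """Deterministic pseudo-reference base for a coordinate.

    Stable across processes and seeds so that independently generated pileups
    (e.g. ancestor and evolved sample) agree on the reference.
    """
    return BASES[zlib.crc32(f"{chrom}:{pos}".encode()) & 3]


@lru_cache(maxsize=64)
def reference_array(chrom: str, size: int) -> np.ndarray:
    """Vector of :func:`reference_base` for positions 1..size (cached)."""
    return np.array([reference_base(chrom, p) for p in range(1, size + 1)])


def default_genome(
    n_nuclear: int = 6, chrom_size: int = 10_000, mito_size: int = 2_000
) -> GenomeModel:
    """A compact synthetic genome for simulation and caller tests.

    ``n_nuclear`` nuclear chromosomes named with roman numerals, plus a
    mitochondrial chromosome whose coding intervals tile half its length.
    """
    romans = [
        "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
        "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
    ]
    if n_nuclear > len(romans):
        raise ValueError(f"at most {len(romans)} nuclear chromosomes supported")
    sizes = {f"chr{r}": chrom_size for r in romans[:n_nuclear]}
    sizes["chrM"] = mito_size
    # coding blocks of 200 bp every 400 bp
    coding = tuple(
        Interval("chrM", s, min(s + 199, mito_size), label=f"mt_cds_{i}")
        for i, s in enumerate(range(1, mito_size, 400))
    )
    return GenomeModel(chrom_sizes=sizes, mito_chrom="chrM", mito_coding=coding)


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Normalize a seed or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
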