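"""Synthetic cohorts, depth/pileup profiles, growth curves and competition series.

Every generator is deterministic given its seed and returns plain pandas
tables alongside ground-truth records, so that downstream callers and
statistics can be exercised in parameter-recovery mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mitoevo.errors import ConfigurationError
from mitoevo.model import (
    BASES,
    DEFAULT_GENOTYPES,
    DEFAULT_MEDIA,
    GenomeModel,
    Interval,
    MitonuclearGenotype,
    circumstance_label,
    default_genome,
    reference_array,
    reference_base,
    rng_from_seed,
)

MUTATION_TYPES = ("SNV", "CNV", "ANEUPLOIDY")

CALL_COLUMNS = [
    "clone_id",
    "type",
    "chromosome",
    "start",
    "end",
    "ref_allele",
    "alt_allele",
    "copy_ratio",
    "annotation",
    "artifact_flag",
]

META_COLUMNS = ["clone_id", "nuclear", "mito", "genotype", "medium", "circumstance"]


@dataclass(frozen=True)
class LocusSpec:
    """An annotated locus with per-circumstance expected mutation counts.

    ``rates`` maps circumstance labels (e.g. ``"NN:FF"``) to the expected
    number of mutations per evolved clone at this locus; circumstances not
    listed fall back to ``base_rate``.
    """

    label: str
    chrom: str
    start: int
    end: int
    base_rate: float = 0.0
    rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_rate < 0 or any(r < 0 for r in self.rates.values()):
            raise ConfigurationError(f"locus {self.label}: rates must be >= 0")
        if self.start < 1 or self.end < self.start:
            raise ConfigurationError(f"locus {self.label}: invalid interval")

    def rate(self, circumstance: str) -> float:
        return float(self.rates.get(circumstance, self.base_rate))


@dataclass
class CohortConfig:
    """Design of a synthetic evolution cohort."""

    genotypes: Sequence[str] = DEFAULT_GENOTYPES
    media: Sequence[str] = DEFAULT_MEDIA
    replicates_per_circumstance: int = 96
    locus_catalog: Sequence[LocusSpec] = ()
    mutation_type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"SNV": 0.9, "CNV": 0.07, "ANEUPLOIDY": 0.03}
    )
    extinction_probability: float = 0.0
    seed: int = 0
    genome: GenomeModel = field(default_factory=default_genome)
    #: allele fraction of planted SNVs; clonal/haploid isolates default to ~1
    snv_allele_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.locus_catalog:
            raise ConfigurationError("locus_catalog must not be empty")
        if self.replicates_per_circumstance < 1:
            raise ConfigurationError("replicates_per_circumstance must be >= 1")
        if not 0.0 <= self.extinction_probability <= 1.0:
            raise ConfigurationError("extinction_probability must be in [0, 1]")
        mix_total = sum(self.mutation_type_mix.values())
        if not math.isclose(mix_total, 1.0, abs_tol=1e-9):
            raise ConfigurationError("mutation_type_mix proportions must sum to 1")
        if any(t not in MUTATION_TYPES for t in self.mutation_type_mix):
            raise ConfigurationError(f"mutation types must be among {MUTATION_TYPES}")
        for g in self.genotypes:
            MitonuclearGenotype.from_label(g)
        for locus in self.locus_catalog:
            if locus.chrom not in self.genome.chrom_sizes:
                raise ConfigurationError(
                    f"locus {locus.label} on unknown chromosome {locus.chrom}"
                )

    @property
    def circumstances(self) -> list[str]:
        return [circumstance_label(g, m) for g in self.genotypes for m in self.media]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort: planted events and parameters."""

    calls: pd.DataFrame
    locus_rates: pd.DataFrame  # columns: circumstance, annotation, rate
    extinct_populations: list[str] = field(default_factory=list)
    gompertz_params: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    selection_coefficients: Mapping[str, float] = field(default_factory=dict)

    def calls_for(self, clone_id: str) -> pd.DataFrame:
        return self.calls[self.calls["clone_id"] == clone_id].reset_index(drop=True)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate one evolved clone per surviving population.

    Returns ``(metadata, calls, truth)``. Per-clone mutation counts at each
    catalog locus are Poisson with the configured per-circumstance rate;
    mutation types are drawn from ``mutation_type_mix``; populations go
    extinct with ``extinction_probability`` before clone isolation.
    """
    rng = rng_from_seed(config.seed)
    type_names = sorted(config.mutation_type_mix)
    type_probs = np.array([config.mutation_type_mix[t] for t in type_names])

    meta_rows: list[dict] = []
    call_rows: list[dict] = []
    extinct: list[str] = []

    for genotype in config.genotypes:
        gt = MitonuclearGenotype.from_label(genotype)
        for medium in config.media:
            circ = circumstance_label(genotype, medium)
            for rep in range(1, config.replicates_per_circumstance + 1):
                pop_id = f"{genotype}-{medium}-r{rep:03d}"
                if rng.random() < config.extinction_probability:
                    extinct.append(pop_id)
                    continue
                meta_rows.append(
                    {
                        "clone_id": pop_id,
                        "nuclear": gt.nuclear,
                        "mito": gt.mitochondrial,
                        "genotype": genotype,
                        "medium": medium,
                        "circumstance": circ,
                    }
                )
                for locus in config.locus_catalog:
                    n_mut = rng.poisson(locus.rate(circ))
                    for _ in range(n_mut):
                        call_rows.append(
                            _plant_mutation(
                                rng, pop_id, locus, config, type_names, type_probs
                            )
                        )

    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    calls = pd.DataFrame(call_rows, columns=CALL_COLUMNS)
    rate_rows = [
        {"circumstance": c, "annotation": locus.label, "rate": locus.rate(c)}
        for c in config.circumstances
        for locus in config.locus_catalog
    ]
    truth = SimTruth(
        calls=calls.copy(),
        locus_rates=pd.DataFrame(rate_rows),
        extinct_populations=extinct,
    )
    return meta, calls, truth


def _plant_mutation(
    rng: np.random.Generator,
    clone_id: str,
    locus: LocusSpec,
    config: CohortConfig,
    type_names: Sequence[str],
    type_probs: np.ndarray,
) -> dict:
    mtype = type_names[rng.choice(len(type_names), p=type_probs)]
    row = {
        "clone_id": clone_id,
        "type": mtype,
        "chromosome": locus.chrom,
        "ref_allele": "",
        "alt_allele": "",
        "copy_ratio": np.nan,
        "annotation": locus.label,
        "artifact_flag": False,
    }
    if mtype == "SNV":
        pos = int(rng.integers(locus.start, locus.end + 1))
        ref = reference_base(locus.chrom, pos)
        alt = rng.choice([b for b in BASES if b != ref])
        row.update(start=pos, end=pos, ref_allele=ref, alt_allele=str(alt))
    elif mtype == "CNV":
        max_len = locus.end - locus.start + 1
        length = int(rng.integers(min(200, max_len), max_len + 1))
        start = int(rng.integers(locus.start, locus.end - length + 2))
        ratio = float(rng.choice([0.5, 2.0]))
        row.update(start=start, end=start + length - 1, copy_ratio=ratio)
    else:  # ANEUPLOIDY: whole chromosome, annotated by chromosome
        size = config.genome.chrom_sizes[locus.chrom]
        ratio = float(rng.choice([0.5, 1.5, 2.0]))
        row.update(start=1, end=size, copy_ratio=ratio, annotation=locus.chrom)
    return row


def generate_depth_profile(
    genome: GenomeModel,
    karyotype: Mapping[str, float] | None = None,
    cnvs: Sequence[tuple[str, int, int, float]] = (),
    mtdna_fraction_target: float | None = None,
    mean_depth: float = 30.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Per-position depth with planted aneuploidies and CNVs.

    Expected depth at a position is ``mean_depth`` times the chromosome's
    karyotype ratio, times the CNV ratio if the position falls inside a
    planted CNV. Multiplicative Gaussian noise with relative SD ``noise_sd``
    is applied and depths are truncated at zero and rounded.
    """
    karyotype = dict(karyotype or {})
    if mean_depth <= 0:
        raise ConfigurationError("mean_depth must be > 0")
    for chrom, ratio in karyotype.items():
        if ratio <= 0:
            raise ConfigurationError(f"karyotype ratio for {chrom} must be > 0")
        if chrom not in genome.chrom_sizes:
            raise ConfigurationError(f"karyotype references unknown chromosome {chrom}")
    for c, s, e, _r in cnvs:
        if c not in genome.chrom_sizes:
            raise ConfigurationError(f"CNV references unknown chromosome {c}")
        if e > genome.chrom_sizes[c]:
            raise ConfigurationError(f"CNV {c}:{s}-{e} exceeds chromosome size")
    ivs = [Interval(c, s, e, label=f"cnv{i}") for i, (c, s, e, _) in enumerate(cnvs)]
    for i, a in enumerate(ivs):
        for b in ivs[i + 1 :]:
            if a.overlaps(b):
                raise ConfigurationError(f"overlapping CNV intervals: {a} / {b}")

    mito_mult = 1.0
    if mtdna_fraction_target is not None:
        mito_mult = _mito_multiplier(genome, mtdna_fraction_target)

    rng = rng_from_seed(seed)
    frames = []
    for chrom, size in genome.chrom_sizes.items():
        expected = np.full(size, mean_depth * karyotype.get(chrom, 1.0))
        if chrom == genome.mito_chrom:
            expected *= mito_mult
        for (c, s, e, ratio), _iv in zip(cnvs, ivs):
            if c == chrom:
                expected[s - 1 : e] *= ratio
        if noise_sd > 0:
            depth = expected * rng.normal(1.0, noise_sd, size=size)
        else:
            depth = expected.copy()
        depth = np.maximum(np.rint(depth), 0).astype(int)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": np.arange(1, size + 1), "depth": depth}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _mito_multiplier(genome: GenomeModel, target: float) -> float:
    """Depth multiplier for chrM yielding the requested mito-coding fraction."""
    if not 0 < target < 1:
        raise ConfigurationError("mtdna_fraction_target must be in (0, 1)")
    l_coding = sum(iv.length for iv in genome.mito_coding)
    l_mito = genome.chrom_sizes[genome.mito_chrom]
    l_nuc = genome.total_size - l_mito
    denom = l_coding - target * l_mito
    if denom <= 0:
        raise ConfigurationError(
            "mtdna_fraction_target unreachable for this genome's coding fraction"
        )
    return target * l_nuc / denom


def generate_pileup(
    genome: GenomeModel,
    snvs: Sequence[tuple[str, int, str, float]] = (),
    depth: int = 30,
    error_rate: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    chroms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Base counts per position with planted SNVs and sequencing error.

    ``snvs`` holds ``(chrom, pos, alt_base, allele_fraction)`` tuples. The
    reference base at each position is the deterministic pseudo-reference of
    :func:`mitoevo.model.reference_base`, so independently generated pileups
    (ancestor vs evolved clone) share coordinates and references.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be > 0")
    if not 0 <= error_rate < 1:
        raise ConfigurationError("error_rate must be in [0, 1)")
    seen: set[tuple[str, int]] = set()
    for chrom, pos, alt, af in snvs:
        if chrom not in genome.chrom_sizes or not 1 <= pos <= genome.chrom_sizes[chrom]:
            raise ConfigurationError(f"SNV at unknown coordinate {chrom}:{pos}")
        if (chrom, pos) in seen:
            raise ConfigurationError(f"duplicate SNV position {chrom}:{pos}")
        seen.add((chrom, pos))
        if not 0 <= af <= 1:
            raise ConfigurationError(f"allele_fraction for {chrom}:{pos} not in [0,1]")
        if alt not in BASES:
            raise ConfigurationError(f"invalid alt base {alt!r}")

    rng = rng_from_seed(seed)
    snv_map = {(c, p): (a, f) for c, p, a, f in snvs}
    use_chroms = list(chroms) if chroms is not None else list(genome.chrom_sizes)
    frames = []
    for chrom in use_chroms:
        size = genome.chrom_sizes[chrom]
        pos = np.arange(1, size + 1)
        refs = reference_array(chrom, size)
        counts = {b: np.zeros(size, dtype=int) for b in BASES}
        base_idx = {b: i for i, b in enumerate(BASES)}

        ref_reads = np.full(size, depth, dtype=int)
        # planted variants first
        for (c, p), (alt, af) in snv_map.items():
            if c != chrom:
                continue
            i = p - 1
            n_alt = int(rng.binomial(depth, af))
            counts[alt][i] += n_alt
            ref_reads[i] = depth - n_alt
        # sequencing error on the remaining (reference) reads
        if error_rate > 0:
            n_err = rng.binomial(ref_reads, error_rate)
            ref_reads = ref_reads - n_err
            with_err = np.nonzero(n_err)[0]
            for i in with_err:
                others = [b for b in BASES if b != refs[i]]
                split = rng.multinomial(n_err[i], [1 / 3] * 3)
                for b, k in zip(others, split):
                    counts[b][i] += int(k)
        for b in BASES:
            counts[b][refs == b] += ref_reads[refs == b]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": refs,
                    "A": counts["A"],
                    "C": counts["C"],
                    "G": counts["G"],
                    "T": counts["T"],
                }
            )
        )
        del base_idx
    return pd.concat(frames, ignore_index=True)


def gompertz(t: np.ndarray, A: float, mu: float, lam: float) -> np.ndarray:
    """Zwietering modified Gompertz curve.

    ``y(t) = A * exp(-exp(mu * e / A * (lam - t) + 1))`` with carrying
    capacity ``A``, maximum specific growth rate ``mu`` and lag ``lam``.
    """
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp(mu * np.e / A * (lam - t) + 1.0))


def generate_growth_curves(
    params: tuple[float, float, float],
    noise_sd: float = 0.0,
    timepoints: Sequence[float] | None = None,
    n_replicates: int = 4,
    seed: int | np.random.Generator | None = 0,
    curve_prefix: str = "curve",
) -> pd.DataFrame:
    """Replicated colony-size time series from a Gompertz curve with noise.

    Returns long-format rows ``(curve_id, time_h, size)``; sizes are
    truncated at zero after additive Gaussian noise.
    """
    A, mu, lam = params
    if A <= 0 or mu <= 0 or lam < 0:
        raise ConfigurationError("require A > 0, mu > 0, lam >= 0")
    if timepoints is None:
        timepoints = np.linspace(0.0, 48.0, 25)
    t = np.asarray(list(timepoints), dtype=float)
    if t.size < 5:
        raise ConfigurationError("at least 5 timepoints required")
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("timepoints must be strictly increasing")
    rng = rng_from_seed(seed)
    y0 = gompertz(t, A, mu, lam)
    frames = []
    for rep in range(1, n_replicates + 1):
        y = y0 + (rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0)
        frames.append(
            pd.DataFrame(
                {"curve_id": f"{curve_prefix}-r{rep:02d}", "time_h": t, "size": np.maximum(y, 0.0)}
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_competition_series(
    s_true: float,
    days: int = 3,
    generations_per_day: float = 5.2,
    initial_ratio: float = 1.0,
    count_depth: int | None = 10_000,
    seed: int | np.random.Generator | None = 0,
    assay_id: str = "assay",
) -> pd.DataFrame:
    """Daily mutant/reference counts under a constant selection coefficient.

    The expected log-ratio changes by ``s_true * generations_per_day`` per
    day. With finite ``count_depth``, daily counts are a multinomial sample
    of that many events; ``count_depth=None`` emits exact expected counts at
    a fixed total of 1e6 (noise-free limit).
    """
    if days < 2:
        raise ConfigurationError("days must be >= 2")
    if initial_ratio <= 0:
        raise ConfigurationError("initial_ratio must be > 0")
    if generations_per_day <= 0:
        raise ConfigurationError("generations_per_day must be > 0")
    if count_depth is not None and count_depth <= 0:
        raise ConfigurationError("count_depth must be > 0 (or None for noise-free)")
    rng = rng_from_seed(seed)
    rows = []
    for day in range(days + 1):
        ratio = initial_ratio * math.exp(s_true * generations_per_day * day)
        p = ratio / (1.0 + ratio)
        if count_depth is None:
            cm, cr = p * 1e6, (1 - p) * 1e6
        else:
            cm = int(rng.binomial(count_depth, p))
            cr = count_depth - cm
        rows.append(
            {"assay_id": assay_id, "day": day, "count_mutant": cm, "count_reference": cr}
        )
    return pd.DataFrame(rows)
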