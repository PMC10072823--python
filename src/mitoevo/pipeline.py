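"""End-to-end pipeline driver: synthetic generation (or user tables) through
calling, profiles, dissimilarity/NMDS/partition and locus specificity.

Every run writes a provenance manifest recording parameters, seeds and
SHA-256 digests of all emitted tables; identical configurations therefore
yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mitoevo import __version__
from mitoevo.calls import annotate_calls, call_aneuploidies, call_cnv_segments, call_snvs
from mitoevo.convergence import (
    bray_curtis_matrix,
    build_profiles,
    locus_specificity,
    nmds_embed,
    partition_dissimilarity,
)
from mitoevo.errors import ConfigurationError, MitoevoError
from mitoevo.io import intervals_to_frame, read_table, write_table
from mitoevo.model import (
    DEFAULT_GENOTYPES,
    DEFAULT_MEDIA,
    GenomeModel,
    Interval,
    default_genome,
)
from mitoevo.simulate import CohortConfig, LocusSpec, generate_cohort, generate_depth_profile, generate_pileup

log = logging.getLogger("mitoevo.pipeline")


class PipelineStageError(MitoevoError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (synthetic or user-data mode)."""

    outdir: str
    run_mode: str = "synthetic"  # or "user-data"
    seed: int = 0
    # synthetic-mode design
    genotypes: Sequence[str] = DEFAULT_GENOTYPES
    media: Sequence[str] = DEFAULT_MEDIA
    replicates_per_circumstance: int = 10
    extinction_probability: float = 0.0
    n_background_loci: int = 12
    base_rate: float = 0.05
    specific_rate: float = 1.0
    n_specific_loci: int = 3
    call_genomes: bool = False
    mean_depth: float = 30.0
    depth_noise_sd: float = 0.03
    pileup_error_rate: float = 0.002
    # analysis parameters
    nmds_n_init: int = 100
    nmds_dims: int = 2
    fdr_alpha: float = 0.05
    mi_sd_mult: float = 2.0
    specificity_factor: str = "medium_x_background"
    # user-data mode inputs
    calls_path: str | None = None
    metadata_path: str | None = None

    def __post_init__(self) -> None:
        if self.run_mode not in ("synthetic", "user-data"):
            raise ConfigurationError("run_mode must be 'synthetic' or 'user-data'")
        if self.run_mode == "user-data":
            for p in (self.calls_path, self.metadata_path):
                if not p or not os.path.exists(p):
                    raise ConfigurationError(f"user-data mode: missing input file {p!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def default_locus_catalog(
    genome: GenomeModel,
    genotypes: Sequence[str],
    media: Sequence[str],
    n_background: int = 12,
    base_rate: float = 0.05,
    specific_rate: float = 1.0,
    n_specific: int = 3,
    seed: int = 0,
) -> list[LocusSpec]:
    """A locus catalog with uniform background loci and a few loci whose
    mutation rate is elevated in one circumstance each (planted specificity)."""
    rng = np.random.default_rng(seed)
    chroms = genome.nuclear_chroms
    loci = []
    n_total = n_background + n_specific
    circumstances = [f"{g}:{m}" for g in genotypes for m in media]
    for i in range(n_total):
        chrom = chroms[i % len(chroms)]
        size = genome.chrom_sizes[chrom]
        start = int(rng.integers(1, max(2, size - 1_000)))
        end = min(size, start + 999)
        if i < n_specific:
            circ = circumstances[i % len(circumstances)]
            loci.append(
                LocusSpec(
                    label=f"spec{i+1:02d}", chrom=chrom, start=start, end=end,
                    base_rate=base_rate, rates={circ: specific_rate},
                )
            )
        else:
            loci.append(
                LocusSpec(
                    label=f"gene{i+1:02d}", chrom=chrom, start=start, end=end,
                    base_rate=base_rate,
                )
            )
    return loci


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the provenance manifest (also written).

    Stage order in synthetic mode: generate -> (optional) call -> profiles ->
    dissimilarity -> NMDS -> partition -> specificity -> manifest. Any stage
    failure raises :class:`PipelineStageError`; outputs of completed stages
    are retained on disk.
    """
    os.makedirs(config.outdir, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = os.path.join(config.outdir, name)
        write_table(df, path, index=index)
        outputs[name] = path

    genome = default_genome()

    if config.run_mode == "synthetic":
        try:
            log.info("stage=generate seed=%d", config.seed)
            catalog = default_locus_catalog(
                genome, config.genotypes, config.media,
                n_background=config.n_background_loci,
                base_rate=config.base_rate,
                specific_rate=config.specific_rate,
                n_specific=config.n_specific_loci,
                seed=config.seed,
            )
            cohort_cfg = CohortConfig(
                genotypes=tuple(config.genotypes),
                media=tuple(config.media),
                replicates_per_circumstance=config.replicates_per_circumstance,
                locus_catalog=catalog,
                extinction_probability=config.extinction_probability,
                seed=config.seed,
                genome=genome,
            )
            metadata, truth_calls, truth = generate_cohort(cohort_cfg)
            emit("metadata.tsv", metadata)
            emit("truth_calls.tsv", truth_calls)
            emit("locus_rates.tsv", truth.locus_rates)
            features = [Interval(l.chrom, l.start, l.end, l.label) for l in catalog]
            emit("features.tsv", intervals_to_frame(features))
        except Exception as exc:
            raise PipelineStageError("generate", exc) from exc

        if config.call_genomes:
            try:
                log.info("stage=call n_clones=%d", len(metadata))
                calls = _call_from_planted(
                    metadata, truth_calls, genome, features, config
                )
            except Exception as exc:
                raise PipelineStageError("call", exc) from exc
        else:
            calls = truth_calls
        emit("calls.tsv", calls)
    else:
        try:
            log.info("stage=load calls=%s", config.calls_path)
            calls = read_table(config.calls_path)
            metadata = read_table(config.metadata_path)
        except Exception as exc:
            raise PipelineStageError("load", exc) from exc

    try:
        log.info("stage=profiles")
        profiles = build_profiles(calls, metadata)
        emit("profiles.tsv", profiles.reset_index())
    except Exception as exc:
        raise PipelineStageError("profiles", exc) from exc

    try:
        log.info("stage=dissimilarity")
        D = bray_curtis_matrix(profiles)
        emit("bray_curtis.tsv", D.reset_index())
    except Exception as exc:
        raise PipelineStageError("dissimilarity", exc) from exc

    try:
        log.info("stage=nmds n_init=%d", config.nmds_n_init)
        dims = min(config.nmds_dims, len(D) - 1)
        if dims < config.nmds_dims:
            log.warning("nmds dims clamped to %d (only %d circumstances)", dims, len(D))
        nmds = nmds_embed(D, dims=dims, n_init=config.nmds_n_init, seed=config.seed)
        coords = nmds.coordinates.reset_index().rename(columns={"index": "circumstance"})
        coords["stress"] = nmds.stress
        emit("nmds_coords.tsv", coords)
    except Exception as exc:
        raise PipelineStageError("nmds", exc) from exc

    try:
        log.info("stage=partition")
        pairs, anova = partition_dissimilarity(D)
        emit("dissimilarity_pairs.tsv", pairs)
        emit("partition_anova.tsv", anova)
    except Exception as exc:
        raise PipelineStageError("partition", exc) from exc

    try:
        log.info("stage=specificity factor=%s", config.specificity_factor)
        spec = locus_specificity(
            calls,
            metadata,
            factor=config.specificity_factor,
            fdr_alpha=config.fdr_alpha,
            mi_sd_mult=config.mi_sd_mult,
        )
        emit("specificity.tsv", spec)
    except Exception as exc:
        raise PipelineStageError("specificity", exc) from exc

    manifest = {
        "package_version": __version__,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()},
        "outputs": {
            name: _sha256(path) for name, path in sorted(outputs.items())
        },
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("stage=done outputs=%d", len(outputs))
    return manifest


def _call_from_planted(
    metadata: pd.DataFrame,
    truth_calls: pd.DataFrame,
    genome: GenomeModel,
    features: Sequence[Interval],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Regenerate per-clone depth/pileup from planted events and re-call them."""
    seeds = np.random.SeedSequence(config.seed).spawn(len(metadata) + 1)
    ancestor = generate_pileup(
        genome, snvs=(), depth=int(config.mean_depth),
        error_rate=0.0, seed=np.random.default_rng(seeds[-1]),
    )
    all_calls = []
    for i, clone in enumerate(metadata["clone_id"]):
        planted = truth_calls[truth_calls["clone_id"] == clone]
        karyotype, cnvs, snvs = _planted_to_events(planted, genome)
        rng = np.random.default_rng(seeds[i])
        depth = generate_depth_profile(
            genome, karyotype=karyotype, cnvs=cnvs,
            mean_depth=config.mean_depth, noise_sd=config.depth_noise_sd, seed=rng,
        )
        aneu = call_aneuploidies(depth)
        cnv = call_cnv_segments(depth)
        pileup = generate_pileup(
            genome, snvs=snvs, depth=int(config.mean_depth),
            error_rate=config.pileup_error_rate, seed=rng,
        )
        snv = call_snvs(pileup, ancestor)
        for part in (
            annotate_calls(snv, features, clone_id=clone),
            annotate_calls(cnv, features, clone_id=clone),
            annotate_calls(aneu, features, clone_id=clone),
        ):
            if len(part):
                all_calls.append(part)
    if not all_calls:
        return truth_calls.iloc[0:0]
    return pd.concat(all_calls, ignore_index=True)


def _planted_to_events(planted: pd.DataFrame, genome: GenomeModel):
    """Convert planted calls into non-conflicting generator inputs."""
    karyotype: dict[str, float] = {}
    cnvs: list[tuple[str, int, int, float]] = []
    snvs: list[tuple[str, int, str, float]] = []
    seen_pos: set[tuple[str, int]] = set()
    for _, row in planted.iterrows():
        if row["type"] == "ANEUPLOIDY":
            karyotype.setdefault(row["chromosome"], float(row["copy_ratio"]))
        elif row["type"] == "CNV":
            cand = (row["chromosome"], int(row["start"]), int(row["end"]), float(row["copy_ratio"]))
            if not any(
                c == cand[0] and s <= cand[2] and cand[1] <= e for c, s, e, _ in cnvs
            ):
                cnvs.append(cand)
        else:
            key = (row["chromosome"], int(row["start"]))
            if key not in seen_pos:
                seen_pos.add(key)
                snvs.append((row["chromosome"], int(row["start"]), row["alt_allele"], 1.0))
    return karyotype, cnvs, snvs


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
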