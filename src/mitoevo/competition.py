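"""Selection-coefficient estimation from competition assays.

The selection coefficient per generation is the OLS slope of
``ln(count_mutant / count_reference)`` on elapsed generations. Fitness
effects across genotypes feed a per-locus nuclear x mitochondrial ANOVA and
a rank-concordance test against evolved mutation frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mitoevo.errors import ConfigurationError, InsufficientSeriesError
from mitoevo.growth import factorial_anova
from mitoevo.model import MitonuclearGenotype

GENERATIONS_PER_DAY = 5.2  # ~300 generations over 58 daily passages
ZERO_PSEUDOCOUNT = 0.5


@dataclass
class FitnessEffect:
    """Per-generation selection coefficient for one competition assay."""

    s: float
    se: float
    r2: float
    n_days: int
    genotype: str = ""
    locus: str = ""
    medium: str = ""


def estimate_fitness(
    series: pd.DataFrame,
    generations_per_day: float = GENERATIONS_PER_DAY,
    pseudocount: float = ZERO_PSEUDOCOUNT,
    genotype: str = "",
    locus: str = "",
    medium: str = "",
) -> FitnessEffect:
    """OLS fit of the log count ratio against elapsed generations.

    ``series`` needs columns (day, count_mutant, count_reference). Days on
    which either count is zero receive ``pseudocount`` added to both
    populations; days where both counts are zero are dropped.
    """
    if generations_per_day <= 0:
        raise ConfigurationError("generations_per_day must be > 0")
    df = series.sort_values("day").copy()
    cm = df["count_mutant"].to_numpy(dtype=float)
    cr = df["count_reference"].to_numpy(dtype=float)
    if (cm < 0).any() or (cr < 0).any():
        raise ConfigurationError("counts must be >= 0")
    both_zero = (cm == 0) & (cr == 0)
    cm, cr = cm[~both_zero], cr[~both_zero]
    days = df["day"].to_numpy(dtype=float)[~both_zero]
    any_zero = (cm == 0) | (cr == 0)
    cm = cm + pseudocount * any_zero
    cr = cr + pseudocount * any_zero
    if days.size < 3:
        raise InsufficientSeriesError(f"only {days.size} usable timepoints (need >= 3)")

    x = days * generations_per_day
    y = np.log(cm / cr)
    res = stats.linregress(x, y)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return FitnessEffect(
        s=float(res.slope),
        se=se,
        r2=r2,
        n_days=int(days.size),
        genotype=genotype,
        locus=locus,
        medium=medium,
    )


def estimate_fitness_table(
    assays: pd.DataFrame,
    generations_per_day: float = GENERATIONS_PER_DAY,
    pseudocount: float = ZERO_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Apply :func:`estimate_fitness` per assay_id.

    ``assays`` is long format with columns (assay_id, day, count_mutant,
    count_reference) and optional (genotype, locus, medium) metadata that is
    carried through.
    """
    rows = []
    meta_cols = [c for c in ("genotype", "locus", "medium") if c in assays.columns]
    for assay_id, sub in assays.groupby("assay_id", sort=True):
        meta = {c: sub[c].iloc[0] for c in meta_cols}
        eff = estimate_fitness(
            sub, generations_per_day=generations_per_day, pseudocount=pseudocount, **meta
        )
        rows.append(
            {
                "assay_id": assay_id,
                "s": eff.s,
                "se": eff.se,
                "r2": eff.r2,
                "n_days": eff.n_days,
                **meta,
            }
        )
    return pd.DataFrame(rows)


def fitness_matrix(
    effects: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Locus x genotype mean-s matrices per medium, plus per-locus ANOVA.

    ``effects`` needs columns (s, genotype, locus, medium), one row per
    assay replicate. For every locus with >= 2 genotypes, a two-way
    nuclear x mitochondrial ANOVA is run on the replicate-level selection
    coefficients. Loci with a single genotype are skipped.
    """
    required = {"s", "genotype", "locus", "medium"}
    if missing := required - set(effects.columns):
        raise ConfigurationError(f"effects table missing columns: {sorted(missing)}")
    matrices = {}
    for medium, sub in effects.groupby("medium", sort=True):
        matrices[medium] = sub.pivot_table(
            index="locus", columns="genotype", values="s", aggfunc="mean"
        )

    anova_rows = []
    for locus, sub in effects.groupby("locus", sort=True):
        genotypes = sub["genotype"].unique()
        if len(genotypes) < 2:
            continue
        nuclear = [MitonuclearGenotype.from_label(g).nuclear for g in sub["genotype"]]
        mito = [MitonuclearGenotype.from_label(g).mitochondrial for g in sub["genotype"]]
        if len(set(nuclear)) < 2 or len(set(mito)) < 2:
            continue
        table = factorial_anova(
            sub["s"], {"nuclear": nuclear, "mito": mito}, include_interactions=True
        )
        table.insert(0, "locus", locus)
        anova_rows.append(table)
    anova = (
        pd.concat(anova_rows, ignore_index=True)
        if anova_rows
        else pd.DataFrame(columns=["locus", "term", "sum_sq", "df", "F", "p"])
    )
    return matrices, anova


@dataclass
class ConcordanceResult:
    """Agreement between fitness-effect ranking and mutation frequency."""

    rho: float
    rho_p: float
    slope_p: float
    concordant: bool
    n: int


def rank_concordance(
    fitness_effects: np.ndarray | pd.Series,
    mutation_frequencies: np.ndarray | pd.Series,
    rho_threshold: float = 0.7,
    slope_alpha: float = 0.05,
) -> ConcordanceResult:
    """Spearman rank correlation plus regression-slope test.

    ``concordant`` requires Spearman rho above ``rho_threshold`` AND p <
    ``slope_alpha`` for the null that the OLS slope of one vector on the
    other is zero. Constant vectors make rho undefined (NaN, not concordant).
    """
    x = np.asarray(fitness_effects, dtype=float)
    y = np.asarray(mutation_frequencies, dtype=float)
    if x.size != y.size:
        raise ConfigurationError("vectors must be aligned")
    if x.size < 3:
        raise ConfigurationError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConcordanceResult(np.nan, np.nan, np.nan, False, int(x.size))
    rho, rho_p = stats.spearmanr(x, y)
    slope_p = float(stats.linregress(x, y).pvalue)
    concordant = bool(rho > rho_threshold and slope_p < slope_alpha)
    return ConcordanceResult(float(rho), float(rho_p), slope_p, concordant, int(x.size))
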