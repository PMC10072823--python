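"""Mutational-profile convergence statistics.

Builds circumstance x annotation count profiles, compares them by
Bray-Curtis dissimilarity, ordains them by nonmetric MDS (SMACOF with
monotone regression, Kruskal stress-1), partitions pairwise dissimilarity
by match/mismatch of environment and backgrounds, and scores per-locus
specificity with a joint chi-square / mutual-information criterion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from mitoevo.errors import ConfigurationError
from mitoevo.growth import factorial_anova
from mitoevo.model import EvolutionCircumstance

#: pyrimidine-context single-nucleotide substitution classes
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

FACTOR_COLUMNS = {
    "medium": "medium",
    "mitonuclear": "genotype",
    "nuclear": "nuclear",
    "mito": "mito",
    "medium_x_background": "circumstance",
}


def build_profiles(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    drop_artifacts: bool = True,
) -> pd.DataFrame:
    """Circumstance x annotation matrix of mutation counts.

    Every non-artifact call contributes exactly one count under its
    annotation, regardless of mutation type or size. Unknown clone_ids in
    ``calls`` are an error.
    """
    meta = metadata.set_index("clone_id")
    unknown = set(calls["clone_id"]) - set(meta.index)
    if unknown:
        raise ConfigurationError(f"calls reference unknown clone_ids: {sorted(unknown)[:5]}")
    use = calls
    if drop_artifacts and "artifact_flag" in calls.columns:
        use = calls[~calls["artifact_flag"].astype(bool)]
    circ = meta.loc[use["clone_id"], "circumstance"].to_numpy()
    table = pd.crosstab(pd.Series(circ, name="circumstance"), use["annotation"])
    # include circumstances with zero calls so the design stays rectangular
    all_circ = sorted(metadata["circumstance"].unique())
    table = table.reindex(all_circ, fill_value=0)
    table.columns.name = "annotation"
    return table


def bray_curtis_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between profile rows.

    ``BC(u, v) = 1 - 2 * sum(min(u, v)) / (sum(u) + sum(v))``. A pair of
    all-zero rows is undefined and reported as NaN with a warning.
    """
    if len(profiles) < 2:
        raise ConfigurationError("need >= 2 profile rows")
    X = profiles.to_numpy(dtype=float)
    zero_rows = X.sum(axis=1) == 0
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    if zero_rows.any():
        warnings.warn("all-zero profile rows: their pairwise dissimilarities are undefined")
        zz = np.outer(zero_rows, zero_rows)
        D[zz] = np.nan
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=profiles.index, columns=profiles.index)


@dataclass
class NmdsResult:
    """Best nonmetric-MDS embedding over all random initializations."""

    coordinates: pd.DataFrame
    stress: float
    n_init_used: int
    converged: bool
    all_stresses: np.ndarray


def nmds_embed(
    D: pd.DataFrame,
    dims: int = 2,
    n_init: int = 10_000,
    max_iter: int = 3_000,
    tol: float = 1e-9,
    seed: int = 0,
) -> NmdsResult:
    """Nonmetric MDS minimizing Kruskal stress-1, best of ``n_init`` starts.

    SMACOF iterations alternate a Guttman transform with monotone (isotonic)
    regression of configuration distances on dissimilarity ranks; ties in
    the dissimilarities are handled by the primary approach (tied pairs may
    untie freely). Deterministic given ``seed``.
    """
    n = len(D)
    if dims >= n:
        raise ConfigurationError("dims must be < number of points")
    Dm = np.asarray(D, dtype=float)
    d = squareform(Dm, checks=False)
    if np.isnan(d).any():
        raise ConfigurationError("dissimilarity matrix contains NaN")
    rng = np.random.default_rng(seed)

    best_X, best_stress, best_conv = None, np.inf, False
    stresses = np.empty(n_init)
    scale = max(d.max(), 1.0)
    for i in range(n_init):
        X0 = rng.normal(scale=scale, size=(n, dims))
        X, stress, conv = _smacof_single(d, X0, max_iter, tol)
        stresses[i] = stress
        if stress < best_stress:
            best_X, best_stress, best_conv = X, stress, conv
    coords = pd.DataFrame(
        best_X, index=D.index, columns=[f"dim{i+1}" for i in range(dims)]
    )
    return NmdsResult(coords, float(best_stress), n_init, best_conv, stresses)


def _monotone_disparities(d: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Primary-ties monotone regression of distances against dissimilarity order."""
    order = np.lexsort((dist, d))
    fitted = isotonic_regression(dist[order]).x
    dhat = np.empty_like(dist)
    dhat[order] = fitted
    return dhat


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom <= 0:
        return np.inf
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _smacof_single(
    d: np.ndarray, X: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool]:
    n = X.shape[0]
    old_stress = np.inf
    converged = False
    stress = np.inf
    for _ in range(max_iter):
        dist = pdist(X)
        dist = np.maximum(dist, 1e-12)
        dhat = _monotone_disparities(d, dist)
        stress = _stress1(dist, dhat)
        if old_stress - stress < tol:
            converged = True
            break
        old_stress = stress
        # Guttman transform with disparities as target distances
        ratio = squareform(dhat / dist, checks=False)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = B @ X / n
    return X, stress, converged


def partition_dissimilarity(
    D: pd.DataFrame,
    circumstances: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify circumstance pairs by match/mismatch and run a 3-way ANOVA.

    ``circumstances`` optionally maps the labels of ``D`` to ``nuclear``,
    ``mito`` and ``medium`` columns; by default labels are parsed as
    ``"<nuclear><mito>:<medium>"``. Returns (pair table, ANOVA table); the
    pair table has one row per unordered pair with the three match booleans
    and the pair's dissimilarity.
    """
    labels = list(D.index)
    if circumstances is None:
        parsed = {}
        for lab in labels:
            c = EvolutionCircumstance.from_label(lab)
            parsed[lab] = (c.genotype.nuclear, c.genotype.mitochondrial, c.medium)
    else:
        cc = circumstances.set_index(circumstances.columns[0]) if (
            "circumstance" not in circumstances.columns
        ) else circumstances.set_index("circumstance")
        parsed = {
            lab: (cc.at[lab, "nuclear"], cc.at[lab, "mito"], cc.at[lab, "medium"])
            for lab in labels
        }

    rows = []
    for a, b in itertools.combinations(labels, 2):
        na, ma, ea = parsed[a]
        nb, mb, eb = parsed[b]
        rows.append(
            {
                "circumstance_a": a,
                "circumstance_b": b,
                "env_match": ea == eb,
                "nuclear_match": na == nb,
                "mito_match": ma == mb,
                "dissimilarity": float(D.at[a, b]),
            }
        )
    pairs = pd.DataFrame(rows)
    factors = {
        "env_match": pairs["env_match"],
        "nuclear_match": pairs["nuclear_match"],
        "mito_match": pairs["mito_match"],
    }
    constant = [k for k, v in factors.items() if v.nunique() < 2]
    if constant:
        warnings.warn(f"match factors constant across pairs, dropped: {constant}")
        factors = {k: v for k, v in factors.items() if k not in constant}
    if len(factors) < 2:
        raise ConfigurationError("fewer than 2 varying match factors; ANOVA undefined")
    anova = factorial_anova(pairs["dissimilarity"], factors, include_interactions=True)
    return pairs, anova


def mutual_information_dits(table: np.ndarray) -> float:
    """Mutual information of a contingency table's joint distribution, in dits.

    Zero exactly when rows and columns are independent; log base 10.
    """
    T = np.asarray(table, dtype=float)
    N = T.sum()
    if N <= 0:
        raise ConfigurationError("contingency table is empty")
    P = T / N
    pr = P.sum(axis=1, keepdims=True)
    pc = P.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = P * np.log10(P / (pr @ pc))
    return float(np.nansum(terms))


def locus_specificity(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    factor: str = "medium_x_background",
    fdr_alpha: float = 0.05,
    mi_sd_mult: float = 2.0,
    drop_artifacts: bool = True,
    monte_carlo: bool = False,
    n_resamples: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each annotation for nonrandom distribution across factor levels.

    For each annotation, a 2 x k contingency table of in-locus vs out-of-locus
    call counts across the ``factor`` levels is submitted to a chi-square
    test of independence; p-values are BH-adjusted over annotations and
    mutual information (dits) is computed from the same table. An annotation
    is ``specific`` when q <= ``fdr_alpha`` and its MI is at least
    ``mi_sd_mult`` standard deviations above the mean MI over all tested
    annotations.

    ``monte_carlo`` switches to a permutation chi-square p-value, for tables
    with small expected counts.
    """
    col = FACTOR_COLUMNS.get(factor)
    if col is None:
        raise ConfigurationError(
            f"factor must be one of {sorted(FACTOR_COLUMNS)}, got {factor!r}"
        )
    use = calls
    if drop_artifacts and "artifact_flag" in calls.columns:
        use = calls[~calls["artifact_flag"].astype(bool)]
    if use.empty:
        raise ConfigurationError("no calls to test")
    meta = metadata.set_index("clone_id")
    categories = meta.loc[use["clone_id"], col].to_numpy()
    levels = sorted(pd.unique(categories))
    if len(levels) < 2:
        raise ConfigurationError("factor must have >= 2 observed categories")

    totals = (
        pd.Series(1, index=range(len(use)))
        .groupby(categories)
        .sum()
        .reindex(levels, fill_value=0)
        .to_numpy()
    )
    in_counts = (
        pd.crosstab(use["annotation"].to_numpy(), categories)
        .reindex(columns=levels, fill_value=0)
    )

    rng = np.random.default_rng(seed)
    rows = []
    small_expected: list[str] = []
    for annotation, in_row in in_counts.iterrows():
        inside = in_row.to_numpy()
        if inside.sum() == 0:
            continue
        table = np.vstack([inside, totals - inside])
        keep = table.sum(axis=0) > 0
        tab = table[:, keep]
        if tab.shape[1] < 2 or (tab.sum(axis=1) == 0).any():
            continue
        expected = stats.contingency.expected_freq(tab)
        if (expected < 1).any():
            small_expected.append(str(annotation))
        if monte_carlo:
            chi2, p = _monte_carlo_chi2(tab, n_resamples, rng)
        else:
            res = stats.chi2_contingency(tab, correction=False)
            chi2, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "annotation": annotation,
                "n_calls": int(inside.sum()),
                "chi2_stat": chi2,
                "p_value": p,
                "mi_dits": mutual_information_dits(table),
            }
        )
    if not rows:
        raise ConfigurationError("no annotation had calls to test")
    if small_expected:
        warnings.warn(
            f"{len(small_expected)} annotations with expected counts < 1 "
            f"(e.g. {small_expected[:3]}); consider monte_carlo=True"
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    mi_mean, mi_sd = out["mi_dits"].mean(), out["mi_dits"].std(ddof=1)
    if not np.isfinite(mi_sd):
        mi_sd = 0.0
    out["mi_threshold"] = mi_mean + mi_sd_mult * mi_sd
    out["specific"] = (out["q_value"] <= fdr_alpha) & (out["mi_dits"] >= out["mi_threshold"])
    return out


def _monte_carlo_chi2(
    table: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Permutation p-value for the chi-square statistic at fixed margins."""
    obs = stats.chi2_contingency(table, correction=False).statistic
    r_margin = table.sum(axis=1)
    c_margin = table.sum(axis=0)
    hits = 0
    for _ in range(n_resamples):
        sim = stats.random_table(r_margin, c_margin).rvs(random_state=rng)
        sim_stat = stats.chi2_contingency(sim, correction=False).statistic
        if sim_stat >= obs - 1e-12:
            hits += 1
    return float(obs), (hits + 1) / (n_resamples + 1)


def count_distribution_test(
    counts: np.ndarray | pd.Series,
    expected_proportions: np.ndarray | None = None,
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of counts against expected proportions.

    Default expectation is uniform across categories.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ConfigurationError("need >= 2 categories")
    if expected_proportions is None:
        expected = np.full(c.size, c.sum() / c.size)
    else:
        p = np.asarray(expected_proportions, dtype=float)
        if p.size != c.size:
            raise ConfigurationError("expected_proportions length mismatch")
        expected = p / p.sum() * c.sum()
    if (expected <= 0).any():
        raise ConfigurationError("expected count of zero in some category")
    res = stats.chisquare(c, expected)
    return float(res.statistic), float(res.pvalue)


def substitution_class(ref: str, alt: str) -> str:
    """Collapse a substitution to its pyrimidine-context class (e.g. G>T -> C>A)."""
    ref, alt = ref.upper(), alt.upper()
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    cls = f"{ref}>{alt}"
    if cls not in SPECTRUM_CLASSES:
        raise ConfigurationError(f"not a single-base substitution: {ref}>{alt}")
    return cls


def mutation_spectrum_test(
    snv_calls: pd.DataFrame,
    groups: pd.Series | dict,
) -> tuple[pd.DataFrame, float, float]:
    """Compare nucleotide-level mutation spectra between clone groups.

    SNVs are collapsed to the six pyrimidine-context substitution classes;
    the group x class count table is submitted to a chi-square test of
    independence. Groups with zero SNVs are excluded with a warning.
    Returns ``(spectrum table, chi2, p)``.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    snvs = snv_calls[snv_calls["type"] == "SNV"] if "type" in snv_calls.columns else snv_calls
    ref_col = "ref_allele" if "ref_allele" in snvs.columns else "ref"
    alt_col = "alt_allele" if "alt_allele" in snvs.columns else "alt"
    if snvs.empty:
        raise ConfigurationError("no SNVs supplied")
    classes = [
        substitution_class(r, a) for r, a in zip(snvs[ref_col], snvs[alt_col])
    ]
    glabels = groups.reindex(snvs["clone_id"]).to_numpy()
    table = (
        pd.crosstab(pd.Series(glabels, name="group"), pd.Series(classes, name="class"))
        .reindex(columns=list(SPECTRUM_CLASSES), fill_value=0)
    )
    empty = table.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"groups with zero SNVs excluded: {list(table.index[empty])}")
        table = table[~empty]
    if len(table) < 2:
        raise ConfigurationError("need >= 2 non-empty groups")
    tab = table.loc[:, table.sum(axis=0) > 0]
    res = stats.chi2_contingency(tab, correction=False)
    return table, float(res.statistic), float(res.pvalue)


def phenotype_association(
    calls: pd.DataFrame,
    phenotypes: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    min_mutant_clones: int = 5,
    by_circumstance: bool = False,
    drop_artifacts: bool = True,
) -> pd.DataFrame:
    """Rank-sum association between mutant status per annotation and phenotype.

    ``phenotypes`` holds (clone_id, value). For each annotation (optionally
    within each circumstance), clones mutant at the annotation are compared
    with non-mutant clones by Mann-Whitney; annotations with fewer than
    ``min_mutant_clones`` clones on either side are skipped. BH correction
    is applied over all emitted rows. Effect size is the difference of group
    means.
    """
    use = calls
    if drop_artifacts and "artifact_flag" in calls.columns:
        use = calls[~calls["artifact_flag"].astype(bool)]
    pheno = phenotypes.dropna(subset=["value"]).set_index("clone_id")["value"]

    if by_circumstance:
        if metadata is None:
            raise ConfigurationError("metadata required when by_circumstance=True")
        meta = metadata.set_index("clone_id")
        strata = {
            circ: set(meta.index[meta["circumstance"] == circ])
            for circ in meta["circumstance"].unique()
        }
    else:
        strata = {"all": set(pheno.index)}

    rows = []
    for stratum, clone_set in sorted(strata.items()):
        clones = sorted(clone_set & set(pheno.index))
        if not clones:
            continue
        values = pheno.loc[clones]
        stratum_calls = use[use["clone_id"].isin(clone_set)]
        for annotation, sub in stratum_calls.groupby("annotation", sort=True):
            mutants = set(sub["clone_id"]) & set(clones)
            others = set(clones) - mutants
            if len(mutants) < min_mutant_clones or len(others) < min_mutant_clones:
                continue
            ym = values.loc[sorted(mutants)].to_numpy()
            yo = values.loc[sorted(others)].to_numpy()
            res = stats.mannwhitneyu(ym, yo, alternative="two-sided")
            rows.append(
                {
                    "stratum": stratum,
                    "annotation": annotation,
                    "n_mutant": len(mutants),
                    "n_other": len(others),
                    "effect_size": float(ym.mean() - yo.mean()),
                    "p_value": float(res.pvalue),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["stratum", "annotation", "n_mutant", "n_other", "effect_size", "p_value"],
    )
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
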