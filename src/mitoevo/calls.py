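"""Depth- and pileup-based callers for genomic changes in evolved clones.

Inputs are per-position depth tables (samtools-depth dialect: chrom, pos,
depth, already base-quality gated) and pileup base-count tables. Callers
emit tidy pandas tables; :func:`annotate_calls` converts them into the
unified mutation-call table consumed by the convergence statistics.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mitoevo.errors import CoordinateMismatchError, ConfigurationError
from mitoevo.model import BASES, Interval
from mitoevo.simulate import CALL_COLUMNS

ANEUPLOIDY_WINDOW_BP = 1_000
ANEUPLOIDY_GAIN = 1.35
ANEUPLOIDY_LOSS = 0.65
CNV_WINDOW_BP = 50
CNV_GAIN = 1.5
CNV_LOSS = 0.5
CNV_MIN_LEN_BP = 150
SNV_MIN_DEPTH = 10
SNV_MIN_ALT_FRACTION = 0.8
SNV_MAX_ANCESTOR_ALT_FRACTION = 0.05


def mtdna_fraction(depth: pd.DataFrame, mito_coding: Sequence[Interval]) -> float:
    """Fraction of sequenced bases falling in mitochondrial coding regions.

    Sum of depth over the mito coding intervals divided by the sum of depth
    over the whole table. The depth table is assumed base-quality gated
    upstream (>Q20).
    """
    total = float(depth["depth"].sum())
    if total <= 0:
        raise ConfigurationError("total depth is zero: mtDNA fraction undefined")
    mito_sum = 0.0
    for iv in mito_coding:
        rows = depth[
            (depth["chrom"] == iv.chrom)
            & (depth["pos"] >= iv.start)
            & (depth["pos"] <= iv.end)
        ]
        mito_sum += float(rows["depth"].sum())
    return mito_sum / total


def _window_medians(pos: np.ndarray, depth: np.ndarray, window_bp: int) -> np.ndarray:
    """Median depth per fixed-size window; trailing partial window kept if >= half."""
    order = np.argsort(pos)
    d = depth[order]
    n_full = d.size // window_bp
    meds = []
    for w in range(n_full):
        meds.append(np.median(d[w * window_bp : (w + 1) * window_bp]))
    rest = d[n_full * window_bp :]
    if rest.size >= window_bp // 2:
        meds.append(np.median(rest))
    return np.asarray(meds, dtype=float)


def call_aneuploidies(
    depth: pd.DataFrame,
    min_ratio_gain: float = ANEUPLOIDY_GAIN,
    max_ratio_loss: float = ANEUPLOIDY_LOSS,
    alpha: float = 0.05,
    window_bp: int = ANEUPLOIDY_WINDOW_BP,
    exclude_chroms: Sequence[str] = ("chrM",),
) -> pd.DataFrame:
    """Whole-chromosome copy-number calls from relative depth of coverage.

    For each chromosome, its windowed median depths are compared with those
    of all other chromosomes: ``copy_ratio`` is the ratio of medians, and a
    call requires both the ratio beyond threshold and a Bonferroni-corrected
    Mann-Whitney rank test at ``alpha``.

    Returns columns ``chromosome, copy_ratio, direction, p_value, n_windows``.
    """
    usable = depth[~depth["chrom"].isin(exclude_chroms)]
    chroms = list(dict.fromkeys(usable["chrom"]))
    if len(chroms) < 2:
        raise ConfigurationError("need >= 2 chromosomes to call aneuploidies")
    windows: dict[str, np.ndarray] = {}
    for chrom in chroms:
        sub = usable[usable["chrom"] == chrom]
        meds = _window_medians(sub["pos"].to_numpy(), sub["depth"].to_numpy(), window_bp)
        if meds.size == 0:
            warnings.warn(f"{chrom}: shorter than one {window_bp}-bp window, skipped")
            continue
        windows[chrom] = meds

    n_tests = len(windows)
    rows = []
    for chrom, meds in windows.items():
        rest = np.concatenate([w for c, w in windows.items() if c != chrom])
        rest_med = np.median(rest)
        if rest_med <= 0:
            warnings.warn(f"{chrom}: zero baseline depth, skipped")
            continue
        ratio = float(np.median(meds) / rest_med)
        if not (ratio >= min_ratio_gain or ratio <= max_ratio_loss):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ties with zero variance
            p = stats.mannwhitneyu(meds, rest, alternative="two-sided").pvalue
        p_adj = min(1.0, float(p) * n_tests)
        if p_adj >= alpha:
            continue
        rows.append(
            {
                "chromosome": chrom,
                "copy_ratio": ratio,
                "direction": "gain" if ratio > 1 else "loss",
                "p_value": p_adj,
                "n_windows": int(meds.size),
            }
        )
    return pd.DataFrame(
        rows, columns=["chromosome", "copy_ratio", "direction", "p_value", "n_windows"]
    )


def call_cnv_segments(
    depth: pd.DataFrame,
    window_bp: int = CNV_WINDOW_BP,
    gain_threshold: float = CNV_GAIN,
    loss_threshold: float = CNV_LOSS,
    min_len_bp: int = CNV_MIN_LEN_BP,
    exclude_chroms: Sequence[str] = ("chrM",),
) -> pd.DataFrame:
    """Sub-chromosomal CNV calls from windowed, chromosome-normalized depth.

    Window means are normalized by the enclosing chromosome's median depth
    (which also absorbs whole-chromosome aneuploid shifts); maximal runs of
    consecutive windows beyond threshold spanning at least ``min_len_bp``
    become calls with ``copy_ratio`` the mean normalized depth over the run.

    Returns columns ``chromosome, start, end, copy_ratio, n_windows,
    direction, artifact_flag``.
    """
    if window_bp < 1:
        raise ConfigurationError("window_bp must be >= 1")
    rows = []
    for chrom in dict.fromkeys(depth["chrom"]):
        if chrom in exclude_chroms:
            continue
        sub = depth[depth["chrom"] == chrom].sort_values("pos")
        d = sub["depth"].to_numpy(dtype=float)
        pos = sub["pos"].to_numpy()
        chrom_median = np.median(d)
        if chrom_median <= 0:
            warnings.warn(f"{chrom}: zero median depth, skipped")
            continue
        n_win = d.size // window_bp
        if n_win == 0:
            continue
        means = d[: n_win * window_bp].reshape(n_win, window_bp).mean(axis=1)
        norm = means / chrom_median
        state = np.zeros(n_win, dtype=int)
        state[norm >= gain_threshold] = 1
        state[norm <= loss_threshold] = -1
        for run_start, run_end, s in _runs(state):
            if s == 0:
                continue
            start_bp = int(pos[run_start * window_bp])
            end_bp = int(pos[min(run_end * window_bp, d.size) - 1])
            if end_bp - start_bp + 1 < min_len_bp:
                continue
            rows.append(
                {
                    "chromosome": chrom,
                    "start": start_bp,
                    "end": end_bp,
                    "copy_ratio": float(norm[run_start:run_end].mean()),
                    "n_windows": int(run_end - run_start),
                    "direction": "gain" if s > 0 else "loss",
                    "artifact_flag": False,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start", "end", "copy_ratio",
            "n_windows", "direction", "artifact_flag",
        ],
    )


def _runs(state: np.ndarray):
    """Yield (start, end, value) for maximal constant runs of `state`."""
    if state.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(state)) + 1
    edges = np.concatenate([[0], boundaries, [state.size]])
    for a, b in zip(edges[:-1], edges[1:]):
        yield int(a), int(b), int(state[a])


def resolve_cnv_artifacts(
    calls: pd.DataFrame,
    sample_depths: Mapping[str, pd.DataFrame],
    residual_cutoff: float = 2.0,
    min_samples: int = 8,
) -> pd.DataFrame:
    """Flag recurrent CNV candidates explained by shared coverage bias.

    Candidate calls (with a ``sample_id`` column) are grouped into loci by
    overlap; for each locus, mean depth in the locus is regressed on
    genome-wide mean depth across *all* samples. Calls from samples whose
    standardized residual exceeds ``residual_cutoff`` are kept; the rest are
    flagged as artifacts (the locus deviates identically in everyone, so the
    signal is mappability/library bias, not a clone-specific CNV).
    """
    out = calls.copy()
    if "artifact_flag" not in out.columns:
        out["artifact_flag"] = False
    if out.empty:
        return out
    if "sample_id" not in out.columns:
        raise ConfigurationError("calls must carry a sample_id column")
    if len(sample_depths) < min_samples:
        warnings.warn(
            f"only {len(sample_depths)} samples (< {min_samples}); "
            "artifact resolution skipped, calls passed through unflagged"
        )
        return out

    sids = sorted(sample_depths)

    for locus in _merge_call_loci(out):
        chrom, start, end, idx = locus
        locus_means = np.array(
            [_mean_depth_in(sample_depths[s], chrom, start, end) for s in sids]
        )
        # genome-wide mean excludes the candidate locus itself: a sample's own
        # CNV must not leverage the regression toward fitting its outlier
        gw = np.array(
            [_mean_depth_excluding(sample_depths[s], chrom, start, end) for s in sids]
        )
        resid = _standardized_residuals(gw, locus_means)
        keep_samples = {s for s, r in zip(sids, resid) if abs(r) > residual_cutoff}
        for i in idx:
            if out.at[i, "sample_id"] not in keep_samples:
                out.at[i, "artifact_flag"] = True
    return out


def _merge_call_loci(calls: pd.DataFrame):
    """Group candidate calls into overlap-merged loci; yields (chrom, start, end, [index])."""
    for chrom, sub in calls.groupby("chromosome", sort=True):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        cur_idx: list = []
        for i, row in sub.iterrows():
            if cur_start is None or row["start"] > cur_end:
                if cur_idx:
                    yield chrom, cur_start, cur_end, cur_idx
                cur_start, cur_end, cur_idx = int(row["start"]), int(row["end"]), [i]
            else:
                cur_end = max(cur_end, int(row["end"]))
                cur_idx.append(i)
        if cur_idx:
            yield chrom, cur_start, cur_end, cur_idx


def _mean_depth_excluding(depth: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    in_locus = (depth["chrom"] == chrom) & (depth["pos"] >= start) & (depth["pos"] <= end)
    rows = depth.loc[~in_locus, "depth"]
    return float(rows.mean()) if len(rows) else 0.0


def _mean_depth_in(depth: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    rows = depth[(depth["chrom"] == chrom) & (depth["pos"] >= start) & (depth["pos"] <= end)]
    return float(rows["depth"].mean()) if len(rows) else 0.0


def _standardized_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residuals of OLS y ~ x, standardized by residual SD (0 if SD ~ 0)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = resid.std(ddof=2) if resid.size > 2 else resid.std()
    if sd < 1e-12:
        return np.zeros_like(resid)
    return resid / sd


def call_snvs(
    sample: pd.DataFrame,
    ancestor: pd.DataFrame,
    min_depth: int = SNV_MIN_DEPTH,
    min_alt_fraction: float = SNV_MIN_ALT_FRACTION,
    max_ancestor_alt_fraction: float = SNV_MAX_ANCESTOR_ALT_FRACTION,
) -> pd.DataFrame:
    """Ancestor-subtracted SNV calls from paired pileups.

    A site is called when the sample's most frequent non-reference base has
    alt fraction >= ``min_alt_fraction`` at depth >= ``min_depth`` while the
    ancestor's fraction of that base stays <= ``max_ancestor_alt_fraction``.

    Returns columns ``chromosome, position, ref, alt, depth, alt_fraction,
    ancestor_alt_fraction``.
    """
    key_cols = ["chrom", "pos"]
    if len(sample) != len(ancestor) or not (
        sample[key_cols].reset_index(drop=True).equals(
            ancestor[key_cols].reset_index(drop=True)
        )
    ):
        raise CoordinateMismatchError("sample and ancestor pileups must share coordinates")
    s_counts = sample[list(BASES)].to_numpy(dtype=float)
    a_counts = ancestor[list(BASES)].to_numpy(dtype=float)
    refs = sample["ref"].to_numpy()
    base_arr = np.array(BASES)
    ref_idx = np.searchsorted(base_arr, refs)

    s_depth = s_counts.sum(axis=1)
    masked = s_counts.copy()
    masked[np.arange(len(masked)), ref_idx] = -1
    alt_idx = masked.argmax(axis=1)
    alt_count = s_counts[np.arange(len(s_counts)), alt_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(s_depth > 0, alt_count / s_depth, 0.0)
        a_depth = a_counts.sum(axis=1)
        a_frac = np.where(
            a_depth > 0, a_counts[np.arange(len(a_counts)), alt_idx] / a_depth, 0.0
        )

    keep = (
        (s_depth >= min_depth)
        & (alt_frac >= min_alt_fraction)
        & (a_frac <= max_ancestor_alt_fraction)
        & (alt_idx != ref_idx)
    )
    out = pd.DataFrame(
        {
            "chromosome": sample["chrom"].to_numpy()[keep],
            "position": sample["pos"].to_numpy()[keep],
            "ref": refs[keep],
            "alt": base_arr[alt_idx[keep]],
            "depth": s_depth[keep].astype(int),
            "alt_fraction": alt_frac[keep],
            "ancestor_alt_fraction": a_frac[keep],
        }
    )
    return out.reset_index(drop=True)


def annotate_calls(
    calls: pd.DataFrame,
    features: Sequence[Interval],
    clone_id: str | None = None,
    proximity_bp: int = 500,
    intergenic_bin_bp: int = 10_000,
) -> pd.DataFrame:
    """Attach feature labels to raw caller output, yielding a MutationCall table.

    ``calls`` may be SNV output (``position`` column), CNV output
    (``start``/``end``) or aneuploidy output (``chromosome`` only, labeled by
    chromosome). SNV/CNV calls take the label of the overlapping feature; if
    none overlaps, the nearest feature within ``proximity_bp``; otherwise an
    ``intergenic:<chrom>:<bin>`` label.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in features:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    rows = []
    for _, call in calls.iterrows():
        chrom = call["chromosome"]
        if "position" in calls.columns:  # SNV
            start = end = int(call["position"])
            row = {
                "type": "SNV",
                "ref_allele": call.get("ref", ""),
                "alt_allele": call.get("alt", ""),
                "copy_ratio": np.nan,
            }
        elif "start" in calls.columns:  # CNV
            start, end = int(call["start"]), int(call["end"])
            row = {
                "type": "CNV",
                "ref_allele": "",
                "alt_allele": "",
                "copy_ratio": float(call.get("copy_ratio", np.nan)),
            }
        else:  # aneuploidy
            start, end = 1, -1
            row = {
                "type": "ANEUPLOIDY",
                "ref_allele": "",
                "alt_allele": "",
                "copy_ratio": float(call.get("copy_ratio", np.nan)),
            }
        if row["type"] == "ANEUPLOIDY":
            annotation = chrom
            start = 1
            end = int(call["end"]) if "end" in calls.columns else 1
        else:
            annotation = _feature_label(
                by_chrom.get(chrom, []), chrom, start, end, proximity_bp, intergenic_bin_bp
            )
        rows.append(
            {
                "clone_id": clone_id or call.get("sample_id", ""),
                "chromosome": chrom,
                "start": start,
                "end": end,
                "annotation": annotation,
                "artifact_flag": bool(call.get("artifact_flag", False)),
                **row,
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def _feature_label(
    ivs: Sequence[Interval],
    chrom: str,
    start: int,
    end: int,
    proximity_bp: int,
    intergenic_bin_bp: int,
) -> str:
    if not ivs:
        warnings.warn(f"no features on {chrom}; call labeled by chromosome")
        return chrom
    best_label, best_dist = None, None
    for iv in ivs:
        if iv.start <= end and start <= iv.end:
            return iv.label
        dist = iv.start - end if iv.start > end else start - iv.end
        if best_dist is None or dist < best_dist:
            best_label, best_dist = iv.label, dist
    if best_dist is not None and best_dist <= proximity_bp:
        return best_label
    return f"intergenic:{chrom}:{start // intergenic_bin_bp}"
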