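"""Readers and writers for the table formats used across the pipeline.

Internal coordinates are uniformly 1-based inclusive; conversions happen
only at format boundaries (BED is 0-based half-open, GFF3 and depth/pileup
tables are 1-based).
"""

from __future__ import annotations

import os
import warnings
from typing import Sequence

import pandas as pd
import yaml

from mitoevo.errors import TableFormatError
from mitoevo.model import BASES, Interval

DEPTH_COLUMNS = ["chrom", "pos", "depth"]
PILEUP_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T"]


def read_intervals(path: str, dialect: str | None = None) -> list[Interval]:
    """Read labeled intervals from BED or GFF3 into 1-based inclusive form.

    ``dialect`` is ``"bed"`` or ``"gff3"``; by default it is taken from the
    file extension, and an unrecognizable extension is an error rather than
    a guess.
    """
    if dialect is None:
        ext = os.path.splitext(path)[1].lower()
        if ext == ".bed":
            dialect = "bed"
        elif ext in (".gff", ".gff3"):
            dialect = "gff3"
        else:
            raise TableFormatError(
                f"cannot infer interval dialect from extension {ext!r}; pass dialect="
            )
    dialect = dialect.lower()
    if dialect not in ("bed", "gff3"):
        raise TableFormatError(f"unknown interval dialect {dialect!r}")

    if os.path.getsize(path) == 0:
        warnings.warn(f"{path}: empty interval file")
        return []

    import pyranges as pr  # deferred: heavy import

    try:
        ranges = pr.read_bed(path) if dialect == "bed" else pr.read_gff3(path)
    except Exception as exc:  # pyranges raises various parse errors
        raise TableFormatError(f"{path}: failed to parse as {dialect}: {exc}") from exc
    df = ranges.df
    if df.empty:
        warnings.warn(f"{path}: no intervals parsed")
        return []

    intervals = []
    for i, row in df.iterrows():
        # pyranges normalizes both dialects to 0-based half-open internally
        start = int(row["Start"]) + 1
        end = int(row["End"])
        label = ""
        for cand in ("Name", "ID", "Feature"):
            if cand in df.columns and pd.notna(row.get(cand)) and row.get(cand) != ".":
                label = str(row[cand])
                break
        if not label:
            label = f"{row['Chromosome']}:{start}-{end}"
        try:
            intervals.append(Interval(str(row["Chromosome"]), start, end, label))
        except ValueError as exc:
            raise TableFormatError(f"{path} line {i + 1}: {exc}") from exc
    return intervals


def read_depth_table(path: str) -> pd.DataFrame:
    """Read a samtools-depth style 3-column TSV (chrom, pos, depth)."""
    try:
        df = pd.read_csv(
            path, sep="\t", names=DEPTH_COLUMNS, header=None,
            dtype={"chrom": str, "pos": "int64", "depth": "int64"}, comment="#",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise TableFormatError(f"{path}: not a depth TSV: {exc}") from exc
    if df["depth"].lt(0).any():
        raise TableFormatError(f"{path}: negative depth values")
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise TableFormatError(f"{path}: duplicate (chrom, pos) rows")
    return df


def write_depth_table(df: pd.DataFrame, path: str) -> None:
    df[DEPTH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_pileup_table(path: str) -> pd.DataFrame:
    """Read a pileup base-count TSV (chrom, pos, ref, A, C, G, T; with header)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise TableFormatError(f"{path}: not a pileup TSV: {exc}") from exc
    if list(df.columns) != PILEUP_COLUMNS:
        raise TableFormatError(
            f"{path}: expected columns {PILEUP_COLUMNS}, got {list(df.columns)}"
        )
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise TableFormatError(f"{path}: duplicate positions")
    if not df["ref"].isin(BASES).all():
        raise TableFormatError(f"{path}: ref bases must be one of {BASES}")
    if (df[list(BASES)] < 0).any().any():
        raise TableFormatError(f"{path}: negative base counts")
    return df


def write_pileup_table(df: pd.DataFrame, path: str) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_table(path: str, sep: str = "\t") -> pd.DataFrame:
    """Generic header-ful table reader (calls, metadata, growth, competition)."""
    try:
        return pd.read_csv(path, sep=sep)
    except (ValueError, pd.errors.ParserError) as exc:
        raise TableFormatError(f"{path}: unreadable table: {exc}") from exc


def write_table(df: pd.DataFrame, path: str, sep: str = "\t", index: bool = False) -> None:
    df.to_csv(path, sep=sep, index=index)


def write_snv_vcf(snvs: pd.DataFrame, path: str, source: str = "mitoevo") -> None:
    """Write SNV calls as minimal VCF 4.2 (CHROM, POS, REF, ALT, INFO DP/AF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in snvs.iterrows():
            info = f"DP={int(r['depth'])};AF={float(r['alt_fraction']):.4f}"
            fh.write(
                f"{r['chromosome']}\t{int(r['position'])}\t.\t{r['ref']}\t{r['alt']}"
                f"\t.\tPASS\t{info}\n"
            )


def read_config(path: str) -> dict:
    """Read a flat YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise TableFormatError(f"{path}: config must be a YAML mapping")
    return cfg


def intervals_to_frame(intervals: Sequence[Interval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "label": iv.label}
            for iv in intervals
        ],
        columns=["chrom", "start", "end", "label"],
    )
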