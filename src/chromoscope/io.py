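"""Readers and writers for the tabular formats the pipeline exchanges.

Everything is plain text: two-column chromosome sizes, BED3/BED4 intervals,
BED12 or GTF gene models, counts matrices with a sample sheet, bedGraph-like
viewpoint profiles, and dense contact matrices.  Coordinates are 0-based
half-open everywhere except GTF, which is converted on read.
"""

from __future__ import annotations

import pandas as pd


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column (name, length) TSV, faidx-style extra columns ignored."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least two columns")
            out[fields[0]] = int(fields[1])
    return out


def write_chrom_sizes(chrom_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path) -> pd.DataFrame:
    """BED3/BED4 intervals as a DataFrame (chrom, start, end[, name])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_counts(path) -> pd.DataFrame:
    """Features x samples integer count matrix, feature ids in column 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV with sample, individual, cell_type[, replicate, day]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "individual", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_profile(path) -> pd.DataFrame:
    """bedGraph-like TSV (chrom, start, end, value) for a viewpoint profile."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "start", "end", "value"]
    )
    return df


def write_profile(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_dense_matrix(path) -> tuple[pd.DataFrame, list[str]]:
    """Dense contact matrix TSV; header labels are '<chrom>:<bin start>'."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df, list(df.columns)


def write_dense_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="bin")
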