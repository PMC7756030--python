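"""Readers and writers for the pipeline's plain-text tabular formats.

All matrices are feature x sample TSV files: first column holds the feature
identifier, the header row holds sample identifiers, and missing values are
written as the literal ``NA``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

NA_LITERAL = "NA"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (``NA`` literal for missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_LITERAL],
                     keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate feature ids in {path}: {dupes}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample matrix as TSV with ``NA`` for missing."""
    df.to_csv(path, sep="\t", na_rep=NA_LITERAL, float_format="%.6g")


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest TSV (probe_id, chrom, pos[, strand])."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe manifest {path} lacks columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise ValueError(f"duplicate probe ids in manifest {path}")
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise ValueError("probe positions must be 1-based (>= 1)")
    return df


def write_probe_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical follow-up TSV (sample_id, time, event)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table {path} lacks columns {sorted(missing)}")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death observed)")
    return df.set_index("sample_id")


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index() if df.index.name == "sample_id" else df
    out.to_csv(path, sep="\t", index=False)
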