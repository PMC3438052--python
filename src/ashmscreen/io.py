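"""Tab-separated and BED readers/writers.

Site tables and read observations are TSV with 1-based positions
(VCF-like); BED tracks are 0-based half-open.  Output files may carry
``#``-prefixed provenance header lines (package version, seed, resolved
thresholds) which the readers skip.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "label"]


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None
                ) -> Path:
    """Write a TSV, optionally preceded by ``#`` provenance lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(regions: pd.DataFrame, path) -> Path:
    """Write ``chrom start end label`` BED (0-based half-open)."""
    path = Path(path)
    cols = [c for c in BED_COLUMNS if c in regions.columns]
    regions[cols].to_csv(path, sep="\t", index=False, header=False)
    return path


def read_bed(path, track: str = "custom") -> pd.DataFrame:
    """Read a BED track into an annotation frame (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : 4]
    df.columns = BED_COLUMNS[: df.shape[1]]
    if "label" not in df.columns:
        df["label"] = [f"{track}_{i + 1}" for i in range(len(df))]
    df["track"] = track
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"BED file {path} has start >= end records")
    return df
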