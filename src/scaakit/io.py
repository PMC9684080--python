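"""Readers and writers for the plain-text formats the pipeline exchanges.

All interval formats are 0-based half-open (BED convention).  Everything is
tab-separated text so that outputs diff cleanly and round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synthetic import CohortConfig

FRAGMENT_COLS = ["chrom", "start", "end", "sample"]
ALLELE_COLS = [
    "chrom", "pos", "ref", "alt", "sample",
    "ref_count", "alt_count", "multiplicity", "copy_number", "clonal_flag",
]
BIN_COLS = ["chrom", "start", "end", "log2ratio"]


def write_fragments_bed(df: pd.DataFrame, path) -> None:
    """BED3+1: chrom, start, end, sample id."""
    df[FRAGMENT_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLS)


def write_allele_counts(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"clonal": "clonal_flag"})
    out["clonal_flag"] = out["clonal_flag"].astype(int)
    out[ALLELE_COLS].to_csv(path, sep="\t", index=False)


def read_allele_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["clonal"] = df.pop("clonal_flag").astype(bool)
    return df


def write_peaks(peaks: pd.DataFrame, counts: pd.DataFrame, prefix) -> None:
    """BED6 peak intervals plus a peaks x samples count matrix TSV."""
    prefix = Path(prefix)
    bed = peaks[["chrom", "start", "end"]].copy()
    bed["name"] = peaks["peak_id"]
    bed["score"] = 0
    bed["strand"] = "."
    bed.to_csv(prefix.with_suffix(".bed"), sep="\t", header=False, index=False)
    counts.to_csv(prefix.with_suffix(".counts.tsv"), sep="\t")


def read_peaks(prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    bed = pd.read_csv(
        prefix.with_suffix(".bed"), sep="\t", header=None,
        names=["chrom", "start", "end", "peak_id", "score", "strand"],
    )
    counts = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col=0)
    return bed[["peak_id", "chrom", "start", "end"]], counts


def write_bins_bed(bins: pd.DataFrame, path, sample: str | None = None) -> None:
    """BED4 with log2 ratio for one sample."""
    df = bins if sample is None else bins[bins["sample"] == sample]
    df[BIN_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bins_bed(path, sample: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BIN_COLS)
    if sample is not None:
        df.insert(0, "sample", sample)
    return df


def write_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"cohort": config.to_dict()}, fh, sort_keys=False)


def read_config(path) -> CohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CohortConfig.from_dict(data["cohort"])


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
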