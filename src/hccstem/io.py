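"""Readers and writers for the tab-separated formats the pipeline touches.

Expression matrices are genes x samples log2-scale tables (first column
gene id, header row of sample ids).  Clinical tables carry sample id,
survival time in months, event flag and drug-response label.  Gene sets
use standard GMT.  Somatic mutations use MAF with the standard column
names.  Readers validate strictly and log anything they discard.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetDB

logger = logging.getLogger(__name__)

RESPONSE_LEVELS = {"responder", "non_responder", "unknown"}

# MAF variant classes that do not alter the protein product; excluded from
# mutation frequencies by default, per standard MAF summarisation
SILENT_CLASSES = {
    "Silent",
    "Intron",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "IGR",
    "RNA",
}

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_maf",
    "mutation_frequency",
    "write_ground_truth",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Load a genes x samples expression table.

    Duplicate gene ids are collapsed by keeping the row with the highest
    mean expression (a common microarray convention); the collapse is
    logged.  Non-numeric cells and duplicate sample ids raise.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(samples) != len(set(samples)):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty expression file") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().sum() > df[col].isna().sum():
            row = df.index[bad.isna() & df[col].notna()][0]
            raise ValueError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    df = df.astype(float)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values present")

    if df.index.duplicated().any():
        n_before = len(df)
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        df = df.sort_index(kind="stable")
        logger.info(
            "collapsed %d duplicate gene rows by max mean expression", n_before - len(df)
        )
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_expression(X: pd.DataFrame, path: str | Path) -> None:
    out = X.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Load a clinical table (sample_id, time_months, event, response, ...)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if (df["time_months"] < 0).any():
        raise ValueError(f"{path}: negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event flags must be 0/1")
    if "response" in df.columns:
        bad = set(df["response"].dropna().unique()) - RESPONSE_LEVELS
        if bad:
            raise ValueError(f"{path}: unknown response labels {sorted(bad)}")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gmt(path: str | Path) -> GeneSetDB:
    """Parse a GMT file: one set per line as name, description, members."""
    sets: dict[str, list[str]] = {}
    descs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                logger.info(
                    "GMT set %s: deduplicated %d member(s)", name, len(members) - len(uniq)
                )
            sets[name] = uniq
            descs[name] = desc
    return GeneSetDB(sets, descs)


def write_gmt(db: GeneSetDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in db.items():
            fh.write("\t".join([name, db.description(name), *members]) + "\n")


def read_maf(path: str | Path) -> pd.DataFrame:
    """Load a MAF table; '#' comment lines are skipped.

    Requires the standard Hugo_Symbol, Tumor_Sample_Barcode and
    Variant_Classification columns.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty MAF file") from exc
    required = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required MAF column {col!r}")
    return df


def mutation_frequency(
    maf: pd.DataFrame,
    n_samples: int,
    panel: list[str] | None = None,
    exclude_silent: bool = True,
    top_n: int = 10,
) -> pd.Series:
    """Per-gene mutated-sample fraction from a MAF table.

    A gene's frequency is the number of distinct samples carrying at
    least one (by default non-silent) record, over ``n_samples``.
    Returns the top ``top_n`` genes by frequency plus every panel gene
    (even at frequency 0), sorted descending.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    panel = list(panel or [])
    records = maf
    if exclude_silent and len(records):
        dropped = records["Variant_Classification"].isin(SILENT_CLASSES)
        if dropped.any():
            logger.info("mutation_frequency: excluded %d silent records", int(dropped.sum()))
        records = records[~dropped]
    if len(records):
        counts = records.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].nunique()
        freq = counts / n_samples
    else:
        freq = pd.Series(dtype=float)
    top = freq.sort_values(ascending=False, kind="stable").head(top_n)
    for gene in panel:
        if gene not in top.index:
            top.loc[gene] = float(freq.get(gene, 0.0))
    top = top.sort_values(ascending=False, kind="stable")
    top.name = "mutated_fraction"
    top.index.name = "gene"
    return top


def write_ground_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
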