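"""Readers and writers for the pipeline's on-disk dialects.

Everything is plain text: TSV with headers for tabular data (manifest,
counts, sample sheet, TF scores, reports), BED3+/narrowPeak for intervals,
JSON/YAML for configuration and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .library import LibraryManifest
from .screen import CountMatrix

__all__ = [
    "read_manifest", "write_manifest",
    "read_count_matrix", "write_count_matrix",
    "read_bed", "write_bed",
    "read_narrowpeak",
    "read_gene_annotation",
    "read_tf_table", "write_table",
    "write_json",
]

NARROWPEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                      "signalValue", "pValue", "qValue", "peak"]


def read_manifest(path: str | Path) -> LibraryManifest:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "hairpin_id": str})
    if "pool_id" in df.columns:
        df["pool_id"] = df["pool_id"].astype("Int64")
    else:
        df["pool_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return LibraryManifest(df)


def write_manifest(manifest: LibraryManifest, path: str | Path) -> None:
    manifest.entries.to_csv(path, sep="\t", index=False)


def read_count_matrix(counts_path: str | Path, samples_path: str | Path,
                      normalized: bool = False, scale: float = 1e7) -> CountMatrix:
    """Counts TSV: hairpin_id + one column per sample.  Sample sheet TSV:
    sample_id, class_, pool_id, scored."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="hairpin_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    if "scored" in samples.columns:
        samples["scored"] = samples["scored"].astype(bool)
    else:
        samples["scored"] = True
    return CountMatrix(counts, samples, normalized=normalized, scale=scale)


def write_count_matrix(matrix: CountMatrix, counts_path: str | Path,
                       samples_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="hairpin_id")
    matrix.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ (no header).  Extra columns beyond chrom/start/end are kept
    under generic names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, df.shape[1] + 1)]
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "summit", "score"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """narrowPeak: BED6+4; the 10th column is the summit offset from start
    (-1 when absent), converted here to an absolute ``summit`` position."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=NARROWPEAK_COLUMNS)
    offset = df["peak"].astype(int)
    df["summit"] = np.where(offset >= 0, df["start"] + offset,
                            (df["start"] + df["end"]) // 2)
    return df[["chrom", "start", "end", "name", "score", "summit"]]


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene table TSV: gene_id, chrom, strand, tss, exon_starts, exon_ends
    (comma-separated coordinate lists)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str,
                                            "strand": str,
                                            "exon_starts": str, "exon_ends": str})
    required = {"gene_id", "chrom", "strand", "tss", "exon_starts", "exon_ends"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns {sorted(missing)}")
    return df


def read_tf_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="tf_id")


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.ndarray,)):
        return value.tolist()
    raise TypeError(f"not JSON-serializable: {type(value)}")
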