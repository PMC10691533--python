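"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: expression, beta, and count matrices are TSV with the feature id
in the first column and sample ids in the header; genomic coordinates are
1-based inclusive internally, with BED input converted from its 0-based
half-open dialect at this boundary; cytoband tables follow the UCSC cytoBand
dialect (chrom, start, end, band name, Giemsa stain).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("panconet")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------- matrices

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene id).

    Raises :class:`ParseError` on empty files, ragged rows, or duplicated
    gene/sample ids (naming the duplicate).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows or columns")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated gene id {dup[0]!r}")
    dupc = df.columns[df.columns.duplicated()]
    if len(dupc):
        raise ParseError(f"{path}: duplicated sample id {dupc[0]!r}")
    df.index = df.index.astype(str)
    return df.astype(float)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


# beta matrices share the expression layout (probes x samples)
read_beta = read_expression


def write_beta(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe", na_rep="NA")


# ---------------------------------------------------------------- clinical

def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical table: sample id column plus time/event and covariates."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    if "sample" not in df.columns:
        raise ParseError(f"{path}: missing 'sample' column")
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated sample id {dup.iloc[0]!r}")
    df = df.set_index("sample")
    if "time" in df.columns and (df["time"].dropna() <= 0).any():
        bad = df.index[df["time"] <= 0][0]
        raise ParseError(f"{path}: nonpositive survival time for sample {bad!r}")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample", na_rep="NA")


# ---------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into {set name: gene set}.

    Lines are ``name<TAB>description<TAB>gene1<TAB>gene2...``; empty sets are
    dropped with a warning, short lines raise with their line number.
    """
    sets: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: GMT line has fewer than 3 columns")
        name = parts[0]
        genes = {g for g in parts[2:] if g}
        if not genes:
            logger.warning("GMT set %r at %s:%d is empty; dropped", name, path, ln)
            continue
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------- genomic

def read_cytoband(path: str | Path) -> pd.DataFrame:
    """Read a UCSC-dialect cytoband table into 1-based inclusive coordinates.

    Returns columns chrom, start, end, band, stain; band names are qualified
    as ``chrom`` + ``band`` (e.g. chr1q11) in the ``name`` column.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "band", "stain"])
    if df.empty:
        raise ParseError(f"{path}: empty cytoband table")
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based incl.
    df["end"] = df["end"].astype(int)
    df["name"] = df["chrom"].astype(str) + df["band"].astype(str)
    return df


def write_cytoband(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["chrom", "start", "end", "band", "stain"]].copy()
    out["start"] = out["start"] - 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV: gene, chrom, tss, strand, cytoband."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    need = {"gene", "chrom", "tss", "strand"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df.set_index("gene")


def write_gene_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Probe annotation TSV: probe, chrom, pos, maf (NA = no SNP), gene."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={"probe": str})
    if "probe" not in df.columns:
        raise ParseError(f"{path}: missing 'probe' column")
    return df.set_index("probe")


def write_probe_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe", na_rep="NA")


def read_peaks(bed_path: str | Path, counts_path: str | Path) -> pd.DataFrame:
    """Read fixed-width peak regions (BED) plus their counts TSV.

    The BED is 0-based half-open; the returned frame has 1-based inclusive
    start/end plus one log2-count column per sample, indexed by peak id.
    """
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "peak"])
    if bed.empty:
        raise ParseError(f"{bed_path}: empty BED")
    bed["start"] = bed["start"].astype(int) + 1
    bed["end"] = bed["end"].astype(int)
    widths = bed["end"] - bed["start"]
    if widths.nunique() != 1:
        raise ParseError(f"{bed_path}: peaks are not fixed-width")
    counts = read_expression(counts_path)
    bed = bed.set_index("peak")
    missing = bed.index.difference(counts.index)
    if len(missing):
        raise ParseError(f"{counts_path}: no counts for peak {missing[0]!r}")
    return bed.join(counts.loc[bed.index])


def write_peaks(df: pd.DataFrame, bed_path: str | Path,
                counts_path: str | Path) -> None:
    bed = df[["chrom", "start", "end"]].copy()
    bed["start"] = bed["start"] - 1
    bed["peak"] = df.index
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    df.drop(columns=["chrom", "start", "end"]).to_csv(
        counts_path, sep="\t", index_label="peak")


# ---------------------------------------------------------------- misc

def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_default))
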