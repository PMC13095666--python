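"""Readers and writers for the tabular interchange formats.

Tab-delimited UTF-8 text with a header line is the canonical interchange;
every writer emits a header and every reader accepts its own writer's
output. Panel positions are 1-based (mtDNA convention).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .heteroplasmy import MOUSE_MT_GENOME_LENGTH, HaplotypePanel, VariantSite

logger = logging.getLogger(__name__)

__all__ = ["SCHEMAS", "load_table", "write_table", "load_panel", "write_panel"]

PathLike = Union[str, Path]

#: required columns and dtypes per table kind; optional columns in brackets
SCHEMAS: dict[str, dict] = {
    "guide_reads": {
        "required": {"cell_barcode": str, "guide_id": str, "mapq": int, "read_id": str},
        "optional": {"umi": str},
    },
    "allele_counts": {
        "required": {
            "cell_barcode": str, "position": int, "ref_count": int, "alt_count": int,
        },
        "optional": {},
    },
    "coverage": {
        "required": {"cell_barcode": str, "total_mt_bases": int},
        "optional": {"nuclear_fragments": int, "mean_coverage": float},
    },
    "calls": {
        "required": {"cell_barcode": str, "heteroplasmy": float, "combined_depth": int},
        "optional": {},
    },
    "metadata": {
        "required": {"cell_barcode": str},
        "optional": {
            "guide_id": str, "target_gene": str, "group": str,
            "phase": str, "pseudotime": float,
        },
    },
    "assignments": {
        "required": {
            "cell_barcode": str, "status": str, "guide_id": str,
            "top_reads": int, "total_reads": int,
        },
        "optional": {},
    },
    "longreads": {
        "required": {"read_id": str, "position": int, "allele": int},
        "optional": {},
    },
    "guide_map": {
        "required": {"guide_id": str, "target_gene": str},
        "optional": {},
    },
}


def load_table(path: PathLike, schema: str) -> pd.DataFrame:
    """Read and validate a TSV against a named schema.

    The header is checked for the schema's required columns (an error names
    any missing one), numeric columns are coerced, and rows that fail
    coercion are rejected with their line numbers. CRLF files parse
    identically to LF.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty") from None
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for schema {schema!r}")
    types = {**spec["required"], **{c: t for c, t in spec["optional"].items() if c in df.columns}}
    bad_rows: set[int] = set()
    for col, typ in types.items():
        if typ is str:
            df[col] = df[col].fillna("")
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        bad_rows.update((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = coerced
    if bad_rows:
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s",
                       path, len(bad_rows), sorted(bad_rows)[:10])
        df = df.drop(index=[ln - 2 for ln in bad_rows]).reset_index(drop=True)
    for col, typ in types.items():
        if typ is int:
            df[col] = df[col].astype(np.int64)
        elif typ is float:
            df[col] = df[col].astype(float)
    logger.info("%s: loaded %d rows (schema %s)", path, len(df), schema)
    return df


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    """Write a TSV with header at full double precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format=None)


def load_panel(path: PathLike, focal_position: Optional[int] = None,
               genome_length: int = MOUSE_MT_GENOME_LENGTH) -> HaplotypePanel:
    """Panel TSV: columns position, ref, alt and optional orientation.

    The focal site is either given explicitly or taken as the first cis site
    in file order.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("position", "ref", "alt"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing panel column {col!r}")
    if "orientation" not in df.columns:
        df["orientation"] = "unknown"
    df["orientation"] = df["orientation"].fillna("unknown")
    sites = tuple(
        VariantSite(int(r.position), str(r.ref), str(r.alt), str(r.orientation))
        for r in df.itertuples(index=False)
    )
    if focal_position is None:
        cis = [s for s in sites if s.orientation == "cis"]
        if not cis:
            raise ValueError(f"{path}: no cis site to take as focal; pass focal_position")
        focal_position = cis[0].position
    return HaplotypePanel(sites, focal_position, genome_length)


def write_panel(panel: HaplotypePanel, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# positions are 1-based on the circular mtDNA reference\n")
        fh.write("position\tref\talt\torientation\n")
        for s in panel.sites:
            fh.write(f"{s.position}\t{s.ref_allele}\t{s.alt_allele}\t{s.orientation}\n")
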