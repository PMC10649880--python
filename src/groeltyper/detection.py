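"""Reading and cleaning peptide-level identification tables.

The upstream peptide-centric search (outside this package) produces one row
per identified peptide with a summed MS1 precursor intensity and optionally a
spectral count.  This module parses such tables, strips modification
annotations, folds I onto L (same canonicalization as the database), merges
duplicate rows, removes contaminant peptides, and pools technical replicates.

Detected peptides are carried as a pandas DataFrame with columns
``sample``, ``peptide`` (canonical), ``intensity``, ``spectral_count``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .digest import canonicalize_peptide

logger = logging.getLogger(__name__)

COLUMNS = ["sample", "peptide", "intensity", "spectral_count"]

#: Default mapping from logical fields to column names in input tables.
DEFAULT_DIALECT: dict[str, str] = {
    "peptide": "peptide",
    "intensity": "intensity",
    "count": "count",
    "sample": "sample",
}


def read_peptide_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sample_id: str | None = None,
    score_column: str | None = None,
    max_score: float | None = None,
) -> pd.DataFrame:
    """Parse a peptide identification table (CSV/TSV/semicolon, sniffed).

    ``dialect`` maps the logical fields ``peptide``, ``intensity``, ``count``
    and ``sample`` to the file's column names.  Peptide and intensity columns
    are mandatory; a missing count column defaults to one spectral count per
    row, and a missing sample column falls back to ``sample_id`` (or the file
    stem).  Sequences are modification-stripped, upper-cased and I/L-folded.
    Rows with negative intensity are rejected with a warning.  Optionally a
    score column can be thresholded (keep rows with score <= ``max_score``),
    mirroring an FDR-style cut applied upstream.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=None, engine="python")
    for field in ("peptide", "intensity"):
        if cols[field] not in df.columns:
            raise ValueError(
                f"missing mandatory column {cols[field]!r} (field {field}) in {path}"
            )
    out = pd.DataFrame(
        {
            "peptide": df[cols["peptide"]].astype(str).map(canonicalize_peptide),
            "intensity": pd.to_numeric(df[cols["intensity"]]),
        }
    )
    out["spectral_count"] = (
        pd.to_numeric(df[cols["count"]]) if cols["count"] in df.columns else 1
    )
    if cols["sample"] in df.columns:
        out["sample"] = df[cols["sample"]].astype(str)
    else:
        out["sample"] = sample_id if sample_id is not None else Path(path).stem
    if score_column is not None and max_score is not None:
        keep = pd.to_numeric(df[score_column]) <= max_score
        out = out[keep.to_numpy()]
    negative = out["intensity"] < 0
    if negative.any():
        logger.warning("rejecting %d rows with negative intensity", int(negative.sum()))
        out = out[~negative]
    empty = out["peptide"] == ""
    if empty.any():
        logger.warning("rejecting %d rows with empty peptide sequence", int(empty.sum()))
        out = out[~empty]
    return out[COLUMNS].reset_index(drop=True)


def aggregate_duplicates(detected: pd.DataFrame) -> pd.DataFrame:
    """Merge rows with equal (sample, canonical peptide); sum intensities and
    spectral counts.  Total intensity is conserved."""
    return (
        detected.groupby(["sample", "peptide"], as_index=False, sort=True)
        .agg(intensity=("intensity", "sum"), spectral_count=("spectral_count", "sum"))
        [COLUMNS]
    )


def remove_contaminants(
    detected: pd.DataFrame, contaminant_peptides: Iterable[str]
) -> pd.DataFrame:
    """Drop detected peptides whose canonical sequence is a contaminant
    (cRAP) tryptic peptide."""
    contaminants = set(contaminant_peptides)
    keep = ~detected["peptide"].isin(contaminants)
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d contaminant peptide rows", removed)
    return detected[keep].reset_index(drop=True)


def pool_samples(tables: list[pd.DataFrame], pooled_id: str = "pooled") -> pd.DataFrame:
    """Pool technical replicates: concatenate under one sample id and merge
    duplicates (intensities and spectral counts sum)."""
    pooled = pd.concat(tables, ignore_index=True).assign(sample=pooled_id)
    return aggregate_duplicates(pooled)
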