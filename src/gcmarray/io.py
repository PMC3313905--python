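"""Tab-delimited readers and writers for every pipeline intermediate.

Slide files carry raw linear median intensities (feature_id, F_R, B_R,
F_G, B_G); log2 is taken on load and inverted on write, so a write/read
round trip is the identity on the in-memory (log2) representation.
Missing values may be empty fields or NA.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import TwoChannelSlide

__all__ = [
    "read_slide_table",
    "write_slide_table",
    "read_mapping_table",
    "read_two_column_tsv",
    "write_tsv",
    "read_matrix",
]

SLIDE_COLUMNS = ("feature_id", "F_R", "B_R", "F_G", "B_G")

log = logging.getLogger(__name__)


def read_slide_table(
    path, experiment_id: str = "", replicate_index: int = 0
) -> TwoChannelSlide:
    """Read one raw slide file (linear intensities -> log2)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed slide table: {exc}") from exc
    missing = [c for c in SLIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    vals = {}
    for c in SLIDE_COLUMNS[1:]:
        raw = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(raw) | (raw <= 0)
        if bad.any():
            log.info("%s: %d missing/non-positive %s values masked", path, int(bad.sum()), c)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals[c] = np.where(bad, np.nan, np.log2(np.where(bad, 1.0, raw)))
    return TwoChannelSlide(
        feature_id=df["feature_id"].to_numpy(dtype=object),
        experiment_id=experiment_id,
        replicate_index=replicate_index,
        **vals,
    )


def write_slide_table(slide: TwoChannelSlide, path) -> None:
    """Write a slide back to the raw linear-intensity dialect."""
    df = pd.DataFrame({"feature_id": slide.feature_id})
    for c in SLIDE_COLUMNS[1:]:
        df[c] = np.exp2(getattr(slide, c))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_mapping_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"reporter_id", "gene_id"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: mapping table needs columns {sorted(need)}")
    return df[["reporter_id", "gene_id"]]


def read_two_column_tsv(path, key: str, value: str) -> dict:
    """Generic loader for gene->chromosome, term->category, gene->term
    style tables (the last as a dict of sets)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {key, value} <= set(df.columns):
        raise ValueError(f"{path}: expected columns {key!r} and {value!r}")
    if df[key].duplicated().any():
        out: dict = {}
        for k, v in zip(df[key], df[value]):
            out.setdefault(k, set()).add(v)
        return out
    return dict(zip(df[key], df[value]))


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_matrix(path) -> pd.DataFrame:
    """Unified matrix TSV: gene_id column plus one column per experiment."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: unified matrix needs a gene_id column")
    return df.set_index("gene_id")
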