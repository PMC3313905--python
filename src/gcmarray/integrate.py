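"""Cross-platform data integration.

Reporter identifiers are mapped to gene identifiers through a
user-supplied table, the common gene set (CGS) is the intersection of
the per-platform gene lists, and median rank score (MRS) normalization
aligns the value distribution of every non-reference experiment with
per-rank medians of a reference experiment set, preserving ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MappingTable",
    "map_reporters",
    "common_gene_set",
    "reference_rank_medians",
    "mrs_normalize",
    "build_unified_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class MappingTable:
    """reporter_id -> gene_id pairs; validated to be one-to-one."""

    table: pd.DataFrame  # columns reporter_id, gene_id
    provenance: str = ""
    n_dropped_ambiguous: int = 0

    @classmethod
    def from_pairs(cls, table: pd.DataFrame, provenance: str = "") -> "MappingTable":
        """Validate a raw two-column table, dropping ambiguous rows.

        Reporters mapped to more than one gene, and genes targeted by
        more than one reporter, violate the required one-to-one
        relationship and are removed (counts logged).
        """
        if table.empty:
            raise ValueError("empty reporter-to-gene mapping table")
        t = table[["reporter_id", "gene_id"]].dropna().drop_duplicates()
        amb_rep = t["reporter_id"].duplicated(keep=False)
        amb_gene = t["gene_id"].duplicated(keep=False)
        bad = amb_rep | amb_gene
        n_bad = int(bad.sum())
        if n_bad:
            log.info("mapping: dropped %d rows violating one-to-one", n_bad)
        t = t[~bad].reset_index(drop=True)
        if t.empty:
            raise ValueError("no one-to-one reporter-gene pairs remain")
        return cls(table=t, provenance=provenance, n_dropped_ambiguous=n_bad)

    def as_dict(self) -> dict:
        return dict(zip(self.table["reporter_id"], self.table["gene_id"]))


def map_reporters(profile: pd.DataFrame, mapping: MappingTable) -> pd.DataFrame:
    """Re-key a reporter-level profile to gene level.

    ``profile`` is indexed by reporter_id.  Reporters absent from the
    (validated, one-to-one) mapping are dropped with a logged count.
    """
    if mapping.table.empty:
        raise ValueError("empty mapping table")
    m = mapping.as_dict()
    keep = profile.index.isin(m.keys())
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("map_reporters: %d reporters without mapping omitted", n_drop)
    out = profile[keep].copy()
    out.index = pd.Index([m[r] for r in out.index], name="gene_id")
    return out


def common_gene_set(*gene_lists) -> list:
    """Sorted intersection of two or more per-platform gene lists."""
    if len(gene_lists) < 2:
        raise ValueError("at least two gene lists required")
    cgs = set(gene_lists[0])
    for gl in gene_lists[1:]:
        cgs &= set(gl)
    if not cgs:
        raise ValueError("common gene set is empty: platforms share no genes")
    return sorted(cgs)


def reference_rank_medians(reference: pd.DataFrame) -> np.ndarray:
    """Per-rank medians across the reference experiments, ascending.

    Each reference column is sorted; the median across columns is taken
    at every rank, producing the template distribution that MRS imposes
    on the non-reference experiments.
    """
    ranks = np.sort(reference.to_numpy(dtype=float), axis=0)
    return np.median(ranks, axis=1)


def mrs_normalize(
    target: np.ndarray,
    rank_medians: np.ndarray,
    gene_id: np.ndarray | None = None,
) -> np.ndarray:
    """Median rank score normalization of one experiment.

    The gene holding rank r in the target receives the reference median
    at rank r; the sorted output therefore equals the sorted reference
    medians exactly, and the target's rank order is preserved.  Ties in
    the target are resolved by stable ordinal ranking on
    (value, gene_id), which is deterministic across runs.
    """
    target = np.asarray(target, dtype=float)
    ref = np.sort(np.asarray(rank_medians, dtype=float))
    if target.shape != ref.shape:
        raise ValueError(
            f"target length {target.size} != reference rank count {ref.size}"
        )
    if gene_id is None:
        gene_id = np.arange(target.size)
    if np.unique(target).size < target.size:
        log.info("mrs_normalize: ties in target broken by (value, gene_id)")
    order = np.lexsort((np.asarray(gene_id, dtype=object), target))
    out = np.empty_like(ref)
    out[order] = ref
    return out


def build_unified_matrix(
    profiles: dict[str, pd.Series],
    reference_experiments: tuple[str, ...] = ("4", "5"),
    apply_mrs: bool = True,
) -> pd.DataFrame:
    """Assemble the CGS x experiments matrix and MRS-normalize it.

    ``profiles`` maps experiment id to a gene-indexed Series of
    normalized log2 ratios.  The CGS is the intersection of the gene
    indices; the reference experiments (the higher-quality platform)
    define the rank medians and are left untouched, while every other
    experiment is replaced rank-wise by those medians.
    """
    cgs = common_gene_set(*[list(s.index) for s in profiles.values()])
    mat = pd.DataFrame({e: s.loc[cgs] for e, s in profiles.items()}, index=cgs)
    mat.index.name = "gene_id"
    missing_ref = [e for e in reference_experiments if e not in mat.columns]
    if missing_ref:
        raise ValueError(f"reference experiments absent from data: {missing_ref}")
    if apply_mrs:
        ref = reference_rank_medians(mat[list(reference_experiments)])
        for e in mat.columns:
            if e in reference_experiments:
                continue
            mat[e] = mrs_normalize(
                mat[e].to_numpy(), ref, gene_id=mat.index.to_numpy()
            )
    return mat
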