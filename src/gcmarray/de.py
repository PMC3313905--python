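"""Intensity-dependent differential-expression calling.

Without replicated conditions, per-slide significance is judged against
the local behaviour of features of similar intensity: features are
ranked by A, a sliding window of 20% of the data provides local mean
and SD of M, and the standard Z-score of each feature's M against its
window decides up- (U), down- (D) or unchanged (S) status at a given
confidence level (default two-sided 95%, z ~ 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DELabeling", "sliding_window_stats", "classify_de", "label_experiment"]

LABELS = ("U", "D", "S")


@dataclass
class DELabeling:
    """Per-gene Z-scores and U/D/S labels for one experiment."""

    gene_id: np.ndarray
    experiment_id: str
    M: np.ndarray
    A: np.ndarray
    Z: np.ndarray
    mu_local: np.ndarray
    sd_local: np.ndarray
    label: np.ndarray  # 'U' | 'D' | 'S'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "experiment": self.experiment_id,
                "M": self.M,
                "A": self.A,
                "Z": self.Z,
                "label": self.label,
            }
        )

    def sets(self) -> dict[str, set]:
        return {
            lab: set(self.gene_id[self.label == lab]) for lab in LABELS
        }


def sliding_window_stats(
    M: np.ndarray,
    A: np.ndarray,
    window_frac: float = 0.20,
    gene_id: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Local mean and SD of M over an A-ranked sliding window.

    Features are stably sorted by (A, gene_id); each feature's window
    holds ceil(window_frac * n) nearest ranks centered on the feature
    itself, truncated (shifted inward, not reflected) at the ends.
    Returns (mu_local, sd_local) in the original feature order.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    n = M.size
    if n < 10:
        raise ValueError(f"at least 10 features required, got {n}")
    if not (0.0 < window_frac <= 1.0):
        raise ValueError(f"window_frac must be in (0, 1], got {window_frac}")
    if gene_id is None:
        gene_id = np.arange(n)
    w = int(np.ceil(window_frac * n))
    w = max(w, 2)

    order = np.lexsort((np.asarray(gene_id, dtype=object), A))
    Ms = M[order]
    mu = np.empty(n)
    sd = np.empty(n)
    for j in range(n):
        lo = max(0, min(j - w // 2, n - w))
        win = Ms[lo : lo + w]
        mu[j] = win.mean()
        sd[j] = win.std(ddof=1)
    out_mu = np.empty(n)
    out_sd = np.empty(n)
    out_mu[order] = mu
    out_sd[order] = sd
    return out_mu, out_sd


def classify_de(
    M: np.ndarray,
    mu_local: np.ndarray,
    sd_local: np.ndarray,
    confidence: float = 0.95,
    gene_id: np.ndarray | None = None,
    experiment_id: str = "",
    A: np.ndarray | None = None,
    allow_degenerate: bool = False,
) -> DELabeling:
    """Z-score labelling: U if Z >= z_crit, D if Z <= -z_crit, else S.

    z_crit is the two-sided normal quantile at the given confidence
    level (1.959964 at 95%).  A zero local SD is an error unless
    ``allow_degenerate`` maps it to Z = 0.
    """
    M = np.asarray(M, dtype=float)
    mu_local = np.asarray(mu_local, dtype=float)
    sd_local = np.asarray(sd_local, dtype=float)
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    zero_sd = sd_local == 0
    if zero_sd.any() and not allow_degenerate:
        raise ValueError(
            f"{int(zero_sd.sum())} features have zero local SD; "
            "pass allow_degenerate=True to assign Z = 0 there"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(zero_sd, 0.0, (M - mu_local) / np.where(zero_sd, 1.0, sd_local))
    z_crit = stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    label = np.full(M.shape, "S", dtype=object)
    label[Z >= z_crit] = "U"
    label[Z <= -z_crit] = "D"
    if gene_id is None:
        gene_id = np.arange(M.size)
    return DELabeling(
        gene_id=np.asarray(gene_id, dtype=object),
        experiment_id=experiment_id,
        M=M,
        A=A if A is not None else np.full(M.shape, np.nan),
        Z=Z,
        mu_local=mu_local,
        sd_local=sd_local,
        label=label,
    )


def label_experiment(
    M: np.ndarray,
    A: np.ndarray,
    gene_id: np.ndarray,
    experiment_id: str = "",
    window_frac: float = 0.20,
    confidence: float = 0.95,
    allow_degenerate: bool = False,
) -> DELabeling:
    """Window statistics plus classification in one call."""
    mu, sd = sliding_window_stats(M, A, window_frac=window_frac, gene_id=gene_id)
    return classify_de(
        M,
        mu,
        sd,
        confidence=confidence,
        gene_id=gene_id,
        experiment_id=experiment_id,
        A=A,
        allow_degenerate=allow_degenerate,
    )
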