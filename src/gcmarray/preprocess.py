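"""Per-slide preprocessing for two-channel cDNA microarrays.

Stages, in pipeline order:

1. robust loess-based background correction (rLsBC): per channel, the
   log2 background B is regressed on the log2 foreground F and the fitted
   value is subtracted, under a multiplicative background-noise model;
2. replicate averaging by geometric mean of the corrected intensities;
3. iterative outlier exclusion at 3 inter-quartile ranges beyond the
   first/third quartile;
4. within-slide M-A normalization with a robust local quadratic loess;
5. loop-design consistency filtering: for the experimental triangle
   ('1', '2', '3') the per-feature discrepancy LdF = M1 + M2 - M3 should
   vanish, and features beyond mean +/- 2 SD of LdF are discarded from
   all downstream analysis.

All logarithms are base 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loess import loess_fit

__all__ = [
    "TwoChannelSlide",
    "CorrectedSlide",
    "AveragedSlide",
    "RatioProfile",
    "LoopFilterResult",
    "background_correct_rlsbc",
    "average_replicates",
    "remove_outliers_iqr",
    "compute_ma",
    "normalize_loess_ma",
    "loop_design_filter",
]


@dataclass
class TwoChannelSlide:
    """One hybridization: log2 median fore/background per channel."""

    feature_id: np.ndarray
    F_R: np.ndarray
    B_R: np.ndarray
    F_G: np.ndarray
    B_G: np.ndarray
    experiment_id: str = ""
    replicate_index: int = 0

    def __post_init__(self) -> None:
        ids = pd.Index(self.feature_id)
        if ids.has_duplicates:
            dup = ids[ids.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate feature ids within slide: {dup}")
        n = len(ids)
        for name in ("F_R", "B_R", "F_G", "B_G"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != {n} features")
            setattr(self, name, arr)
        self.feature_id = np.asarray(self.feature_id, dtype=object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_id,
                "F_R": self.F_R,
                "B_R": self.B_R,
                "F_G": self.F_G,
                "B_G": self.B_G,
            }
        )


@dataclass
class CorrectedSlide:
    """Background-corrected slide: Fc = F - Bl, fc = 2**Fc per channel."""

    feature_id: np.ndarray
    Bl_R: np.ndarray
    Bl_G: np.ndarray
    Fc_R: np.ndarray
    Fc_G: np.ndarray
    experiment_id: str = ""
    replicate_index: int = 0

    @property
    def fc_R(self) -> np.ndarray:
        return np.exp2(self.Fc_R)

    @property
    def fc_G(self) -> np.ndarray:
        return np.exp2(self.Fc_G)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_id,
                "Bl_R": self.Bl_R,
                "Bl_G": self.Bl_G,
                "Fc_R": self.Fc_R,
                "Fc_G": self.Fc_G,
                "fc_R": self.fc_R,
                "fc_G": self.fc_G,
            }
        )


@dataclass
class AveragedSlide:
    """Replicate-averaged signal intensities (geometric mean per channel)."""

    feature_id: np.ndarray
    fa_R: np.ndarray
    fa_G: np.ndarray
    mask: np.ndarray  # True = feature valid
    experiment_id: str = ""


@dataclass
class RatioProfile:
    """Per-feature log-ratio M and log-mean intensity A."""

    feature_id: np.ndarray
    M: np.ndarray
    A: np.ndarray
    experiment_id: str = ""
    normalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.feature_id, "M": self.M, "A": self.A}
        )


@dataclass
class LoopFilterResult:
    """Loop-design discrepancy LdF = M1 + M2 - M3 and the keep mask."""

    feature_id: np.ndarray
    ldf: np.ndarray
    mean_ldf: float
    sd_ldf: float
    keep: np.ndarray
    n_sd: float = 2.0

    @property
    def kept_features(self) -> np.ndarray:
        return self.feature_id[self.keep]


def background_correct_rlsbc(
    slide: TwoChannelSlide,
    span: float = 0.3,
    robust_iterations: int = 4,
    degree: int = 2,
) -> CorrectedSlide:
    """Robust loess-based background correction, per channel.

    The log2 background distribution B is regressed on the log2
    foreground F; the regression estimate Bl replaces the raw local
    background, so Fc = F - Bl and fc = 2**Fc.  Multiplicative
    background noise on the raw scale is additive on the log scale,
    which is what the subtraction removes.
    """
    out = {}
    for ch in ("R", "G"):
        F = getattr(slide, f"F_{ch}")
        B = getattr(slide, f"B_{ch}")
        n_valid = int((np.isfinite(F) & np.isfinite(B)).sum())
        if n_valid < 10:
            raise ValueError(
                f"channel {ch}: only {n_valid} valid features; "
                "at least 10 required for background regression"
            )
        Bl = loess_fit(
            F, B, span=span, degree=degree, robust_iterations=robust_iterations
        )
        out[f"Bl_{ch}"] = Bl
        out[f"Fc_{ch}"] = F - Bl
    return CorrectedSlide(
        feature_id=slide.feature_id,
        experiment_id=slide.experiment_id,
        replicate_index=slide.replicate_index,
        **out,
    )


def average_replicates(replicates: list[CorrectedSlide]) -> AveragedSlide:
    """Geometric-mean averaging of replicate corrected intensities.

    fa = (prod_i fc_{r_i})**(1/n) per channel, i.e. 2 to the arithmetic
    mean of the Fc values.  A feature missing in some replicates keeps
    the geometric mean of the remaining ones provided at least two
    remain (or one, when only a single replicate exists); otherwise it
    is masked.
    """
    if not replicates:
        raise ValueError("at least one replicate slide required")
    ids = pd.Index(replicates[0].feature_id)
    for rep in replicates[1:]:
        if not ids.equals(pd.Index(rep.feature_id)):
            raise ValueError("replicate slides must share the feature space")

    n_rep = len(replicates)
    need = 1 if n_rep == 1 else 2
    fa = {}
    mask = np.ones(len(ids), dtype=bool)
    for ch in ("R", "G"):
        stack = np.vstack([getattr(r, f"Fc_{ch}") for r in replicates])
        avail = np.isfinite(stack).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_log = np.nanmean(np.where(np.isfinite(stack), stack, np.nan), axis=0)
        ok = avail >= need
        mask &= ok
        fa[ch] = np.where(ok, np.exp2(mean_log), np.nan)
    return AveragedSlide(
        feature_id=replicates[0].feature_id,
        fa_R=fa["R"],
        fa_G=fa["G"],
        mask=mask,
        experiment_id=replicates[0].experiment_id,
    )


def remove_outliers_iqr(
    values: np.ndarray, k_iqr: float = 3.0, iterative: bool = True
) -> np.ndarray:
    """Keep mask for values within [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (type 7).  With ``iterative``,
    quartiles are recomputed on the survivors until a fixed point.
    NaN values are always excluded from the mask.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if int(finite.sum()) < 4:
        raise ValueError("at least 4 finite values required for quartiles")
    keep = finite.copy()
    while True:
        q1, q3 = np.percentile(values[keep], [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k_iqr * iqr, q3 + k_iqr * iqr
        new = finite & (values >= lo) & (values <= hi)
        if not iterative or np.array_equal(new, keep):
            return new
        if not new.any():  # degenerate; do not empty the mask
            return keep
        keep = new


def compute_ma(
    fa_R: np.ndarray,
    fa_G: np.ndarray,
    feature_id: np.ndarray | None = None,
    experiment_id: str = "",
) -> RatioProfile:
    """M-A transform: M = log2(fa_R/fa_G), A = log2(fa_R*fa_G)/2.

    Non-positive or missing intensities yield NaN (masked) features.
    """
    fa_R = np.asarray(fa_R, dtype=float)
    fa_G = np.asarray(fa_G, dtype=float)
    ok = np.isfinite(fa_R) & np.isfinite(fa_G) & (fa_R > 0) & (fa_G > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        FR = np.where(ok, np.log2(np.where(ok, fa_R, 1.0)), np.nan)
        FG = np.where(ok, np.log2(np.where(ok, fa_G, 1.0)), np.nan)
    M = np.where(ok, FR - FG, np.nan)
    A = np.where(ok, (FR + FG) / 2.0, np.nan)
    if feature_id is None:
        feature_id = np.arange(len(fa_R)).astype(str)
    return RatioProfile(
        feature_id=np.asarray(feature_id, dtype=object),
        M=M,
        A=A,
        experiment_id=experiment_id,
    )


def normalize_loess_ma(
    profile: RatioProfile,
    span: float = 0.10,
    degree: int = 2,
    robust_iterations: int = 4,
) -> RatioProfile:
    """Intensity-dependent normalization: subtract the robust local
    quadratic loess of M on A; A is unchanged."""
    n_valid = int((np.isfinite(profile.M) & np.isfinite(profile.A)).sum())
    if n_valid < 20:
        raise ValueError(
            f"only {n_valid} valid features; at least 20 required for M-A loess"
        )
    trend = loess_fit(
        profile.A,
        profile.M,
        span=span,
        degree=degree,
        robust_iterations=robust_iterations,
    )
    return RatioProfile(
        feature_id=profile.feature_id,
        M=profile.M - trend,
        A=profile.A,
        experiment_id=profile.experiment_id,
        normalized=True,
    )


def loop_design_filter(
    m1: RatioProfile,
    m2: RatioProfile,
    m3: RatioProfile,
    n_sd: float = 2.0,
) -> LoopFilterResult:
    """Loop-design consistency filter over the experimental triangle.

    The fold changes of experiments '1' and '2' composed should equal
    the fold change of experiment '3', so LdF = M1 + M2 - M3 should be
    zero.  Features whose LdF lies more than ``n_sd`` standard
    deviations from the mean LdF are eliminated; the surviving feature
    set applies to every downstream experiment.
    """
    ids = pd.Index(m1.feature_id)
    for other in (m2, m3):
        oi = pd.Index(other.feature_id)
        if not ids.equals(oi):
            only_a = ids.difference(oi).tolist()[:5]
            only_b = oi.difference(ids).tolist()[:5]
            raise ValueError(
                "loop profiles must share a feature set; "
                f"asymmetric difference (truncated): {only_a} vs {only_b}"
            )
    ldf = m1.M + m2.M - m3.M
    finite = np.isfinite(ldf)
    mean = float(np.mean(ldf[finite]))
    sd = float(np.std(ldf[finite], ddof=1)) if finite.sum() > 1 else 0.0
    keep = finite & (np.abs(ldf - mean) <= n_sd * sd)
    if sd < 1e-12:  # loop consistent to machine precision: nothing to filter
        keep = finite
    return LoopFilterResult(
        feature_id=m1.feature_id,
        ldf=ldf,
        mean_ldf=mean,
        sd_ldf=sd,
        keep=keep,
        n_sd=n_sd,
    )
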