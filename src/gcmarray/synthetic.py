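"""Synthetic two-channel microarray data with known ground truth.

Emulates the study design that the pipeline targets: a loop of three
co-hybridized dose comparisons at 4 h (experiments '1', '2', '3', three
replicate slides each, whose true log-ratios satisfy T1 + T2 = T3),
single slides for the two 72 h comparisons ('4', '5'), two array
platforms with overlapping gene content, multiplicative background
noise, an intensity-dependent quadratic dye bias, planted
differentially expressed genes, and planted cluster structure.

Truth tables are returned as separate objects and are never consumed
by pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrich import Ontology
from .preprocess import TwoChannelSlide

__all__ = [
    "SimulationConfig",
    "SlideTruth",
    "generate_loop_experiment",
    "generate_study",
    "generate_platform_pair",
    "generate_cluster_profiles",
    "generate_toy_ontology",
    "generate_chromosome_map",
]


@dataclass
class SimulationConfig:
    """Knobs of the slide simulator.

    The defaults mirror the study conditions: three replicates per 4 h
    experiment, a visible quadratic dye bias, mild multiplicative
    background noise (log2 units), ~10% planted DE genes at a two-fold
    effect, and a raw-intensity dynamic range of 2**6 to 2**16.
    """

    n_features: int = 500
    n_replicates: int = 3
    dye_bias_coefficients: tuple = (2.0, -0.35, 0.015)  # c0 + c1*A + c2*A^2
    background_noise_sd: float = 0.15
    de_fraction: float = 0.10
    de_effect: float = 1.0
    outlier_fraction: float = 0.01
    seed: int = 0
    a_min: float = 6.0
    a_max: float = 16.0
    background_intercept: float = 3.0
    background_slope: float = 0.25

    def __post_init__(self) -> None:
        if self.n_features < 50:
            raise ValueError(f"n_features must be >= 50, got {self.n_features}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("de_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if not (0.0 <= self.background_slope < 1.0):
            raise ValueError("background_slope must be in [0, 1)")
        if len(tuple(self.dye_bias_coefficients)) != 3:
            raise ValueError("dye_bias_coefficients must be (c0, c1, c2)")


@dataclass
class SlideTruth:
    """Ground truth for one experiment."""

    feature_id: np.ndarray
    true_log_ratio: np.ndarray

    @property
    def is_de(self) -> np.ndarray:
        return np.abs(self.true_log_ratio) > 0

    @property
    def true_direction(self) -> np.ndarray:
        d = np.full(self.true_log_ratio.shape, "S", dtype=object)
        d[self.true_log_ratio > 0] = "U"
        d[self.true_log_ratio < 0] = "D"
        return d


def _dye_bias(A: np.ndarray, coef: tuple) -> np.ndarray:
    c0, c1, c2 = coef
    return c0 + c1 * A + c2 * A**2


def _plant_truth(
    n: int, de_fraction: float, de_effect: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Gene-level true log2 ratios for experiments 1, 2, 4, 5 (3 = 1+2).

    DE features carry +/- de_effect in experiments 1, 2, 4 and 5 with
    independent random signs; experiment 3's truth is forced to
    T1 + T2 so the loop identity holds in the noiseless limit.
    """
    T = {e: np.zeros(n) for e in ("1", "2", "4", "5")}
    n_de = int(round(de_fraction * n))
    if n_de and de_effect != 0:
        idx = rng.choice(n, size=n_de, replace=False)
        for e in ("1", "2", "4", "5"):
            T[e][idx] = de_effect * rng.choice([-1.0, 1.0], size=n_de)
    T["3"] = T["1"] + T["2"]
    return T


def _make_slide(
    feature_id: np.ndarray,
    A_base: np.ndarray,
    true_ratio: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    experiment_id: str,
    replicate_index: int,
) -> TwoChannelSlide:
    """One hybridization under the multiplicative background model.

    Log2 foreground per channel is the true signal plus half the dye
    bias (red) or minus half (green), then corrupted multiplicatively:
    the observed log foreground solves F_obs = F_true + b0 + b1*F_obs
    plus Gaussian noise, and the reported log background is the linear
    trend b0 + b1*F_obs (plus noise), which the rLsBC regression can
    recover and remove.
    """
    n = feature_id.size
    bias = _dye_bias(A_base, config.dye_bias_coefficients)
    F_true = {
        "R": A_base + true_ratio / 2.0 + bias / 2.0,
        "G": A_base - true_ratio / 2.0 - bias / 2.0,
    }
    b0, b1 = config.background_intercept, config.background_slope
    sd = config.background_noise_sd
    cols = {}
    for ch in ("R", "G"):
        F_obs = (F_true[ch] + b0) / (1.0 - b1)
        if sd > 0:
            F_obs = F_obs + rng.normal(0.0, sd, size=n)
        B = b0 + b1 * F_obs
        if sd > 0:
            B = B + rng.normal(0.0, sd / 2.0, size=n)
        cols[f"F_{ch}"] = F_obs
        cols[f"B_{ch}"] = B
    if config.outlier_fraction > 0:
        n_out = int(round(config.outlier_fraction * n))
        if n_out:
            idx = rng.choice(n, size=n_out, replace=False)
            ch = rng.choice(["R", "G"], size=n_out)
            shift = rng.choice([-6.0, 6.0], size=n_out)
            for i, c, s in zip(idx, ch, shift):
                cols[f"F_{c}"][i] += s
    return TwoChannelSlide(
        feature_id=feature_id,
        F_R=cols["F_R"],
        B_R=cols["B_R"],
        F_G=cols["F_G"],
        B_G=cols["B_G"],
        experiment_id=experiment_id,
        replicate_index=replicate_index,
    )


def generate_loop_experiment(
    config: SimulationConfig,
) -> tuple[dict[str, list[TwoChannelSlide]], dict[str, SlideTruth]]:
    """Replicated slides for the 4 h loop (experiments '1', '2', '3').

    Returns (slides, truth): slides maps experiment id to its replicate
    slides; truth maps experiment id to the planted per-feature log2
    ratios, with truth['3'] = truth['1'] + truth['2'] feature-wise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    feature_id = np.array([f"FT{i:05d}" for i in range(n)], dtype=object)
    A_base = rng.uniform(config.a_min, config.a_max, size=n)
    T = _plant_truth(n, config.de_fraction, config.de_effect, rng)
    slides: dict[str, list[TwoChannelSlide]] = {}
    truth: dict[str, SlideTruth] = {}
    for e in ("1", "2", "3"):
        truth[e] = SlideTruth(feature_id=feature_id, true_log_ratio=T[e])
        slides[e] = [
            _make_slide(feature_id, A_base, T[e], config, rng, e, r)
            for r in range(config.n_replicates)
        ]
    return slides, truth


def generate_platform_pair(
    config: SimulationConfig,
    overlap_fraction: float,
    n_genes_a: int = 120,
    n_genes_b: int = 480,
    n_unmapped: int = 5,
    n_ambiguous: int = 5,
) -> tuple[list, list, pd.DataFrame]:
    """Two platform gene lists with an overlap, plus a reporter map.

    The overlap holds round(overlap_fraction * n_genes_a) genes shared
    by both platforms.  The mapping table is one-to-one on the real
    content but deliberately contains ``n_ambiguous`` extra reporters
    mapped to two genes each (violating one-to-one; a validator must
    drop exactly those reporters) and leaves ``n_unmapped`` reporters
    per platform out of the table entirely.
    """
    if not (0.0 < overlap_fraction <= 1.0):
        raise ValueError(
            f"overlap_fraction must be in (0, 1], got {overlap_fraction} "
            "(zero overlap would empty the common gene set)"
        )
    rng = np.random.default_rng(config.seed + 1)
    n_shared = int(round(overlap_fraction * min(n_genes_a, n_genes_b)))
    if n_shared < 1:
        raise ValueError("overlap produces no shared genes")
    shared = [f"Hs.{i:05d}" for i in range(n_shared)]
    only_a = [f"Hs.A{i:05d}" for i in range(n_genes_a - n_shared)]
    only_b = [f"Hs.B{i:05d}" for i in range(n_genes_b - n_shared)]
    genes_a = shared + only_a
    genes_b = shared + only_b
    # both platforms come from the same manufacturer: a shared gene is
    # probed by the same reporter on both arrays, keeping the mapping
    # one-to-one overall
    rows = []
    for prefix, genes in (("RPTS", shared), ("RPTA", only_a), ("RPTB", only_b)):
        for i, g in enumerate(genes):
            rows.append({"reporter_id": f"{prefix}_{i:05d}", "gene_id": g})
    # leave some reporters unmapped: they exist on the arrays but not here
    mapping = pd.DataFrame(rows)
    if n_unmapped:
        drop = rng.choice(len(mapping), size=min(n_unmapped, len(mapping) // 10), replace=False)
        mapping = mapping.drop(index=drop).reset_index(drop=True)
    # ambiguous reporters map to two (off-platform) genes each: the
    # reporter-side duplication violates one-to-one, so a validator
    # must drop exactly these reporters and nothing else
    amb_rows = [
        {"reporter_id": f"RPTX_{j:03d}", "gene_id": f"Hs.X{2 * j + k:05d}"}
        for j in range(n_ambiguous)
        for k in (0, 1)
    ]
    if amb_rows:
        mapping = pd.concat([mapping, pd.DataFrame(amb_rows)], ignore_index=True)
    return genes_a, genes_b, mapping


def generate_study(
    config: SimulationConfig, overlap_fraction: float = 0.9
) -> dict:
    """A complete five-experiment study over two platforms.

    4 h experiments ('1', '2', '3') are replicated slides on platform A
    reporters; 72 h experiments ('4', '5') are single slides on
    platform B reporters.  Gene-level truth is shared, so the common
    gene set carries consistent planted signal across platforms.

    Returns a dict with keys: slides (experiment -> list of slides),
    truth (experiment -> SlideTruth at gene level), mapping (reporter
    table DataFrame), genes_a, genes_b, chromosome_map.
    """
    rng = np.random.default_rng(config.seed)
    # platform sizes scale with the configured feature count, keeping
    # the small:large platform ratio of the emulated design (~1:4)
    genes_a, genes_b, mapping = generate_platform_pair(
        config,
        overlap_fraction,
        n_genes_a=max(50, config.n_features // 4),
        n_genes_b=config.n_features,
        n_unmapped=0,
        n_ambiguous=0,
    )
    all_genes = sorted(set(genes_a) | set(genes_b))
    gpos = {g: i for i, g in enumerate(all_genes)}
    n_all = len(all_genes)
    A_base_all = rng.uniform(config.a_min, config.a_max, size=n_all)
    T_all = _plant_truth(n_all, config.de_fraction, config.de_effect, rng)
    rep_of = dict(zip(mapping["gene_id"], mapping["reporter_id"]))

    slides: dict[str, list[TwoChannelSlide]] = {}
    truth: dict[str, SlideTruth] = {}
    for e, genes, n_rep in (
        ("1", genes_a, config.n_replicates),
        ("2", genes_a, config.n_replicates),
        ("3", genes_a, config.n_replicates),
        ("4", genes_b, 1),
        ("5", genes_b, 1),
    ):
        idx = np.array([gpos[g] for g in genes])
        feature_id = np.array([rep_of[g] for g in genes], dtype=object)
        truth[e] = SlideTruth(
            feature_id=np.array(genes, dtype=object),
            true_log_ratio=T_all[e][idx],
        )
        slides[e] = [
            _make_slide(
                feature_id, A_base_all[idx], T_all[e][idx], config, rng, e, r
            )
            for r in range(n_rep)
        ]
    return {
        "slides": slides,
        "truth": truth,
        "mapping": mapping,
        "genes_a": genes_a,
        "genes_b": genes_b,
        "chromosome_map": generate_chromosome_map(all_genes, config.seed + 2),
    }


def generate_cluster_profiles(
    n_genes: int,
    n_experiments: int,
    k_true: int,
    separation: float,
    seed: int,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Genes drawn around k_true centroid profiles with isotropic noise.

    ``separation`` is the minimum pairwise Euclidean distance between
    centroids.  Returns (matrix, true_assignment).
    """
    if k_true < 2:
        raise ValueError("k_true must be >= 2")
    if k_true > n_genes:
        raise ValueError(f"k_true={k_true} exceeds n_genes={n_genes}")
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    # planted-partition geometry: centroids inside a ball whose radius
    # is a small multiple of the separation, pairwise at least
    # ``separation`` apart, so inter-centroid distances are comparable
    radius = 1.25 * separation
    centroids: list[np.ndarray] = []
    tries = 0
    while len(centroids) < k_true:
        c = rng.normal(0.0, 1.0, size=n_experiments)
        c *= radius * rng.uniform(0, 1) ** (1.0 / n_experiments) / np.linalg.norm(c)
        if all(np.linalg.norm(c - o) >= separation for o in centroids):
            centroids.append(c)
        tries += 1
        if tries % 2000 == 0:  # pack too tight for this radius: relax
            radius *= 1.1
            centroids = []
        if tries > 200_000:
            raise RuntimeError("could not place well-separated centroids")
    centroids = np.array(centroids)
    assignment = np.concatenate(
        [np.arange(k_true), rng.integers(0, k_true, size=n_genes - k_true)]
    )
    rng.shuffle(assignment)
    X = centroids[assignment] + rng.normal(0.0, noise_sd, size=(n_genes, n_experiments))
    matrix = pd.DataFrame(
        X,
        index=[f"Hs.{i:05d}" for i in range(n_genes)],
        columns=[str(j + 1) for j in range(n_experiments)],
    )
    return matrix, assignment


def generate_toy_ontology(
    n_terms: int,
    n_genes: int,
    planted_term: str | None = None,
    planted_enrichment: float = 1.0,
    seed: int = 0,
    study_fraction: float = 0.2,
) -> tuple[Ontology, dict, set, set]:
    """A random rooted DAG, gene annotations, and a study set.

    Each non-root term gets one or two parents among earlier terms
    (guaranteeing acyclicity and a single root); each gene is directly
    annotated to a few random non-root terms.  The study set samples
    genes annotated (after closure) to ``planted_term`` with weight
    ``planted_enrichment`` relative to the rest.

    Returns (ontology, direct_annotations, study_set, reference_set).
    """
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_par = 1 if i == 1 else int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in parents:
            edges.append((terms[i], terms[p]))
    onto = Ontology.from_edges(edges, names={t: f"term {t}" for t in terms})
    genes = [f"G{i:04d}" for i in range(n_genes)]
    annotations = {}
    for g in genes:
        k = int(rng.integers(1, 4))
        picked = rng.choice(terms[1:], size=min(k, n_terms - 1), replace=False)
        annotations[g] = set(picked)
    reference = set(genes)
    if planted_term is None:
        planted_term = terms[-1]
    from .enrich import propagate_annotations

    closed = propagate_annotations(onto, annotations)
    weights = np.array(
        [planted_enrichment if planted_term in closed[g] else 1.0 for g in genes]
    )
    weights = weights / weights.sum()
    n_study = max(2, int(round(study_fraction * n_genes)))
    study = set(rng.choice(genes, size=n_study, replace=False, p=weights))
    return onto, annotations, study, reference


def generate_chromosome_map(genes, seed: int = 0) -> dict:
    """Assign genes to human-style chromosomes 1-22, X."""
    rng = np.random.default_rng(seed)
    chroms = [str(i) for i in range(1, 23)] + ["X"]
    return {g: chroms[int(rng.integers(0, len(chroms)))] for g in sorted(genes)}
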