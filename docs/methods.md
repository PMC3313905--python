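# Methods

This note documents the statistical procedures implemented in
`gcmarray`, the assumptions behind them, the defaults that matter, and
what the synthetic test bed does and does not establish about real
data.

## Scope and data model

The pipeline targets a five-experiment, two-platform dose-response
design on two-channel cDNA arrays: three co-hybridized comparisons at
4 h forming a loop (control vs low dose = '1', low vs high = '2',
control vs high = '3', three replicate slides each) and two single
slides at 72 h ('4' = intermediate vs high, '5' = control vs high).
All logarithms are base 2; "M" always denotes the log ratio red/green
and "A" the mean log intensity.

## Background correction (rLsBC)

Assumption: background noise scales spot intensities multiplicatively,
so it is additive in log space. Rather than subtracting the noisy
per-spot local background, the log background *B* is regressed on the
log foreground *F* per channel and the regression estimate *Bl* is
subtracted: *Fc = F − Bl*, *fc = 2^Fc*. The regression is a robust
local polynomial (loess): tricube weights over the `span` fraction of
nearest neighbours, bisquare robustness re-weighting.

- `span_bg = 0.3` (default, configurable). Only the M-A span is
  prescribed by the procedure itself (10%, see below); the background
  regression gets a wider window because the B-vs-F relationship is
  smooth and a narrow window would chase noise.
- `degree = 2`, `robust_iterations = 4` for both loess fits. An exact
  polynomial of degree ≤ 2 is reproduced to machine precision, which
  pins down the noiseless behaviour exactly.
- Negative corrected intensities cannot arise (fc = 2^Fc > 0 for
  finite Fc); missing inputs propagate as masked features rather than
  being imputed, preserving the multiplicative model.

## Replicate averaging and outlier exclusion

Replicates are combined by geometric mean per channel — the arithmetic
mean of the log intensities — which is scale-equivariant and the
natural average under multiplicative noise. A feature missing in some
replicates keeps the mean of the rest when at least two remain (one,
if the experiment has a single slide); otherwise it is masked.
Averaging precedes outlier exclusion; exclusion operates on the log2
averaged intensities per channel with the type-7 (linear
interpolation) quartile estimator, keeping values within
[Q1 − 3·IQR, Q3 + 3·IQR] and iterating on the survivors to a fixed
point. A constant vector has IQR 0 and keeps everything.

## M-A normalization

Dye bias and intensity-dependent distortions appear as a smooth trend
of M against A; the normalized M is the residual of a robust local
*quadratic* loess with span 0.10. The quadratic degree matters: a
local-linear smoother cannot remove curvature exactly, whereas the
local quadratic removes any exactly-quadratic injected bias to below
1e-6 in the noiseless case.

Note that loess normalization is *not* an exact projection: a second
pass re-smooths residual noise at amplitude ≈ σ/√window, so
idempotence holds exactly only when the first pass removes the entire
trend (noiseless polynomial input). On noisy input the second-pass
change is a strong contraction of the first, which is what the tests
assert.

## Loop-design filter

For the 4 h triangle the composed fold changes must agree:
f₁·f₂ = f₃, i.e. *LdF = M₁ + M₂ − M₃ = 0* per feature. Features with
LdF outside mean ± 2 SD are eliminated, and the elimination propagates
to the 72 h experiments through the common gene set, since downstream
analysis needs one shared feature universe. When the loop is
consistent to machine precision (SD(LdF) < 1e-12) filtering is
disabled — a band of ±2 float-epsilons would otherwise discard ~5% of
perfect features on numerical fuzz alone.

## Integration: mapping, CGS, MRS

Reporter→gene mapping is a user-supplied two-column table; validation
enforces a one-to-one relationship by dropping every reporter mapped
to more than one gene and every gene targeted by more than one
reporter (counts logged). The common gene set (CGS) is the sorted
intersection of the per-platform gene lists; an empty intersection is
an error, not an empty result.

Median rank score (MRS) normalization aligns distributions across
platforms: the reference experiments ('4' and '5', the higher-quality
platform) define per-rank medians (each reference column sorted, the
median across columns taken at every rank), and each non-reference
experiment's gene at rank *r* receives the reference median at rank
*r*. The transform is rank-preserving (Spearman 1 against the target
in the absence of ties) and makes all experiments' value multisets
identical. The values normalized are the per-experiment log2-ratio
vectors M restricted to the CGS, because the unified output of the
design is a genes × experiments fold-change matrix. Ties in the
target are broken by (value, gene_id) — deterministic across runs.
Reference experiments pass through untouched.

## Differential expression

Without replicated conditions, significance is judged against genes of
similar intensity. Features are stably sorted by (A, gene_id); each
feature's window holds ⌈0.20·n⌉ nearest ranks centered on itself
(shifted inward at the edges, never reflected, and including the
feature); μ and σ (ddof = 1) over the window's M values give
*Z = (M − μ)/σ*. Labels: U if Z ≥ z_crit, D if Z ≤ −z_crit, else S,
with z_crit = Φ⁻¹(0.975) ≈ 1.96 at the default two-sided 95%
confidence — two-sided because both the up- and down-regulated sets
enter the verdict logic. A zero local SD is an error unless the
degenerate-input flag maps it to Z = 0. No multiple-testing correction
is applied by default (an optional Bonferroni/BH flag exists in the
enrichment stage); the window statistics are per-feature rather than
additionally smoothed across overlapping windows, a deliberate
simplification of the published smoothing whose exact form is
unspecified.

Calibration: on a 5,000-feature null (M ~ N(0, σ(A)) with
σ(A) = 0.30 + 0.05·(16 − A)/10 over A ~ U(6, 16) — a mild, smooth
increase of spread toward dim spots, chosen once as a realistic
profile), the fraction labelled S is 95.2%, matching the confidence
level within the ±1% band. `scripts/acceptance.py` recomputes this
number from scratch.

## Clustering and model selection

Genes are ranked by sample SD (ddof = 1) across the five experiments
and the top 100 (SD100) kept; ties break by gene identifier. k-means
uses squared Euclidean distance, seeds centroids at k distinct random
data points, and runs Lloyd's iteration to convergence; an emptied
cluster is re-seeded with the point farthest from its centroid. The
final clustering is the best of `n_init_final = 100` restarts by
within-cluster SSE (all restart scores are retained so the minimality
of the returned run is checkable). Model selection runs independently:
for each k in 2…30 the best *average silhouette width* over
`n_init_scan = 1000` restarts is recorded, with silhouettes also
computed under squared Euclidean distance and singleton clusters
scored 0; k* maximizes the curve, smallest k on ties. The in-package
k-means/silhouette implementation exists because this protocol needs
per-restart scores and best-silhouette-over-restarts selection;
scikit-learn serves as an independent cross-check in the tests.

In the tests the recovery of a planted k (including k = 7) is checked
at 20 seeded trials with k scanned over 2…12 and 60 restarts per k —
sizes chosen to keep the check quick; separated profiles converge in
very few Lloyd iterations, and recovery is insensitive to further
restarts at 10× separation-to-noise.

## Enrichment (parent-child-union)

Annotations are first true-path closed (each gene inherits all
ancestors of its direct terms; the closure is idempotent). For each
non-root term *t* with parent set P(t): the population is the
reference genes annotated to ⋃P(t); draws are the study genes in that
population; successes are reference genes annotated to *t*; the
p-value is the hypergeometric upper tail P(X ≥ observed). Conditioning
on the parents' gene set prevents the cascade of spurious hits below a
genuinely enriched term that the term-independent test produces.
Terms with an empty parent-union population or no reference
annotation are skipped rather than assigned p = 1, so result lists are
not padded. p-values are exact against a rational-arithmetic tail-sum
oracle on all toy instances. Raw p < 0.05 decides category presence
by default, matching the design's summary convention; Bonferroni and
Benjamini-Hochberg are available behind a flag.

## Verdict logic

Each experiment's genes partition into U/D/S; ten named dose-pair
intersections are formed (S₁∩S₃, U₁∩U₃, D₁∩D₃, U₁∩D₃, D₁∩U₃ and the
72 h analogues). The rule table encodes the biological reading: e.g.
genes down-regulated at both 4 h doses with apoptosis-induction
functions (F_a) indicate *inherent* resistance (apoptotic machinery
already being switched off), while the same set enriched for
apoptosis-evasion functions (F_p) indicates *acquired* resistance
(originally sensitive cells adapting). Late (72 h) rules are more
conservative: several category outcomes are undefined because
homeostatic feedback obscures the initial state, and the late
down-regulated-apoptotic verdict is flagged "qualified". Rules for
individual sets (U₁, D₅, …) follow the same early/late asymmetry and
are user-overridable via a rules table, since unlike the intersection
rules they are a reading of the summary-table precedent rather than a
stated procedure. A set with no enriched F_p/F_a category is
*undefined*; both categories firing yields a mixed call with both
sub-verdicts reported; an empty gene set is *not applicable*.
Clusters are assigned a behavioural label (e.g. "~D5": down only in
experiment '5') by thresholding their mean profile against each
experiment's DE scale, then judged under the matching individual-set
rule.

## Chromosome aggregation

Per chromosome, M values pool over genes × experiments within a scope
(all, 4 h, 72 h) and are averaged separately over strictly positive
and strictly negative values (zeros count in neither, following the
strict-inequality convention of the m_M > 0 / m_M < 0 summaries); a
chromosome with no values of a sign has an undefined mean. Pearson
correlations between gene counts and the six sign-split means use
pairwise-complete observations; constant vectors yield undefined
(flagged) correlations.

## Synthetic data: what it emulates, and what it does not

The generator produces: per-feature baseline intensities uniform on
log2 ∈ [6, 16] (a configurable stand-in for the unreported scanner
dynamic range); gene-level true log ratios with a planted DE fraction
(default 10%) at ± a fixed effect (default 1.0 log2) with independent
random signs per experiment and T₃ ≡ T₁ + T₂ enforcing the loop
identity; a quadratic-in-A dye bias added to M (so the pipeline's
quadratic loess can remove it exactly in the noiseless limit);
multiplicative background following F_obs = (F_true + b₀)/(1 − b₁)
with the reported log background b₀ + b₁·F_obs, making background
correction exactly invertible without noise; Gaussian log-scale noise
(default SD 0.15) per replicate; and a small outlier fraction. Cluster
test beds use a planted-partition geometry — centroids inside a ball
of radius 1.25× the separation, pairwise at least the separation
apart — so "separation" is the typical inter-centroid scale.
Toy ontologies are random single-rooted DAGs with planted enrichment.

Not emulated: spot morphology and image-level artifacts, print-tip or
spatial effects, platform-specific probe biases beyond the value
distributions MRS addresses, correlated (co-regulated) noise between
genes, and annotation noise. Passing tests therefore establish the
correctness and calibration of the algorithms under the stated noise
model, not the biological validity of any verdict on real slides.

## Numerical choices and degenerate inputs

- Loess: nearest-rank contiguous windows on sorted x; local centering
  for conditioning; least-squares via `lstsq` (rank-robust); all
  robustness weights zero falls back to kernel weights; perfect fits
  short-circuit robustification.
- Quartiles: linear interpolation (type 7); IQR edge case (constant
  data) keeps everything.
- Stable (value, identifier) ordering wherever ranks or ties matter:
  MRS ranking, DE window sort, SD100 ties.
- Seeds: a single integer seed drives each generator; the pipeline
  splits its master seed per stage and per restart, and identical
  configs reproduce byte-identical outputs (checksummed in the run
  manifest).
- Problem sizes in the test suite (hundreds of features, 100-gene
  matrices, 20-gene ontology toys) were chosen so the whole suite runs
  in well under a minute while every check retains its discriminating
  power; the null-calibration check uses the full 5,000 features of
  its specification.

## Known limitations

- The sliding-window Z-score treats each window's statistics as exact;
  no smoothing across overlapping windows is performed, and the S/U/D
  boundary is hard (no FDR control), matching the original procedure.
- MRS forces identical value multisets across experiments; genuine
  global shifts between platforms are absorbed by design and cannot be
  recovered downstream.
- Verdicts depend entirely on the user-supplied term→category map;
  the package ships no curated F_p/F_a assignment.
- With a single slide per 72 h experiment, replicate-based quality
  control is unavailable for those arrays; the loop filter covers the
  4 h triangle only.
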