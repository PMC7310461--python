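# Methods

This note documents the statistical model, the pipeline's numerical
choices, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable convention
exists.

## Model and procedure

**Network structure.** A signaling pathway is parsed to a gene-level
directed graph: KGML gene entries expand to one node per symbol, group
(complex) entries bequeath their in/out edges to every member, and
compound-mediated relations collapse to direct gene→gene edges. Relation
labels (activation/inhibition) are stored for reporting but are not used
in estimation — the sign of every relationship is estimated from data.
Bayesian networks require acyclicity; feedback edges are removed by
depth-first search from nodes in lexicographic order, deleting back-edges
as encountered. This rule is a declared convention, chosen because it is
deterministic (reproducible results, auditable `removed_edges` report),
not a reconstruction of any particular upstream tool.

**Cross-platform normalization.** Within a platform, each cohort is
quantile-normalized (ties receive the mean of the reference quantiles at
the tied ranks, the limma `normalizeQuantiles` convention), cohorts are
merged on the intersection of their gene sets (the per-cohort fraction of
genes lost is reported), and the merged matrix is adjusted with
parametric ComBat: per-gene standardization against a grand model,
method-of-moments normal/inverse-gamma hyperpriors for per-batch
location/scale effects, iterative empirical-Bayes shrinkage, subtraction
and rescaling, back-transformation. The batch unit is the cohort
(dataset), and the case/control label is included as a covariate by
default (`preserve_group=True`) so the group contrast is not absorbed
into the batch fit; this is exposed as a flag because reasonable
pipelines differ here. The implementation reproduces the Bioconductor
`sva::ComBat` output on a fixed test fixture to ~1e-7; the shrinkage
iteration stops when the largest absolute parameter change falls below
1e-4 (default; configurable). Zero-variance genes pass through unadjusted
with a warning. Expression is assumed to arrive on log2 scale; no
re-logging is performed.

**Estimation.** Each group's network is fitted by per-gene OLS of the
child on an intercept plus its parents, in topological order. The
intercept is the node parameter, parent coefficients are edge parameters,
and `cov_beta = σ̂²(XᵀX)⁻¹` supplies standard errors (σ̂² = RSS/(n−p)).
Collinear parent columns are dropped greedily in lexicographic parent
order (the later parent loses) with a Gram–Schmidt rank test at relative
tolerance 1e-8 — a deterministic rule preferred over pivoting heuristics.
Genes absent from a platform's matrix are skipped; absent parents are
excluded from that node's design; both are recorded. No shrinkage or
structure simplification is applied: plain OLS keeps β₀ interpretable as
an expression level. Fits are invariant to sample and gene ordering.

**Differential testing.** "Independent t test" on two per-group
coefficient estimates is implemented as a Welch-type Wald contrast: each
group contributes one estimate, one SE and its residual df, so
t = (β̂_s−β̂_h)/√(se_s²+se_h²) with Welch–Satterthwaite df — exactly the
variance-sum form of the contrast distribution. Exact fits (zero SE) are
handled explicitly (p = 1 when the estimates agree). FDR control is
Benjamini–Hochberg over nodes and edges jointly within each
(pathway, platform) family, matching how significant counts are reported
per pathway per platform; parameters estimable in only one group are
untestable and excluded from the family. α = 0.05 by default.

**Mixture merge.** Per parameter, each platform contributes a normal
component with mean equal to its contrast estimate and variance equal to
its squared SE when significant, and a zero-mean zero-variance component
otherwise; weights are platform subject counts normalized to one. The
merged mean/variance are the exact mixture moments, and μ* = μ/√Var.
Parameters significant on no platform are omitted rather than reported as
0/0. A zero-variance mixture (single exact-fit component) is flagged
degenerate, never divided. The zero-imputation rule has a consequence
worth knowing when reading results: a parameter detected on one platform
of three keeps at most ~√p_j of its per-platform standardized effect
(the imputed zeros both pull μ down and inflate Var through the
between-component term), so μ* deliberately rewards cross-platform
consistency.

## Synthetic studies: what they emulate, and what not

The generator draws data from the exact generative counterpart of the
fitted model: a linear-Gaussian SEM on the pathway DAG (roots
~ N(β₀, σ²), children = β₀ + Σβ·parent + noise, homoscedastic σ = 1 per
gene by default), group-specific parameters, per-cohort linear
location/scale batch effects (the class parametric ComBat removes:
additive shift ~ N(shift, 0.3²) and multiplicative scale ~ N(1, 0.05²)
per gene by default), and per-platform gene dropout. The default study
mirrors a six-cohort, three-platform layout (two cohorts per platform).

Three modeling choices deserve explanation:

* **Marginal means in the microarray band.** Intercepts are parametrized
  so every gene's marginal mean lands in 5–9 (log2 scale) regardless of
  topology. Without this, negative edge weights push downstream means far
  outside any realistic intensity range.
* **Background genes.** Each cohort carries non-differential background
  genes (default 1000; heterogeneous means U(3,12) and sds U(0.5,2.5))
  alongside the pathway genes. Real arrays measure 10⁴–10⁵ genes of which
  a pathway contributes a few dozen; rank-based quantile normalization
  and ComBat's across-gene shrinkage only behave as they do on real
  arrays when the gene count is array-like. With the pathway genes alone,
  quantile normalization is a coarse 12-point rank map that destroys a
  substantial fraction of the signal.
* **Edge perturbations as rewiring at constant expression.** A perturbed
  edge shifts the coefficient by a chosen multiple of the analytic
  contrast SE and compensates the child's intercept by −Δ·E[parent], so
  the child's marginal expression does not move. A naked coefficient
  shift of ~0.5 with a parent mean near 7 would move the child by several
  log2 units — a 30-fold expression change no microarray shows — and park
  it in the normalization tails. The compensatory intercept change is a
  genuine case/control difference and is recorded in the truth table; the
  `injected` list tracks only the deliberately calibrated parameters.

Effect sizes are calibrated in units of the analytic contrast SE,
computed from the SEM's closed-form moments (mean (I−B)⁻¹β₀, covariance
(I−B)⁻¹D(I−B)⁻ᵀ) and the asymptotic OLS covariance, so "a 3-SE effect"
is sample-size-consistent. The calibration is verified empirically
(sampling SD of fitted contrasts within 20% of the analytic SE).

What passing tests on these studies do **not** show: robustness to
probe-level artifacts, non-Gaussian or heteroscedastic noise, nonlinear
regulation, annotation mismatches between platforms, or confounding that
is not a per-gene location/scale batch effect. Conclusions about real
data inherit those caveats.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline on the
12-gene, 14-edge default cascade with 40 cases + 40 controls per cohort
(80 per group per platform), 1000 background genes, across tens of seeded
replicates — null calibration over ≥2000 parameter-level replicates,
recovery over 30–50 study replicates, mixture-moment checks against 10⁶
Monte-Carlo draws. These sizes give Monte-Carlo error comfortably inside
the asserted margins while the whole pipeline stays fast enough to rerun
casually; all randomness flows from explicit seeds.

## Known limitations

* Cycle breaking and KGML group expansion are conventions; other choices
  yield different (equally defensible) DAGs, and results depend on the
  pathway release used.
* One-platform-only evidence is heavily shrunk by design (see above);
  genes dropped from a platform's arrays can never reach full weight.
* OLS treats parents as exogenous per node; latent confounders and
  measurement error in parents bias edge estimates in either group
  (the contrast removes only the shared part).
* The mixture merge is a model-averaging summary, not a joint test; its
  Var(β_f) mixes sampling variance with between-platform disagreement.
* Real-data ingestion expects preprocessed, gene-annotated, log2
  matrices; probe-to-gene collapsing keeps the highest-mean probe (a
  recorded convention), and raw CEL/IDAT preprocessing is out of scope.
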