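# Methods

cortexflow reconstructs how a hormone-responsive transcriptional program
spreads through a developing tissue from a single-cell time course. The
biological template is brassinosteroid (BL) response in the root: cortex
cells entering the transition/elongation zones switch on a cell-wall gene
module, and the analysis asks which cells respond, where their ancestors
sat at earlier times, which genes define the response, and which
transcription factors sit at the top of the context-specific regulatory
network. This note describes each model, its assumptions, and the design
choices made where the method left room.

## Preprocessing

Counts are library-size scaled and log-transformed,
`x = log(1 + s·c/total)` with `s = 1e4`. This is the conventional
normalization and is strictly monotone in counts within a cell, which the
scoring and DE machinery rely on. PCA (default K = 30) is computed by exact
SVD on gene-centered values with a deterministic sign convention; the PCA
embedding is the substrate for the transport cost and for pseudotime
smoothing. Highly-variable-gene selection ranks genes by dispersion
(variance/mean of normalized values) without mean-binning — simpler and
deterministic; binned variants are a possible extension. QC is a plain
threshold filter on total counts and detected genes; the original study's
dedicated QC pipeline is out of scope here, so the thresholds are exposed
and default to permissive values appropriate for synthetic data.

## Signature score and responsive states

The cell-wall score is a bin-matched module score: genes are ranked by mean
expression and cut into 25 equal-size bins; each signature gene draws up to
100 control genes from its own bin (without replacement; signature genes
are excluded from the pool unless that would empty it). The score is the
mean normalized expression over signature genes minus the mean over the
pooled controls. Controls are sampled once per dataset and seed and shared
by all cells, so scores are comparable cell-to-cell, and adding a constant
to every gene of a cell leaves its score unchanged.

Cortex cells with score ≥ 1 are classified "cortex-responsive", other
cortex cells "cortex-nonresponsive", all remaining cell types "other". The
threshold is inclusive (score exactly 1 is responsive); it is a parameter
with default 1.

## Pseudobulk differential expression

Counts are summed per replicate × cell type × stage × condition (groups
with fewer than 10 cells are dropped), and each (cell type, stage) context
is tested on its own. Size factors are median-of-ratios — total-count
scaling is biased whenever an appreciable fraction of genes is DE. Per-gene
NB dispersion is a method-of-moments estimate on normalized sums, pooled
across conditions, clipped at zero and shrunk (weight 0.7) toward an
`a0 + a1/μ` trend fitted across genes; the shrinkage borrows strength
across genes, which is what keeps a normal-reference Wald test honest with
three replicates per condition. Group means are fitted by damped Newton
iteration with log-library-size offsets; the Wald statistic uses the
observed Fisher information. BH correction is applied within each context
(matching per-context DEG reporting), and a gene is called up/down only if
|log2fc| > log2(1.5) and FDR < 0.05. Genes with zero counts in both
conditions get p = 1, never an error.

Calibration at the design scale (2,000 genes, NB α = 0.1, mean 100, 3v3):
null fraction of p < 0.05 ≈ 0.05–0.06, power for 4-fold genes ≈ 0.99.
These are recomputed by `scripts/acceptance.py`, not asserted constants.

## Optimal-transport trajectories

Adjacent time points are coupled by entropic optimal transport in PCA
space. The squared-Euclidean cost is divided by its median so ε is
scale-free. Marginals are KL-relaxed (unbalanced transport): minimize
⟨Π,C⟩ − ε·H(Π) + λ₁·KL(Π1∥p) + λ₂·KL(Πᵀ1∥q), solved by log-domain diagonal
scaling (no overflow for ε ≥ 1e-3 after normalization); λ = ∞ recovers
balanced transport. Defaults ε = 0.05, λ₁ = 1, λ₂ = 50: the loose source
constraint absorbs growth-rate error, while the tight target constraint
trusts the observed cells. None of these values is fixed by the underlying
method; they follow its conventions and are exposed in `SinkhornParams`.
Convergence is declared on potential change (`tol`) or, in balanced mode,
on marginal L1 error (`marginal_tol`); a non-converged plan is returned
flagged, with its marginal error, never silently.

Source masses implement proliferation: `p_i ∝ rate(stage_i)^Δt`, with
defaults 2.0 / 1.5 / 1.0 / 0.8 for proliferation / transition / elongation /
differentiation (dividing meristem cells contribute more descendants).
Uniform rates give uniform masses.

Only adjacent-pair plans are fitted. Longer-range queries compose plans:
couplings are row-normalized to Markov transitions, chained, and
re-weighted by the first source mass. Fate probabilities anchor at a
reference time (default 2 h): at the reference, probabilities are exact
membership indicators of the three-state partition; before it, a cell's
probability of a state is the fraction of its transported mass landing in
that state's cells; after it, the symmetric descendant construction
applies. Cells with zero transported mass are reported missing (NaN) and
never imputed. Barycentric (ternary) coordinates place non-responsive at
(0,0), responsive at (1,0) and other at (0.5, √3/2); the map is affine in
the probabilities.

## Trajectory-level DE

The "probabilistic DE" between responsive and non-responsive fates at a
time point is a weighted-mean contrast: each cell weights the responsive
mean by its (normalized) responsive probability and likewise for
non-responsive; the statistic is the difference. The null distribution
comes from jointly permuting weight pairs across cells (1,000 permutations,
add-one correction), then BH over genes. This statistic was chosen because
it is exact under permutation and linear in the weights; a rank-based
variant would be a drop-in replacement. Genes whose effective support is
fewer than 3 cells on either side are flagged `low_support`.

## Pseudotime and stage association

The pseudotime is a transcriptional-diversity ordering in the spirit of
CytoTRACE, not a reimplementation of it: raw score = number of detected
genes, smoothed over the 30 nearest embedding neighbors (smoothing is
skipped when the lineage has ≤ 30 cells), rank-scaled to [0,1], and
oriented so proliferation-domain cells sit near 0 (stage-anchored sign).
It is invariant to gene order and uniform count scaling. Association of
expression with pseudotime uses a cubic B-spline basis (df = 4, knots at
quantiles) against an intercept-only model with a classical F-test and BH
over genes; "developmentally varying" means FDR < 0.05. Expression trends
are per-gene z-scaled means over 50 equal-width pseudotime bins with linear
interpolation of empty bins.

## Core set and enrichment

The core hormone-responsive set is the triple intersection of: (A) genes
up-regulated by BL in any cortex context, (B) genes down-regulated in the
receptor-null cortex relative to wild type, and (C) genes varying along the
wild-type cortex trajectory. Set A pools all cortex stages (the
corresponding published comparison is cortex-wide). Overlap against
user-supplied target lists is |query∩reference|/|query|; enrichment is the
upper-tail hypergeometric probability with fold =
(overlap/|query|)/(|reference|/|universe|). The universe defaults to the
genes detected in the dataset, not a genome; no multiple-testing correction
is applied inside the enrichment call — callers BH over collections.

## GRN inference and TF ranking

Within a candidate TF→target prior, each target is regressed on its
candidate TFs by ridge regression (α = 1) on centered expression, bagged
over 20 bootstrap resamples of cells. Centering without variance scaling
keeps edge weights on the regression scale. An edge is retained when
(i) its |mean coefficient| exceeds the (1 − keep_frac) quantile of all
candidate magnitudes (keep_frac default 0.1), (ii) its sign agrees in ≥ 80%
of bags, and (iii) its bootstrap t-statistic (|mean|/bootstrap SD) is ≥ 2.
The t gate is what actually rejects edges whose target is independent of
the TF — bootstrap signs alone are correlated with the full-sample fit and
reject only about half of null edges. Contexts are (cell type, stage, time
point) triples; TF prioritization is by out-degree on retained edges, ties
broken by node id, and network comparison counts exact (TF, target) pairs,
ignoring sign and weight. In-silico perturbation machinery of the
inspiration method is out of scope.

## Synthetic-data generator

The generator emulates the study design: six time points (0, 0.5, 1, 2, 4,
8 h), BL-treated and mock cells at every time point, three replicates, six
cell types (cortex 30%) each stratified into four developmental stages, and
NB counts (var = μ + αμ², α = 0.1 shared across genes) on 2,000 genes with
1,500 cells per time point. Planted structures:

* **Induction.** 107 signature genes gain
  `ln(4)·t/(t + 1 h)` in log-mean in BL-treated, induction-competent
  (probability 0.8) cortex transition/elongation cells of the wild type;
  the receptor-null genotype has no induction. Signature genes also carry a
  +0.5 log baseline elevation in cortex transition/elongation cells: cell
  wall genes are elongation-associated, and this baseline program is what
  lets an induced cell's score clear the fixed threshold of 1 at 2 h (the
  saturating induction alone reaches only ln(4)·2/3 ≈ 0.92 by then) and
  makes the core genes developmentally varying.
* **Diversity gradient.** A global −0.25 log shift per stage index thins
  the detected-gene repertoire as cells differentiate — the structure a
  diversity-based pseudotime measures.
* **Growth.** Stage-wise relative growth rates (2.0/1.5/1.0/0.8) recorded
  per cell; they enter only as transport masses (no lineage simulation).
* **TF hub network.** 20 TFs with per-cell activity (sd 1.0) active in
  cortex cells; true targets shift by 0.5 × activity × sign. The hub TF has
  out-degree 40 (others 4–10) and is itself BL-induced (fold 3) in
  competent cortex cells. The candidate prior is the true edges plus an
  equal number of decoys.
* **Nuisance.** Per-cell depth (log-normal, sd 0.3) and per-sample
  replicate effects (sd 0.05).

Gene and network parameters are drawn from a genotype-independent stream,
so wild-type and receptor-null datasets are directly comparable; the same
seed reproduces every byte.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, spatial structure, cell-to-cell induction kinetics beyond the
competence coin-flip, and continuous developmental transitions (stages are
discrete labels). Passing recovery tests therefore demonstrates that the
machinery is correct and calibrated under the stated statistical model, not
that it is robust to every artifact of real data.

## Problem sizes and numerical choices

Recovery runs use the generator defaults above (9,000 wild-type cells over
six time points); the planted-hub benchmark simulates single-time-point
datasets (1,200 cells) over ten seeds; calibration simulations use 2,000
genes. Degenerate inputs are handled explicitly: zero-total cells are
rejected before normalization with a pointer to the QC filter; constant
genes give z-scaled trend rows of 0 and F ≈ 0; empty pseudobulk groups and
empty GRNs are warnings or empty results, not crashes; ties in HVG ranking,
TF ranking and pseudotime ranks break deterministically (gene/node id
order, midpoint ranks). All stochastic steps (control-gene sampling,
bootstrap bags, permutations, the generator itself) consume explicit seeds,
and the pipeline report is byte-identical across runs with the same seed.

## Known limitations

The pseudotime stand-in measures transcriptional diversity only; it will
fail on data where diversity does not track development. The Wald test
relies on trend shrinkage for small-replicate calibration and has no
mixed-model or covariate machinery. Growth rates are taken as known
stage-wise constants rather than estimated from proliferation signatures
(one re-estimation pass is stubbed via `growth_iters`). Transport runs on a
single shared PCA; batch-aware embeddings are out of scope.
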