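# Methods

## Kinetic model

Per gene, unspliced (u) and spliced (s) abundances follow the standard
two-stage first-order system

    du/dt = α(t) − β u,      ds/dt = β u − γ s,

with splicing rate β and degradation rate γ constant and the transcription
rate α(t) piecewise constant in latent time t ∈ [0, 1]: one value per
*regime*, with regime boundaries at the gene's switch times. The solution is
evaluated in closed form and chained across regimes, keeping (u, s) continuous
at every boundary; the boundary instant itself belongs to the earlier regime
(left-continuous state, right-discontinuous rate). The β = γ case is handled
by its analytic limit (the t·e^{−βt} secular term), switched at
|β − γ| < 1e−9 rather than by perturbing the inputs. Closed form and a
fourth-order Runge–Kutta integrator agree to below 1e−6 absolute over random
parameter sets including the near-degenerate block (tested).

A **MURK gene** has a later regime whose α strictly exceeds an earlier one;
all other genes have equal α across regimes. Two initial conditions are
supported:

* `steady_state_of_first_regime` (default): cells enter the trajectory at the
  first regime's fixed point (α/β, α/γ). Single-regime genes are then flat,
  so all downstream signal comes from rate switches — the cleanest setting for
  screening calibration.
* `zero`: induction from (0, 0), the classic phase-plot scenario in which
  every gene sweeps out an arc above the steady-state diagonal (u/s ≥ γ/β
  throughout, tested). Used for the velocity demonstration, where non-MURK
  genes must carry genuine temporal signal.

## Synthetic data generator

The generator emulates an ordered differentiation trajectory: latent times
uniform on [0, 1]; population labels by breakpoints (default quartiles,
Prog < Ery1 < Ery2 < Ery3); per-gene rates drawn from uniform priors
α ∈ [5, 20], β ∈ [3, 8], γ ∈ [0.5, 1.5] per unit latent time. The β ≫ γ
ordering reflects the biology — splicing completes in minutes while mRNA
half-lives are hours, comparable to the differentiation window — and is what
makes a transcription boost visible: unspliced counts equilibrate quickly
after the step while spliced counts lag.

A fraction `murk_fraction` (default 0.1) of genes receives a second regime
with α multiplied by `boost_factor` (default 4) at `switch_time` (default
0.75, the Ery2/Ery3 boundary, mirroring the late-erythroid boost).
Knockout-genotype cells are evaluated with every MURK gene collapsed to its
first-regime α — the boost simply never happens — while non-MURK genes are
genotype-independent.

Counts are Poisson with mean = capture × expected abundance, independently
per layer, with capture 1.0 (spliced) and 0.3 (unspliced): oligo-dT
protocols capture intronic reads inefficiently. Negative-binomial
overdispersion (gamma–Poisson mixture) is available via `dispersion`. All
draws flow from a single `numpy.random.default_rng(seed)` in documented order
(MURK slots, rates, latent times, genotypes, U counts, S counts), so a config
plus seed determines the dataset byte-for-byte.

Default scale is 4000 cells × 500 genes (1000 cells per population). What the
generator does **not** emulate: branching topologies, batch effects, ambient
RNA, doublets, cell-cycle variation, gene–gene correlation beyond the shared
trajectory, or down-regulation programs. Passing tests therefore show the
screen behaves correctly when its model assumptions hold plus count noise and
composition effects; they do not certify behaviour under every real-data
artifact.

## Preprocessing

1. **Shared-count filter**: a gene's score is min(total spliced, total
   unspliced) summed over the cells expressing it in *both* layers; genes
   below 20 are dropped. (The threshold is standard; the precise formula is a
   documented reading of "shared counts" chosen so that a gene dead in either
   layer scores zero.)
2. **Normalization**: per cell and per layer, counts are divided by the cell's
   size factor (layer total / median of layer totals; zero-total cells get
   factor 1 with a warning) and log1p-transformed.
3. **Imputation (first-order moments)**: each value is replaced by the
   unweighted mean over the cell and its k = 30 nearest neighbours, found by
   Euclidean distance in a 30-component PCA of the log-normalized spliced
   layer (or in a caller-provided embedding for real data). Unweighted
   averaging over self ∪ neighbours is the simplest faithful reading of
   moment imputation; the smoother is row-stochastic, so imputed values stay
   within per-gene bounds and symmetric uniform graphs preserve gene means
   (tested).

HVG selection is off by default for synthetic data (all genes retained) and
available as top-k by dispersion for real-data mode.

## The MURK screen

On the imputed layers, for each gene and each population with at least 20
cells, u is regressed on s by ordinary least squares *with intercept* (phase
plots do not pass through the origin once normalized; a through-origin switch
exists for reconciliation with steady-state-style fits). The slope b and its
standard error come from the standard OLS variance estimate with n − 2
degrees of freedom; genes with constant s in a population get an undefined
fit and are excluded from testing.

The slope-increase test between the designated late and early populations uses

    T = (b_late − b_early) / sqrt(se_late² + se_early²)

referred to a t distribution with Welch–Satterthwaite degrees of freedom
built from (se², n − 2) of each fit; a normal-approximation option exists.
Zero-SE degeneracies resolve by convention (equal slopes → p = 0.5, larger
late slope → 0, smaller → 1). A gene is called MURK when p < 0.05 (raw — no
multiple-testing correction, a deliberate faithfulness choice; a BH option is
available but off), its late-population mean spliced expression is *strictly*
the maximum over all populations (ties break against calling), and the late
slope is positive. Calls are ranked by slope increase, descending.

**Calibration caveat.** kNN imputation correlates cells, so OLS standard
errors on imputed values are slightly anticonservative (null T-statistics
have sd ≈ 1.2 rather than 1), and per-cell normalization introduces a
composition effect: when a tenth of the panel boosts 4×, late-population size
factors rise, tilting null genes' imputed values into weak spurious slopes.
The conjunction with the strict max-expression criterion keeps the realized
null call rate near 1% (≤ 5% asserted), and at the default configuration the
screen recovers planted genes with sensitivity ~1.0 and precision ~0.9–0.98
across seeds. Both artifacts are properties of the standard
normalize-impute-regress pipeline itself, not of this implementation.

## Velocity and the direction score

γ′ per gene is the through-origin least-squares slope of u on s over cells in
the lower and upper 5% tails of s (pooled tails below 10 cells fall back to
all cells; degenerate genes are dropped). Velocity is the residual
v = u − γ′s per cell, computed on the same normalized/imputed layers as the
screen. On noise-free collinear data velocities vanish to 1e−8 (tested).

The direction score asks whether the velocity field points forward in true
latent time. For each cell, cosine similarities between its velocity vector
(restricted to retained genes) and the displacement vectors to its k graph
neighbours are converted to transition weights by a temperature-1 softmax;
the cell contributes the weighted mean sign of (neighbour latent time − own
latent time), **minus the uniform-weight baseline** (the unweighted mean
sign). The centring is necessary because neighbour sets are not
time-symmetric — cells crowd where expression saturates, so most neighbours
of a mid-trajectory cell lie later in time — and without it the score
measures sampling density rather than velocity (a zero-information velocity
field orthogonal to the trajectory would otherwise score strongly positive;
with centring it scores exactly 0, tested). Cells with an exactly zero
velocity vector contribute 0; the mean over cells is clipped to [−1, 1].
With temperature-1 softmax over k = 30 neighbours the score's practical
dynamic range is modest (a perfectly aligned field on a 2-neighbour ring
scores tanh(1) ≈ 0.76); only sign and ordering comparisons are meaningful.

The corruption-and-rescue demonstration (`rescue_demo_config`) uses zero-start
induction, a MURK-heavy panel (20% of 300 genes — erythroid branches are
dominated by the erythroid program) and the default 4× boost: the step-change
genes steepen their γ′ fits, the majority of their mid-trajectory velocities
turn negative, and the panel-wide direction score drops; removing the
detector-flagged genes raises it (≈ +0.02 → +0.03 across seeds, both
positive, the gap stable). Under the steady-state initial condition non-MURK
genes carry no temporal signal at all, so a positive post-removal score would
be impossible by construction — the zero-start choice is what makes the
rescue claim testable.

This estimator is intentionally minimal: the full dynamical-model EM (per-gene
latent time inference) used by scVelo is out of scope, so magnitudes of
corruption are not comparable to UMAP-level arrow flips — only the ordering
(all genes < MURK-removed) and the sign of the rescued score are asserted.

## Overlap testing

Enrichment of a query list (the MURK calls) in a reference category within a
universe of N genes is the exact upper-tail hypergeometric probability
P(X ≥ m), summed in log space. Universes up to N = 20000 use exact integer
binomial coefficients (log of an exact big integer is correct to one ulp, so
point masses normalize to 1 within ~1e−13); larger universes use
gammaln-based log-binomials (~1e−11 relative accuracy, ample for tail
p-values far below float underflow). The primary statistic is the
enrichment-only upper tail; a two-sided Fisher option exists. List
bookkeeping harmonizes identifiers case-insensitively and drops (with a
warning) query genes outside the universe.

For the published comparison counts m = 55, n = 89, A = 1022, N = 4195 the
exact tail is 3.698×10⁻¹⁴ (log10 p = −13.43), expected overlap 21.68, fold
enrichment 2.54 — computed at run time by `scripts/acceptance.py` and
cross-checked against an independent distribution implementation in the
tests.

## Numerical and design notes

* Matrix layers are dense float64 in memory (desk-scale: ≤ 8000 × 2000);
  archives are Matrix Market coordinate (1-based, integer for raw counts,
  17-significant-digit real otherwise) + TSV, chosen over binary single-cell
  containers for language-agnostic, byte-exact round-tripping. An adapter to
  annotated-matrix containers is a documented extension point, not core.
* The kNN graph excludes the cell itself from its k neighbours; imputation
  re-includes it in the average. PCA and neighbour queries are seeded and
  deterministic.
* Population minimum of 20 cells for slope fits: below that, slope SEs are
  too unstable to test.
* `run-all` reports are deterministic for identical config + seed; every
  reported number is recomputable from the persisted stage outputs.
* Accession-based reproduction of the published mouse/human gene lists
  requires downloading the original datasets and is out of scope for the
  test suite; the real-data entry point is the archive reader plus a
  provided embedding.
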