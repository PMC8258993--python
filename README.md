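# murkscreen

Detection of **multiple-rate-kinetics (MURK) genes** — genes whose
transcription rate undergoes a coordinated step increase partway along a
differentiation trajectory — and demonstration of how they corrupt RNA-velocity
trajectory inference and how removing them rescues it.

RNA velocity infers a cell's future transcriptional state from the balance of
unspliced (pre-mRNA) and spliced transcripts under the first-order model

```
du/dt = α − βu          (transcription α, splicing β)
ds/dt = βu − γs         (degradation γ)
```

with α, β, γ assumed constant per gene. During erythropoiesis that assumption
fails: a coherent set of red-blood-cell genes (hemoglobins and friends,
downstream of Gata1) steps its transcription rate up midway through
differentiation. In the per-gene phase plot of unspliced vs spliced counts the
step produces a sudden excess of unspliced transcript that steepens the fitted
steady-state line u = γ′s, flips velocity residuals v = u − γ′s negative for
cells that are genuinely progressing, and reverses inferred differentiation
arrows. This package implements, as a tested pipeline:

* **`kinetics`/`simulate`** — exact closed-form solution of the two-equation
  model with piecewise-constant α (including the β = γ analytic limit), and a
  synthetic-data generator: cells with latent time in [0,1] ordered into
  populations (Prog < Ery1 < Ery2 < Ery3), per-gene rates from realistic
  priors, a designated MURK subset boosted `boost_factor`-fold at a switch
  point, a knockout genotype in which the boost is abrogated, and Poisson (or
  negative-binomial) count sampling with asymmetric capture of the two layers.
* **`preprocess`** — shared-count gene filter (default ≥ 20 counts shared
  between layers), per-layer median-ratio normalization with log1p, and
  k-nearest-neighbour moment imputation (default k = 30, PCA embedding of the
  spliced layer).
* **`detect`** — the MURK screen: per-population OLS slope of unspliced on
  spliced imputed counts with its standard error; a gene is called when the
  late-population slope significantly exceeds the early-population slope
  (one-sided Welch t-test, raw p < 0.05, no multiple-testing correction), its
  mean spliced expression is strictly maximal in the late population, and the
  late slope is positive. Calls are ranked by slope increase.
* **`velocity`** — steady-state velocity (through-origin γ′ fit on extreme
  spliced quantiles, residual v = u − γ′s) and a direction score in [−1, 1]
  measuring agreement between the velocity field and true latent time via
  softmax-weighted neighbour transition signs.
* **`overlap`** — exact hypergeometric enrichment of a gene list against an
  independent reference set (e.g. Gata1-induction responders), computed in log
  space so tails far below float underflow stay exact.
* **`io`/`pipeline`/`cli`** — Matrix Market + TSV dataset archives with exact
  round-tripping, a validated YAML run configuration, and a
  `murkscreen` command with `simulate`, `preprocess`, `detect`, `velocity`,
  `overlap` and `run-all` subcommands.

## Worked example

```bash
python examples/02_murk_screen.py
```

simulates the default study configuration (4000 cells, 500 genes, 10% MURK
genes boosted 4× at the Ery2/Ery3 boundary, seed 1), runs the full screen and
prints:

```
planted MURK genes : 50
called MURK genes  : 54 (50 true, 4 false)
sensitivity        : 1.000
precision          : 0.926

top five by slope increase (the screen's ranking):
gene_id  slope_increase      p_value
   g099        2.587671 2.341864e-49
   g450        1.942589 1.345572e-40
   ...
```

All 50 planted step-change genes are recovered (sensitivity 1.0) with four
false calls (precision 0.93); the ranking orders genes by how strongly their
phase-plot slope rises between the two erythroid populations. The other
examples show the kinetic trajectories themselves (`01`), the velocity
corruption-and-rescue (`03` — the direction score rises from +0.019 to +0.034
when flagged genes are removed), and the enrichment of the screened list in an
independent Gata1-response gene set (`04` — 55/89 observed vs 21.7 expected,
fold enrichment 2.5, p ≈ 3.7×10⁻¹⁴).

The same pipeline runs from the shell:

```bash
murkscreen simulate --seed 1 --out run/raw
murkscreen preprocess run/raw --out run/imputed
murkscreen detect run/imputed --out run/murk.tsv
murkscreen run-all --seed 1 --out run/full
```

Real velocyto-style data can be analysed by laying out spliced/unspliced
Matrix Market files with `cells.tsv`/`genes.tsv` metadata as described in
`murkscreen/io.py` (a pseudotime or sampling-stage ordering stands in for
latent time).

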