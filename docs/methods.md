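# Methods

## The problem

Imaging-based spatial transcriptomics (IST) assays — Xenium, MERSCOPE,
CosMx — report individual transcript molecules with μm coordinates, which a
segmentation step assigns to cells. Segmentation is imperfect: molecules
produced by one cell end up counted in a neighbour (spillover), and diffuse
extracellular signal (ambient contamination) is absorbed by whichever cell
polygon covers it. The resulting count matrix contains entries that are not
endogenous expression, which inflates apparent co-expression of mutually
exclusive markers and dilutes cell-type signatures.

`istclean` removes this contamination at the (cell, gene) level. The
decision is all-or-nothing: each gene's count in each cell is either kept
whole or set to zero. This fits the targeted panels of current IST assays,
where most genes are cell-type markers expected to be mutually exclusive;
it is *not* appropriate for whole-transcriptome panels where a gene can
plausibly be partly endogenous and partly contaminated in the same cell.

## Model

For cell *i* with counts `x_ij` over a panel of G genes, a spatial context
`x⁺_ij` is assembled (below). Conditional on a latent indicator
`Z_ij ∈ {0, 1}` ("gene j endogenously expressed in cell i"):

```
x_ij | Z_ij=1  ~  Poisson(m_e(x⁺_ij, λ_e))      endogenous
x_ij | Z_ij=0  ~  Poisson(m_c(x⁺_ij, λ_c))      contamination
Z_ij           ~  Bernoulli(π_i)
```

with per-cell parameters `θ_i = (π_i, λ_e, λ_c)`, `λ_e ≥ λ_c`. Two context
couplings are implemented:

* **multiplicative** (default): `m(x⁺, λ) = (x⁺ + 1)·λ`. Here `λ_c` is the
  fraction of the surrounding signal that reappears inside the cell — a
  leakage rate, near zero in clean data — and `λ_e` the cell's expression
  level per unit of context. The `+1` is a pseudo-context of one molecule:
  it keeps the likelihood informative for genes with empty neighbourhoods
  (a zero count then has probability `e^{-λ}`), without which isolated
  cells produce an unidentifiable likelihood ridge.
* **additive**: `m(x⁺, λ) = x⁺ + λ`, the literal offset form. With
  `x⁺ ≡ 0` this is exactly a textbook two-component Poisson mixture, which
  is how the fit is validated against independent references. At realistic
  cell densities, however, `x⁺` (a sum over all neighbours) exceeds any
  single cell's counts several-fold, both rates clamp to their floor and
  the posterior degenerates to the prior — so the additive form is kept as
  an option and for validation, not as the default.

Fitting is per-cell EM: the E-step computes
`α_ij = P(Z_ij = 1 | x_ij, θ̂_i)` (log-sum-exp stabilised; the `x!` term
cancels), the M-step sets `π = mean(α)` (clamped to `[1e-4, 1-1e-4]`) and
solves the weighted Poisson score for each rate — closed form
`λ = Σwx / Σw(x⁺+1)` in multiplicative mode, bracketed Brent root finding
of `Σ w[x/(x⁺+λ) − 1] = 0` on `[1e-6, max(x)+1]` in additive mode. Rates
are floored at `1e-6` and re-ordered so `λ_e ≥ λ_c` (flipping π). Ten
restarts draw `π₀ ~ Unif(0, 0.5)` — a cell is unlikely to truly express
more than half of a targeted panel — and seed the rates from the genes
most in excess of their context; the restart with the highest final
log-likelihood wins. Convergence: relative log-likelihood change `< 1e-6`,
at most 200 iterations.

A gene is filtered (count set to 0) when `α_ij ≤ 0.75` (inclusive; the
cutoff is configurable).

### When the filter is withheld

Two guards protect cells the model cannot speak for:

* **Skip rule** — cells with fewer than 3 non-zero genes are passed
  through unfitted (a three-parameter mixture on fewer informative
  observations is unidentifiable). Their posterior rows are NaN.
* **Contamination-evidence guard** — a two-component fit on a cell with no
  actual contamination still improves its likelihood by splitting the
  sampling noise of expression, but the spurious "contamination" component
  is recognisable: in multiplicative mode its rate lands far above any
  plausible leakage fraction (we require `λ_c ≤ 0.25`; genuine leakage is
  roughly `p_spill / n_neighbours`, an order of magnitude smaller), and in
  additive mode the two rates coincide (`λ_c ≥ 0.95·λ_e`), making
  `α ≡ π`. Such cells are passed through unfiltered and counted in the run
  report (`n_no_separation`). On contaminated synthetic tissue the guard
  never fires; on contamination-free tissue it is what keeps retention of
  real signal above 99%.

## Spatial context

**Local.** `T_i` is the set of cells whose centroids lie within `d` μm of
cell *i*'s centroid (Euclidean, boundary inclusive, default d = 50 μm);
the local context of gene *j* is `Σ_{t∈T_i} x_tj`. A distance criterion
rather than k-nearest neighbours makes dense tissue — where contamination
is worse — contribute proportionally more context.

**Global.** When a transcript table is available, molecules are binned
into a regular flat-top hexagonal lattice (target 200 bins; circumradius
`r = sqrt(2·bbox_area / (3√3·n_target))`, exact hex area
`A = (3√3/2)r²`, lattice anchored at the bounding-box min corner; bins are
the lattice cells covering the bounding box plus any cell actually hit by
a transcript, so transcript conservation is exact). A two-component
Gaussian mixture is fitted to the bin totals by EM (deterministic
median-split initialisation, variance floor `1e-6·var`, ≤500 iterations,
relative tolerance `1e-8`); each bin is hard-assigned by posterior
responsibility and the lower-mean component is background. The per-gene
background level is the mean count over background bins scaled by
`π·d²/A` — the expected ambient contribution to a neighbourhood-sized
disc — and is added to every cell's local context. Without a transcript
table the global term is zero (cell-level counts cannot populate
extracellular bins) and a warning is logged.

On simulated tissue whose cells cover the whole extent the "background"
component latches onto partially covered edge bins, mildly overestimating
the ambient level; in real samples genuinely empty regions dominate the
low component. The term is nevertheless beneficial in simulation: it gives
otherwise context-free genes a small positive context.

## Evaluation statistics

* **MECR** (mutually exclusive co-expression rate), per gene pair: cells
  expressing both genes / cells expressing either. Counts are rounded
  half-up first (0.5 is positive, 0.49 is not) so fractional outputs of
  other tools are comparable. 0/0 is reported as missing.
* **PMP** (positive marker purity), per cell: fraction of the cell's
  counts in its type's marker set; the summary is the unweighted mean over
  cell types of within-type means (type-balanced), excluding zero-total
  cells.
* **Pair/marker derivation** from a labelled reference: per type, a gene
  qualifies if detected in ≥50% of the type's cells and ≤5% of all other
  cells; among qualifying genes the top 30% by mean pairwise AUC (focal
  type vs each other type, mid-rank ties, averaged; ceil rounding) are the
  type's specific genes. Applying the detection filters before the AUC
  quantile keeps the quantile on an already-specific pool, which is
  stabler than quantiling the whole panel. Pairs are all cross-type
  combinations of specific genes.

## Synthetic data

The generator plants ground truth for every (cell, gene) entry:

* cells uniform over a rectangular extent; types assigned uniformly, so
  the tissue is fully interleaved (no spatial domains);
* disjoint per-type programs of `genes_per_type` genes plus optional
  `n_shared_genes` expressed by every type; endogenous counts Poisson with
  common mean `expr_mean` on program genes;
* spillover: for each ordered neighbour pair within `neighbour_radius`, a
  `Binomial(x_endo, p_spill)` thinning of the neighbour's realised
  endogenous counts is added to the cell — thinning realised counts (not
  the rate) keeps the truth bookkeeping exact;
* ambient: Poisson(`ambient_rate`) per (cell, gene), plus a matching
  number (`Poisson(ambient_rate·N·G)`) of extracellular molecules
  scattered uniformly (transcript table only);
* molecules owned by a cell are placed uniformly in a 10 μm disc around
  its centroid — they only feed the hexbinning, so placement is a free
  choice.

Defaults: 2,000 cells on 2.5 × 2.5 mm (≈320 cells/mm², two to three
neighbours within 50 μm — a sparse-to-moderate tissue section), 2 types ×
50 program genes + 20 shared genes, `expr_mean = 10`, `p_spill = 0.15`
from neighbours within 30 μm (one to two cell diameters — spillover is a
segmentation-boundary effect), `ambient_rate = 0.02`. These sizes keep a
full five-replicate evaluation under two minutes on one CPU.

What the generator does **not** emulate: empty tissue regions (cells cover
the extent uniformly, so the background GMM sees no truly empty bins),
per-gene expression heterogeneity within a cell, cell morphology and
segmentation polygons, spatial domains, batch structure. Passing tests on
this generator therefore demonstrate the mechanics of context-based
filtering, not performance on any particular real tissue.

## Known limitations

* **Ubiquitously expressed genes.** A gene expressed by every cell type
  has roughly twice the context of a type-specific gene at equal
  expression, so a single shared endogenous rate under-fits it and part of
  its counts are filtered (in simulation, shared genes retain ~60–70%
  under contamination while type-specific genes retain ~95%+). This is the
  flip side of the model's core assumption — panels composed of mutually
  exclusive markers — and matches the design intent of current targeted
  panels, which avoid housekeeping genes.
* **Shared Poisson mean.** All endogenous genes of a cell share one rate;
  wide dynamic range within a cell degrades the fit. Low-sensitivity IST
  data with compressed dynamic range fits this assumption better than
  deeply sampled data would.
* **Heavy contamination.** When leakage approaches the endogenous rate
  (dense tissue, high spill), the components overlap and sensitivity
  decays; conversely the contamination-evidence guard makes the tool
  conservative when contamination is extreme enough to masquerade as
  expression.
* **Per-cell independence.** Cells of the same type are fitted
  independently; no information sharing is attempted.
* Denoising is not idempotent: re-running on an adjusted matrix changes
  neighbour counts and hence offsets. The only guaranteed relation is
  `adjusted ≤ raw` elementwise, with every entry kept whole or zeroed.

## Reproducibility

Every run is determined by (inputs, configuration, master seed). Per-cell
RNG streams derive from the master seed and the cell index, so results are
bit-identical regardless of evaluation order; the run report echoes the
full configuration and seed.
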