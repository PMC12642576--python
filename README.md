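# istclean

Spatial-context denoising of imaging-based spatial transcriptomics (IST)
count matrices.

Segmented cells in Xenium / MERSCOPE / CosMx data absorb transcripts that
are not theirs: molecules spilling over imperfect segmentation boundaries
from neighbouring cells, and diffuse ambient signal. `istclean` classifies
every gene count in every cell as *endogenous* or *contamination* and
returns an integer count matrix with the contaminated entries set to zero —
each count is kept whole or removed, never fractionally reweighted.

## Model in brief

For cell *i*, counts are a two-component Poisson mixture conditioned on the
cell's spatial context `x⁺_ij` — the summed counts of gene *j* over all
cells within 50 μm, plus a global ambient level estimated from hexagonally
binned transcripts via a two-component Gaussian mixture:

```
x_ij | Z_ij=1 ~ Poisson((x⁺_ij + 1)·λ_e)   endogenous
x_ij | Z_ij=0 ~ Poisson((x⁺_ij + 1)·λ_c)   contamination (λ_c ≈ leakage fraction)
Z_ij          ~ Bernoulli(π_i)
```

Per-cell parameters `(π_i, λ_e, λ_c)` are fitted by EM with ten random
restarts (`π₀ ~ U(0, 0.5)`); the posterior `α_ij = P(Z_ij=1 | x_ij)` drives
the filter: counts with `α_ij ≤ 0.75` are zeroed. An additive context
coupling (`mean = x⁺ + λ`) is available via `offset_mode="additive"`.
Cells whose fit shows no contamination-like component pass through
untouched, so clean data is not over-corrected.

Two evaluation statistics are included: **MECR** (mutually exclusive
co-expression rate, the fraction of cells co-expressing a gene pair that
biology says should be exclusive — a false-positive proxy) and **PMP**
(positive marker purity, the fraction of a cell's counts in its own type's
markers — a true-positive proxy), together with reference-based derivation
of exclusive pairs and marker sets. A synthetic tissue generator with
planted per-(cell, gene) ground truth makes everything testable offline.

## Worked example

```python
import numpy as np
from istclean import (RunConfig, SimConfig, denoise, derive_exclusive_pairs,
                      evaluate_against_truth, simulate_dataset)

# a synthetic 500-cell tissue: two interleaved cell types, 15% spillover
ds = simulate_dataset(SimConfig(n_cells=500, extent=(1250.0, 1250.0), seed=0))
res = denoise(ds.counts, ds.cells, tx=ds.transcripts,
              config=RunConfig(seed=0), gene_names=ds.gene_names)

# evaluate with pairs/markers derived from a contamination-free reference
ref = simulate_dataset(SimConfig(n_cells=500, extent=(1250.0, 1250.0),
                                 seed=0, p_spill=0.0, ambient_rate=0.0))
pairs, markers = derive_exclusive_pairs(ref.counts.toarray(), ref.gene_names,
                                        ref.type_labels)
ev = evaluate_against_truth(res, ds, pairs=pairs, markers=markers)
print(f"counts kept: {res.report['total_counts_adjusted']} / "
      f"{res.report['total_counts_raw']}")
print(f"sensitivity: {ev['sensitivity']:.3f}  specificity: {ev['specificity']:.3f}")
print(f"mean MECR:   {ev['mecr_before']:.3f} -> {ev['mecr_after']:.3f}")
print(f"mean PMP:    {ev['pmp_before']:.3f} -> {ev['pmp_after']:.3f}")
```

prints

```
counts kept: 366368 / 397814
sensitivity: 0.951  specificity: 0.963
mean MECR:   0.300 -> 0.012
mean PMP:    0.203 -> 0.219
```

92% of counts survive; 95% of truly endogenous entries are retained while
96% of purely contaminated entries are removed. Co-expression of mutually
exclusive marker pairs collapses from 0.30 to 0.01 (a 96% reduction of the
false-positive proxy) and marker purity rises — contamination is removed
without flattening real signal.

## Command line

```sh
istclean simulate --config sim.json --out data/
istclean run --counts data/counts.mtx --genes data/genes.tsv \
             --cell-ids data/ids.tsv --cells data/cells.tsv \
             --transcripts data/transcripts.csv --out results/
istclean markers derive --ref ref.mtx --genes genes.tsv --cell-ids ids.tsv \
             --labels labels.tsv --out derived/
istclean metrics mecr --counts results/adjusted.mtx --genes data/genes.tsv \
             --cell-ids data/ids.tsv --pairs derived/pairs.tsv --out mecr.tsv
```

Counts travel as Matrix Market with sibling gene/cell TSVs; transcript
tables use the Xenium CSV dialect (`x_location, y_location, feature_name`,
configurable). `run` writes `adjusted.mtx`, a per-cell fit table
(`fits.tsv`) and a JSON run report that echoes the configuration and seed;
every run is bit-reproducible from those.

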