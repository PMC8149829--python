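# regarch

Comparative regulatory genomics of closely related species: from
chromatin-state segmentations to gene regulatory architectures, their
evolutionary conservation, and the statistics that connect chromatin to
gene expression.

`regarch` is aimed at groups comparing ChIP-seq / ATAC-seq / RNA-seq
panels across a handful of species (e.g., human and nonhuman primate
lymphoblastoid cell lines, two biological replicates each).  It
implements the analysis layer that sits downstream of segmentation and
alignment:

- **Regulatory elements and epigenetic states.** 200-bp chromatin-state
  bins are merged into elements (dropping elongating, low-signal and
  repressed-heterochromatin states); each element is labeled strong /
  poised / weak promoter or enhancer (sP, pP, wP, sE, pE, wE) from a
  fixed state hierarchy, refined by linear discriminant analysis on the
  quantitative mark and accessibility signals, and reconciled across
  replicates (ambiguities: aP/aE, P/E, P-or-E/Non-RE).
- **Gene regulatory architectures.** Elements become genic promoters
  (gP, ≤ 5 kb upstream of a TSS), intragenic enhancers (gE), proximal
  enhancers (prE, ≤ 10 kb), and — through Hi-C-style interaction pairs —
  promoter-interacting (PiE) and enhancer-interacting (EiE) enhancers.
- **Conservation.** Per-state species-conservation counts over
  orthologous regions, repurposing/gain event classes, column-permutation
  randomization tests, and TAD-background-normalized phastCons-style
  Z-scores (200-bp bins overlapping 50 bp, per-region maximum) with
  permutation-based Spearman tests.
- **Networks and expression.** The gene × 51-variable design matrix
  (expression + 5 marks × 2 state classes × 5 components), eigencomponent
  summaries (first PC per block, sign-aligned with H3K27ac), sparse
  partial correlations with per-species replication and cross-validated
  reciprocal LASSO filtering, and a 15-variable GLM of expression on
  H3K27ac/H3K27me3/H3K36me3 at gP and gE with their cross-products.
- **Tissue specificity.** The tau index,
  τ = Σᵢ (1 − xᵢ)/(N − 1) with xᵢ normalized by the profile maximum
  (0 = housekeeping, 1 = single-tissue), with the two-step low-expression
  filter and Friedman + Wilcoxon–Nemenyi–McDonald–Thompson comparisons.
- **Human-fixed nucleotide changes (hSNCs).** Calling fixed differences
  from a multi-species diversity panel (coverage and 90%-monomorphy
  filters, biallelic only), per-enhancer density enrichment by
  length-corrected randomization with Bonferroni adjustment, a global
  hits-count test, Fisher overlap statistics and a W→S (gBGC) check.

Every input format is plain text (BED, GTF-like, BEDPE, bedGraph, TSV)
bundled behind a YAML manifest, and a first-class synthetic-data
generator (`regarch.synthetic`) emulates the complete input set with
known ground truth, so the whole pipeline is testable end to end without
any external data.

## Worked example

```python
import pandas as pd
from regarch import (SimulationConfig, simulate_epigenome, annotate_bundle,
                     architecture_table, design_matrix_from_bundle,
                     expression_glm, compute_tau)

cfg = SimulationConfig(n_genes=50, n_elements=300, seed=42)
bundle, truth = simulate_epigenome(cfg)

annotated = annotate_bundle(bundle)           # per-species consensus states
arch = architecture_table(bundle, annotated)  # gP/gE/prE/PiE/EiE/orphan
matrix = design_matrix_from_bundle(bundle, architectures=arch)
fit = expression_glm(matrix)                  # core 15-variable model
print(f"expression GLM (core15) variance explained: {fit.variance_explained:.3f}")
print(f"tau(10, 5, 0) = {compute_tau(pd.Series([10.0, 5.0, 0.0])).tau:.2f}")
```

Output:

```
expression GLM (core15) variance explained: 0.864
tau(10, 5, 0) = 0.75
```

The simulated panel covers 5 species × 2 replicates; the annotation step
labels 1267 species-elements (from sE 356 down to wP 57 at these
defaults), the architecture step assigns all six component roles, and
the design matrix has one row per (gene, species, replicate) case and 51
variables.  The GLM's variance explained is high because the generator's
expression really is driven by promoter/intragenic-enhancer chromatin —
the number to read is the match between fitted and generative
coefficients, which the test suite checks exactly in the noiseless limit.

A CLI mirrors the library (`regarch simulate`, `validate`, `annotate`,
`architecture`, `conserve`, `network`, `depattern`, `tau`, `hsnc`); run
`regarch --help`.

## Layout

```
src/regarch/
  io_core.py        manifest + readers/writers for all table formats
  synthetic.py      ground-truth dataset generator
  states.py         element definition, state hierarchy, LDA, consensus
  architecture.py   component assignment and gene architectures
  conservation.py   conservation counts, randomization, TAD Z-scores
  networks.py       design matrix, eigencomponents, SPC networks, GLM
  expression_evolution.py  DE pattern labels, complexity association
  tissue.py         tau, expression filters, cross-tissue tests
  hsnc.py           fixed-difference calling and enrichment tests
  pipeline.py       end-to-end wrappers
  cli.py            click command group
```

See `docs/methods.md` for the statistical details and design decisions.
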