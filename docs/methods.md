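# Methods

This note documents the models and procedures implemented in `regarch`,
the parameters that matter, the synthetic-data generator's assumptions,
and the numerical choices made where the design was genuinely open.

## Regulatory elements and epigenetic states

Chromatin-state segmentations arrive as 200-bp bins labeled E1–E16 (a
ChromHMM-style 16-state model; learning the model itself is out of
scope).  Elements are maximal runs of consecutive bins after excluding
elongating (E1, E2), low-signal (E15) and repressed-heterochromatin
(E16) states; species elements are the interval union of the replicate
elements, with an option to drop elements supported only by a named
anomalous replicate.

The chromatin-state label follows a fixed hierarchy.  Promoter states
are those containing E8, E9 or E11; among promoters, E14 marks poised
(pP), otherwise E9/E11 mark strong (sP) and the rest are weak (wP).
Non-promoter elements are enhancers: E14 poised (pE), any of
E3/E4/E5/E6/E12 strong (sE), remainder weak (wE).  The label is a total,
permutation-invariant function of the state set (tested exhaustively
over all 2¹² − 1 subsets of informative states).

**LDA refinement.** Qualitative state calls blur exactly where the
promoter/enhancer distinction rests on the quantitative
H3K4me3/H3K4me1 balance, so the six-class label is refined by linear
discriminant analysis on the six signals (5 marks + accessibility),
each background-normalized as log2((IP + c)/(input + c)) with
pseudocount c = 1 (the pseudocount stabilizes zeros; the exact upstream
normalization is a deliberate stand-in, as enrichment pipelines differ).
The refined label is the posterior argmax.  Numerical choices: empirical
class priors; classes need ≥ 7 members (more observations than
predictors); a singular within-class scatter switches the solver to a
lightly regularized eigendecomposition (shrinkage 1e-6) instead of
aborting; exact posterior ties break poised > strong > weak, mirroring
the gene-level state precedence.  Refinement is pooled across samples
and species by default (per-sample available), and is restricted to the
six core labels — ambiguity classes arise only at consensus time.

**Replicate consensus.** Identical replicate labels pass through;
same-class different-activity pairs become aP/aE; opposite classes P/E;
single-replicate detections P/Non-RE or E/Non-RE.  Downstream analyses
consume only the six unambiguous core labels.

## Gene regulatory architectures

Per gene, strand-aware and edge-to-TSS: elements up to 5 kb upstream of
the TSS are genic promoters (gP), elements overlapping the gene body are
intragenic enhancers (gE), further elements up to 10 kb upstream are
proximal enhancers (prE).  Precedence gP > gE > prE applies per gene;
an element may hold different roles for different genes.  The 10-kb prE
window is read as upstream-only for consistency with the gP wording
(symmetric windows behind a flag); distances are edge-to-TSS rather than
midpoint (both interpretations were open; edge-to-TSS is the BED-native
choice).

Remaining distal elements (dE) are rescued through interaction pairs
(BEDPE anchors, half-open): a dE on an anchor whose partner overlaps a
gP becomes a promoter-interacting enhancer (PiE) of that gene; one whose
partner overlaps an enhancer component (gE, prE or a just-made PiE)
becomes enhancer-interacting (EiE).  Rescue never relabels proximity
components; by default only dE are eligible (a flag additionally lets
already-assigned enhancers *gain* PiE/EiE roles for other genes).
Unrescued dE are orphans.  Architectures group the component-labeled
elements per gene; a gene with at least one element of every type is
flagged full-architecture.

## Conservation

For each one-to-one orthologous region the per-state conservation count
is the number of species (1..5) sharing the state, either at class level
(promoter vs enhancer, ambiguous activities collapsed) or at activity
level (exact labels; regions with ambiguous labels are excluded).
Event classes: repurposed (one species promoter, the rest enhancers, or
vice versa), gained/novel (one species regulatory, the rest not),
fully conserved, species-specific, other.

The randomization test permutes each species' state column independently
across regions (1000 randomizations by default) and reports
p = (#randomizations with mean conservation ≥ observed)/n — the plain
r/n convention, reported as "< 1/n" when r = 0, rather than
(r+1)/(n+1); the package favors the simple counting definition and
flags its resolution limit.  Calibration holds in the
effectively-continuous regime (hundreds of regions); with few regions
ties make the test mildly conservative, which the test suite documents.

Sequence conservation: per-bp Z-scores against the mean and SD of the
containing TAD (regions straddling a boundary are assigned by midpoint;
a zero-SD TAD is an error), averaged in 200-bp bins overlapping 50 bp
with the next (stride 150; the alternative stride-50 reading is a flag),
final partial bin kept by default; the region score is the maximum bin
mean.  The score is invariant to affine rescaling of the track.
Epigenetic–sequence association uses Spearman rho between Z-scores and
conservation counts with a Z-permutation p-value per state.

## Design matrix, eigencomponents and networks

One row per (gene, species, replicate) case; 51 columns = expression
plus the summed signal of 5 marks × {promoter-state, enhancer-state} ×
5 components.  Summation over all elements of a (component, state-class)
per gene reflects the observed additivity of strong elements; missing
components contribute zeros.  At the reference scale of 5737 genes this
is 57,370 cases — the closed-form shape is asserted in tests.

Each block of 5 mark columns is summarized by its first principal
component on standardized columns ("eigencomponent", the WGCNA eigengene
idea applied to components), sign-aligned so its correlation with the
block's H3K27ac column is nonnegative; all-zero blocks yield flagged
degenerate eigencomponents.

**Sparse partial correlations.** Per species, the partial-correlation
matrix is derived from the inverse of a Ledoit–Wolf-shrunk correlation
matrix (deterministic, well-conditioned); edges are tested with the
t-approximation for partial correlations and BH-adjusted.  An edge is a
candidate when significant in ≥ 4 of 5 species; candidates survive only
if the reciprocal LASSO models of both endpoint variables generalize
across species — each variable is regressed on all others with
LassoCV (penalty chosen by inner 3-fold CV on the training species) in a
leave-one-species-out loop, and its mean held-out R² must exceed 0.
"Does not overfit" therefore means *positive out-of-species predictive
power*, the simplest threshold consistent with the cross-validation
intent.  The residual network regresses each mark column on its block's
eigencomponent and re-runs the procedure on residuals plus expression
(degenerate eigencomponents pass their block through unresidualized).

**Expression GLM.** The core model uses H3K27ac, H3K27me3 and H3K36me3
at gP (promoter state) and gE (enhancer state): 6 main effects + 9
gP×gE cross-products = 15 predictors — the only reading that yields
exactly 15; the 21-variable all-pairwise alternative is exposed via
flag.  The naive reference model uses all 50 signal columns without
interactions (the 1225-variable all-interactions variant is also
available but asserted nowhere).  Fits are ordinary least squares on
continuous signals; rank-deficient designs raise an error naming the
most collinear column pair.

## Differential-expression patterns and complexity

Pairwise Q-values are inputs (the upstream count-model fit is out of
scope; the generator emits them).  A gene is not-DE when no pair passes
the FDR (0.1); species-specific when the significant pairs are exactly
the pairs involving one species (direction from that species' mean vs
the rest); anything else — including inconsistent topologies — is
non-species-specific, with direction read off the most DE-involved
species group.  The loose published description of label assignment from
ordered Q-values is resolved this way and documented as an
interpretation; equal Q-values break ties by species order for
determinism.

The complexity association pairs, per gene and species, the deviation of
a (component, state) element count from its cross-species mean with the
matching expression deviation (the simplest paired design; the original
pairing is not printed), and applies a one-sided Wilcoxon signed-rank
test — greater expression for strong and weak states, lower for poised —
BH-corrected across the 30 (component, state) tests; under 10
informative pairs the result is flagged underpowered.

## Tissue specificity

τ = Σᵢ (1 − xᵢ)/(N − 1), xᵢ = expression normalized by the profile
maximum; τ(constant) = 0, τ(one-hot) = 1, τ(10,5,0) = 0.75; invariant
to positive rescaling and monotone under concentration (property
tested).  The two-step filter zeroes entries below 0.1 TPM and drops
genes whose row sum stays below 0.1·N — the entry-wise reading of the
threshold, the only one that keeps the second filter non-redundant (a
per-gene variant is flagged).  The optional pre-normalization offers
per-tissue rank-quantile scaling or log10(x+1); the referenced tau
package's internals are unpublished, so both are labeled
interpretations.  Cross-tissue comparisons: Friedman test (computed as
the exact two-sided sign test when N = 2, where the chi-square
approximation is invalid and the two tests coincide), a
Wilcoxon–Nemenyi–McDonald–Thompson post-hoc via the studentized-range
distribution on rank sums, and matched-pairs rank-biserial effect sizes.

## hSNCs and enrichment

A site's species call needs coverage-passing data for at least half of
its individuals, and ≥ 90% of kept individuals sharing one allele
(otherwise polymorphic).  Indels and triallelic sites are removed.  An
hSNC is a biallelic site where the human majority allele differs from
the single allele shared by every other species.  The caller is verified
against a brute-force re-evaluation on exhaustively enumerated toy
panels.

Per-enhancer enrichment: the observed number of changes in the enhancer
universe is re-placed uniformly over the concatenated universe (a
multinomial draw — sampling with replacement; collisions are negligible
at realistic densities and match the Poisson-style null), 10,000 times
by default; each enhancer's p is the fraction of simulations at or above
its observed density (length-corrected by construction), Bonferroni-
adjusted.  The hits-count test sets each enhancer's critical density at
the upper-tail quantile of its simulated densities at level
alpha/n_tests (5th largest at 5%/100 tests/10,000 simulations) and
compares the observed number of enhancers at or above criticals with the
per-simulation hit counts.  The published worked description counts
"from smallest to largest", a lower-tail reading inconsistent with an
enrichment test; the upper tail is the default and the literal reading
sits behind `tail="lower"`.  Gene-set overlaps use Fisher's exact test
(sample odds ratio, inf-flagged on zero cells); the gBGC check
classifies each change W(A/T)→S(G/C) vs other from the outgroup
(ancestral) to the human (derived) allele and one-tails the focal vs
background composition; the background defaults to hSNCs in conserved
weak intragenic enhancers and is configurable, as no canonical
background is established.

## Synthetic data: what it emulates, and what it does not

The generator lays out per-gene 60-kb cassettes on one toy chromosome,
each with one element per component (gP 2.6 kb upstream, prE 7.2 kb,
gE intragenic, two interaction-wired distal elements, one orphan), plus
optional extra intergenic orphans.  Reference-species states are drawn
promoter-like at gP positions and enhancer-like elsewhere; other species
keep the state with a per-state conservation probability (defaults fall
from 0.90 for sP to 0.45 for wE, mirroring the strong-to-weak
conservation gradient) and otherwise flip to non-regulatory (50%) or a
random other state — the independent-flip structure is the simplest that
exercises counts 1–5, repurposing and gains.  Signals are
element-level draws around state-conditional means (promoters high
H3K4me3, enhancers high H3K4me1, strong states rich in H3K27ac and
accessibility, poised in H3K27me3; SD 0.5, separations ≥ 3 SD);
replicates are two draws (SD 0.25) around a shared element effect.
Expression comes from the core15 GLM applied to the same sums the design
matrix computes, plus Gaussian noise (SD 1 by default) — so the noiseless
limit is exactly identifiable and recovery tests are sharp.  Tissue
profiles mix flat housekeeping genes with one-hot tissue-specific genes;
conservation tracks add element-conservation-dependent elevation to TAD
backgrounds; the variant panel plants fixed differences at configured
per-bp rates with low-coverage, 89.5%-polymorphic and triallelic decoys
the caller must reject.

Not emulated: read-level noise, linkage and phylogenetic correlation
between species (flips are independent), methylation, inter-chromosomal
structure, realistic interaction maps, and assembly artifacts.  Passing
tests therefore demonstrate correctness of the implemented rules and
estimators under their stated models — not robustness to the full
messiness of real panels.

## Problem sizes in the test and acceptance runs

Unit and property tests run at dozens-to-hundreds of genes; calibration
suites use ≥ 100 null fixtures at reduced randomization counts (60–100)
with fixture sizes chosen so the discrete permutation statistics are
effectively continuous; recovery tests use the sizes at which their
guarantees are stated (10-variable/10,000-case graphical model;
1,200–2,400 simulated elements).  The acceptance script runs the
design-matrix structure check at the full 5737-gene scale and the hSNC
randomization at the full 10,000 simulations.

## Known limitations

- The per-species edge-replication rule ("recovered in ≥ 4 of 5
  species") estimates networks independently per species and intersects
  significance; pooled estimation with species as a blocking factor is a
  possible alternative the package does not implement.
- Empirical p-values use r/n and cannot go below 1/n; results at the
  resolution limit are flagged rather than extrapolated.
- The architecture builder assumes one TSS per gene (the annotation's
  TSS column); alternative promoters are not modeled.
- LDA refinement assumes shared within-class covariance; strongly
  heteroscedastic signal classes would argue for its quadratic variant.
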