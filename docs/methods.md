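# Methods

## Model and procedure

The pipeline treats tissue-level gene expression as a binary character on a
rooted species tree. An expression matrix in TPM is collapsed to one value
per species and thresholded (expressed at TPM ≥ 2.0, an inclusive boundary;
below → not expressed; no data → missing `?`). Each gene's character is then
analyzed by unit-cost, unordered parsimony: the reconstruction seeks the
minimum number of 0 ↔ 1 changes explaining the tip states, with `?` tips
free to take either state at no cost.

### Parsimony dynamic program

The implementation is a Sankoff-style dynamic program rather than set-based
Fitch, because the downstream classification needs *constrained* minima that
Fitch state sets do not directly provide. Two passes are computed per
character:

* inside (postorder): `in(v, s)` = minimal changes within v's subtree given
  v = s;
* outside (preorder): `out(v, s)` = minimal changes in the rest of the tree
  given v = s, with v's subtree excluded (computed by subtracting the
  child's message from its parent's inside cost, so polytomies need no
  special casing).

Then `in + out` is the whole-tree cost with a node pinned, the parsimony
score is its minimum at any node, the MPR state set of a node is the set of
states whose pinned cost equals the score, and the possible (parent, child)
state pairs of an edge are those whose jointly pinned cost
`out(u, s) + excl(u→v, s) + [s ≠ t] + in(v, t)` equals the score. A change
s → t on an edge is *possible* if its pair is realized by some MPR and
*unambiguous* if it is the only realized pair. This existential joint-edge
definition (rather than pairing node-marginal MPR sets) is used because node
marginals can combine states no single reconstruction realizes; the two
views provably coincide for the unambiguous case, and the test suite asserts
that equivalence. Ambiguity is never resolved — no ACCTRAN/DELTRAN — since
the three-way ambiguous / most-parsimonious / unambiguous classification is
the point of the analysis.

All per-node tables are arrays over genes, so a genome-scale matrix
(e.g. 21,750 characters × 27 taxa) reconstructs in well under a second.

### Focal-branch classification

The focal branch is specified as the stem of a named taxon set (the edge
subtending their MRCA); naming a set whose MRCA is the root is an error.
Per gene: `unambiguous_gain` when (0, 1) is the only possible pair on that
edge; `most_parsimonious_gain` when (0, 1) is possible but not exclusive
(so unambiguous ⊂ most-parsimonious, and summary counts report the union as
the most-parsimonious count); losses symmetric; `uninformative` when all
observed tips agree or all are missing; `no_change` otherwise. In the rare
case that distinct MPRs place a gain and a loss on the same edge, gains are
checked first — a documented tie-break. Per-edge change totals over all
genes are exported and can annotate a Newick tree as branch lengths
(unambiguous totals by default; most-parsimonious totals optionally),
mirroring trees drawn with branch lengths proportional to inferred
expression changes.

## Encoding choices

* Boundary inclusivity: a value exactly at the threshold is expressed.
* Replicate collapse defaults to the mean of TPM across a species' samples
  before thresholding; median is provided, as is a majority rule that
  thresholds per sample first and takes the majority call (ties round up to
  expressed, mirroring the inclusive boundary). Combining abundances first
  and thresholding once is the default order; the per-sample-first order is
  exactly what the majority rule exposes. The two orders can disagree —
  e.g. replicates (1, 1, 4) are expressed under the mean (2.0) but not the
  median (1.0) — which is why both are surfaced.
* A gene with no data in a species is `?`, not 0: absence of evidence is
  treated as missing, not as silence.

## Over-representation analysis

Hypergeometric upper tail computed via the survival function in log space;
k = 0 returns exactly 1. Term sizes K are counted after intersecting each
set with the caller's background universe (custom-background ORA
convention), queries are intersected with the background (the number
dropped is reported), and BH FDR is computed per collection, never pooled
across collections. By default every set with K > 0 is reported
(`min_set_size = 1`, `min_overlap = 0`); both filters are parameters for
callers who want web-tool-style minimum set sizes. Identifier matching is
exact and case-sensitive.

## Effect-size estimation

Mean difference Δ = mean(test) − mean(control). The BCa interval resamples
each group independently (B = 5000 default), takes the bias term z₀ from
the fraction of bootstrap deltas strictly below Δ (clamped to 1/(2B) at the
boundaries, with a warning), and the acceleration from a leave-one-out
jackknife over all observations, each removed within its own group. A
degenerate bootstrap distribution yields the point interval [Δ, Δ] with a
warning. The permutation test reshuffles group labels (P = 5000 default, or
exhaustively when the number of distinct splits is ≤ 20,000) and reports
the plain proportion of |Δ*| ≥ |Δ| — matching the reporting convention in
which perfect separation prints p = 0.00 — together with the add-one
estimate (count + 1)/(P + 1). Bootstrap and permutation streams are spawned
independently from one seed; identical seeds give identical results.

Calibration, measured by the package's own simulations: permutation p is
uniform under the null (rejection at 0.05 ≈ 5%), and BCa coverage for a
shift of normal data at n = 12 per group is ≈ 92% at the 95% nominal level
— the familiar small-sample narrowness of bootstrap intervals (an
independent BCa implementation gives the same number). Coverage figures
quoted here are recomputed by the test suite and the acceptance script, not
assumed.

## Synthetic data: what it emulates and what it does not

Characters evolve by independent per-edge Bernoulli flips (defaults: gain =
loss = 0.05 per edge, root expressed with probability 0.5, no missing data
unless asked), a flip-probability model chosen because the analysis tree
has no meaningful time-calibrated branch lengths. Missing-data masking is
independent per cell. A forced-single-gain mode plants exactly one 0 → 1
change on a chosen edge for recovery tests. Expression tables draw Gaussian
TPM (truncated at 0) around well-separated expressed/silent means (10 vs
0.1, sd 0.5, 3 replicates) so encoding recovers the source states ≥ 99% of
the time; assay tables are Gaussian on the log scale (n = 12 per group,
sd 0.1, raw scale = 10^log). Real data differ in ways the generator does not
model: phylogenetically correlated missingness (whole species lacking
annotation), abundance-dependent noise near the threshold, correlated
evolution among genes, and non-normal assay noise. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not robustness to those real-data pathologies.

The 27-leaf amniote topology shipped as a fixture is a transcription of the
study system's taxon sampling with standard vertebrate relationships; it is
a labelled test fixture for realistic-shape simulations, not a phylogenetic
claim.

## Numerical and degenerate-input choices

* Costs are small integers held in float64 with a large finite sentinel for
  impossible leaf states; equality against the score is exact.
* An all-`?` character has score 0, every MPR set {0, 1}, and is classified
  uninformative.
* Unary nodes are collapsed at tree load with a warning; trees are used as
  rooted exactly as written, never rerooted.
* Ties in ORA sorting are broken by term name for deterministic output.
* Problem sizes in the test and acceptance runs — 10,000 fuzzed
  tree/character cases against the enumeration oracle, 1000-character
  recovery runs, one 21,750 × 27 study-scale run, 1000–10,000-replicate
  Monte-Carlo calibrations — were chosen to keep the whole suite under a
  minute while leaving Monte-Carlo error well below the tolerances asserted.

## Known limitations

* Only binary (plus missing) characters are surfaced; the DP generalizes to
  k states but no multistate interface exists.
* No likelihood or Bayesian reconstruction; no asymmetric gain/loss costs —
  a gene family where losses are cheaper than gains would need a weighted
  step matrix the v1 interface does not expose.
* ORA assumes exact identifier matching; no alias resolution is applied by
  default.
* Effect sizes cover independent two-group designs only (no pairing,
  no standardized effect sizes).
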