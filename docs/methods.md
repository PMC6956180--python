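# Methods

This note documents the models, algorithms, and design choices behind
`pathreverse`, in the spirit of the methods documentation of statistical
packages: what is computed, under which assumptions, with which defaults,
and what the synthetic validation does and does not demonstrate.

## Pre-ranked enrichment score

Input is a ranked signature: genes sorted by a per-gene statistic
(descending), with ties broken by input row order (stable sort), so
re-reading the same file reproduces the same ranking. The running-sum
score with exponent `weight` on `|stat|` follows the weighted-statistic
form of preranked GSEA; `weight = 0` recovers the classic
Kolmogorov–Smirnov form. The default is `weight = 1`.

Implementation detail: the walk only attains candidate extrema adjacent to
hit positions (it decays linearly between hits and ends at zero), so the
score is computed from the hit positions alone, vectorised across
permutations. This is algebraically identical to walking all N positions.
The implementation agrees with `fgsea::calcGseaStat` to at least 1e-9 on
random inputs (cross-checked in the test suite) and with an exact
rational-arithmetic walk to 1e-12.

Conventions for degenerate cases:

* A magnitude tie between the positive and negative extreme resolves to
  the positive deviation. Such ties are not rare — the walk is piecewise
  rational — so the comparison uses a 1e-12 relative tolerance to make the
  convention robust to float summation order.
* A set whose members all carry zero statistic has no signal mass; its ES
  is defined as 0 with an empty leading edge (this makes an all-zero drug
  signature produce no calls rather than an error).
* A set equal to the whole ranked universe has an undefined miss increment
  and is rejected.

The leading edge is the in-set genes from the top of the list to the
walk's peak (ES > 0) or from the trough to the end (ES < 0).

## Permutation null and p-values

The null for one pathway is formed by `nperm` gene sets of the same
intersected size drawn uniformly without replacement from the ranked
universe. "Same or more extreme" is evaluated one-sided in the sign of the
observed ES: null draws of the opposite sign do not count. An
absolute-value mode (`absolute=True`) is available because the alternative
reading — magnitude comparison regardless of sign — is also defensible;
the signed mode is the default as it preserves the up/down interpretation
of the ES.

The default estimator is the add-one-smoothed ratio
`p = (b + 1)/(nperm + 1)`, which can never return zero (zero p-values
would break BH adjustment); `smoothed=False` selects the plain ratio
`b/nperm`, floored at `1/nperm`.

A consequence of dividing by the *total* permutation count while counting
only same-sign draws is that null p-values are approximately uniform on
(0, q) where q ≈ the probability of the observed sign (~0.5), i.e. the
test is anti-conservative by about a factor of two at small α. This is a
property of the published estimator, retained deliberately; the test suite
verifies the factor-of-two calibration explicitly, and the null-calibration
acceptance check shows that BH across 50 pathways still keeps the realised
fraction of significant calls far below 0.07 under a global null.

Reproducibility: each pathway draws from an RNG stream derived from
`(seed, crc32(pathway name))`, so results are independent of collection
order and stable across platforms.

Defaults: `min_size = 15`, `max_size = 500` (intersected sizes);
`nperm = 10,000` for disease datasets and `1000` for drug panels (the drug
side is hundreds of times larger, and with FDR ≤ 0.05 over ~dozens of
pathways, 1000 draws resolve the relevant p-value range). BH is applied
over exactly the retained pathways. The FDR threshold is inclusive
(padj ≤ 0.05).

## Collapsing redundant pathways

Gene set collections are redundant; several significant pathways can carry
one shared signal. The collapsing procedure is greedy: order significant
pathways by raw p (ties by name); promote the best to "main"; re-test each
remaining candidate on the ranked list with the main pathway's genes
removed from both the universe and the candidate set; candidates whose
conditional permutation p exceeds `dependence_p = 0.05` become children of
that main pathway; repeat. A candidate left with fewer than two genes
after removal is absorbed outright. The conditional test reuses the same
permutation machinery with a derived seed. This concrete definition of the
conditional test is this package's own; other implementations differ in
the details of the conditioning.

## Amplitude

`a = (t − c)/((t + c)/2)` on thresholded (non-negative) average-difference
expression values. The degenerate case `t = c = 0` returns 0 rather than
raising: no differential expression is the correct reading, and the
operation stays total on its domain (with non-negative inputs, `t + c = 0`
with `t ≠ c` cannot occur). Probe-level tables are collapsed to gene
symbols by keeping the row with the largest `|stat|` — the same rule used
for duplicate symbols in DE tables — because it preserves the strongest
signal; this collapse rule is a repository decision, as sources differ.

## Cell-type marker enrichment

Direction lists use strict nominal `p < 0.05` and a nonzero fold change
(direction from the fold-change sign). The test is the upper-tail
hypergeometric `P(X ≥ overlap)` with the population equal to all genes in
the DE table — the measured background — rather than the union of marker
lists; this is standard for expression-based enrichment but it is a
parameter of the analysis, not a universal convention. The Bonferroni
family is all (marker list × direction) tests within one dataset, matching
a per-dataset presentation; significance requires corrected `p < 0.05`
(strict). When a cell type has several source lists, a best-p summary per
cell type is also provided.

## Signature filters and reversal matching

Drug signatures are filtered on a reproducibility score (the L1000
`distil_cc_q75` statistic) with an inclusive threshold of 0.15; records
without a score are dropped and counted. A repurposeability flag (marketed
/ in trials / preclinical with good ADME) can additionally be required.

A signature's direction profile is its set of significant pathway calls
(FDR ≤ 0.05, direction = sign of ES). A reversal query is matched by full
conjunction: every queried pathway must be called in exactly the desired
direction. Compounds qualify when **any** of their signatures matches;
each signature is analysed separately (cell line, dose and time all
modulate drug response), and the per-compound match frequency is reported
so users can impose a stricter majority rule themselves. Candidate
filtering by clinical phase and by user-supplied annotations (e.g. CNS
penetrance) happens after roll-up; such annotations are inputs, not
computed.

## Synthetic data

The generator emulates the *shape* of the real inputs, not their biology:

* **Pathways**: uniquely named sets over a synthetic symbol universe
  (`G000001…`). Defaults: 5000 genes, 50 pathways of 20–100 genes,
  disjoint. With `overlap_fraction` f > 0 each set draws ≈ f of its
  members from one shared pool sized to the largest shared draw, giving
  pairwise overlaps of roughly f of a set's size (an approximation).
* **Disease signatures**: per-gene statistic = Normal(0, `noise_sd`) plus
  the planted shift (±`effect_size` for members of planted pathways,
  additive when pathways overlap). Two-sided normal-tail p-values are
  computed on the statistic standardised by `noise_sd`, so null p-values
  are uniform whatever the noise scale; log2 fold change is proportional
  to the statistic, so signs agree. Defaults mirror a unit-variance
  moderated-t regime with effect sizes of 2 (twice the noise scale) for
  planted pathways.
* **Drug panels**: genes × signatures z-score matrices, Normal(0,
  `noise_sd`) noise, with every signature of a planted reverser compound
  shifted by `reverser_effect_size` (default 2) in the query direction on
  the queried pathways' members. Metadata cycles realistic cell lines,
  doses, times, and clinical phases; quality scores are uniform on
  `quality_range` (default (0.2, 0.95), i.e. above the 0.15 filter so the
  planted panel survives filtering — tests of the filter itself use ranges
  straddling the threshold).
* **Markers**: one designated cell type draws 80% of its markers from
  genes with positive planted shift; all others sample uniformly.

What the synthetic validation shows: the statistics are computed
correctly, the FDR is controlled under the null, and planted effects of
realistic size are recovered through the full pipeline with the correct
sign and without false compound calls. What it does not show: robustness
to the correlation structure of real expression data (genes within real
pathways are co-expressed; the generator draws independent noise), to
microarray/RNA-seq platform artefacts, to the 978-landmark imputation
structure of L1000, or to annotation noise in real gene set collections.

## Problem sizes and numerical choices

The acceptance checks run at desk scale, chosen to keep the statistical
claims sharp while remaining laptop-friendly: null calibration uses 100
replicate signatures at the default 5000 genes / 50 pathways with
`nperm = 1000`; planted-pathway recovery uses 20 replicates at the same
scale; reversal recovery uses 10 replicates of a 100-compound × 3-signature
panel over 2000 genes and 20 pathways with `nperm = 100` (a planted shift
of twice the noise scale saturates the permutation null, so 100 draws
suffice to resolve p well below the BH threshold for a 5-pathway query).
Permutation subsets are sampled per permutation via partial Fisher–Yates
(`Generator.choice` without replacement), which profiled an order of
magnitude faster than key-sorting a full random matrix at these sizes.

All randomness flows from explicit integer seeds through named
`SeedSequence` substreams (per generator call, per dataset, per pathway),
making every output bit-reproducible from its manifest.

## Known limitations

* The collapsing step's conditional test is a concrete choice among
  several defensible ones; collapsed/main assignments near
  `dependence_p` are sensitive to `nperm`.
* The permutation p-value's factor-of-two anti-conservatism (above) is
  inherited from the published estimator; users wanting exact one-sided
  calibration should halve α or use the absolute mode.
* Binary GCT/GCTX containers are not read; convert to the TSV matrix +
  metadata contract first.
* Pathway name matching is exact; no fuzzy KEGG-identifier mapping is
  attempted.
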