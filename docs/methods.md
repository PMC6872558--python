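# Methods

## Problem setting

A DNA-barcode evaluation asks, for each candidate marker, three questions:
how variable is it (sequence characteristics), does between-species
divergence dominate within-species divergence (divergence statistics and the
barcoding gap), and does a tree built from it recover species as clades
(monophyly with bootstrap support)? The package implements that full
workflow on aligned FASTA input and provides a simulator so every stage can
be validated against known truth.

## Sequence characteristics

Columns are classified as follows: a column with at least one gap or IUPAC
ambiguity code is `gap_containing` (or `all_missing` when no unambiguous
base remains); among fully unambiguous columns, a column is `conserved` when
a single state occurs and `variable` otherwise; a variable column is
parsimony-informative when at least two states each occur in at least two
sequences. The aberration rate is `100 · variable / alignment_length` — the
denominator keeps all columns. This combination (gap columns excluded from
the conserved/variable split but retained in the aberration denominator) is
the only reading under which the customary marker-description table is
internally consistent: conserved + variable equals alignment length exactly
for gap-free markers and falls short of it by exactly the gap-containing
columns otherwise, while the printed aberration rates still equal
variable/length. Whether published informative-site counts treat gaps as a
fifth character state is generally unstated; here gap-containing columns are
never informative, and that choice is documented rather than tuned.

GC content is computed per sequence over unambiguous bases only and reported
as a min–max range across samples. Mean pairwise similarity is the average
over sample pairs of percent identity on pairwise-comparable (both
unambiguous) columns; pairs with no comparable columns are skipped with a
warning.

## K2P distances

For a sequence pair, `P` and `Q` are the transition (A↔G, C↔T) and
transversion proportions over comparable columns, and
`d = -½ ln[(1-2P-Q)√(1-2Q)]`. Deletion is pairwise by default — each pair
keeps every column where both sequences carry an unambiguous base — because
barcoding-gap analysis needs per-pair information that complete deletion
destroys; `deletion="complete"` is available for parity with distance
software whose default drops any column containing a gap. Ambiguity codes
are treated as missing, never partially matched. Saturated pairs (log
argument ≤ 0) are flagged NaN and excluded from downstream summaries with a
logged count; they are never clamped to a large constant, which would
manufacture fake distances in gap histograms.

## Divergence statistics

Three interspecific summaries — the mean over heterospecific pairs, θ′
(per-species mean distance to all heterospecific individuals, averaged over
species), and the per-species minimum heterospecific distance averaged over
species — and three intraspecific ones — the mean over conspecific pairs, θ
(per-species mean conspecific distance), and coalescent depth (per-species
maximum conspecific distance), the latter two averaged over species with at
least two samples. θ′ is defined per-species-then-averaged by default; both readings circulate,
so `divergence_summary(..., theta_prime="per_species_pair")` (CLI
`--theta-prime per_species_pair`) switches to the per-species-pair mean. Dispersion is reported as both SD and SE because published
"±" columns rarely say which they are; comparisons in this package use means
only. Note that the average of per-species minima (minimum interspecific
distance) can legitimately exceed the pair-weighted grand mean under uneven
sampling — it is not an error.

## Wilcoxon signed-rank comparison

Markers are compared on distances paired by sample pair: the intersection of
(sample_i, sample_j) keys across two markers' distance tables defines the
paired sample, which is the only pairing construction the data admit.
Zero differences are dropped and ties mid-ranked. For n ≤ 25 the two-sided
p-value is exact: the distribution of the positive-rank sum over all 2^n
sign assignments is accumulated by dynamic programming on doubled (integer)
ranks, which is arithmetically identical to full enumeration while staying
O(n · Σranks). Beyond 25, a normal approximation with tie correction
(−Σ(t³−t)/48 in the variance) and a 0.5 continuity correction is used, and
the method is recorded in the result. No multiple-testing correction is
applied across marker pairs; raw p-values are reported and the omission
logged, since the evaluation convention reports unadjusted tests.

## Barcoding gap

The gap criterion is the distribution-extrema rule: a gap exists iff the
minimum interspecific distance exceeds the maximum intraspecific distance,
with interval `[max_intra, min_inter]` reported in percent (100·d). The
overlap fraction — the share of interspecific distances at or below the
intraspecific maximum — quantifies failure; ties count as overlap. Relative,
per-lineage gap formulations are deliberately out of scope. Histograms on
shared percent-scale bins (default width 0.2%, configurable) are emitted for
the paired-distribution plots; detection itself uses raw extrema, not bins.
Distances stay in substitutions/site internally and convert to percent only
at reporting boundaries.

## Neighbor joining, bootstrap, monophyly

NJ follows Saitou–Nei: repeatedly join the pair minimising
`Q(i,j) = (m-2)d(i,j) - r_i - r_j`, assign branch lengths
`l_i = d/2 + (r_i - r_j)/(2(m-2))`, reduce the matrix, and close the final
three nodes with the three-point formulas. Determinism is guaranteed by
processing taxa in lexicographic label order and breaking Q ties (within
1e-10 relative tolerance) by the smallest label pair, where an internal
node's label is the smallest leaf label beneath it — so the tree is
invariant to input row order. Negative branch lengths are clamped to zero
with the deficit moved to the sibling edge and the node flagged.

Bootstrap support resamples alignment columns with replacement (seeded
generator), recomputes K2P + NJ, and counts each original-tree bipartition's
recurrence among successful replicates; replicates containing a saturated
pair are dropped and counted, with more than 10% drops escalated to an
error. Support attaches to the original tree's edges (Felsenstein style),
not to a consensus. A species is monophyletic iff some edge of the unrooted
tree bipartitions exactly its leaves; single-sample species are trivially
monophyletic and flagged. Trees are unrooted; outgroup re-rooting is a
reporting convenience only, since evaluation datasets often lack a
documented outgroup.

## Simulator

Sequences evolve down a Newick species tree (branch lengths in expected
substitutions/site) under the K80 process with transition/transversion rate
ratio κ, normalised to unit substitution rate (α = κ/(κ+2), β = 1/(κ+2));
transition probabilities use the closed spectral form, verified against the
matrix exponential in tests. Each marker scales all branches by its
`rate_multiplier`. Within a species, individuals radiate as a star from the
species ancestor, each on a private branch of
`intraspecific_scale × terminal branch / 2`, so the expected conspecific
distance is `intraspecific_scale × terminal branch` and the expected
heterospecific distance between individuals is the species-tree path plus
both private branches. Base composition enters through root frequencies
only; the K80 process is composition-neutral, so GC drifts toward 0.5 at
rates that are negligible over barcode-scale divergences but real — the
generator targets composition, it does not pin it. Indels are whole-column
gap events hitting a random subset of sequences: enough to exercise the
gap-column accounting rules without modelling indel evolution.

What the simulator does **not** reproduce: coalescent within-species
genealogies (the star model makes gaps sharper than real data),
recombination, rate heterogeneity across sites, realistic indel length
distributions, alignment error, or sequencing artefacts. Passing tests on
simulated data therefore validate the estimators and the pipeline logic, not
the behaviour of any particular real marker.

### Default study conditions

`reference_config` emulates a six-species congeneric study: a balanced
species tree of three cherry pairs (terminal branches 0.3, heterospecific
tip paths 0.6 within a pair and 1.0 across, in relative units), sampling
skewed toward one heavily collected species (20 + 2–3 each, 32 samples), and
five markers whose lengths (225–1560 columns), GC targets (27–65%), indel
loads, and rate multipliers follow the classic plant-barcode profiles, with
expected interspecific divergences spanning 0.001–0.029 substitutions/site
in the order ITS2 > ITS > psbA-trnH > matK > rbcL and within-species
divergence about one fifth of the between-species level
(`intraspecific_scale = 0.75`). These values were fixed once from the
published profile of such studies and are not adjusted per run.

### The planted-ranking experiment

Recovering the full five-marker divergence ranking from a single dataset
requires each marker to accrue enough substitutions that adjacent markers
are statistically distinguishable. With a marker's expected tree-wide
substitution count `n ≈ 2.4 · rate · length` (2.4 = total tree length in
relative units), adjacent rates must satisfy
`log(ratio) > 2.6 · √(1/n_i + 1/n_j)` for ~99% per-comparison reliability.
At realistic plastid-marker magnitudes (a few substitutions tree-wide) the
slowest two markers fail this by a wide margin — their realised ranking is
close to a coin flip, a genuine limitation of single-genus-scale marker
comparisons. `ranking_config` therefore spaces the planted rates to meet the
inequality (0.004 to 0.30 across the five markers) and is the configuration
under which ranking recovery is tested; the study-scale `reference_config`
is kept for everything else.

## Numerical choices and degenerate inputs

- Distances: NaN marks undefined (saturated or zero-overlap) entries;
  `DistanceMatrix` forbids negatives and asymmetry. `-0.0` distances are
  normalised to `0.0`.
- Wilcoxon: half-integer mid-ranks are doubled to integers before the DP;
  the two-sided tail uses a 1e-9 guard on the midpoint comparison.
- NJ requires a fully defined matrix and at least three taxa; callers must
  exclude or impute undefined pairs upstream (the error says so).
- Exact-vs-approximate signed-rank boundary: n = 25, checked both ways at
  the boundary in tests (agreement within 0.01).
- Gap detection with a tied extremum (`min_inter == max_intra`) is **no
  gap**, and the tied inter distances count as overlap.
- Problem sizes in the test-suite experiments (20 seeds, 1000-column
  two-species recovery runs, 5×50 classification oracles, 100 additive
  matrices of 4–12 taxa) were chosen as the smallest scales at which the
  Monte-Carlo tolerances (3 SE; ≥19/20) are meaningful.

## Known limitations

- The extrema gap rule is brittle under sampling: one aberrant conspecific
  pair destroys a gap that a quantile-based rule would retain. The overlap
  fraction is the more robust summary and both are reported.
- Bootstrap support uses the successful-replicate count as denominator;
  with heavy saturation (>10%) the run errors rather than reporting
  support from a biased subsample.
- Concatenation drops samples missing either marker (never pads), so
  combined-marker statistics describe the intersection cohort.
- The simulator's star model within species makes planted gaps optimistic;
  real intraspecific genealogies overlap more.
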