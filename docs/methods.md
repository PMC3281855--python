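# Methods

## Distance model

The Kimura 2-parameter (K2P) distance corrects observed divergence for
multiple hits while distinguishing transitions from transversions:
d = −½·ln[(1 − 2P − Q)·√(1 − 2Q)], with P and Q the transition and
transversion proportions over compared sites. It is the de facto standard
for barcode surveys because distances are mostly small, where the correction
is mild and stable. The uncorrected p-distance is provided as a baseline;
d_K2P ≥ d_p always (the correction is convex), and the package's property
tests assert this on random pairs.

**Pairwise deletion.** For each pair, only sites where both sequences carry
an unambiguous base (A/C/G/T) are compared; gaps and IUPAC ambiguity codes
are treated as missing at that site, never as match or mismatch. Complete
deletion would discard columns globally and is inappropriate for the
variable-length rRNA alignments; pairwise deletion matches the per-pair
semantics of a distance and is the package default throughout.

**Saturation.** When 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 the K2P logarithm is
undefined. The scalar function raises a dedicated `SaturationError`; the
matrix routine masks the cell, counts it (`DistanceMatrix.n_undefined`), and
downstream stages either exclude masked pairs (summaries, NND) or refuse to
run (NJ, which needs a complete matrix) with an instruction to exclude or
impute upstream. NaN never propagates silently.

**Reporting scale.** Distances are proportions internally and percentages
(2 decimals, round-half-even, applied only at reporting) in every TSV —
a mean of 0.18 in a summary row means 0.18%.

## Comparison classes and summary statistics

A specimen pair's class is the most specific taxonomic rank the two share:
within_species, within_genus (same genus, different species), within_family,
within_order, within_class. Classes are disjoint and exhaustive for pairs
sharing the top rank; a `cumulative` flag additionally folds each class's
pairs into every less specific class, an alternative convention some surveys
appear to use for the upper rows of their summary tables.

The "taxa" column counts taxa actually contributing comparisons at that
level: species with ≥ 2 specimens, genera with ≥ 2 species, families with
≥ 2 genera, and so on. Singleton species therefore appear in NND results
(their distances to other species exist) but not in intraspecific
statistics.

The SE column is the sample standard deviation of the class's pairwise
distances divided by √n_comparisons. Pairwise distances sharing a specimen
are not independent, so this SE understates the true sampling error; it is
kept because it is the convention of the summary tables this output mirrors,
and it is documented here as a caveat rather than replaced with a resampling
scheme.

Band edges for the congeneric band table are half-open — [0, 5), [5, 10),
[10, ∞) in percent — so a distance of exactly 5.00% falls in the middle
band; the edges are configurable. Threshold fractions use strict "below".
Boxplot statistics follow Tukey: quartiles by linear interpolation, whiskers
at the most extreme observations within 1.5×IQR of the quartiles, mild
outliers beyond that, extreme outliers beyond 3×IQR.

## Numt screening

Nuclear mitochondrial pseudogenes co-amplify with the target locus and,
being released from selection, accumulate frameshifts and stop codons. The
screen translates each sequence with the vertebrate mitochondrial code
(stops TAA, TAG, AGA, AGG; TGA = Trp) and flags: any in-frame stop, any gap
character internal to the aligned region, and any ungapped length not
congruent mod 3 with the dataset's modal length. The reading frame is
detected dataset-wide — the frame under which the most sequences translate
stop-free — so a frameshifted numt cannot select its own convenient frame.
A sequence passes only when all three indicators are clean. The screen is
in-silico only: numts of expected length without in-frame stops (which
exist) are invisible to it, a known limitation shared with
submission-pipeline checks.

## Neighbor joining

Classic NJ: iteratively join the pair minimizing
Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), assign branch lengths by
the standard rate-corrected formulas, reduce the matrix, finish with the
three-point solution. Two determinism choices: Q-ties (within 1e−12) are
broken on the lexicographically smallest label pair, where an internal
node's label is the smallest leaf label beneath it; and negative branch
estimates — legitimate NJ outputs on non-additive data — are clamped to
zero with the deficit logged, matching the behavior of the widely used
desktop implementations. On additive matrices NJ is exact; the test suite
verifies exact recovery (topology and lengths, via patristic distances) on
random 5–8-leaf trees, and the three-point branch formulas directly.

A species "forms a cluster" when some edge's removal bipartitions the leaf
set into exactly that species versus everything else (singletons trivially
qualify). This is the tree-based operationalization of "all species formed
clusters" claims in survey reports; it is a monophyly test on an unrooted
tree.

## Diagnostic characters

Only "pure simple" diagnostics are implemented: a column is diagnostic for
a species when the set of states observed in that species is disjoint from
the set observed in all others. Polymorphic-but-disjoint columns qualify.
Specimens with a gap or ambiguity code at a column are excluded from that
column's state sets, and a column is reported only when ≥ 80% (configurable)
of target specimens are informative there — otherwise a single sequenced
specimen could "diagnose" a species through missing data. Both target and
background must contribute at least one informative specimen. Compound
(multi-column) characters and tree-guided character organization are out of
scope. Query scoring ranks species by the fraction of their diagnostic
columns at which the (pre-aligned) query carries a diagnostic state, with
ties broken by diagnostic-site count, then name.

## Synthetic data generator

The generator emulates the statistical structure of a barcode survey, not
its biology. A balanced tree — families under one order, genera, species,
specimens — carries branch lengths solved so the *expected* pairwise
divergence between two specimens equals the configured target for their
class: specimen branches are d_species/2, species branches
(d_genus − d_species)/2, and so on. Defaults (0.2%, 13.5%, 19.7%, 24%;
652 bp; κ = 2) sit on the scale fish COI surveys report. Divergence targets
must increase strictly with rank.

Sites evolve independently under the two-parameter (Kimura) process with
transition/transversion rate ratio κ, sampled per branch from the exact
transition probabilities — so the K2P estimator is correctly specified, and
parameter-recovery tests (mean estimate within 3 SE of truth at divergences
0.002/0.05/0.15 over 200 pairs) are clean checks of the estimator, not of a
simulator approximation.

For coding markers the root sequence is drawn from stop-free codons and any
codon that mutates into an in-frame stop along a branch is re-evolved from
its parent (conditioning the process on stop-free outcomes). This guarantees
clean simulations pass numt screening with zero false positives; the induced
downward bias in realized divergence is tiny (stops are 4 of 64 codons) and
irrelevant at the tolerances used. `simulate_pair`, used for estimator
recovery, applies no such conditioning. The generator does not model rate
heterogeneity across sites, indel evolution, selection, or coalescent
within-species structure — passing tests demonstrate correctness of the
analysis pipeline under its assumed model, not robustness to real-data
violations of it.

Planted artifacts are deterministic per (specimen, seed): `inject_numt`
plants an in-frame TAA or a single-base deletion (an internal gap in aligned
data), `plant_deep_split` gives half a species' specimens extra divergence,
`plant_diagnostic_columns` fixes chosen columns to a state unique to one
species. All are recorded in a truth JSON serialized next to the data so
tests never re-derive ground truth.

## Problem sizes and numerical choices

The default simulated dataset is 2 families × 2 genera × 2 species × 3
specimens (24 records, 652 bp) — large enough that every comparison class is
populated and species clustering is non-trivial, small enough that the full
suite and the acceptance experiments (1,000 oracle pairs, 100 NJ
recoveries, 600 recovery pairs, 75 screening simulations, 10 clustering
simulations, 100 diagnostic alignments) complete in seconds on one core.
Matrix symmetry uses exact assignment, not averaging; Q-tie tolerance is
1e−12; −0.0 distances and branch lengths are normalized to +0.0; all
stochastic draws flow from one seeded `numpy` generator per entry point.

## Known limitations

- SE of class means ignores pair non-independence (above).
- The NND "nearest neighbor" names the species of the arg-min specimen;
  co-equal neighbors at the same distance are not enumerated.
- Numt screening cannot see stop-free, length-conserving numts.
- Species-cluster assessment is topology-only; it attaches no support
  values (no bootstrap).
- Distance-based stages require a complete matrix; heavily saturated
  datasets must be subset before tree building.
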