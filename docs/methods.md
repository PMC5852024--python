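# Methods

This note documents the models, numerical choices and limitations behind
`comorbnet`, in the order the pipeline runs.

## Records and aggregation

Input is long-format diagnosis episodes (patient, calendar year, raw code,
inpatient/outpatient setting). Three cleaning steps mirror standard claims
practice:

- **Code-class filter.** Raw ICD-9-CM-style codes beginning with E or V, and
  codes whose 3-digit numeric prefix falls in 630–679 or 760–999, are
  removed. The filter operates on the numeric prefix only; codes that are
  neither E/V nor numeric (e.g. already-grouped phenotype codes) are
  retained and counted as unclassifiable, since only the named classes are
  excluded. The filter is idempotent.
- **Code mapping.** An optional user-supplied many-to-one table maps raw
  codes to analysis codes (e.g. ICD-9-CM → PheCode grouping). Unmapped
  codes are kept, dropped or fatal per configuration. The package ships no
  mapping table content; the interface accepts any two-column CSV.
- **Common-disease restriction.** Analysis codes must have nonzero
  occurrence in *every* study year. This stabilises per-year estimates and
  guarantees the φ denominator is nonzero (0 < P_i, still guarded).

Within a year, episode multiplicity collapses to presence/absence: the φ
model counts patients, not episodes. A patient contributes to a year's *N*
only with ≥ 1 retained record that year (per-year cohorts vary); a fixed
cohort can be imposed via the `patients` argument.

## Similarity, threshold, adjacency

φ is computed from the count formula and equals the Pearson correlation of
binary indicators; this equivalence is the test oracle (asserted to 1e−12).
Degenerate marginals (P ∈ {0, N}) yield NaN, which thresholding maps to 0
with a log entry.

Eq.-level choice: the adjacency predicate. The default keeps `|s_ij| ≥ τ`
(positive and negative association treated alike, range [0, 1]); a strict
literal mode (`s_ij ≥ τ`, zeroing negative correlations) is available by
flag. Boundary values (s = τ) are kept.

**Scale-free threshold selection.** For each candidate τ the connectivity
vector K is binned into 10 equal-count bins over the connected nodes and
log10 frequency *density* (bin count divided by bin width and sample size)
is regressed on log10 mean K. With equal-count bins the raw frequency is
constant by construction, so density is the quantity with a meaningful
log–log slope. The smallest τ reaching R² ≥ 0.80 with negative slope wins;
otherwise the maximal-R² candidate is used and flagged as a fallback.
Default grid: 0.005–0.10 in steps of 0.005.

On 60-node synthetic networks this criterion is underpowered — the degree
distribution of so small a graph rarely shows a stable power-law regime,
and the selector lands on the fallback path at erratic values. The
synthetic analyses and the acceptance battery therefore run with the fixed
policy τ = 0.03 (the magnitude conventional for claims-scale φ networks,
inside the default grid); `select_threshold` remains the default policy for
real-scale data, where one τ chosen on a reference year is applied to all
years so edge semantics stay comparable.

## TOM and module detection

TOM follows the standard unsigned topological overlap:
`TOM_ij = (l_ij + a_ij)/(min(K_i, K_j) + 1 − a_ij)`, `l_ij` summed over
u ∉ {i, j}. The min is over the two scalar connectivities (the standard
reading of the min term), and the denominator is provably ≥ 1 − a_ij > 0.
Entries stay in [0, 1]; dissTOM = 1 − TOM with zero diagonal is the
clustering dissimilarity. Linkage is average (UPGMA).

**Dynamic tree cut.** dissTOM dendrograms of hard-thresholded networks
occupy a narrow band just below 1 (with 60 nodes, typically 0.86–1.0), so
all height parameters are *fractions of the observed merge-height range*,
never absolute dissimilarities. The cut is an adaptive branch harvest:

1. **Attach-gap harvesting.** Walking from the root, a branch with at least
   `min_module_size` leaves is harvested when the gap between its top merge
   height and its *effective attach height* is ≥ `gap_frac` (default 0.10)
   of the height range. The effective attach height skips ancestors that
   merge only straggler branches (≤ `straggler_size` = 2 leaves), because a
   genuine module's detachment is otherwise diluted across a chain of tiny
   late attachments.
2. **Trim and split.** Harvested branches are trimmed of stragglers
   attaching a full gap above the core, and recursively split where both
   halves are viable modules separated by the same gap.
3. **Iterate and peel.** Harvested leaves are removed, the remainder is
   re-clustered and harvested again (a module masked by unrelated leaves
   chaining onto its branch reappears cleanly in the remainder tree).
4. **Membership refinement.** Every disease is reassigned to the module
   maximising its mean similarity to the members, provided that mean
   exceeds both `refine_beta` (3) times the median off-diagonal similarity
   (the background level) and `refine_member_frac` (0.4) of the median
   member score. The refinement similarity is the signed φ matrix when
   available (its background centres on zero, giving the cleanest
   member/background separation); otherwise 1 − dissTOM. Modules falling
   below the minimum size dissolve to grey.

The defaults were fixed by Monte-Carlo calibration on the reference planted
registries *before* the acceptance suite was written: across seeds they
give median adjusted Rand index 1.0 against the planted truth, leave ≥ 90%
of diseases grey on independence registries, and keep zero-drift
consecutive-year matched Jaccards ≥ 0.9 in the large majority of seeds.
Two limitations are inherent to the design: a partition in which *every*
disease belongs to one single module cannot be detected (the root always
descends), and the signed-φ refinement assumes positive-correlation
modules, which is the empirical regime of disease co-occurrence.

## Eigen-diseases and hubs

The eigen-disease of a module is the first principal component of the
column-standardised patient × member-disease incidence submatrix (the
binary incidence playing the role expression data plays in gene networks),
oriented so its mean correlation with member columns is positive; constant
columns are dropped with a warning. The hub is the member whose indicator
correlates most with the eigen-disease, ties broken by higher intramodular
connectivity, then lexicographic code; hubs are found within their own
module only (one hub per module). Eigen-diseases are themselves clustered
(average linkage on 1 − correlation) and exported as a Newick tree.

Intramodular connectivity restricts the K sum to same-module partners;
grey diseases get a missing value.

## Temporal comparison

Module tracking uses Jaccard indices between membership sets over the
common disease universe, with grey included as an ordinary row/column (it
is part of the published comparison convention). Matching is greedy: each
later-year module takes its argmax earlier-year module (no global
assignment), and matched values above 0.5 are reported as stable
correspondences. Trend series (prevalence, K, intramodular K) get a lowess
smooth with span 0.5.

## Synthetic registries

The generator emulates the statistical structure the pipeline assumes in
claims data, not any real population:

- per-disease base prevalence drawn log-uniform (default range
  [0.005, 0.3], echoing heavy-tailed prevalence rankings);
- per patient, year and module, a latent activation indicator (default
  rate 0.3) lifting all of that module's diseases by a common factor
  (default 4), truncated below 1 — block-positive φ via shared risk
  factors, not pairwise copulas;
- yearly drift reassigning a fraction of diseases to a different module or
  background;
- settings assigned at random (1% inpatient) since the pipeline pools both.

The *reference planted condition* used throughout testing is 2,000
patients, 60 diseases, three modules of 15, lift 4, base prevalence
log-uniform on [0.03, 0.08] (≈ 0.05). The tight prevalence band matters:
with φ ≈ √(p_i p_j) for this generator and sampling noise ≈ 1/√N ≈ 0.022,
diseases below ~2% prevalence are statistically invisible at this sample
size, so a wider band makes module recovery information-limited rather
than algorithm-limited.

What passing these tests does *not* show: real claims data have age/sex
structure, coding-practice drift, correlated background comorbidity and
six orders of magnitude more episodes; none of these are modelled. The
synthetic studies validate the machinery (estimators, matrices, cut,
tracking), not epidemiological conclusions.

## Problem sizes

The shipped analyses and tests run 60-disease, 2,000-patient registries
over 1–3 years (seconds per run); all matrix operations are dense and
scale as O(n²)–O(n³) in the number of diseases, comfortably handling the
~1,400-disease scale of national registries on a workstation.

## Reference fixture

`data/modules_2013.csv` transcribes a published nine-module 2013 disease
partition (239 diseases; sizes 39/32/27/25/25/24/24/22/21) used for size
checks and Jaccard comparisons. The file is integrity-checked by SHA-256;
a corrected transcription can be supplied as an explicit override path,
which bypasses the checksum.
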