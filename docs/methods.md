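# Methods

This note documents the models, conventions and design choices behind
`barcodegap`, in the spirit of the methods documentation of simulation
and statistics packages: what is computed, under which assumptions, and
what the synthetic benchmarks do and do not demonstrate.

## Data model

A `BarcodeAlignment` is a set of equal-length sequences over the IUPAC
nucleotide alphabet plus `-`, keyed by unique specimen ids; a
`TaxonomyMap` assigns each specimen a (species, genus, family) triple.
Taxonomy normally travels as a separate TSV so sequence files stay
standard FASTA; a `specimenID|species|genus|family` header dialect is
accepted when no TSV is given.  Characters are read case-insensitively
and stored uppercase.  All user-facing position labels (e.g. the
diagnostic character `G_5`) are 1-based on the alignment columns;
internal indexing is 0-based.  Every downstream module consumes these
two types only — nothing re-parses files.

## K2P distances and summaries

Distances use the Kimura two-parameter (K80) model: with transition
proportion P and transversion proportion Q over the comparable sites of
a pair,

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).

Conventions:

- **Pairwise deletion.** A site where either sequence has a gap or any
  ambiguity code is excluded from that pair's comparison, matching the
  default of the standard distance/tree software.
- **Saturation is flagged, never dropped silently.** If
  1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 the distance is undefined; the scalar
  API raises, the matrix API stores a NaN sentinel, and summaries
  exclude such pairs with a logged count.  Tree building refuses
  matrices containing undefined entries.
- Summary SD uses the n−1 (sample) denominator; SE = SD/√n_pairs.
  Outputs print distances to 4 decimals; computation is full precision.
- The barcoding gap is *positive* iff max(intra) < min(inter); the gap
  range (max intra, min inter) is reported when positive.  Histograms
  bin both levels over the pooled finite range for plotting.

## Neighbor joining and monophyly

Standard Saitou–Nei agglomeration on the K2P matrix, with two policies
fixed for reproducibility:

- Q-matrix ties break by the smallest (row, column) index pair.
- Negative branch lengths are clamped to zero with the deficit
  transferred to the sister branch (preserving the joined pair's
  distance); a residual negative — possible only when the distance
  between two merged nodes is itself negative — is floored at zero.

Bootstrap supports resample alignment columns with replacement; the
support of an internal edge of the full-data tree is the percentage of
replicate NJ trees containing the same bipartition (no consensus tree
is built).  Replicates whose resampled matrix has an undefined pair are
redrawn and logged.  The default replicate count is 1000; supports are
deterministic given the seed.

Monophyly is a bipartition test on the unrooted tree: a taxon is
monophyletic iff some edge splits exactly its specimens from all other
leaves; singletons count as monophyletic.  When an outgroup id set is
supplied, outgroup specimens are excluded from the scored taxa; since a
candidate taxon then never contains outgroup leaves, the matching
edge's far side automatically holds the whole outgroup, so the rooted
clade test coincides with the bipartition test.  Rank may be species or
genus.

## Automatic gap partitioning

A desk-scale re-implementation of the automatic-barcode-gap idea on
ranked pairwise distances, not a port of the original web service.
Given a prior maximum intraspecific divergence P and minimum relative
gap width X (default 1.5):

1. Sort all pairwise distances.  Consider jumps between consecutive
   values whose upper value exceeds P.
2. The first jump wider than X times the mean spacing of the ranked
   curve below it (below the jump, from the smallest value) is the
   barcode gap; the threshold is its midpoint.  For a jump with nothing
   below it the local spacing is zero, so any positive jump qualifies —
   this is what makes very low priors return near-haplotype groups.
3. The *initial* partition takes single-linkage connected components
   under `distance < threshold` (one group containing everything when
   no jump qualifies).  The *recursive* partition re-runs the gap
   search inside every group on its submatrix and keeps splitting until
   no group shows an internal gap; it therefore always refines the
   initial partition.

The prior grid is geometric (log-spaced), by default 10 steps from
0.001 to 0.1.  The module is fully deterministic.  Concordance against
a taxonomy counts groups that equal exactly one species' specimen set;
raw counts are reported so any ratio convention can be derived.
The pipeline's headline partition uses the mid-grid prior 0.0215: a
prior inside the intraspecific tail splits haplotype clusters (by the
mechanism in step 2), while the plateau of stable group counts above
the tail and below the gap is where the supported species count lives.

## Diagnostic characters

A nucleotide n at column c is diagnostic for taxon T iff every member
of T carries exactly n at c and no specimen outside T can carry n
there.  Only single positions are considered; multi-position
combinations are out of scope.  Ambiguity handling is conservative, so
a reported diagnostic can never be contradicted by resolving an
ambiguity: any member gap/ambiguity makes the column ineligible for T,
and an outside ambiguity whose expansion includes n blocks n.  Two
monotonicities follow directly (and are property-tested): adding
specimens to a taxon can only remove its diagnostics; removing other
taxa can only add them.  The second explains why small data sets or
within-family subsets show much higher diagnostic success ratios than
the same species embedded in a large data set.  Ranks species, genus
and family are supported; the success ratio is
100 × (taxa with ≥ 1 character)/(total taxa).

## Success rates and confidence intervals

Identification success is Number_hit/Number_test kept as an exact
rational; percentage rounding happens only at print time.  The
confidence interval is the Wald normal-approximation Bernoulli
interval, p̂ ± z₁₋α/₂ √(p̂(1−p̂)/n), clipped to [0, 1], with z from the
normal quantile function so any α works.  The Wald interval's known
under-coverage near p → 1 is asserted in the tests against its exact
binomial expectation rather than against the nominal level.  Wilson or
Clopper–Pearson intervals are deliberately not provided: the Wald form
is the convention this pipeline reports.

## Synthetic data generator

The generator emulates the statistical shape of a curated barcode
study: by default 80 species with 2–20 specimens each (drawn
uniformly), 615 alignment columns, mean intraspecific K2P 0.0046 and
mean interspecific 0.1368, K80 substitution with TS/TV = 2.0.  Species
relationships are a star phylogeny by default — one random ancestral
sequence, each species' representative evolved independently by
(inter − intra)/2 expected substitutions per site, specimens evolved
from the representative by intra/2 — so pairwise expectations are
exactly the targets and the downstream K2P estimator is measuring the
same quantity the generator dials (verified by replicate-level
Monte-Carlo calibration tests).  An optional coalescent mode draws a
random Kingman genealogy over species, rescaled to the target mean
divergence, for monophyly stress tests.  No indels or rate
heterogeneity are simulated.  Planted diagnostics overwrite chosen
columns with a base fixed within one species and absent outside (any
outside carrier is pushed a transversion away); planting is refused
when species × planted columns exceed the alignment length.  The same
seed yields a byte-identical data set.

What passing tests on these data do and do not show: they demonstrate
correct recovery of known structure under the model's own assumptions
(homogeneous divergences, no gaps/ambiguities, star or coalescent
species history).  They do not demonstrate performance on real COI
data, where intraspecific divergence is heterogeneous across species
(which is exactly what breaks the global barcoding gap in large real
data sets), genera and families carry shared derived characters, and
sequences contain ambiguity codes.  Two visible consequences in the
study-scale simulation: family-level diagnostics are near 0% (star
families are arbitrary groupings of independent lineages with no
synapomorphies) and multi-species genera are rarely monophyletic, so
genus-level monophyly sits near the fraction of monotypic genera.
Species-level results (gap, partitions, monophyly, diagnostics) are the
meaningful benchmark outputs.

## Numerical and degenerate-input choices

- K2P of identical sequences is exactly 0 (signed zero normalised).
- Zero comparable sites between a pair is an error in the scalar API
  and a NaN in the matrix.
- Empty intraspecific summaries (no species with ≥ 2 specimens) are
  flagged empty rather than reported as zero.
- Partition groups are ordered by smallest member id; grid and
  membership tables are byte-stable for diffing.
- All randomness (simulation, bootstrap, random taxon subsets) flows
  through explicit integer seeds via numpy Generators.

## Known limitations

- The gap detector is the ranked-distance rule described above, chosen
  for transparency and determinism; it is not the original model-based
  implementation and can differ on borderline jumps.
- Bootstrap supports attach only to edges of the full-data tree; no
  majority-rule consensus is computed.
- Maximum-likelihood and Bayesian tree inference, best-close-match /
  minimum-distance assignment, GMYC and guide-tree (CAOS-style)
  character analysis are out of scope.
- The simulator's star mode gives no deep phylogenetic structure; use
  the coalescent mode when higher-rank monophyly matters.
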