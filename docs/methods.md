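# Methods

This note documents the models and decision rules implemented in
`ciloss`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions adopted where
the design was genuinely open.

## Complex I screening

The unit of evidence is a (genome, subunit) pair for the seven
mitochondrially encoded CI subunits (ND1–ND6, ND4L). A subunit is
*present* when it is annotated or when a homology-based gene prediction
covers at least 50 % of its protein-coding region (boundary inclusive);
both evidence channels are carried in the distilled genome TSV, so the
rule engine never parses free-text annotations. Genomes with fewer than
three CDS annotations are treated as incomplete and discarded, and at
most 50 genomes per species are retained — subsampled uniformly with a
per-species random stream derived from (seed, CRC32(species id)), so
the draw is reproducible and independent of input order, and the filter
is idempotent.

A genome supports CI loss when it misses at least 5 of 7 subunits. The
rule is one-sided; genomes missing 3–4 subunits sit between the two
modes of the empirically bimodal subunit-count distribution and are
logged for curation. Species aggregation is deliberately conservative:
*absent* only if every retained genome misses ≥ 5 subunits, *present*
only if every genome misses ≤ 2, otherwise *conflicting*. Conflicting
and data-less species are excluded downstream — a machine-checkable
stand-in for the manual curation such disagreements normally receive.

## Independent losses on the species tree

Tips carry states present/absent/unknown; unknown (or conflicting) tips
are ignored when evaluating clade uniformity, because species without
usable mitochondrial data cannot separate CI loss from loss of the
whole mitochondrial genome. An *independent loss* is a maximal clade
whose known tips are all CI-absent while the parent clade contains a
CI-present tip. Losses are modelled as irreversible (CI comprises
dozens of co-adapted subunits; regain is not considered), under which
the number of such clades equals the minimum number of present→absent
transitions (Camin–Sokal parsimony with a CI-present ancestor); the
test suite checks this equivalence exhaustively on 6-tip trees,
unknown states included. Polytomies are handled as given. Recency:
events spanning ≥ 2 genera are *ancient*; single-genus events with a
CI-present congener elsewhere in the tree are *recent*; a single-genus
event with no CI-present congener cannot be confirmed as recent and is
labelled `recent_unconfirmed` rather than guessed.

## Copy-number association (KS scan)

For each gene family the test compares orthologue counts between the
CI⁺ and CI⁻ sides of the tree with a two-sided two-sample
Kolmogorov–Smirnov test (exact null whenever n·m ≤ 10 000, asymptotic
otherwise; significance at p < 0.05). Three sampling units are
available via `ks_scan(..., nodes=...)`:

* `"pooled"` (default) — the raw per-species counts of each side. Under
  the null both samples come from the same distribution, so the nominal
  type-I error holds (slightly conservatively, counts being discrete).
  Measured on the default synthetic conditions: power ≈ 0.96 at the
  default effect size, false-positive rate ≈ 0.01 at α = 0.05.
* `"maximal"` — one median per maximal CI⁺/CI⁻ clade. Faithful to a
  per-clade reading of the procedure, but with only ~5 CI⁻ clades the
  exact test needs near-complete separation of heavily tied medians:
  measured power ≈ 0.71 at the same effect size, FPR ≈ 0.01.
* `"all"` — one median per monophyletic node, nested nodes included.
  Nested medians are strongly dependent and differently dispersed
  between the two sides, which inflates the measured FPR to ≈ 0.15;
  this mode exists for comparison only.

The pooled unit is the default because it is the only variant that is
simultaneously calibrated and powered at desk scale; the per-clade
variants remain one keyword away. Medians of even-sized clades are the
mean of the two central values; ancestral copy numbers are medians over
extant clade members.

## Duplication, loss and the sister filter

Gene-tree duplications use the species-overlap criterion: a node is a
duplication iff the species sets of (any two of) its child subtrees
intersect; a species is flagged D when ≥ 2 of its genes descend from a
single duplication node. Family loss in a focal CI⁻ species requires
zero orthologues there *and* ≥ 1 orthologue in some sister-group
species — shared absence predates the focal lineage and is not an
event. Families whose events are mirrored in the CI⁺ sister group are
discarded; "similar evolution" is operationalized per event type (D
with D, L with L, …), the simplest reading that is falsifiable.

## Positive-selection overlap

Branch-site LRT p-values are adjusted per species with
Benjamini–Hochberg; PS calls require adjusted p strictly below 0.05.
The overlap statistic is the number of families with ≥ 1 PS gene in
every focal species. The null keeps each species' number of PS calls
fixed and reassigns them uniformly without replacement over that
species' tested genes (10 000 draws by default; a per-family
reassignment variant is available via `unit="family"`). The reported
p-value uses the add-one estimator (#{null ≥ observed}+1)/(n+1), the
standard convention that never reports zero. Exhaustive-enumeration
oracles in the test suite confirm the Monte-Carlo estimate on all small
configurations within three standard errors.

## Mitochondrial retargeting

Localization predictors emit nine compartment probabilities (softmax-
like; validated to sum to 1 ± 0.01, renormalized with a warning
otherwise, tolerating rounded files) plus a membrane score. Because
yeast proteins are often multi-localized, retargeting is scored
quantitatively: delta = P(mito, target) − max over sisters of P(mito).
Requiring the target to exceed *all* sisters is the conservative
reading of "compared to any of the sister orthologues"; the
exceed-any-one variant (minimum sister) is available via
`mode="any"`. The call is strict: delta > 0.2. The benchmark sweeps a
threshold grid over labelled paralogue pairs and selects the threshold
maximizing sensitivity subject to precision ≥ 0.7 (ties to the smaller
threshold; `None` when the floor is infeasible). Family-level main
localization is the set of compartments that are the argmax for ≥ 50 %
of the family's proteins, argmax ties broken by a fixed compartment
order with mitochondrion first, for determinism.

## Pathway convergence scoring

Scores roll up gene → enzyme → pathway under six positive parameters.
Gene: p4 for innovation (PS/MR/D), p5 for loss only, −p6 otherwise,
times 10 (high-identity mapping) or 1 (low). Enzyme: + p1 when exactly
two CI⁻ species innovate in its genes, + p2 when all do, + p3 when the
enzyme is present in every CI⁻ species but no close CI⁺ relative or
vice versa, plus the summed gene scores. Pathway (per species): sum of
enzyme scores, −p6 for every enzyme unmapped in that species. The −p6
absence penalty is applied per (enzyme, species) so that scores remain
species-resolved; an enzyme retained by the CI⁺ relatives but mapped in
no CI⁻ species earns its p3 "lost with CI" bonus alongside the absence
penalty, otherwise that arm of the uniqueness rule could never fire.

No principled values for p1–p6 exist, so pathways are scored under all
729 = 3⁶ combinations of {lower bound, midpoint, upper bound} per
parameter, with dependent bounds evaluated at the parent's sampled
value in the order p5 → p4 → p6 → p3 → p1 → p2. Interval endpoints are
treated as inclusive — with open intervals the stated bounds would be
unreachable and the grid underdetermined. Raw scores are linear in
(p1…p6), so the implementation evaluates the whole grid as one matrix
product of per-(pathway, species) coefficient vectors; the test suite
checks this against direct rule application. Per (species, parameter
set), scores are z-scored across pathways (population sd; a
zero-variance slice yields z = 0 with a warning rather than a crash);
the per-species final score is the mean z over the grid, pathways are
ranked by the mean final score across species (ties broken by pathway
id), and the top 10 reported.

## GO convergence

Per species and gene category, over-representation uses the one-sided
hypergeometric tail P(X ≥ k) against the species' annotated background,
with gene annotations propagated up is_a/part_of edges (true-path
rule; `load_obo_ancestors` reads OBO via obonet). BH FDR is applied
across terms within a species. A term is convergent at level X when its
raw p < 0.05 in every CI⁻ species, and XX when the FDR-adjusted p is
also < 0.05 everywhere. Skipping within-species correction for the X
level is intentional: requiring the signal independently in every loss
already suppresses false positives while keeping sensitivity in small
categories (duplication ∩ positive selection sets can hold a handful of
genes). Depletion is not tested.

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults define the study conditions: 40 species, 5
independent losses alternating recent (single species, CI⁺ congeners
in the genus) and ancient (clades spanning ≥ 2 genera), 4 mitochondrial
genomes per species, 60 gene families, 6 planted copy-number-associated
families, 8 planted all-species PS-overlap families (the scale of the
real overlap this pipeline is built to test), 24 paralogue pairs of
which 8 planted retargeted, 20 pathways with 3 planted convergently
altered. Focal comparative species are one representative per recent
loss, mirroring an analysis centred on recent losses with close
CI-bearing relatives.

Distributional choices (no empirical forms are claimed): orthologue
counts are Poisson with mean 2, shifted by +3 in CI⁻ clades for planted
associated families; localization vectors put the non-mitochondrial
mass on a Dirichlet with a dominant cytoplasmic component; planted
retargeted targets exceed their maximum sister's mitochondrial
probability by exactly the configured delta (0.6), non-planted pairs
stay within ±0.15; branch-site p-values are 10^U(−6,−4) for planted
overlap families, 10^U(−5,−3.5) for a ~5 % sprinkling of species-
private calls, U(0.05, 1) otherwise; annotation noise flips individual
subunit evidence with probability 0.02 and 5 % of genomes are emitted
incomplete (< 3 CDS). A single seed drives all stages through
CRC-hashed per-stage streams, so identical configurations reproduce
byte-identical datasets while stages remain independently perturbable.

What the generator does *not* emulate: real sequences, alignments or
codon evolution (only the branch-site p-value table is produced);
phylogenetic non-independence of counts along branches (counts are
drawn i.i.d. per species within a regime); annotation biases that are
correlated across subunits; overdispersed copy numbers; incomplete or
biased taxon sampling. Passing the planted-truth suites therefore shows
that the decision rules and statistics behave as specified under
controlled conditions — not that the pipeline is robust to every
pathology of real genome databases.

## Problem sizes and runtime

The test and acceptance runs use the default conditions above: 20
independent seeds for the recovery suites, 10 000 permutation draws for
the overlap test, and the full 729-point grid for every pathway
ranking. The whole test suite runs in well under a minute on one CPU;
`scripts/acceptance.py` (which additionally repeats the pipeline over
10 seeds) takes a few seconds.

## Known limitations

* The conservative species-aggregation rule can label borderline
  species `conflicting` and drop them; on trees where such a species is
  the only CI⁺ separator between two loss clades, adjacent events would
  merge — the database-scale remedy (manual curation) is out of scope.
* The KS scan treats species as exchangeable within each side; a
  phylogenetically aware count model (e.g. a birth–death process along
  branches) would be a natural extension.
* The sister-group "similar evolution" filter and the per-species −p6
  penalty are single-reading implementations of rules that admit
  alternatives; both alternatives are noted inline and the filter is
  per event type by design.
* GO convergence inherits the usual caveats of raw-p intersections:
  it controls false positives only through the independence of the
  losses, which is a biological, not statistical, guarantee.
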