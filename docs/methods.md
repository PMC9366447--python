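# Methods

## The marker system

A retroelement insertion is a nearly ideal cladistic character: the
combination of an element of a specific family, in a specific orientation,
at a specific genomic position, framed by a target-site duplication (TSD),
is vanishingly unlikely to arise twice independently, and precise excision
is negligible. Presence of the same insertion at an orthologous locus in
two species therefore marks a shared ancestor; a clean "empty site" (the
two flanks directly adjoining) marks divergence before the insertion. The
one systematic confounder is hemiplasy: an insertion that is still
polymorphic through a short internal branch can fix discordantly in the
descendant lineages (incomplete lineage sorting, ILS), producing genuine
markers for a grouping that contradicts the species tree.

## Simulation model

The generator realizes a rooted four-taxon tree `(((L1,L2),L3),O)`:

* **Internal-branch sorting.** An insertion on the (L1,L2) stem fixes in
  the concordant pattern {L1,L2} with probability 1 − (2/3)e^(−τ) and in
  each conflicting pattern ({L1,L3}, {L2,L3}) with probability
  (1/3)e^(−τ), where τ is the internal branch length in coalescent units.
  This is the standard neutral gene-tree discordance form; the source
  analysis invokes ILS only qualitatively, so this closed form is a
  declared stand-in for an unspecified population process, not an inference
  from data. Default τ = 0.451, the value at which the closed form
  reproduces a 57.5/21.2/21.2 split of informative patterns — the regime the
  pipeline is designed around. An optional `hybrid_fraction` reroutes
  internal-branch events to one fixed conflicting pattern, creating the
  asymmetry a hybridization test detects.
* **Insertion mechanics.** Each event copies a family consensus (four
  synthetic tRNA-SINE-sized consensus sequences, 150–220 nt, stand in for a
  curated marsupial SINE library, which is not shipped), flanked by an exact
  duplicated target site of 8–30 nt drawn uniformly. A configurable fraction
  of events (default 0.10) receives a 5′ truncation of 11–100 nt to
  exercise the "nearly full-length" filter. Placement is uniform over the
  ancestral sequence with a minimum spacing of 1200 nt (so 500-nt flanks
  never overlap) and a 1500-nt margin from contig ends; collisions are
  resampled.
* **Substitutions.** A uniform single-nucleotide model (Jukes–Cantor-like),
  applied per branch (internal branch shared by L1 and L2), default 0.01
  substitutions/site/branch. Substitutions hit the ancestral backbone only,
  not the inserted element copies: this keeps flank orthology and truth
  coordinates exact, at the cost of not modelling element divergence —
  which is instead exercised by constructed fixtures in the test suite.
  There are no indels outside insertion events, no rearrangements and no
  evolved repeat landscape; nested or duplicated elements are planted
  explicitly where a test needs them. Consequences: anchoring and
  coordinate bookkeeping are exact on synthetic data, so passing end-to-end
  tests demonstrates the pipeline's logic, not its robustness to assembly
  artifacts, alignment indels or deep element decay.

Coordinates are 0-based half-open throughout.

## Locus selection and screening

* **Annotation.** Library consensus copies are found by exact 12-mer
  seeding, clustered on the alignment diagonal and refined by gapped local
  alignment (match 2, mismatch −3, gap open 5, extend 2); both strands are
  searched and overlapping same-family hits keep the higher-identity
  (then leftmost) one. Truncations are read off the local alignment in
  consensus coordinates, strand-normalized. A RepeatMasker `.out` reader
  (1-based inclusive → 0-based half-open, `C` → `−` with the repeat
  coordinate triple read right-to-left) supports real annotations.
* **Filters.** Candidates keep elements with truncations strictly under
  10 nt at both ends and repeat coverage strictly under 50% in *each*
  500-nt flank (the source criterion does not say whether the 50% applies
  per flank or pooled; per-flank is the stricter reading and is what is
  implemented). Coverage counts the union of all annotations of any
  family. Loci within 500 nt of a contig end are rejected.
* **Anchoring.** Each flank is placed in a query genome by exact 20-mer
  seeds refined with a semiglobal (edlib) alignment; an anchor is accepted
  when its identity is ≥ 0.90 and its score beats the best non-overlapping
  alternative placement by a factor of 1.2 (both configurable). A locus is
  *present* when an element of some library family (≥ 0.80 identity over
  ≥ 40 nt) lies between the anchors in the expected frame, *absent* when
  the anchors are contiguous within ± (tsd_max + 5) nt — at a clean empty
  site the anchors *overlap* by the TSD length, because both reference
  flanks carry one copy of the duplicated target site — and *ambiguous*
  otherwise (split contigs, non-unique or low-identity anchors, oversized
  gaps). Ambiguity is deliberately the only failure mode: a conservative
  screen loses loci to ambiguity but never converts absence into presence.
* **Merging.** Loci discovered from different reference genomes are merged
  when their anchored windows overlap reciprocally by ≥ 50% in any shared
  species; merged state conflicts downgrade that species to ambiguous.

## Validation thresholds

* Element start shifts are measured in the locus frame relative to the
  anchored flank; "shifted by less than 3 nt" is enforced as a strict
  maximum pairwise shift ≤ 2 nt.
* TSD detection scans lengths 30 down to 8 for a direct repeat with one
  copy ending at the element 5′ boundary and one beginning at the 3′
  boundary, allowing ≤ 1 mismatch for lengths ≥ 10 and none for 8–9. The
  mismatch allowance is a declared choice; the source states only the
  length range.
* The duplication screen flags a locus when either flank has a second
  genomic match at ≥ 90% identity over ≥ 80% of its length outside the
  locus. The thresholds quantify an undefined "evidence of duplication"
  criterion and are exposed in the configuration.
* A "clear absent state" is a contiguous empty-site alignment within the
  slack above; at most 5 nt of unexplained sequence is tolerated at an
  absence junction, beyond which the junction must match one retained TSD
  copy (≥ 80% identity) or the locus is rejected for flank co-transfer.
* Consistency is required across ≥ 2 representatives per lineage by
  default; the four-taxon synthetic design has one genome per lineage and
  therefore runs with the minimum set to 1, where the check degenerates to
  state consistency.

## Statistics

For counts (n₁, n₂, n₃) with N = n₁+n₂+n₃:

* **Tree vs polytomy.** Under a hard polytomy each marker supports each
  grouping with probability 1/3. The reported p is the directional exact
  binomial tail P(X ≥ max nᵢ), X ~ Bin(N, 1/3) — the form that reproduces
  the printed headline value for (61, 26, 19), p ≈ 2.74×10⁻⁷. Because the
  supported hypothesis is chosen post hoc as the argmax, the *verdict*
  (and the power/type-I simulations) compare this p against α/3
  (Bonferroni over the three candidate resolutions); without that factor
  the realized type-I error at τ = 0 is ≈ 3α. The Monte-Carlo oracle
  (`monte_carlo_null`) measures the same directional statistic by default
  so that exact and empirical tails are estimates of the same quantity;
  the family-wise variant (`statistic="max"`) is available separately.
* **ILS vs hybridization.** ILS predicts the two conflicting counts to be
  exchangeable; the larger is tested against Bin(n₂′+n₃′, 1/2), two-sided
  by doubling the one-sided tail and capping at 1. Equal counts give
  p = 1; a zero conflict total returns p = 1 with an explanatory note.
* **Calibration.** `power_table` simulates counts from the τ-closed form
  over a (τ, N) grid; the τ = 0 row estimates the type-I error. All random
  draws take one explicit seed; there is no global random state.

## Matrix and concordance

Markers become an irreversible binary matrix (1 presence, 0 absence,
`?` unscored); every column must segregate among the ingroup. Split support
is a column bootstrap under gain-once logic: each column votes for the
two-lineage split it supports, columns are resampled with replacement, and
a split scores a replicate when it holds the strict plurality (ties count
as unresolved). NEXUS output uses `DATATYPE=STANDARD SYMBOLS="01"
MISSING=?` so external split-network and Bayesian tools (with irreversible
character settings) can consume it; those analyses themselves are out of
scope here.

Flank concordance extracts 500 nt on each side of the element or empty-site
junction (1 kb per locus), concatenates per hypothesis group with a
partition table, and counts four-taxon site patterns (xxyy / xyxy / xyyx)
for the site concordance factor; gene concordance lets each locus vote by
strict plurality of its informative sites, abstaining on ties. With more
than four taxa one representative per group is sampled per site under a
fixed seed. Random-locus alignments are excluded when any row has a gap
run longer than 25% of the alignment length or when ≥ 50% of all cells are
gaps — the two stated rules; no further trimming heuristics are emulated.
Marker positional dispersion is a chi-square goodness of fit of per-contig
counts against length-proportional expectations, pooling contigs with
expected count < 1.

## Problem sizes

The shipped tests and the acceptance script run the genome-scale study at a
2 Mb ancestral sequence with ~300 insertions and 0.01 substitutions per
branch (about 10 s end to end), the Monte-Carlo oracle at up to 10⁷
replicates, and bootstrap/power grids at 500–2000 replicates. These sizes
were chosen as the smallest at which every statistical check has the
resolution it claims; all of them are parameters, and nothing in the
implementation depends on the scale.

## Known limitations

* The fixation closed form is a stand-in; real insertion fixation dynamics
  (population bottlenecks, rate variation across the tree) are not
  modelled, so τ is a tuning of discordance levels, not an estimate of any
  real quantity.
* The annotator is a consensus scanner: no fragment joining, no
  substitution scoring matrices, no library curation. For real genomes,
  RepeatMasker output should be ingested instead.
* The screen assumes assembled, largely collinear genomes; there is no
  chaining, netting or synteny logic, and anchor uniqueness will degrade in
  highly repetitive or duplicated regions (by design, into ambiguity).
* Gene-conversion and precise-excision homoplasy are assumed negligible,
  as in the marker system's standard interpretation.
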