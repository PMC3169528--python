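# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the synphen pipeline. Coordinates are 0-based half-open
in memory and 1-based inclusive in every text format.

## Anchors

Anchors are maximal exact matches between reference and query sequences that
are unique in the reference (query repeats allowed), the semantics of
maximal-unique-match seeds in nucmer-style aligners; the `io` module also
reads show-coords `-T` tables so external aligner output can replace the
built-in finder. The finder seeds on k-mers (default k = 20, minimum 8) that
occur exactly once in the reference and extends each seed to its maximal
match on both query strands. Any match containing a reference-unique k-mer is
itself unique, so reported anchors are correct; a unique match all of whose
k-mers are repeated has no seed and is missed — in heavily repetitive
sequence the finder is therefore conservative. `N` never matches, including
against itself. Minus-strand anchors carry forward-strand query coordinates
with a strand flag.

## Chaining and filtering

Collinear anchors chain greedily in (ref_id, ref_start) order: an anchor
joins the open chain minimizing the reference gap (ties: smaller query gap,
then earlier chain creation) among chains with the same sequences and strand,
monotone coordinates, and both inter-anchor gaps at most `max_gap`
(default 10,000 bases — the allowance for undetectable similarity between
anchors). Chain score is the spanned reference length.

The overlap filter removes a chain when a strictly higher-scoring chain
overlaps more than `overlap_frac` (default 0.9) of its length on either
sequence. Two deliberate refinements:

* The overlap numerator is measured against the larger chain's merged
  *anchor footprint*, not its raw span. A chain can skip up to `max_gap`
  bases of another block's material; a small genuine block nested inside that
  gap conflicts with nothing, and span-vs-span comparison was observed (on
  simulated rearrangements) to delete such blocks and the genes within them.
* The comparison set is all strictly larger chains, retained or not, making
  the filter order-independent and idempotent.

The denominator is the spanned length by default; `length_mode="aligned"`
uses the anchor-length sum instead, since either reading of "90% of their
length" is defensible.

## Coordinate map and liftover

Filtered chains define a piecewise monotone reference→target map. Positions
inside anchors map exactly. Positions in an inter-anchor gap map to the
preceding anchor boundary plus an offset clamped into the target-side gap and
are flagged approximate; when the two gap sides are equal (pure substitution
divergence) this approximate map is still exact in practice. Chains may
overlap on the reference by a few junction bases (chance anchor extension) or
nest inside another chain's gap, so positions are claimed in two score-ordered
passes — anchor regions first, then gap regions — and construction fails only
when a chain's anchors are entirely shadowed, which indicates unfiltered
input.

Each gene is lifted two ways. *Projection* maps its boundary positions;
boundaries on different chains or scaffolds mark the gene disrupted.
*Realignment* extracts the projected span ± `pad` (default 2,000 bases,
a typical bacterial intergenic scale) from the target, orients it by the
composed strand, and aligns the reference CDS to it with free end gaps on the
region side. The aligned footprint snaps to the nearest in-frame start codon
(ATG/GTG/TTG) within ±30 bases and the in-frame stop codon nearest the
footprint end (±30 + 3); internal stops, missing codons and alignment gaps
are recorded as notes. Bacterial genes being intronless, this CDS-to-region
glocal alignment replaces protein-spliced gene modeling while preserving
boundary-aware re-modeling.

Candidates are scored by global alignment of their CDS against the reference
CDS under match +1, mismatch −1, gap open −5, gap extend −1 (a gap of length
L costs 5 + L). Any fixed scheme satisfies a higher-score-wins rule; this one
is exposed through `make_aligner`. Ties go to projection, the cheaper method.
Reconciliation with ab initio ORFs merges same-strand pairs with reciprocal
overlap ≥ 0.5 (greedy, largest overlap first), keeping mapped coordinates and
the reference gene id; unpaired records pass through.

## Scaffold stitching

A scaffold's orientation is the strand of its highest-scoring chain and its
anchor position the midpoint of that chain's reference span. With several
references, each scaffold uses the reference holding its greatest total chain
score, and references are laid out by genome-wide total score — a
deterministic stand-in for the study's manual inspection of dot plots, so
discrepancies with a manually curated order are expected. Scaffolds without
chains append last, longest first. Stitching joins oriented scaffolds with
runs of exactly 500 N *between* scaffolds (none at the outer ends, so total
length = scaffold bases + 500 × (n − 1); `terminal_spacer=True` restores the
alternative reading) and emits the placement table and an AGP v2.1 file (gap
type `scaffold`, linkage `yes`, evidence `align_genus`).

## Growth screen

The input is a long-format CSV (plate_id, well, species, compound, category,
time_h, a590); uninoculated plates carry the species label `uninoculated` and
no-carbon control wells the compound label `no_carbon`. The dialect has no
explicit pairing column, so an inoculated plate pairs with the uninoculated
plate(s) sharing its exact well→compound layout (an error if none; the mean
if several).

Normalization: (1) per well and time, subtract the same well on the paired
uninoculated plate; (2) average replicate wells per species × compound ×
time; (3) subtract the mean of the species' no-carbon wells (after step 1) at
the same time point. Subtraction is per time point at every declared time;
negative values are retained. Adding a constant to all readings of a plate
and its uninoculated partner leaves the matrix unchanged. Growth calls use a
strict inequality, normalized A590 > 0.2 at 96 h; both threshold and call
time are parameters.

Compound clustering uses distance 1 − centered Pearson correlation between
compound profiles (species × time concatenated) with average linkage —
the linkage choice mirrors the species-clustering setting, as the heatmap
linkage is not otherwise pinned down. Zero-variance profiles sit at distance
1 from everything (correlation undefined); compounds enter in sorted-name
order so leaf order is deterministic. Inoculum normalization (3.8e-3
optical-density units per well) is treated as metadata, not modeled.

## Gene families and EC counts

Edges failing e-value ≤ 1e-5 or percent-aligned ≥ 10 are dropped; weights are
−log10(e-value) capped at 200 (e-value 0 maps to the cap); reciprocal
duplicates merge by mean. Both filters are parameters, since curated family
analyses may deliberately relax them. MCL adds self-loops (weight = max
incident weight, at least 1), column-normalizes, and alternates expansion
(matrix self-product) with inflation (elementwise power 1.5, renormalize)
until the largest column change falls below 1e-6 or 100 iterations
(non-convergence returns the current partition with a warning). Families are
connected components of the limit matrix's attractor structure; columns stay
stochastic to 1e-9 after every normalization, and with no between-family
edges the partition equals the graph's connected components.

The count matrix uses the strict rule by default: a family is implicated for
a reaction category when any member carries an EC in it, and
count(species, category) counts that species' genes that belong to an
implicated family *and* themselves carry such an EC; `family_wide=True`
counts every member instead, since the published counting rule is not printed
and per-gene EC tables make the strict reading the safer default. Merged
categories (e.g. "6.2.1.1/2/3" for the acyl-CoA synthetases of different
chain-length specificities) are first-class: the category map is many-to-one.
Species totals count distinct genes once. Display export clips at 15 genes
(heatmap color saturation); stored counts are untouched.

## Concordance

TP/FP/TN/FN are named with respect to the prediction: TP = predicted
degradable and growth observed, TN = neither. Compounds with no pathway
annotation at all count as predicted-non-degradable (`exclude_unannotated`
drops them instead). Ratios with zero denominators are NaN, never 0.
Delta-by-refinement is refined − initial per metric and requires equal
compound sets.

## Synthetic generators

All generators take a seed and are bitwise deterministic.

* `simulate_genome_pair` plants non-overlapping complete ORFs (ATG start,
  TAA/TAG/TGA stop, length 300–900 in multiples of 3, both strands, ≥ 60 bp
  spacing) in a uniform-random reference, then applies substitutions
  (per-base rate), indels (per-base rate, lengths 1–10), inversions and
  translocations on mutually non-overlapping intervals (uniform, resampled up
  to 100 times, then an error; default lengths 500–5,000, configurable — use
  > 10,000 to guarantee chains cannot bridge a rearrangement), and finally
  fragmentation into scaffolds. Events are logged in application order, with
  substitution/indel intervals on the original reference frame and
  rearrangement intervals in the evolving derived frame; replaying the log
  reproduces the derived scaffolds exactly. The truth records every reference
  position's image (or deletion) and, per gene, its image interval plus two
  flags: `disrupted` (image scattered more than twice the gene length —
  a breakpoint passed through it) and `intact` (contiguous, length-preserving
  image; substitutions only). Exact-recovery statistics are computed over
  intact genes, since a gene hit by an indel has no single true coordinate
  image to recover.
* `simulate_plate_screen` emits one plate per species and replicate with all
  compounds plus six inoculated no-carbon wells, and one uninoculated plate
  with the same layout. Expected reading = plate offset (per-plate Gaussian
  scatter, sd 0.02) + per-compound chemical background (sd 0.05, identical on
  inoculated and uninoculated plates) + inoculum baseline 0.1 (inoculated
  wells) + growth amplitude × t/96 for true-growth wells; noise is Gaussian,
  truncated at zero because plate readers report non-negative absorbance.
  The default truth mirrors the study conditions: four species and 190
  compounds split 64/38/71/17 over carboxylic acids, nitrogen-containing
  compounds, carbohydrates and alcohols, and oligosaccharides, with growth
  truth drawn at 0.45 per species — near the screen-wide positive fraction.
  The generator does not model growth kinetics (lag/rate), well-position
  effects, or cross-well contamination, so passing tests certify the
  normalization and calling arithmetic, not robustness to those artifacts.
* `simulate_similarity_graph` draws a planted-partition graph: within-block
  edges (probability `p_within`) get e-values log-uniform in [1e-50, 1e-10]
  (always past the downstream filter) and 40–100% coverage; between-block
  edges get [1e-9, 1e-6] and 15–60%. Each unordered pair is emitted once.
* `simulate_predictions` flips each non-growth compound to
  predicted-degradable with probability `fp_rate` and each growth compound to
  predicted-non-degradable with probability `fn_rate`.

## Problem sizes and defaults in the analysis scripts

The analysis drivers and the acceptance script use a 60 kb reference with 12
genes (1% substitution divergence, one inversion and one translocation above
the 10 kb gap allowance, 2–4 scaffolds), the 190-compound four-species screen
with noise sd 0.02 and growth amplitude 0.6, a 5 × 6-gene planted-partition
graph, and 190-compound prediction tables (initial fp/fn = 0.35/0.30, refined
0.20/0.15) plus a 10,000-compound table for rate-recovery estimates. These
sizes exercise every code path while keeping a full run within seconds.

## Known limitations

* The anchor finder is O(genome × anchors) Python; it is meant for desk-scale
  genomes (≲ a few Mb), with external aligner import as the escape hatch.
* Greedy chaining is not a global optimum; on interleaved same-strand blocks
  closer than the gap allowance, assignment follows the documented tie rules
  rather than a maximum-weight chaining.
* Liftover assumes intronless genes and does not use protein-level
  homology evidence (domain hits, best database matches) in reconciliation.
* The growth model treats replicate wells as exchangeable and time as a
  linear ramp; the 44 h and 72 h columns are carried through normalization
  but only 96 h enters the growth call, matching the published rule.
* MCL is dense-matrix; fine for the few-hundred-gene graphs targeted here,
  not for proteome-scale clustering.
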