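# Methods

This note documents the models and procedures the package implements,
the parameters that matter and why their defaults are what they are,
what the synthetic-data generators emulate (and do not), and the
numerical and design choices made where the procedure left room.

## Scaffold ordering by homology consensus

### Model

A fragmented assembly is ordered against `n` reference genomes (default
4, mirroring a four-species comparison: a lizard, a bird, and two
mammals at increasing distance). The assumption is that over
super-scaffold scales, genome rearrangement between the target lineage
and at least `k` of the `n` references is rare enough that the order and
orientation of two neighbouring scaffolds is conserved; requiring
agreement of `k = 3` distinct references makes a single lineage-specific
rearrangement (or a spurious paralogous alignment in one reference)
unable to create a false join.

### Stages and parameters

1. **Block filtering** (`alignment.filter_blocks`): scaffold-side span
   ≥ `min_span` (2000 bases, inclusive) and symmetric span ratio
   `max(ref/scaf, scaf/ref)` strictly below `max_expansion` (10).
   The scaffold-side span is used because it is the one coordinate
   system shared by all four comparisons.
2. **Smoothing** (`alignment.smooth_blocks`): within one
   (scaffold, reference), ordered by scaffold start, a block shorter
   than `smooth_max_span` (10 kb) is removed when it is the single
   consecutive block to its chromosome and both immediate neighbours
   agree on one different chromosome. "A large block of separate
   alignments" is not quantified upstream; we operationalize it as ≥ 1
   same-chromosome block on each side (`smooth_min_flank_blocks`,
   configurable). Removals are decided simultaneously against the input
   neighbourhood, which makes the pass idempotent.
3. **Placement** (`ordering.place_scaffolds`): per (scaffold,
   reference), aligned bases are summed per chromosome; the scaffold is
   placed only if the top chromosome holds ≥ `min_place_fraction`
   (0.6) of them. The threshold must exceed 0.5 so the majority
   chromosome is unique; 0.6 additionally rejects borderline split
   alignments. Position is the floor-midpoint of the union span;
   orientation is the strand carrying the majority of aligned bases.
   The single-position-per-reference convention is ours: the upstream
   procedure never states how a scaffold is reduced to one coordinate.
4. **Adjacency derivation and voting**: consecutive placements per
   (reference, chromosome) give ordered, oriented pairs, canonicalized
   (lexicographically smaller id first; a relation and its
   reverse-complement are the same relation) and merged across
   references. Ties at identical positions are broken
   lexicographically and logged. `vote_adjacencies` keeps relations
   with ≥ `min_support` references. No cap is placed by default on the
   reference distance between adjacent scaffolds
   (`max_adjacency_gap=None`): dropped or unplaced scaffolds then
   simply make their neighbours adjacent, which is the desired
   behaviour for path building.
5. **Group linking** (`ordering.build_groups`): each scaffold is a
   segment with two ends; a relation joins one specific end of each
   (orientation decides which). Relations are admitted greedily in
   decreasing (support, weight) order — weight being the summed aligned
   bases of the participating placements — so when two relations
   compete for one scaffold end the better-supported one wins and the
   loser is dropped with a warning. Accepted links form simple paths
   and cycles; a cycle (which cannot be linearized) is broken at its
   weakest link. The greedy path cover is our choice: upstream, orders
   are only said to be "linked into groups". Groups are emitted in a
   canonical direction (first member id ≤ last member id) so output is
   byte-stable.
6. **AGP** (`ordering.write_agp`/`read_agp`): AGP v1.1 component lines
   (`W`) with 1-based inclusive coordinates and consecutive part
   numbers, interleaved with `U` gaps of `gap_length` (default 100)
   typed `contig` with linkage `no` — homology ordering has no spanning
   clone, and no gap-size estimate, so the 100-base gap is a
   conventional placeholder. The reader validates coordinate
   continuity and part numbering, and tolerates (but flags) `yes`
   linkage.

### QC statistics

`est_coverage_fraction` computes the fraction of ESTs whose aligned
fraction reaches a threshold (inclusive, default 0.5).
`phred_error_rate(q) = 10^(−q/10)` converts Phred quality to an error
probability (Q40 ↔ 10⁻⁴).

## Read-consensus indel polishing

A pileup summary (the TSV dialect in `polish.py`) is the contract
boundary; alignment, duplicate-read removal and pileup summarization
are upstream. A site is edited iff its indel is 1–2 bp and the reads
are unanimous with depth strictly between 3 and 200, mapping quality
strictly above 40, and the indel strictly more than 10 bases from the
alignment end. All four thresholds are exclusive, exactly as stated.
Because the per-read phrasing of the quality and distance conditions is
ambiguous, the site fields store the minimum over supporting reads, so
the site-level test is the conservative reading (every read must
qualify). Colliding calls at one position are all rejected, with a
warning. Edits are applied from the highest coordinate down so lower
coordinates stay valid; the test suite checks equivalence against an
independent left-to-right applier with offset tracking.

## Clean-ortholog screen

The four conditions are evaluated from per-model alignment evidence:

- `single_chain`: exactly one covering chain in the syntenic or
  reciprocal-best net;
- `no_significant_gaps`: no single gap run > `max_gap_run` (90 bases)
  and total gaps ≤ `max_gap_fraction` (20%) of the CDS. Neither bound
  is quantified upstream; 90 bases (30 codons) and 20% are our
  defaults, both configurable, judged over exonic alignment gaps;
- `frameshifts_ok`: the cumulative frame offset mod 3 must return to
  zero within `frameshift_window` (30 bases) of the event that
  displaced it. Judging the cumulative offset — rather than matched
  +k/−k pairs — accepts compensation distributed over several indels;
- `elements_preserved`: no donor, acceptor, start or stop marked lost
  (not-applicable statuses, produced by trimming, do not fail).

Per gene, among models clean in the focal species, the winner maximizes
(number of species clean, CDS length, model id). Incomplete variants
trim ⌊0.1 × CDS⌋ bases from each end, rounded down to a codon boundary
so frame logic stays valid; start/stop become not-applicable and event
coordinates shift accordingly.

## GC landscape

Window GC is computed over non-N bases; windows with more than
`max_missing` (20%) N are excluded and counted — the 80%-complete-data
convention — and the trailing partial window is discarded. SD profiles
use the population SD (the windows are the population of interest, not
a sample; configurable by computing on `GCProfile.values` directly).
The homogeneous-genome yardstick is the iid closed form
`expected_sd = sqrt(p(1−p)/w)`, which halves exactly per quadrupling of
`w`. GC3 is the GC fraction over third positions of complete codons,
N excluded from both counts. The dN/dS partition splits at the
within-taxon median GC3 with ties to the low group and applies a
two-sided Mann–Whitney U test — exact when min(n, m) ≤ 8 and tie-free,
mid-rank asymptotics otherwise; fully tied data short-circuits to
p = 1. Equal-count binning pools GC as the length-weighted mean.
Gene-versus-flank GC uses the Pearson coefficient (the upstream
description names no statistic; Pearson on GC fractions in the observed
0.3–0.7 range is standard practice).

## Selection statistics and gene families

For a parameter pinned at the boundary of its space under H0 the LRT
statistic is asymptotically a 50:50 mixture of a point mass at zero and
χ²₁, so `mixture_pvalue(T) = 1` at `T = 0` and `0.5·erfc(sqrt(T/2))`
otherwise (the erfc identity for the χ²₁ upper tail; no table lookup).
`simulate_boundary_lrt` validates this with the canonical boundary
problem (normal mean, H0: θ=0 vs θ≥0, known unit variance), where
`T = max(0, Z)²`. BH q-values come from statsmodels' step-up
implementation behind the `bh_fdr` surface; the default significance
threshold is FDR < 0.1. The likelihood machinery that produces T is
deliberately out of scope — statistics enter via TSV.

The normalized bit-score distance is `1 − min(s′ᵢⱼ, s′ⱼᵢ)/max(s′ᵢⱼ,
s′ⱼᵢ)`: the min/max orientation is the evident intended normalization
(a max/min ratio would make the distance non-positive whenever the
scores differ). Family collapse finds a maximum-cardinality subset with
no pair strictly above 97% amino-acid identity — exact subset search up
to 15 members (deterministically the lexicographically smallest
optimum), a degree-greedy heuristic above that, flagged approximate.

## Synthetic data: what it emulates, and what it does not

- `make_truth_set` fragments a uniform-composition ancestral genome at
  uniform breakpoints into randomly oriented, shuffled scaffolds, and
  derives each reference by Poisson(rate × Mb) inversions and
  translocations of uniformly chosen 1–100 kb segments with ±5%
  per-segment span jitter. There is no substitution or small-indel
  divergence along branches — the ordering rules only see block
  coordinates, so rearrangement and span noise are the relevant axes.
- `simulate_alignments` emits each scaffold's exact image per reference
  (one block per overlapped rearrangement segment), drops blocks with
  probability `drop_rate`, scales reference spans by `expansion_jitter`,
  and adds Poisson(`spurious_rate`) short (<10 kb) blocks per scaffold
  on decoy chromosomes (`chrU*`). Alignment noise statistics are
  free knobs, not estimates: nothing upstream quantifies them.
- `simulate_pileup` gives every true indel unanimous passing evidence
  (depth 4–199, MAPQ > 40, distance > 10) and every noise site a
  violation of exactly one criterion, so the caller can be scored with
  single-factor coverage. Real pileups violate criteria jointly; the
  single-factor design is for oracle sharpness, not realism.
- `simulate_gene_models` implants at most one defect per model; the
  label records the one condition the screen must fail (compensated
  frameshifts within the 30-base window are labeled clean). Premature
  stops are represented as a lost stop-codon element in the evidence
  schema.
- `simulate_gc_genome` draws bases iid (homogeneous) or per-block GC
  from gc ± spread (blockwise) — a caricature of isochores with sharp
  block edges, sufficient to show the variance floor that breaks the
  SD-halving law.

Passing tests on these fixtures shows the rules are implemented as
specified and recover implanted structure exactly; it does not show
robustness to correlated real-data pathologies (paralogous alignment
blocks with high scores, segmental duplications, GC-biased read
coverage).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use a 20-Mb genome for GC-SD
scaling (≥ 1000 windows at the largest scale keeps the SD estimate
within ~2% relative error), 1-Mb/20-scaffold/4-reference truth sets
over 20 seeds for ordering recovery, ≥ 1000 pileup sites, 500 gene
models, and 10,000 boundary-LRT replicates — sizes at which the
binomial/KS acceptance bands are comfortably narrower than the effects
checked. Every generator is a pure function of its arguments including
the seed (numpy `default_rng`); `--seed` drives all derived seeds,
kept below 2³¹.

## Known limitations

- The ordering stage uses no read-pair or physical-map evidence and
  estimates no gap sizes; the 100-base AGP gap is conventional.
- The greedy path cover is not a global optimum over conflicting
  relation sets; with `k = 3` of 4 conflicts are rare by construction.
- The screen's gap thresholds (90 bases, 20%) are package defaults,
  not community standards; sensitivity to them is not explored.
- `collapse_family` above 15 members is heuristic (flagged).
- PSL ingestion maps only the fields the pipeline uses (strand,
  matches, query/target spans); block-level PSL detail is ignored.
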