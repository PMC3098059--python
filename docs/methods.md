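# Methods

## Coordinate model

All internal coordinates are 1-based and closed on both ends, the GFF
convention; a width-1 interval has `start == end`. BED's 0-based half-open
coordinates are converted at the parser (`start = chromStart + 1`,
`end = chromEnd`) and converted back on write, so round trips are exact.
Chromosome names are compared by exact string equality — no `chr`
aliasing, because silent aliasing hides input mistakes; rename before
loading if two sources disagree.

Strand is `+`, `-` or `*` (unstranded). Input tokens `1`/`-1` (numeric
convention) and `.` (GFF placeholder) are canonicalized on read. Peaks are
treated as unstranded everywhere; features must be stranded wherever a TSS
is involved, and unstranded features are rejected with their names rather
than silently skipped.

The gap between two regions is the number of bases strictly between them:
0 for intersecting *or abutting* closed intervals, `+inf` across
chromosomes. "Overlap under maxgap g" means `gap ≤ g`; consequently
`maxgap = 0` includes abutting intervals. This is the only self-consistent
reading once gap 0 is defined as touching, and it is applied uniformly in
annotation, pair finding and component merging.

## Nearest-TSS annotation

The TSS of a feature is its 5' end (start on `+`, end on `-`). The signed
distance from a peak to a feature is `peak.start − TSS` on `+` and
`TSS − peak.start` on `-`: negative values mean the peak start lies
upstream of the TSS in the gene's orientation. The anchor is deliberately
the peak *start*, not the midpoint — the convention under which the worked
example's distances (−5, −1, +216) are exact; a midpoint option was
considered and left out of v1 to keep one documented convention.

`annotate_peaks` supports three outputs: `nearest` (argmin of |distance|
per peak), `overlapping` (all features with `gap ≤ maxgap`, or only the
closest when `multiple=False`), and `both` (nearest rows plus overlapping
rows whose feature is not already the nearest, so a feature that is both
appears once, tagged `NearestStart`). Ties in the argmin are broken by
smaller |d|, then upstream (d < 0) before downstream, then lexicographic
feature name — a total, deterministic order chosen so repeated runs and
reimplementations agree; no biological claim is attached to it. Peaks with
no candidate (empty chromosome, or no overlap in `overlapping` mode) yield
a row with empty feature fields so every peak is accounted for.

The six relative-position classes partition all geometries: for a disjoint
pair, `upstream`/`downstream` in the feature's orientation; for an
intersecting pair, classification by which strand-aware boundaries the
peak covers (`includeFeature` both, `overlapStart` the 5' only,
`overlapEnd` the 3' only, `inside` neither). Exhaustiveness and mutual
exclusivity are verified by enumeration over every interval pair on a
small grid, for both strands.

A note on the mirror-symmetry property used in testing: reflecting all
coordinates through a point and flipping strands preserves every
relative-position class for arbitrary peak widths, but preserves signed
distances only for width-1 peaks — reflection maps a peak's start to its
end, and the distance is anchored at the start. The property test asserts
exactly that.

Distance histograms use strictly half-open bins `[e_i, e_{i+1})` with
explicit underflow/overflow counters (never silently merged into edge
bins), and only `NearestStart` rows with defined distances contribute.
The relative-position tally keeps all `Overlapping` rows and falls back to
`NearestStart` rows only for peaks without any overlap — an overlap is
more informative about position than a possibly distant nearest gene.

## Overlap significance

Merged peaks are the connected components of the overlap graph over all
regions of all input sets (edges where `gap ≤ maxgap`), computed by a
per-chromosome sweep that is equivalent to union-find on the full pairwise
matrix for interval graphs — the equivalence is tested against a
brute-force union-find oracle. Each component records which sets
contribute (its membership pattern) and its minimal covering span.

Venn cell counts are per component: one component, one count, regardless
of how many regions each set contributed (`count_mode="set1"` instead
counts the regions of the lowest-indexed participating set, for users who
want per-peak tallies). Component counting is the default because a Venn
diagram displays one count per diagram region, and components are the only
unit common to all sets.

The pairwise test between sets i and j recomputes components on those two
sets alone — so a 3-set report agrees exactly with its 2-set projections —
and takes `n_i` = components involving set i, `k` = components involving
both, `p = P(X ≥ k)` with `X ~ Hypergeom(total_test, n_i, n_j)`.
`total_test`, the number of potential peaks in the genome, is a required
user input (e.g. 1580 candidate sites in a yeast dataset); estimating it
from genome size would smuggle a model assumption into a reported p-value.
The tail is evaluated by scipy's hypergeometric survival function (exact,
log-space internals); p is non-increasing in k and non-increasing in
`total_test` — a larger universe makes a fixed overlap more surprising.

Null calibration is checked on a slotted design: two sets sample `m` of
`S` non-overlapping slots without replacement, making the component
overlap count exactly `Hypergeom(S, m, m)`; with `total_test = S` the
p-values are then provably super-uniform, and the test verifies
`P(p ≤ α) ≤ α + 2·SE` over 2000 replicates at α = 0.01 and 0.05.

## Sequence extraction

Fetch regions are `[start − upstream, end + downstream]` clipped silently
to `[1, chromosome length]`; clipped peak names are logged at INFO. Peaks
are unstranded, so sequences always come from the forward strand (a
reverse-complement option is reserved but off in v1). FASTA access goes
through pyfaidx; equivalence with naive text slicing is part of the test
suite. Output FASTA headers carry the name and the *fetched* coordinates
(`>name chrom:fetch_start-fetch_end`) so the provenance of a clipped
sequence is visible, and the file re-loads as a genome for round-trip
checking.

## GO enrichment

Per aspect (BP/MF/CC): the universe N is every gene with ≥ 1 annotation in
that aspect — a genome-wide background; sample genes absent from the
universe are dropped from n and logged, not errored, since peak-adjacent
genes legitimately include unannotated ones. Terms with genome-wide count
`K < min_go_term` are removed **before** BH adjustment (the removal
changes the number of tests m); `max_p` then applies to the adjusted
p-value when adjustment is on, to the raw one otherwise. BH is applied
within each aspect separately, matching per-category reporting. Genes are
counted once each, however many peaks hit them. Term propagation along
is_a edges is opt-in (supply an edges file); default is direct annotations
only, because hierarchy snapshots vary between GO releases and a
propagation the user did not ask for makes results irreproducible across
snapshots. Cycles in the supplied hierarchy are detected and rejected.

## Synthetic data generator

One integer seed drives independent substreams (fixed
`SeedSequence(seed, spawn_key=(stream,))` per generator), so identical
specs are byte-identical and adding a generator cannot shift existing
outputs. Genomes are uniform A/C/G/T — adequate for exercising coordinate
arithmetic and I/O, *not* for motif statistics, GC bias or repeat
structure; passing sequence tests says nothing about those. Gene models
are non-overlapping single-interval genes (no exons/UTRs) with uniform
lengths in a configurable range and a `min_gene_gap` spacing floor; the
floor exists so planted-offset fixtures can guarantee (spacing ≫ offset)
that the planted gene is provably the nearest TSS, making the recovery
test exact rather than probabilistic. Defaults (2 × 100 kb chromosomes,
100 genes of 0.5–2 kb, 50 peaks of 100–400 bp, 30 GO terms at annotation
probability 0.1) sketch a yeast-scale experiment compactly enough that
brute-force oracles run instantly.

`planted_offset(d)` places each peak start exactly d bases 5' of a random
gene's TSS (strand-aware), resampling the rare draw that would fall off
the chromosome; `planted_overlap(f, S)` makes exactly `round(f·n)` peaks
intersect the partner set and rejection-samples the rest until they
neither intersect nor abut it. What these fixtures do not emulate: peak
width/score distributions of real callers, clustered binding, chromatin
context — so passing tests demonstrate algorithmic correctness, not
biological realism.

## Numerical and degenerate-input choices

Hypergeometric preconditions (`k ≤ min(n1,n2)`, set sizes ≤ universe) are
errors, never clamped — a violated precondition means the caller's counts
are wrong and a clamped p-value would hide it. `P(X ≥ 0)` is returned as
exactly 1.0. Empty region sets are valid containers but rejected where an
operation needs content (annotation, enrichment). Duplicate names within a
set are errors because joins are keyed by name. Parse errors always name
the file and 1-based line number.

## Known limitations

Venn reports support 2–3 sets only. No BAM/BigBed/VCF input, no on-line
annotation retrieval, no motif discovery (only its FASTA input), no
graphical rendering (counts and tables are the output; any plotting layer
can consume them). The hypergeometric overlap model conditions on
`total_test` being meaningful; for genomes where "potential peaks" is
ill-defined, the p-values inherit that ambiguity.
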