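# Methods

This note records the models, conventions, parameter choices and known
limitations behind `snarlmap`. It is the place to look when a default
seems arbitrary or a behavior surprising.

## Graph model and conventions

A variation graph is a bidirected graph: nodes carry non-empty DNA
strings over {A,C,G,T,N}, edges join node *sides* (left/right), and a
valid walk enters and exits opposite sides of each node, spelling the
node sequence forward or reverse-complemented. Walks are stored
explicitly (GFA P/W lines) rather than in a compressed haplotype panel;
an optional `prune_unsupported_edges` drops edges no walk uses, matching
the convention of formats in which the stored walks implicitly define
the edge set. All offsets are 0-based and all intervals half-open —
including GAF output. N bases are allowed and mismatch everything,
including N.

## Snarl decomposition

Boundary pairs are *defined*, not constructed: a pair of node sides is
separable when cutting both nodes into their component sides leaves the
subgraph between them disconnected from the rest, and minimal when no
interior side is separable with either boundary. The decomposition
enumerates candidates by bridge analysis of the biedged (side) graph —
for each node `u`, the node edges of the other nodes merge the
adjacency components into a multigraph, and a pair `(u.*, v.*)` can only
be separable when `v`'s node edge is a bridge there — then verifies
every candidate against the definitions directly. This is O(n²) with
small constants and is correct by construction; the test-suite
cross-checks it against a fully brute-force scan.

The decomposition is not unique: any site of variation can also be
viewed from its *mirror* boundaries, which delimit the rest of the
graph. The canonical choice here sorts candidates by (content contains
a dangling chain end; boundaries on the same side type; content size;
boundary sides) and greedily keeps candidates compatible (properly
nested or disjoint) with all kept so far. Mirror views enclose the
component's tips or use same-sided boundaries, so the natural serial
form wins wherever one exists; in circular components, where the mirror
ambiguity is genuine, the tie falls to boundary-side order. Cyclic
chains (circular components, or the triangle-like cases where every
pair is a trivial snarl) are represented with one extra snarl closing
the chain. No claim is made that this tree equals the output of other
toolkits' snarl finders — only that every emitted snarl satisfies the
definition and that nodes and edges partition correctly.

Pathological side graphs (e.g. two dead-end spurs hanging off one node
side) can admit no separable-minimal pair at all; leftover nodes then
become singleton root chains and any uncoverable edges are recorded on
the tree rather than silently dropped. Haplotype-built graphs do not
produce these.

## Minimum-distance index

`min_distance(a, b)` counts bases strictly between two positions over
walks that read `a` (in its orientation) and later read `b`: 0 for
adjacent bases, 0 for the identical position, infinity when
unreachable. The strictly-between convention keeps the chaining gap
arithmetic sign-consistent; start-to-start distance is this value plus
one.

Construction is bottom-up over the snarl tree. Each snarl stores a
small state graph over its boundary sides and the outer ends of its
child chains, with each child chain entering as a 2×2 transit matrix —
through-distance plus same-end return distances, finite only when the
child contains an inversion or loop. Each chain stores prefix sums of
item lengths and snarl through-distances plus the positions where a
walk can reverse direction (snarls with finite same-side return, cyclic
closures, end self-loops); straight runs then cost O(1), and routing
with reversals folds a precomputed all-pairs matrix over the handful of
reversal states. Because a finite straight route can never be beaten by
a bounce detour (all costs are non-negative), the common case touches
no search at all.

Queries lift both positions toward the root, proposing a candidate at
every common ancestor; paths that leave a structure and return are
accounted at the parent level, so results are exact — on every random
graph tried, equal to a Dijkstra oracle over the oriented-base graph
for all position pairs. Cycles are not unrolled here; the index must be
exact so it can anchor the zip-code layer. Infinity is `math.inf`,
never a magic number.

## Zip codes and zip code trees

A zip code is the snarl-tree ancestry of a position: chain item indices
(node items at 2i, snarl slots at 2t+1 so they interleave correctly),
snarl child ranks, and a final chain-direction base offset. Sorting by
this key groups seeds by shared ancestry and orders them along chains
without touching the graph.

A read's seeds build one tree per connected component *and traversal
direction* (the reverse view is the mirrored order), since a read can
map to either strand. Seeds whose position can reach itself (finite
loop distance) are duplicated once, block-wise, approximating one
unrolling of the cycle: a read can then chain through a tandem
duplication twice. Deeper repeats rely on chaining across the
duplicated copies. Predecessor iteration walks earlier occurrences
(nearest first), computes the exact index distance, skips unreachable
pairs, and stops after a lookback budget (500 candidates by default at
the API, 64 in the mapping pipeline) or a scan window of 4× that;
distances are emitted in non-decreasing order within the examined band.
Because the distances come from the exact index, the "approximation" of
the unrolled view costs nothing in accuracy — only the second unrolling
bound and the lookback window are approximations.

## Seeding

Minimizers are (w,k)-minimizers of the haplotype walk sequences, both
strands via canonical 2-bit packing, hashed with a fixed splitmix64
finalizer (constants in `seeds.py`) for reproducibility. K-mers crossing
node boundaries are indexed by walking the haplotype sequence, so seeds
may start mid-node and span edges; duplicate occurrences across
haplotypes sharing nodes are stored once per graph position. Defaults
k=29, w=11 follow common long-read minimizer practice; k ≤ 31 so a
k-mer packs into a 64-bit word.

Selection weights each read minimizer that occurs in the graph by
(1+count)^-0.8, processes them in decreasing weight, skips minimizers
over the hard hit cap (500) while still counting their weight as
processed, and stops once 90% (`score_fraction`) of the total weight is
processed. Two deliberate details: minimizers absent from the graph
(sequencing errors, novel sequence) are excluded from the weighting
entirely — otherwise they dominate the budget and starve real seeds —
and ties in weight break on the hash, not the read offset, so any
dropped fraction scatters evenly along the read instead of truncating
one end. Raising the hit cap can only add seeds (monotonicity is
tested).

## Chaining

An anchor chain has strictly increasing read starts and finite graph
distance between consecutive anchors. Score: newly covered read bases
(overlaps don't double-count: min(k, read-distance)) times a match
bonus of 1, minus a gap cost on g = |read distance − graph distance|
of 0 for g = 0 and `0.01·k·g + 0.5·log2(g)` otherwise. Pass 1 links
anchors within 60 bp gaps (read and graph) into fragments — extracted
as disjoint best-first tracebacks of the DP — and pass 2 links whole
fragments within 10 kb gaps. Up to 4 non-duplicative chains survive to
extension; ties break by score, then leftmost read start, then graph
position. With both passes given equal limits the result is optimal —
equal to exhaustive enumeration over all ordered anchor subsets in 500
randomized trials.

## Extension

Per-link alignment tries the haplotype strings spelled between the
anchors (up to 16 distinct local walks, enumerated from an occurrence
index over the walks and their reverses) under an exact gap-affine
wavefront aligner. WFA works in a doubled-cost transform (mismatch
2(A+X), gap-open 2O, extend A+2E) so score maximization becomes cost
minimization; its score budget failure is a value, not an exception,
and triggers the banded fallback, as does any link beyond the
configurable length ceiling (2^16 bases at desk scale — the ceiling
exists so that enormous problems go to the banded aligner by policy).
The banded aligner runs column-wise over (graph-bases-consumed,
position) states, unrolling cycles implicitly, with band width 64
doubled once on failure. Tails use the same engine with X-drop pruning
(x=100) instead of a band, soft-clipping whatever cannot be extended.
Anchor k-mers are exact matches by construction; overlapping anchors
are trimmed, and an anchor whose trimmed link cannot be aligned (an
allele conflict) is dropped rather than failing the chain, up to a
quarter of the chain.

Scoring defaults (match 1, mismatch 4, gap open 6, extend 1) are the
conventional short-read-aligner matrix; every reported score is
recomputable from the CIGAR and tested to match.

## MAPQ

`60 · (primary − secondary) / (primary − min_possible)`, rounded,
clamped to [0, 60], with 60 when no secondary placement exists.
"Secondary" means the best alignment not sharing ≥ 50% of its graph
interval with the primary — two chains over the same locus are one
placement, not competition. A read whose primary score falls below 10%
of the perfect score is reported unmapped. Calibration is validated
empirically: on the synthetic benchmark below, the error rate among
MAPQ-60 reads stays within 1%.

## The simulator, and what passing it does (not) show

`simulate_graph` applies non-overlapping events — SNPs, geometric-length
indels, inversions (traversable both ways), tandem duplications (a back
edge, haplotypes may traverse twice) — to a uniform random backbone and
threads a reference plus haplotype walks through per-haplotype allele
choices (alt frequency 0.5). `simulate_reads` samples uniformly over
haplotype positions and strands and injects independent per-base
substitution/insertion/deletion errors; two presets mirror current
long-read technologies: hifi-like (0.5% total error) and ont-like (5%).
Correctness of a mapping is ≥ 50% overlap between the reported and true
graph intervals (configurable).

The benchmark conditions are a 100 kb backbone, 20 haplotypes, SNP rate
10⁻³, indel rate 2·10⁻⁴, one 300 bp inversion and one 300 bp tandem
duplication, with 1000 reads per error preset of 1–10 kb (uniform), at
fixed seeds; the acceptance script uses 400 reads per preset. These
sizes keep a full run in minutes on one CPU while still exercising
strand choice, allele choice, SV traversal and repeat ambiguity.

What this does *not* emulate: learned error profiles (homopolymer
biases), context-dependent error rates, chimeric reads, overlapping or
nested SV events, near-identical segmental duplication families at
human scale, or reference bias in graph construction. Accuracy numbers
on this simulator therefore bound the easy part of the problem; they
demonstrate the algorithms are correct and calibrated, not that
real-data accuracy matches any published tool.

ROC-shape checks bin MAPQ into [0,10), [10,30), [30,60), {60} and
require the per-bin error fraction to be non-increasing over bins
holding at least 20 reads — sparser bins are noise.

## Numerical and degenerate-input choices

* Distances and scores are integers (floats only for chain scores and
  infinities); WFA's doubled-cost transform keeps everything integral.
* Reads shorter than k seed nothing and are unmapped, not errors.
* Empty link queries between adjacent anchors contribute empty ops.
* Deterministic tie-breaks everywhere: sorted node ids, lexicographic
  chain direction, hash-ordered minimizer ties, leftmost-read-start
  chain ties. Two runs with the same inputs produce byte-identical GAF.
* The mapper is single-threaded; `--threads` is accepted for interface
  compatibility and ignored.

## Known limitations

* Snarl-tree shape (not correctness) can differ from other tools',
  especially around mirrors in circular components.
* The zip-code layer unrolls each cycle once; a read traversing a
  tandem array more than twice chains across copies rather than within
  one unrolled view.
* Haplotype-inconsistent chains are not penalized (no recombination
  scoring); paralog-crossing chains rely on the gap cost alone.
* Paired-end rescue, surjection to linear references, and BAM output
  are out of scope.
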