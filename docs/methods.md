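# Methods

This note documents the models behind each stage of `phylodisco`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that make results
deterministic.

## Multispecies coalescent simulation

Gene trees are simulated on a rooted species tree whose branch lengths are
expressed **directly in coalescent units** (one unit = 2N generations).
There is no separate bookkeeping of effective population sizes or generation
times: only topology frequencies matter downstream, and those depend on
branch lengths in coalescent units alone. One haploid lineage is sampled per
species. Within each species-tree branch, the k lineages present coalesce
with exponential waiting times at rate k(k−1)/2 per unit; lineages still
distinct above the root coalesce in an unbounded root branch. Gene-tree
branch lengths are emitted in coalescent units; sequence simulation rescales
them by a per-site substitution rate, which decouples the ILS level from
sequence divergence.

The expected frequency of the concordant rooted triplet around an internal
branch of length T is 1 − (2/3)e^(−T) (each discordant triplet
(1/3)e^(−T)); the simulator is validated against this closed form at
T ∈ {0, 0.5, 2} with 10,000 loci and a three-binomial-standard-error
tolerance, and the same check is applied end-to-end through the discordance
tally.

Missing taxa are dropped independently per leaf per locus with a fixed
probability. Loci reduced below four leaves are retained but flagged
uninformative, matching the pruning behaviour of the quartet tally, which
simply finds no usable quartets in them. Non-ultrametric species trees are
accepted (branch lengths are treated as durations), but node heights are
reconstructed as the maximum root-ward accumulation over children, so
ultrametric input is the intended case.

The generator deliberately implements ILS only. Real data from groups with
rampant hybridization also contain reticulate signal; no migration or
network model is included, so recovery results on synthetic data say nothing
about robustness to gene flow. There is likewise no indel or read-level
simulation.

## Sequence simulation

Jukes–Cantor: the root sequence is uniform over {A,C,G,T}; along a branch of
d expected substitutions per site each site changes with probability
(3/4)(1 − e^(−4d/3)), uniformly to one of the other three bases. The
two-leaf divergence proportion is tested against the closed form at
d = 0.1 over 100,000 sites.

## Support collapsing

Supports follow the IQ-TREE convention: a numeric internal-node label is the
support of the edge above that node. `collapse_low_support(tree, s)`
contracts internal edges with support strictly below `s` (the common reading
of a "collapse unsupported branches at 10" rule on a 0–100 bootstrap scale);
an `inclusive` flag switches to ≤ for pipelines that intend the boundary the
other way. Edges without a numeric label are never collapsed. Collapsing
can only create polytomies — it never changes the leaf set and never adds
edges — and can only reduce the number of resolved quartets downstream.

## Quartet species trees and per-branch discordance

Quartet frequencies are computed ASTRAL-style over quadripartitions rather
than via cluster-monophyly tests: for an internal branch with adjacent
clusters A, B (below) and C, D (the rest), every quartet drawn one leaf per
cluster — restricted to the leaves present in each gene tree — is classified
by its induced topology, and unresolved quartets (polytomies after
restriction) are excluded from the denominator. This definition remains
well-behaved when clusters are not monophyletic in a gene tree and when taxa
are missing. Gene trees are used unrooted throughout; the tally is invariant
to their rooting and ordering. When a branch implies more than 10⁶ quartets
in total, 10⁵ quartets are subsampled uniformly (tree chosen proportional to
its quartet count) with a recorded seed; the Monte-Carlo error at that
sample size is below the reporting precision.

Internally, trees are encoded as bitmask bipartition lists over a shared
taxon registry; a quartet resolves by finding any split that isolates
exactly two of its four taxa. The same encoding drives the quartet score
(total agreement count between a candidate topology and the gene trees,
equal weight per tree), which is checked against a string-based nested-loop
enumeration.

Species-tree search is exhaustive over all unrooted topologies for up to 7
taxa ((2n−5)!! ≤ 945) and otherwise NNI hill climbing (first pass with no
improving move stops the climb) from a neighbor-joining starting tree plus
three random restarts by default. The NJ starting matrix is the mean
normalized topological (path-edge) distance between taxa across gene trees,
each tree's paths normalized by its diameter — a deliberately cheap
supertree-style seed; the exhaustive oracle at six taxa bounds the loss of
the local search in tests. Ties anywhere in the search are broken by the
lexicographically smallest canonical Newick string, making inference
deterministic.

A branch is labelled `single_dominant` when exactly one of its three
frequencies exceeds the threshold (default 1/3, the value all three take
under complete signal loss), `contested` when two or more do, and
`uninformative` when no quartets resolve. The summary reports the count and
percentage of single-dominant branches among informative internal branches.

## MinHash sketching and Mash distances

Each k-mer (default k = 21, skipping windows containing N) is replaced by
the smaller of itself and its reverse complement, 2-bit packed, and hashed
with a seeded SplitMix64-style 64-bit finalizer (default seed 42). A sketch
keeps the s = 1000 smallest distinct hash values. Any fixed, documented
64-bit hash works for this purpose; the finalizer was chosen because it is
trivially vectorizable and has no dependencies. Jaccard similarity is
estimated from the s smallest values of the merged hash sets, and converted
to distance by d = −(1/k)·ln(2j/(1+j)), capped at 1.0 when j = 0 so NJ
input stays finite. Raw reads and assemblies are treated identically; a
`min_kmer_count` flag (default 1, i.e. off) drops low-copy k-mers as a crude
error filter for read input. Sketching is order- and strand-invariant and
bit-reproducible; estimates are validated against exact canonical k-mer-set
Jaccard on small inputs and against known per-site divergences (25% relative
tolerance for d ∈ [0.01, 0.1] at s = 1000, where the binomial sketch error
dominates).

## Neighbor joining and tanglegrams

NJ is the standard Saitou–Nei agglomeration with two fixed conventions: Q
ties are broken by the lexicographically smallest pair of cluster
representative labels (the smallest leaf label in each cluster), and
negative branch lengths are clamped to zero with the deficit moved to the
sister branch. Consistency on additive matrices is tested exactly, and the
implementation is cross-checked against an independent NJ implementation on
random additive matrices.

Tanglegram leaf ordering allows internal-node rotations only. For small
trees (joint rotation space ≤ 4096 orderings per tree) the search is
exhaustive and therefore exact; larger trees use alternating barycenter
sweeps (children sorted by mean leaf position in the other tree's current
order) until no improvement, which never returns a worse ordering than the
input. The crossing count is the inversion count between the two leaf
orders.

Robinson–Foulds distances restrict both trees to their shared leaf set
first (logged), require at least four shared leaves, and normalize by
2(n−3).

## Coverage profiles and ploidy calls

Depth tables are long-format TSV (sample, scaffold, length, depth); missing
pairs become zero with a logged count, duplicates are errors. Scaffolds not
longer than 1 kb are dropped. Each sample's depths are divided by its mean
over retained scaffolds — by default **before** restriction to a
conserved-scaffold list, i.e. genome-wide normalization followed by zooming
in; a flag flips the order for pipelines that normalize within the conserved
set. Normalization is idempotent and leaves each sample at mean 1.

Samples are clustered by pairwise Manhattan (L1) distance between
normalized profiles with average linkage by default (single/complete/ward
available); sample IDs are sorted before clustering so ties resolve
deterministically. The heatmap export clips values at 2.0 for display and
orders rows by dendrogram leaves.

Ploidy rules fire in order, all thresholds configurable:

1. `diploid_like` — median normalized depth over tetraploid-only scaffolds
   < 0.25 ("no or nearly no reads mapping" on the divergent subgenome);
2. `doubled_subset` — ≥ 20% of conserved (non-tetraploid-only) scaffolds
   above 1.6 ("double the average genome coverage" on a scaffold block);
3. `tetraploid_like` — overall median within [0.5, 1.5];
4. `ambiguous` otherwise.

The synthetic coverage generator draws depths as class mean × base depth
(default 15×, a typical resequencing depth) with multiplicative gamma noise
of a given coefficient of variation. The class mean matrix is: diploid-like
(1, 0, 1), tetraploid-like (1, 1, 1), doubled-subset (1, 1, 2) over
scaffold classes (conserved_all, tetraploid_only, doubled_block). The
default genome composition is 30 conserved, 45 doubled-block and 125
tetraploid-only scaffolds — a diploid thus lacks ~60% of the reference, and
the doubled block is a minority of the genome so its normalized level stays
near 2/(1 + b) ≈ 1.8. At the reference noise level (CV 0.2) the three
classes are linearly separable and the rule set recovers ≥ 95% of truth
labels; this is a statement about the generator's geometry, not about real
mapping data, where reference divergence, contamination and low coverage
add structured noise the generator does not model.

## Consensus and alignment statistics

Consensus calling takes pre-summarized per-site majority bases with depths
(read mapping itself is out of scope); sites below the depth threshold
(default 3×, inclusive at the boundary: depth ≥ 3 is callable) become N.
Locus filtering first drops samples whose consensus is entirely N, then
loci with fewer than three usable samples.

Alignment statistics conventions (the originating GUI tools leave these
underspecified, so each is explicit and the contested ones switchable):

* mean pairwise identity — mean over unordered pairs of identical columns /
  columns where both sequences are non-gap × 100 (a mode counting every
  column, with shared gaps matching, is available);
* identical sites — strict mode requires every sequence non-gap and equal
  in the column; a lenient mode ignores gaps;
* GC content — (G + C + S) / (A + C + G + T + S) × 100: S (G-or-C) is
  fully informative for GC and counts; other ambiguity codes, N and gaps
  are excluded from the denominator;
* ambiguity accounting counts residues in {R,Y,S,W,K,M,B,D,H,V} per
  sequence, plus the number of distinct columns containing any such code
  (columns as the primary figure, residues also reported). N is missing
  data, not ambiguity, since it carries no allele information.

The ribotype-mixture generator replaces exactly n positions of a base
sequence with the two-allele IUPAC code joining the resident base and a
random distinct base, so the ambiguity count of its output is exactly n —
the invariant tying the generator to the counter.

## Determinism and problem sizes

Every stochastic operation takes an integer seed and draws from a single
`numpy` generator per invocation; identical configuration and seed give
bit-identical output, which the CLI records in per-run manifests. The test
suite and the acceptance script use desk-scale problem sizes chosen so the
statistical checks have tight expected error: 10,000 loci for closed-form
frequency checks (3 s.e. ≈ 1.4 percentage points), 300 loci × 10 replicates
for species-tree recovery, 100 kb sequences for sketch accuracy, 150
samples for ploidy recovery. The whole acceptance run takes well under a
minute on one CPU.

## Known limitations

* No hybridization/network simulation or inference; discordance is modelled
  and interpreted as ILS only.
* The quartet search is exact only to 7 taxa; beyond that the NNI climb has
  no optimality guarantee (ties and plateaus are possible on very
  discordant data).
* Mash distances assume unique k-mers dominate; repeat-rich genomes
  compress distances.
* The ploidy caller's thresholds mirror qualitative descriptions
  ("nearly no coverage", "double coverage") and are meant to be tuned per
  data set; the defaults are calibrated on the synthetic generator's
  geometry.
* Coverage analysis consumes per-scaffold mean depths; BAM parsing is out
  of scope.
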