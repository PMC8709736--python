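# Methods

## The model

`snpgraph` works with a restricted class of variation graphs: a linear
reference genome augmented with biallelic SNPs only. Each chromosome is a
chain of *chunk* nodes (reference runs of at most 32 characters, split
greedily left to right), interrupted at every SNP by a *diamond*: two
parallel one-character nodes carrying the reference and the alternative
allele, both wired to the same predecessors and successors. Node
identifiers are assigned sequentially in left-to-right reference order, so
every forward edge strictly increases the node id and the graph is acyclic
by construction. Adjacent SNP positions produce directly connected
diamonds with no intervening chunk; an SNP at a chromosome boundary simply
lacks a predecessor or successor.

Paths record haplotype structure: one path per chromosome through the
reference-allele nodes, plus two single-node paths per SNP,
`alt_<chrom>_<pos>_0` (reference allele) and `alt_<chrom>_<pos>_1`
(alternative allele). A Figure-style narrative in which one "alt path"
contains both parallel allele nodes cannot be a connected walk, so the
per-allele convention is used; it preserves the useful property that
allele membership — and therefore the whole SNP table — is recoverable
from the path set alone, which is why the GFA serialization needs no
sidecar metadata.

Coordinates follow the two conventions of the field: VCF positions are
1-based; graph offsets are 0-based and counted from the start of a node
*in the stated orientation* (offset 0 on a reverse-oriented node is the
node's last forward base). Conversions happen only at the construction
and I/O boundaries.

`N` bases are kept in nodes (the alphabet is {A,C,G,T,N}) but SNPs at `N`
positions are construction errors, patterns containing `N` never match in
the index, and reads containing `N` are rejected: the aligner is exact,
and `N` has no exact-match semantics worth inventing.

## Seed index

The full generalized-compressed-suffix-array machinery that graph mappers
use is replaced by plain dictionaries over the node sequences on both
strands, preserving only the query contract the aligner needs: locate a
pattern and report, per hit, the node id, the orientation-relative offset
and the strand flag. This is a faithful reduction at this graph class'
scale because node length is bounded by 32 and seeds only need to anchor
within (or just across) one node; cross-node matching is the extension
phase's job. Three tables are kept: a lazily built substring table for
the generic `locate()` query, and two aligner-facing tables built eagerly —
oriented node *suffixes* (length >= 2) and *full* oriented node strings
plus each node's oriented last character (for junction anchors, below).

## Aligner

Matching is exact: gap-free, mismatch-free, full read length. The search
is seed-and-extend with two hard caps: a global budget of `2 x N` probed
nodes per seed (`N` = read length) and at most 4 neighbor probes per node.
Both caps are deliberately wide: along a true walk every node consumes at
least one read character and a wrong allele branch dies on its first
character, so a correct seed needs at most `2 x N` probes even if every
node were a diamond. The budget therefore never rejects a true alignment;
it only bounds the damage of false seeds. Each probed neighbor decrements
the budget whether it matches or not, and budget is never refunded on
backtrack (the conservative reading).

**Seeding.** A seed anchors a terminal piece of the query inside a single
node such that the unmatched remainder lies entirely in the traversal
direction — forward-strand anchors extend toward increasing node ids,
reverse-strand anchors toward decreasing ids, which the id-monotone
construction makes equivalent to strand choice. Anchors are enumerated at
*both ends* of the read on *both strands* (the read and its reverse
complement are treated symmetrically), in two shapes:

* *suffix anchors*: the first `L >= 2` query characters equal an oriented
  node suffix (or the whole query lies inside one node);
* *junction anchors*: the first aligned node contributes exactly one
  character (its oriented last base, verified against a graph edge) and
  the next node matches in full.

Junction anchors are what make completeness exact rather than
approximate: a read that starts on a one-base allele node — or one base
before any node boundary — shares only one character with its first node,
so no within-node anchor of length 2 exists at that end. With both
anchor shapes at both ends, every error-free read sampled from a
haplotype walk has at least one true seed, and the budget argument above
turns that into a completeness guarantee (exercised as a 10,000-read
acceptance test, not assumed).

Seeds are ordered by descending anchor length (longest anchors prune
fastest), then ascending node id, then forward strand before reverse —
the "most promising first" heuristic made deterministic. Extension is
depth-first with backtracking bounded by the two caps; a strict
no-backtrack mode (`AlignerParams.backtrack=False`) reproduces the
literal single-path behavior for fidelity experiments.

**Early stopping.** The first complete alignment that traverses an SNP
allele node is reported immediately as the read's best alignment;
otherwise the first complete alignment found is reported after all seeds
are exhausted; otherwise the read is rejected. Reported alignments are
normalized so their steps spell the read itself in read order
(reverse-strand alignments use reverse-oriented steps with decreasing
ids). Only one alignment is ever reported per read.

Consequences worth knowing: a read with a substitution error anywhere
except exactly on a SNP position (converting one allele into the other)
almost never maps — exactness acts as an error filter, and errors that do
land on SNP positions become wrong-allele support, the dominant
false-positive mechanism at nonzero error rates.

## Genotyper

Allele support is counted per site from SNP-covering alignments: an
alignment traversing the reference-allele node adds one reference
observation, the alternative node one alternative observation; the nodes
are parallel so one alignment supports at most one allele per site, and a
read spanning several sites contributes to each independently.

The caller is threshold plumbing, not a likelihood model: total depth
below `min_depth` (default 2) gives `./.`; otherwise the alternative
fraction `f = alt/(ref+alt)` gives `1/1` if `f >= hom_threshold`, `0/0`
if `f <= 1 - hom_threshold`, else `0/1`. The default `hom_threshold` is
0.9: at 20x coverage a heterozygous site's alternative count is
binomial(n, 1/2) with n ~ Poisson(20), and the miscall probability
`P[X >= t*n] + P[X <= (1-t)*n]` averaged over n is ~1-2% at t = 0.8 but
~5e-4 at t = 0.9. Error-filtered exact alignments make allele fractions
concentrate tightly near 0, 1/2 and 1, so the wide threshold costs
essentially nothing in homozygous accuracy. Anyone benchmarking against a
production caller should swap this stage.

Evaluation is genotype-aware: a non-reference call is a true positive only
if the truth set holds the identical genotype at the identical
(chrom, pos, ref, alt) key; a wrong-zygosity call is a false positive
*and* leaves the truth record a false negative. `0/0` and `./.` calls
never enter the confusion counts. Precision, sensitivity and F-measure
use the defined-zero convention for empty denominators. Allele-level
matching (which would score a `1/1` call at a `0/1` truth site as a
partial match) is intentionally not implemented; switching to it would
change FP/FN bookkeeping.

## Simulator

The simulator generates the study's data layout at desk scale: an i.i.d.
uniform-ACGT reference; a panel of biallelic sites sampled without
replacement (count = `round(snp_rate x length)`, REF from the reference,
ALT uniform over the other three bases) with per-site population
alternative-allele frequencies uniform on [0.05, 0.5] (unspecified
upstream; this keeps heterozygotes common, so genotype recovery is
informative); one diploid individual drawn site-wise under Hardy-Weinberg
equilibrium with haplotypes built by substitution; and uniform shotgun
reads, `ceil(coverage x genome_length / read_length)` of them, split
evenly across the two haplotypes, uniform in position and strand, with
independent per-base substitution errors. Read names encode the true
placement (haplotype, chromosome, 0-based start, strand) so aligner tests
can check placements without an alignment oracle.

Each stage draws from an independent RNG stream derived from the single
seed plus a fixed stage label, so changing read parameters never perturbs
the panel or the individual, and all outputs are byte-reproducible under
a fixed configuration.

What the simulator does *not* model — indels, quality-score structure,
coverage biases, repeats, linkage disequilibrium, paired ends — bounds
what passing tests show: they validate the algorithm's contracts
(exactness, completeness on its graph class, budget compliance, genotype
recovery under binomial sampling), not performance on real human data,
where repeats and indel variation would reduce mappability.

## Default study conditions

| Parameter | Default | Meaning |
|---|---|---|
| node length bound | 32 | maximum characters per graph node |
| `node_budget_factor` | 2 | probed-node budget = 2 x read length per seed |
| `neighbor_cap` | 4 | neighbor probes per node |
| `min_seed_length` | 2 | shortest usable anchor (characters shared with the graph) |
| `min_depth` | 2 | below this total depth a site is `./.` |
| `hom_threshold` | 0.9 | alternative fraction for a homozygous call |
| `snp_rate` | 0.01 /bp | panel density (one site per 100 bp) |
| `maf_range` | [0.05, 0.5] | population alternative-allele frequency |
| `coverage` | 20x | mean read bases per position |
| `read_length` | 100 bp | typical short-read length |

Acceptance-scale runs use a 100 kb genome with 1,000 panel SNPs and
10,000 100 bp reads for alignment properties, and 500 panel SNPs at 20x
(20,000 reads) for genotype recovery — sizes chosen so the full suite
exercises every property at meaningful statistical power on one CPU.

## Numerical and degenerate-input choices

* Neighbor iteration order: ascending node id forward, descending
  reverse; all ties in seed order are broken deterministically, so two
  runs (and the whole CLI pipeline) are byte-identical under a seed.
* A node may be partially consumed at the anchor (offset > 0) and at the
  final step (length < node length); interior steps always consume whole
  nodes — forced by gap-free exact matching on a chunked graph.
* Reads shorter than 2 bases, reads with `N`, and empty-sequence records
  are rejected (the latter counted as malformed).
* An empty panel yields a SNP-free chain graph; `printsnp` output is then
  empty by definition.
* Duplicate keys in calls or truth are input errors, not silent merges.

## Known limitations

* SNPs only: no indels, structural variants, or multiallelic sites; the
  id-monotonicity the aligner exploits breaks under node-reusing variant
  types.
* Exact matching discards most error-bearing reads; at realistic error
  rates sensitivity comes from coverage, not per-read tolerance.
* The genotyper has no likelihood model, no strand/mapping bias handling,
  and no phasing.
* The seed index is an in-memory dictionary; graphs far beyond desk scale
  would need a compressed index with the same query contract.
* The CLI accepts a thread-count flag for interface parity but runs
  single-threaded; results are order-stable by construction.
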