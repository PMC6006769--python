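# Methods

This note documents the models, conventions and numerical choices behind
`reptronkit`, what the synthetic generators do and do not emulate, and the
known limitations. Coordinates are 0-based, half-open, forward-strand
throughout; every stochastic routine is a pure function of its seed.

## REP structural descriptor

A REP candidate is a foot tetranucleotide (default degenerate motif
`GT[AG]G`, configurable) followed after a spacer of 0-2 nt by a hairpin:

- **short**: a basal stem of 7-20 fully paired nucleotides and a loop of
  2-5 nt; the first four stem bases must contain at least three G or C.
- **long**: the basal stem plus a second fully paired stem of 1-10 nt
  connected by a bulge of 1-3 nt; the GC content of the 5'-arm stem bases
  (both stems pooled) must be >= 0.50.

"Fully paired" means exact Watson-Crick complementarity (A·T, G·C). G·T
wobble is deliberately excluded: the element is DNA and the descriptor asks
for perfect pairing. The bulge is modelled as unpaired bases on the 5' arm
only (an asymmetric bulge); a symmetric internal loop would be a
straightforward extension but doubles the search space for no clear gain on
the families the descriptor encodes.

The scanner reports, per foot position, the single best parse over all
(offset, stem, loop[, bulge, stem2]) combinations. Tie-breaking prefers, in
order: larger total paired length (most stable structure), smaller foot
offset, smaller loop, short over long kind, then smaller bulge and larger
basal stem (pure determinism). A 3' **double foot** — the reverse complement
of a foot motif (C[TC]AC under the defaults) within 0-2 nt of the 3' arm —
extends the element's `end` and sets a flag; `hairpin_start/hairpin_end`
always delimit the foot-through-arm core so the element proper is
recoverable either way.

Same-strand overlapping candidates are resolved greedily by descending
paired length (ties: leftmost). Opposite-strand overlaps are kept, because
inverted REP pairs (REPINs) legitimately overlap in projection.

Implementation: pairing runs are precomputed with the recurrence
`run[d][i] = pairs(i, i+d) ? 1 + run[d-2][i+1] : 0` (a candidate's pairs all
lie on one anti-diagonal), making each geometry combination an O(1) lookup;
time and memory are O(genome length x maximal span). Non-ACGT characters
never pair and never match a motif. The test suite checks the scanner
against exhaustive brute-force enumeration by string slicing.

Atypical families (e.g. a `CnGA` foot, weaker structures) are handled by
supplying alternative foot motifs or relaxed ranges in the `RepRuleSet`;
nothing is hard-coded.

## REP families, BIMEs, REPtrons

Pairwise REP identity uses global alignment with free end gaps
(match 2, mismatch -1, gap open -3 / extend -1, terminal gaps free);
identity = matches / aligned columns of the overlap. REPs are 20-65 nt, a
regime where word-seeded search is unreliable, hence direct alignment. The
family graph takes an edge wherever identity >= 0.80 (a declared default —
no canonical value exists for REP families) and is partitioned with MCL.
A family consensus is the per-column majority over its modal-length members;
full multiple alignment is intentionally out of scope.

BIMEs are maximal runs of >= 2 REPs whose consecutive gaps
(`next.start - prev.end`) are <= 150 nt, inclusive; a run of exactly two
REPs on opposite strands is flagged a REPIN. REPtron calling retains
families with at least one copy whose distance from a *tnpA*-like gene
boundary is <= 1000 nt (inclusive at exactly 1000, measured edge-to-edge,
not midpoint); retained members split into upstream/downstream by midpoint
side, and copies overlapping the gene itself are kept and additionally
flagged `inside_gene` (such insertions are real but their accounting is a
convention). In the end-to-end convenience pipeline, BIMEs are assembled
among members of retained families, so isolated background structures far
from any gene do not inflate the counts.

## Markov clustering

`mcl_core` implements MCL natively on scipy sparse matrices: add self-loops
(each vertex's maximum incident weight; 1.0 for isolated vertices), column-
normalise, then iterate expansion (matrix square) -> inflation (entrywise
power IF, renormalise) -> prune (entries < 1e-5, renormalise) until the
maximal entrywise change is < 1e-8 or 200 iterations (non-convergence is
reported on the partition, not raised). Clusters come from the converged
flow: attractors are vertices with positive diagonal mass, attractor systems
are connected via attractor-to-attractor support, and every vertex joins the
system receiving the largest share of its column mass (ties toward the
smaller cluster id). Cluster ids are renumbered by smallest member index, so
partitions are comparable across runs. Memory is proportional to edges.

The inflate factor controls granularity: `if_sweep` runs MCL across a list
of IF values and `stable_range` returns the longest plateau of constant
cluster count (ties toward lower IF), the operational rule for choosing a
partition level (coarse IF ~ classes, the plateau ~ subclasses).

## Protein pipeline

Pairwise protein identity is computed from a local alignment (BLOSUM62, gap
open -11 / extend -1 — BLAST-like defaults); identity = identities /
aligned columns. Two guards make this behave like a sane percent identity:

- **coverage**: the aligned region must span >= 50% of the shorter
  sequence, else identity is reported as 0. The optimal local alignment of
  two *unrelated* sequences is a short high-identity segment; without a
  coverage requirement the identity fraction is meaningless.
- **seeding**: an inverted 5-mer index prescreens pairs; pairs sharing no
  5-mer are treated as unaligned (identity 0 / dissimilarity 100), exactly
  how a word-seeded search would treat them. This keeps all-against-all
  comparisons of ~1400 proteins tractable.

Redundancy reduction builds the identity graph at a 70% cutoff and
partitions it with MCL; each cluster is represented by its **medoid**: the
member minimising mean dissimilarity (100 - identity; missing pairs = 100)
among members whose length is within 10% of the cluster median (relaxed to
the nearest-length members if that set is empty; ties by smaller
|len - median|, then lexicographic id). Labels propagate from medoids to
members (`direct` for the medoid, `propagated` otherwise, `discarded` when
the medoid was rejected), and a per-subclass length filter re-discards
members outside [0.6, 1.67] x subclass median length (inclusive bounds) —
the fusion/partial-sequence screen. The filter bounds are configurable
conventions; the source analysis set them by inspection of length
distributions rather than by rule.

Similarity graphs can also be read from BLAST tabular output: edges for
hits with e-value strictly < 1e-5, weight = min(-log10 e-value, 200)
(the cap stands in for reported e-value 0; base-10 chosen, configurable),
reciprocal hits merged by mean, self-hits dropped.

## Motif annotation

Class signatures: HuH = H-u-H with u in {V, I} (class 1), {L, V, I, F, Y, M}
(class 2) or {V, I} (class 3 — only V is observed in the class-3 consensus;
I is admitted as its conservative exchange, mirroring class 1 whose Y
signature class 3 resembles). Y signatures: `Y-x3-Q`, `Y-x3-NP`, `Y-x4-Q`
for classes 1/2/3. The HuH->Y distance is measured as Y position minus the
position of the *second* H (a fixed convention; the original measurement
endpoints are not stated anywhere authoritative). When several HuH/Y pairs
are valid, the pair with distance closest to 62 residues is chosen (the
midpoint of the common 58-67 spacing range), within configurable bounds of
30-160 covering the long-spacing subclasses. A conserved W is recorded in
the 10 residues before the chosen Y. `core_complete` is true iff a valid
pair exists; class assignment comes from the chosen Y's signature (multiple
matches -> `ambiguous`). Subclass-level consensus motifs ship as an editable
data file and act only as optional refinement; several consensus strings
are only partially legible in the source tabulation and are transcribed
conservatively with wildcards.

`trim_columns` removes alignment columns whose gap fraction strictly
exceeds a threshold (default 0.5) and is idempotent.

## Reporting

Coverage statistics use one representative strain per species
(lexicographically first genome id — any deterministic rule would do, none
is prescribed). The genome-size association uses a two-sided Wilcoxon
rank-sum (Mann-Whitney U) test: genome sizes are skewed, so a rank-based
test is the defensible default; the test behind the original p-value is
unnamed.

## Synthetic data: what it emulates, what it does not

The generators emulate the *statistical structure the pipeline assumes*:
i.i.d. background DNA at a chosen GC (default 0.5), REP hairpins built to
satisfy a rule set exactly, REPtron layouts (gene + inverted REP pairs
within the vicinity window, copies derived from one founder by
structure-preserving mutation — 5'-arm substitutions mirrored onto the 3'
arm), protein families as founder + descendants with substitutions at a
rate calibrated to a target identity (replacements uniform over the 19
non-identical residues; no substitution-matrix realism is needed for
identity-threshold behaviour), motif-bearing proteins on a scaffold
alphabet that excludes motif-forming residues so planted motifs are the
only matches, and planted-partition graphs with one or two levels of block
structure. They do **not** emulate phylogenetic correlation, codon
structure, indels, compositional heterogeneity along the genome, or real
REP sequence families — so green tests demonstrate correctness of the
*method* under its stated assumptions, not performance on any particular
organism.

Two ground-truth hygiene rules keep planted truth labels valid:

- An element with foot offset >= 1 can be re-parsed at a smaller offset
  with a one-longer stem whenever its last spacer base happens to pair the
  first background base after the insertion (the alternative parse lies on
  the same pairing anti-diagonal, so it costs a single chance pairing,
  probability ~1/4). The multi-plant helper patches the spacer base against
  the insertion context, which removes every such parse without touching
  the planted geometry.
- After assembly the genome is re-scanned; in the rare residual case that
  background still produces a higher-priority parse at a planted locus (or,
  for the REPtron simulator, a spurious hit adjacent to the planted
  cluster), the placement is redrawn from a derived seed. Without this, the
  "truth" coordinates would be wrong — the scanner would be right to report
  the larger structure.

Background genomes are free to contain chance rule-conformant hairpins;
tests *measure* those against the brute-force oracle rather than forbid
them.

## Problem sizes

The quantitative checks run at desk scale, chosen so the full suite
completes in minutes on one CPU while keeping every estimate's sampling
error far from its decision threshold: 50 x 1-kb sequences for oracle
equivalence, 200 planted REPs in a 100-kb genome, 100 planted-partition
graphs of 40-120 vertices, 100 random medoid clusters of up to 30 members,
20-seed identity-threshold replicates, and a 931-representative protein
library (244 multi-member clusters + 687 singletons, ~1400 proteins) for
label conservation. The corpus-scale figures of the source analysis (2355
genomes, millions of proteins) depend on that specific corpus and are out
of scope by design.

## Known limitations

- No thermodynamic folding: the descriptor is combinatorial, so candidate
  ranking uses paired length, not free energy; pseudoknots and wobble pairs
  are out of scope.
- The long-hairpin bulge is asymmetric by convention; descriptors with
  symmetric internal loops would need a rule-set extension.
- Local-alignment identity is an approximation of BLASTP percent identity;
  numbers can differ by a few percent on gappy pairs.
- MCL cluster numbering is deterministic but arbitrary; class/subclass
  *names* (1.1, 2.3, ...) are size-ordered labels, not biological
  identities, and only align with published subclass names when the input
  graph is the published one.
- `reduce_redundancy` is O(n^2) in accepted pairs; beyond ~10^4 proteins a
  dedicated clustering tool is the right choice, with
  `graph_from_blast_tab` as the ingestion point.
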