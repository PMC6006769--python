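# reptronkit

Detection and classification toolkit for bacterial **REP elements** and the
**TnpA_Y1** superfamily of single-tyrosine HuH endonucleases (IS200/IS605
transposases, TnpA_REP/RAYT proteins and their relatives).

## What it does

Many bacterial genomes carry hundreds of Repetitive Extragenic Palindromic
(REP) sequences: short (~21-65 nt) intergenic elements made of a guide
tetranucleotide (the "foot", typically `GT[AG]G`) sitting 0-2 nt 5' of a DNA
stem-loop. They are processed by TnpA_REP, a REP-associated tyrosine
transposase of the HuH superfamily, and a full-length *tnpA_REP* gene flanked
by its cognate REPs forms a **REPtron**. `reptronkit` provides the
computational machinery to study this system:

- **`rep_scanner`** — exact structural search for REP candidates. A candidate
  is a foot motif followed (after a 0-2 nt spacer) by either a *short* hairpin
  (fully Watson-Crick-paired basal stem of 7-20 nt, loop of 2-5 nt, at least
  three G/C among the first four stem bases) or a *long* hairpin (an
  additional fully paired 1-10 nt stem joined by a 1-3 nt bulge, overall stem
  GC >= 50%). Both strands; per-foot best parse (maximal paired length);
  3' "double feet" (`C[TC]AC`) detected.
- **`rep_families`** — pairwise-identity graph over candidates (global
  alignment, free end gaps), MCL clustering into families, BIME/REPIN
  assembly (consecutive REPs with gaps <= 150 nt; a REPIN is an inverted
  pair), REPtron calling (families with a copy within +/-1000 nt of a
  *tnpA*-like gene).
- **`mcl_core`** — a native sparse Markov Clustering implementation
  (expansion/inflation with column renormalisation and pruning), inflate-
  factor sweeps and granularity-plateau detection.
- **`homolog_pipeline`** — the protein workflow: all-against-all local
  alignment identities (BLOSUM62), redundancy reduction at a 70% identity
  cutoff, medoid representatives (minimum mean dissimilarity under a
  median-length constraint), two-level MCL class/subclass labelling, label
  propagation from medoids to members, per-subclass length-outlier filtering,
  plus a BLAST outfmt-6 graph reader (edge weight `-log10` e-value).
- **`motif_core`** — HuH (H-u-H), W and catalytic Y motif annotation with the
  class-specific tyrosine signatures `Y-x3-Q` (class 1), `Y-x3-NP`
  (class 2), `Y-x4-Q` (class 3), HuH->Y spacing, complete-core calls and
  gap-heavy alignment-column trimming.
- **`reporting`** — per-species subclass presence/absence, coverage
  percentages, intra-genome copy numbers and the genome-size association
  (Wilcoxon rank-sum).
- **`synthetic_data`** — seeded generators for all of the above with known
  ground truth: genomes, rule-conformant REP hairpins, REPtron layouts,
  motif-bearing proteins, protein families with controlled identity and
  planted-partition graphs.

## Worked example

```python
from reptronkit import GeneFeature, analyze_reptrons, scan, simulate_reptron_genome

sim = simulate_reptron_genome(seed=11, n_repin_pairs=3)
g = sim["gene"]
gene = GeneFeature(g.contig_id, g.start, g.end, g.strand,
                   g.params["gene_id"], g.params["product"])
candidates = scan(sim["genome"], sim["rules"])
result = analyze_reptrons(candidates, [gene])
print(len(candidates), len(result["retained_families"]),
      len(result["bimes"]), sum(b.is_repin for b in result["bimes"]))
```

prints `6 1 3 3`: the six planted REP copies are all detected, they form a
single sequence family associated with the gene, and they assemble into
three BIMEs, each an inverted pair (REPIN) — the canonical REPtron layout in
which one *tnpA_REP* gene is flanked by three REP doublets.

More narrative walk-throughs live in `examples/` (scanning, REPtron calling,
MCL classification, motif annotation, redundancy reduction); each prints its
results with a line on what they mean. A thin CLI mirrors the library:
`reptron-kit scan-reps`, `call-reptrons`, `mcl`, `sweep`, `classify`,
`motifs`, `report`, `simulate`.

## Layout

```
src/reptronkit/      library modules (one per pipeline stage)
examples/            narrative scripts, one per capability
tests/               pytest suite with independent brute-force oracles
scripts/acceptance.py  end-to-end quantitative checks
docs/methods.md      models, conventions, parameters, limitations
```
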