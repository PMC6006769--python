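"""Call a REPtron: a tnpA-like gene flanked by its cognate REP family.

Simulates the canonical layout (one gene, three REP pairs in inverted
orientation within 1 kb), then runs scanning, family clustering, BIME
assembly and REPtron calling.
"""

from reptronkit import GeneFeature, analyze_reptrons, scan, simulate_reptron_genome

sim = simulate_reptron_genome(seed=11, n_repin_pairs=3)
g = sim["gene"]
gene = GeneFeature(g.contig_id, g.start, g.end, g.strand,
                   g.params["gene_id"], g.params["product"])

candidates = scan(sim["genome"], sim["rules"])
result = analyze_reptrons(candidates, [gene])

print(f"REP candidates      : {len(candidates)}")
print(f"families (all)      : {len(result['families'])}")
print(f"families near gene  : {len(result['retained_families'])}")
print(f"BIMEs               : {len(result['bimes'])}")
print(f"  of which REPINs   : {sum(b.is_repin for b in result['bimes'])}")
r = result["reptrons"][0]
print(f"REPtron around {r.gene.gene_id}: "
      f"{len(r.upstream_reps)} upstream + {len(r.downstream_reps)} downstream REPs")
# One REPtron with one REP family and three inverted pairs (REPINs) - the
# arrangement described for the E. coli-style REPtron locus.
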