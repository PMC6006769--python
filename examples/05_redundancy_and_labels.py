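"""Redundancy reduction, medoid representatives and label propagation.

Simulates five protein families (founder + descendants at 85% identity),
collapses them at the 70% identity cutoff, picks one medoid per cluster and
propagates subclass labels from medoids to members.
"""

from reptronkit import ProteinRecord, propagate_labels, reduce_redundancy
from reptronkit.synthetic_data import make_protein_family, random_protein

proteins = []
for f in range(5):
    founder = random_protein(200, seed=100 + f)
    family = [founder] + make_protein_family(founder, 5, 0.85, seed=200 + f)
    proteins += [ProteinRecord(f"fam{f}_p{i}", s) for i, s in enumerate(family)]

assignments = reduce_redundancy(proteins, identity_cutoff=0.70)
print(f"{len(proteins)} proteins -> {len(assignments)} clusters")
for a in assignments:
    print(f"  {a.cluster_id}: medoid={a.medoid_id} size={len(a.member_ids)}")

medoid_labels = {a.medoid_id: f"2.{i + 1}" for i, a in enumerate(assignments)}
labels = propagate_labels(medoid_labels, assignments)
direct = sum(l.provenance == "direct" for l in labels)
prop = sum(l.provenance == "propagated" for l in labels)
print(f"labels: {direct} direct (medoids) + {prop} propagated = {len(labels)} total")
# Each planted family collapses to one cluster; its medoid's subclass label
# is inherited by every member, and counts are conserved.
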