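"""Cluster genotypes from band profiles and select trait-linked candidate
bands by bulked-sample contrast.

Distance is 1 - Jaccard over shared band presences; the UPGMA tree is
exported as Newick; a candidate marker is a band present in every tolerant
bulk and absent from every sensitive bulk.
"""

from mirmark import (
    BandMatrix,
    BulkDesign,
    cut_clusters,
    jaccard_similarity,
    select_candidate_markers,
    upgma,
)

samples = ["T1", "T2", "S", "Kasoor", "Bane"]
matrix = BandMatrix.from_records({
    # band label -> presence per sample (1/0, None = NA)
    "mir171g + mir393e:1:990": dict(zip(samples, [1, 1, 0, 1, 0])),
    "mir172b + mir166k:1:690": dict(zip(samples, [1, 1, 0, 1, 0])),
    "mir172b + mir166k:2:420": dict(zip(samples, [0, 0, 1, 0, 1])),
    "ISSR-PvC + mir399a:1:490": dict(zip(samples, [1, 1, 0, 0, 0])),
    "ISSR-PvC + mir399a:2:300": dict(zip(samples, [1, 1, 1, 1, 1])),
})

sim = jaccard_similarity(matrix)
print("Jaccard similarity:")
print(sim.round(2).to_string())

tree = upgma(sim)
print("\nUPGMA dendrogram (Newick):")
print(" ", tree.to_newick())

assignment = cut_clusters(tree, k=3)
print("\n3-cluster cut:", assignment)

design = BulkDesign(tolerant_bulks=(("T1",), ("T2",)), sensitive_bulks=(("S",),))
candidates = select_candidate_markers(matrix, design)
print("\nBSA candidate markers (in both tolerant bulks, not in sensitive):")
for c in candidates:
    print(f"  {c.band.pair_name}  ~{c.band.size_bin:.0f} bp")
# These bands co-segregate with the tolerant phenotype across the bulks and
# are the loci a breeding program would validate next.
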