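"""Design miRNA-derived primers and enumerate marker pairs.

A mature miRNA from the 5' arm of its precursor is back-transcribed and
reverse-complemented; one from the 3' arm is only back-transcribed.  Pairing
n single primers gives n(n-1)/2 combined markers.
"""

from mirmark import Arm, MatureMiRNA, combine_within, design_mirna_primer

mirnas = [
    MatureMiRNA("mir171g", "UGAUUGAGCCGUGCCAAUAUC", Arm.FIVE_PRIME),
    MatureMiRNA("mir393e", "UCCCGACCUGCACCAAGCGAA", Arm.THREE_PRIME),
    MatureMiRNA("mir399a", "UGCCAAAGGAGAGUUGCCCUG", Arm.FIVE_PRIME),
    MatureMiRNA("mir166k", "UCGGACCAGGCUUCAUUCCCC", Arm.THREE_PRIME),
]

primers = [design_mirna_primer(m) for m in mirnas]
for p in primers:
    print(f"{p.name:10s} arm={p.provenance[1]}  5'-{p.sequence}-3'  GC={100 * p.gc_fraction:.0f}%")

pairs = combine_within(primers)
print(f"\n{len(primers)} primers -> {len(pairs)} combined markers:")
for pair in pairs:
    print(" ", pair.pair_name)

# Each printed primer is the synthesizable DNA oligo whose genomic targets
# are the miRNA/miRNA* sites; each pair is one PCR assay amplifying the
# sequence between two neighbouring miRNA loci.
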