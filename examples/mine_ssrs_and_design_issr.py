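"""Mine perfect microsatellites from transcripts and design an anchored
ISSR primer from the most abundant motif.

The miner applies MISA-style thresholds (di >= 6, tri >= 5, tetra >= 5,
penta >= 4, hexa >= 4 repeats); the ISSR primer is the selected motif's
repeat block plus the most frequent 2-mer observed 3' of its tracts.
"""

import numpy as np

from mirmark import (
    NucleotideSequence,
    design_issr_primer,
    find_ssrs_many,
    motif_frequency,
    select_motifs,
)

rng = np.random.default_rng(4)
bases = "ACGT"


def pad(n):
    return "".join(bases[i] for i in rng.integers(0, 4, n))


# transcripts carrying (TC)n tracts flanked 3' by "AG", plus one (GAA)n gene
transcripts = [
    NucleotideSequence("gene001", pad(80) + "A" + "TC" * 9 + "AG" + pad(80)),
    NucleotideSequence("gene002", pad(60) + "G" + "TC" * 7 + "AG" + pad(90)),
    NucleotideSequence("gene003", pad(70) + "T" + "GAA" * 6 + "CT" + pad(70)),
]

loci = find_ssrs_many(transcripts)
print("mined SSR loci (1-based coordinates):")
for locus in loci:
    print(f"  {locus.sequence_id}  ({locus.motif}){locus.repeat_count}  "
          f"{locus.start}-{locus.end}")

freq = motif_frequency(loci)
print("\nmotif frequency table:")
print(freq.to_string(index=False))

chosen = select_motifs(freq, k_per_unit=1, unit_lengths=(2, 3))
print(f"\nselected motifs (most abundant per unit length): {chosen}")

primer = design_issr_primer(chosen[0], transcripts, anchor_len=2, target_len=18)
motif, n_units, anchor, _ = primer.provenance
print(f"\nISSR primer {primer.name}: 5'-{primer.sequence}-3'")
print(f"  = ({motif}){n_units} repeat block + data-derived 3' anchor {anchor!r}")
# The anchor is the flank actually observed after the tracts, so the primer
# anneals in register at the 3' end of genomic (TC)n runs.
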