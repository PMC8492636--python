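"""Predict marker bands by in-silico PCR on a template with planted sites.

A convergent plus-strand and minus-strand primer site delimit one amplicon;
the product length is the span between the outermost primer bases.
"""

import numpy as np

from mirmark import (
    NucleotideSequence,
    Primer,
    PrimerKind,
    PrimerPair,
    find_binding_sites,
    predict_amplicons,
    reverse_complement,
)

rng = np.random.default_rng(8)
bg = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))

fwd = Primer("mir171g", "GATATTGGCACGGCTCAATCA", PrimerKind.MIRNA)
rev = Primer("mir393e", "TCCCGACCTGCACCAAGCGAA", PrimerKind.MIRNA)

# plant fwd at 101 and the reverse site so the product spans 990 bp
template = NucleotideSequence(
    "locus", bg(100) + fwd.sequence + bg(990 - 2 * 21) + reverse_complement(rev.sequence) + bg(150)
)

for primer in (fwd, rev):
    for site in find_binding_sites(template, primer):
        print(f"site: {primer.name:9s} strand {site.strand} at {site.position} "
              f"({site.mismatches} mismatches)")

amplicons = predict_amplicons(template, PrimerPair(fwd, rev))
for a in amplicons:
    print(f"\namplicon {a.pair_name}: {a.start}-{a.end} -> {a.length} bp")
# The 990 bp product is the band this marker would show on a gel; zero
# amplicons would mean the pair cannot co-amplify this template.
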