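# mirmark

A toolkit for **miRNA-derived functional markers** in plant breeding: design
PCR primers from annotated mature miRNAs and from mined microsatellite (SSR)
motifs, predict marker bands by in-silico PCR, quantify polymorphism, cluster
genotypes, and select trait-linked candidate markers by bulked-sample
contrast.

## Who this is for

Plant molecular breeders working with dominant, presence/absence PCR marker
systems (ISSR-style gels) who want **functional** markers — primers anchored
in sequence causally linked to a trait (stress-responsive miRNAs and genes)
rather than anonymous genomic repeats — and a reproducible desk pipeline
from sequence inputs to candidate marker lists.

## The marker system

**miRNA primers.** A mature miRNA of ~18–24 nt excised from one arm of its
pre-miRNA hairpin marks a conserved, trait-associated genomic site. The
primer rule depends on the arm of origin: a 5′-arm mature sequence is
back-transcribed (U→T) and **reverse-complemented**; a 3′-arm sequence is
back-transcribed unchanged. Two such primers amplify the DNA between
neighbouring miRNA/miRNA\* sites, so combining *n* single primers yields
*n(n−1)/2* marker assays; crossing them with ISSR primers yields |A|×|B|
more.

**Semi-random anchored ISSR primers.** Perfect microsatellites are mined
from trait-responsive transcripts with MISA-compatible semantics (unit
lengths 2–6, minimum repeats 6,5,5,4,4; motifs reducible to a shorter unit
reported at that unit). The most abundant (optionally activity-weighted)
di-, tri- and penta-nucleotide motifs seed primers of the form
`motif × n + anchor`, where the 1–4 nt 3′ anchor is the most frequent flank
observed immediately 3′ of the motif's tracts in those same genes — data
derived, hence "semi-random".

**Scoring and statistics.** Predicted or observed band sizes are binned per
primer pair (single-linkage, 2 % relative tolerance) into a binary
presence/absence matrix with NA for failed reactions. Polymorphism
information content follows

> PIC = 1 − Σᵢ pᵢ²

with each band of a pair treated as one allele class of a multi-allelic
locus (a dominant biallelic mode, capped at 0.5 per band, is also provided).
Percent polymorphism and cross-species transferability use the standard
band-count conventions.

**Clustering and selection.** Genotype similarity is Jaccard's coefficient
J = a/(a+b+c) over co-scored bands; UPGMA on d = 1 − J gives an ultrametric
dendrogram (Newick export, deterministic tie-breaking) that can be cut into
k clusters. Bulked-sample analysis (BSA) selects candidate bands present in
**every** tolerant bulk and absent from **every** sensitive bulk — the bands
that co-segregate with the trait across phenotypic extremes.

A deterministic simulator (`mirmark.simulate`) generates genotype panels
with planted miRNA primer sites, SSR tracts and tolerance-linked insertion
loci, so the whole pipeline is testable end to end with known ground truth.

## Worked example

```python
from mirmark import Arm, MatureMiRNA, combine_within, design_mirna_primer

mirnas = [
    MatureMiRNA("mir171g", "UGAUUGAGCCGUGCCAAUAUC", Arm.FIVE_PRIME),
    MatureMiRNA("mir393e", "UCCCGACCUGCACCAAGCGAA", Arm.THREE_PRIME),
]
for p in (design_mirna_primer(m) for m in mirnas):
    print(p.name, p.sequence)
```

prints

```
mir171g GATATTGGCACGGCTCAATCA
mir393e TCCCGACCTGCACCAAGCGAA
```

— the 5′-arm miRNA became its reverse complement, the 3′-arm one only
swapped U for T. Running the full pipeline on a simulated panel
(`python examples/full_pipeline.py`) prints

```
n_mirna_primers: 8        # eight miRNA primers ->
n_mirna_mirna_pairs: 28   #   28 miRNA+miRNA markers
n_issr_primers: 6         # six ISSR primers ->
n_mirna_issr_pairs: 48    #   48 miRNA+ISSR markers
n_bsa_candidates: 3
selected candidates: [('ISSR-PvC + mir171g', 617), ('ISSR-PvS + mir393e', 339), ('mir172b + mir399a', 346)]
planted truth     : [('ISSR-PvC + mir171g', 617), ('ISSR-PvS + mir393e', 339), ('mir172b + mir399a', 346)]
```

i.e. bulked-sample selection recovered exactly the three planted
tolerance-linked loci. The other scripts in `examples/` walk through each
capability (SSR mining, ISSR design, in-silico PCR, diversity statistics,
clustering + BSA) on small inputs.

A thin CLI mirrors the stages:

```bash
mirmark simulate --seed 7 --out-dir panel
mirmark run --config pipeline.yaml --clusters 3
mirmark mine-ssr transcripts.fasta --out ssr.tsv
```

## Layout

```
src/mirmark/
  seqio.py      sequence model, FASTA I/O, reverse complement, U->T
  ssr.py        MISA-compatible SSR mining, motif tables, motif selection
  primers.py    miRNA + ISSR primer construction, pair enumeration
  epcr.py       binding-site search and amplicon prediction
  bands.py      band binning, PIC, polymorphism, transferability
  cluster.py    Jaccard, UPGMA (Newick), cluster cutting, BSA selection
  simulate.py   deterministic synthetic genotype panels with ground truth
  pipeline.py   end-to-end orchestration with TSV/Newick/YAML outputs
  cli.py        click-based command line
docs/methods.md   model, conventions, defaults, limitations
```
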