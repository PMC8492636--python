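# Methods

This note records the models, conventions and defaults behind `mirmark`,
the choices made where several designs were defensible, and what the
synthetic panels do and do not demonstrate.

## Sequence model and coordinates

Sequences are uppercase strings over `{A,C,G,T,N}` (DNA) or `{A,C,G,U,N}`
(RNA); the alphabet is auto-detected per FASTA record (any `U` marks RNA).
Internal coordinates are 0-based half-open; **every user-facing coordinate
is 1-based inclusive**, matching MISA-style reports. `N` is accepted in
templates but never in primers: an oligo with an ambiguous base cannot be
synthesized as written, so design functions reject it.

Mature miRNAs shorter than 15 nt are rejected (too short to prime);
15–17 nt triggers a warning because mature plant miRNAs are typically
18–24 nt. The arm of origin (5p/3p) is mandatory — it decides whether the
primer is the reverse complement (5p) or the back-transcription (3p) of the
mature sequence, which is what lets two primers face each other across the
region between neighbouring miRNA sites.

## SSR mining

`find_ssrs` reports all maximal perfect tandem repeats with unit length
2–6 whose whole-unit repeat count meets the thresholds
`{2:6, 3:5, 4:5, 5:4, 6:4}` (the MISA setting this system standardises on).
Three rules pin down the locus set uniquely:

* only whole repeat units count — a 13 nt AG-period run reports `(AG)6`;
* the motif must be *primitive* (not itself a repetition of a shorter
  unit, including unit 1): `ATATATAT` is an AT repeat, never ATAT, and
  mononucleotide runs are never reported. By the Fine–Wilf periodicity
  argument this also prevents the same tract being reported at two unit
  sizes;
* `N` matches nothing, so it breaks a tract.

Adjacent loci within 100 nt are additionally grouped as compound
annotations (MISA's default) but counted individually in motif frequencies.
Motifs are tabulated exactly as they occur at the locus start; merging
cyclic rotations is opt-in, and reverse complements are never merged (TC
and AG are distinct primer choices). The test suite checks the miner for
exact locus-set agreement with an independent brute-force scan on hundreds
of random sequences.

Motif selection for ISSR design ranks motifs within each unit length
(di/tri/penta by default) by
`w_abund · rank(count) + w_act · rank(mean activity of host genes)`,
ranks normalised to [0, 1]. The exact way abundance and gene activity were
combined in practice is not standardised anywhere; this weighted-rank
scheme is a declared design choice, reducing to pure abundance when no
activity table is supplied. Activity defaults to whatever per-gene score
the user's differential-expression table provides (|log2 fold change| is
the intended use).

## Primer construction

ISSR primers are `motif × n + anchor` with
`n = ceil((target_len − anchor_len)/|motif|)`; defaults `target_len = 18`,
`anchor_len = 2` (typical ISSR dimensions; both configurable). The anchor
is the most frequent `anchor_len`-mer immediately 3′ of the motif's mined
tracts in the template genes, with two exclusions: k-mers containing `N`,
and k-mers starting with the motif's first base, which would merely extend
the repeat rather than fix the annealing register. Ties break
lexicographically so designs are reproducible.

No melting-temperature, GC-clamp or secondary-structure screening is
performed: the marker system this models uses fixed touchdown PCR programs
rather than Tm-matched primers. GC% is reported for information only.

Pair enumeration is exact: all unordered pairs within a set
(`n(n−1)/2`), or the full cross product across two sets, with an optional
seeded subsample to model "randomly combined" subsets. Pairs are unordered
and canonically named `A + B` with names sorted.

## In-silico PCR

A primer binds the plus strand where its sequence matches the template
left-to-right and the minus strand where its reverse complement matches;
matching tolerates `max_mismatch` mismatches except in the 3′-terminal
seed (`seed_len`, default 3), which must be exact — polymerases do not
extend 3′ mismatches. `N` in the template never matches. Defaults are
`max_mismatch = 0` (deterministic, conservative), product window
100–3000 bp (generous margins around the 200–1200 bp range typical of
these assays).

An amplicon is any convergent plus/minus site combination from either
primer of the pair — including both sites from the same primer, the
single-primer amplification seen for stem-loop regions — whose product
length is inside the window and at least the sum of the two primer
lengths (overlapping footprints cannot both prime). All qualifying
products are reported; no polymerase-competition or band-intensity model
is attempted, since gel visibility is handled downstream by binning.

## Band matrices and statistics

Observed sizes of one primer pair are clustered by **single linkage**: two
sizes join a bin when their gap is within `rel_tol` (default 2 %, about
the resolution of agarose sizing) of the smaller size, chained
transitively; the bin representative is the member median. A record with
size `None` declares whole-reaction failure, producing NA for *all* of
that pair's bands in that sample — failure is per reaction, not per band —
while a merely missing band is a 0.

PIC is `1 − Σ pᵢ²`. The default **multiallelic** mode treats each distinct
band of a pair as an allele class, with `pᵢ` the share of band *i* among
all presence calls of the pair. This is the reading consistent with
pair-level PIC values reported above 0.5 in dominant marker studies of
this type: dominant biallelic PIC is capped at 0.5 per band, so pair
values of 0.7–0.9 are only possible if the pair's bands are scored as one
multi-allelic locus. The **dominant** mode (per band
`1 − p² − (1−p)²`, pair value the mean over bands) is provided for
comparison. NA samples are excluded from every denominator; a pair with
zero presence calls has undefined PIC (NaN with a warning). Reports round
PIC to 2 decimals and percentages to 1 decimal.

A band is polymorphic iff present in ≥1 and absent in ≥1 non-NA sample; a
pair is polymorphic iff any of its bands is. Transferability of a marker
set into a related species is
`100 × (pairs with ≥1 band in the species) / (pairs with ≥1 band in the
focal samples)`, rounded to the nearest integer.

## Clustering and bulked-sample selection

Similarity is Jaccard's `a/(a+b+c)` over bands co-scored (non-NA) in both
samples, with `J = 1` by convention when neither sample shows any band —
two blank profiles are indistinguishable, and leaving the value undefined
would break clustering. A sample pair with *zero* co-scored bands is an
error rather than a guess.

UPGMA runs on `d = 1 − J`: repeatedly merge the closest clusters, update
distances as the size-weighted arithmetic mean, set the node height to
`d_merge/2` (the standard ultrametric halving). Ties are broken by the
lexicographically smallest member ids, which makes Newick output
byte-reproducible; the tie rule of legacy packages in this space is
undocumented, so determinism was chosen over emulation. Branch lengths are
parent height minus child height. `cut_clusters(k)` removes the k−1
highest merges and errors when tied heights make the cut ambiguous;
cluster ids are numbered by smallest member id. On ultrametric inputs the
tree's cophenetic distances reproduce the input exactly, and on tie-free
inputs the tree matches SciPy's average-linkage cophenetic matrix (used as
an independent cross-check in the tests, not as the implementation).

BSA selection treats each bulk as pooled DNA: a band is present in a bulk
when **any** member carries it and absent only when all members lack it;
NA anywhere in any bulk makes the pooled call indeterminate and
disqualifies the band (reported separately). A candidate must be present
in every tolerant bulk and absent from every sensitive bulk. The output is
sorted by pair name and size and is invariant to sample and band order;
adding a sensitive bulk can only shrink the set.

## Synthetic panels

`simulate_panel` builds the study design end to end: by default 2 tolerant
bulks and 1 sensitive bulk of 3 genotypes each (mirroring a
two-parallel-tolerant-bulks vs one-sensitive design), eight mature miRNAs
(alternating arms, random 21-mers), and six planted SSR motifs spanning
di/tri/penta units with staggered abundances so motif selection is
deterministic. Transcripts carry each tract with a fixed, non-extending
2-mer flank so ISSR anchors are well defined.

Marker loci are planted as cassettes — forward primer site, spacer,
reverse-complemented second site — of known product size (250–1100 bp).
Kinds: `shared` (all genotypes), `presence` (random carrier subset),
`shift` (all carry it, a random subset holds an extra 50–400 bp spacer
insertion, giving two size bins), and `discriminative` (every
tolerant-bulk genotype, no sensitive genotype) — the planted
tolerance-linked loci, realised as presence/absence insertions exactly as
trait-linked dominant bands are interpreted. Neutral loci are neutral *by
construction*: carrier sets whose pooled-bulk pattern would satisfy the
selection rule are resampled, otherwise roughly one in ten panels would
contain an accidental look-alike and "zero false positives" would not be a
property one could test. Backgrounds are identical across genotypes
(absence is a deletion), GC 0.5, and inter-cassette gaps exceed the
3000 bp product window so no cross-cassette amplicon can form. Recorded
truth coordinates are verified against the assembled genomes at
generation time. Everything derives from one `numpy` generator, so equal
configs give byte-identical panels.

`degrade_bands` models gel scoring noise as independent presence→absence
flips with a given dropout probability; it cannot create bands, so under
dropout the BSA false-negative rate rises monotonically while false
positives stay impossible for planted loci.

**What passing tests show — and don't.** Exact planted-truth recovery
shows the pipeline's bookkeeping (design rules, coordinates, binning,
bulk logic) is correct under ideal amplification. Real gels add partial
amplification failure, co-migrating non-homologous bands, size estimation
error beyond 2 %, heteroduplexes and competition between products — none
of which the simulator emulates beyond uniform dropout. Recovery on
synthetic panels is therefore a correctness statement, not a sensitivity
claim for real germplasm.

## Numerical and interface conventions

* Default problem sizes (9 genotypes, ~70 kb genomes, 12 planted loci,
  10–50 panels in recovery checks) keep a full run in seconds while
  leaving every code path exercised; they are configuration, not limits.
* TSV for all tables, Newick for trees, YAML for configs/summaries/bulk
  designs, BED export of amplicons documents its 0-based half-open
  conversion.
* Percentages are reported to 1 decimal, PIC to 2 decimals; Python's
  round-half-to-even applies.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the pipeline itself is fully
  deterministic given its inputs.

## Known limitations

* Only perfect repeats are mined; imperfect/interrupted SSRs beyond the
  compound annotation are out of scope.
* Exact-match ePCR (default) will miss sites disrupted by single
  polymorphisms; raising `max_mismatch` relaxes this but remains a string
  model, not a thermodynamic one.
* The multiallelic PIC reading assumes a pair's bands behave as alleles of
  one locus; for pairs whose bands are unlinked loci the dominant mode is
  the honest choice.
* Bulk calls assume pooled detection is perfect (any carrier yields a
  band); real pooled PCR can dilute rare alleles below visibility.
* One population-genetics caveat: the simulator plants haplotypes
  directly and models no allele frequencies, recombination or selection.
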