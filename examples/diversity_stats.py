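"""Score gel bands into a presence/absence matrix and compute marker
statistics: PIC, percent polymorphism, cross-species transferability.
"""

from mirmark import bin_bands, percent_polymorphic, pic, transferability

# observed band sizes per (primer pair, sample); approximate gel sizes within
# 2% of each other bin together, None marks a failed reaction (NA)
observations = [
    ("mir171g + mir393e", "Ghazvini", 988.0),
    ("mir171g + mir393e", "BadamiAnar", 992.0),   # same ~990 bp bin
    ("mir171g + mir393e", "Sarakhs", 650.0),
    ("mir172b + mir166k", "Ghazvini", 690.0),
    ("mir172b + mir166k", "BadamiAnar", 688.0),
    ("mir172b + mir166k", "Sarakhs", 690.0),
    ("mir172b + mir166k", "Sarakhs", 420.0),
    ("ISSR-PvC + mir399a", "Ghazvini", 495.0),
    ("ISSR-PvC + mir399a", "BadamiAnar", 495.0),
    ("ISSR-PvC + mir399a", "Sarakhs", None),       # no amplification
    ("ISSR-PvC + mir399a", "Kasoor", 495.0),
    ("mir171g + mir393e", "Kasoor", 988.0),
    ("mir172b + mir166k", "Kasoor", 690.0),
]

samples = ["Ghazvini", "BadamiAnar", "Sarakhs", "Kasoor"]
matrix = bin_bands(observations, rel_tol=0.02, samples=samples)
print(matrix.values.to_string())

print("\nPIC per primer pair (multi-allelic, one locus per pair):")
for result in pic(matrix):
    print(f"  {result.pair_name:20s} PIC = {result.pic:.2f} over {result.n_bands} bands")

flags, pct_pairs, pct_loci = percent_polymorphic(matrix)
print(f"\npolymorphic pairs: {pct_pairs}%   polymorphic loci: {pct_loci}%")

transfer = transferability(
    matrix, focal_samples=["Ghazvini", "BadamiAnar", "Sarakhs"],
    species_samples={"P. khinjuk (Kasoor)": ["Kasoor"]},
)
for species, percent in transfer.items():
    print(f"transferability in {species}: {percent}%")
# 100% here means every marker that amplified in the focal genotypes also
# produced at least one band in the related species.
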