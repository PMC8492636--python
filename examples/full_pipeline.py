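"""Run the whole workflow end to end on a simulated genotype panel.

The generator plants pre-miRNA primer sites, SSR tracts and three
tolerance-linked insertion loci in bulked genotypes; the pipeline then has
to rediscover the planted loci with no knowledge of the truth table.
"""

import tempfile
from pathlib import Path

import yaml

from mirmark import PipelineConfig, SimConfig, run_pipeline, simulate_panel

panel = simulate_panel(SimConfig(seed=42))
print(f"simulated {len(panel.genomes)} genotypes, "
      f"{len(panel.marker_truth)} planted marker loci "
      f"({len(panel.discriminative_bands())} tolerance-linked)")

with tempfile.TemporaryDirectory() as tmp:
    panel_dir = Path(tmp) / "panel"
    panel.write(panel_dir)
    result = run_pipeline(PipelineConfig(
        mirna_fasta=str(panel_dir / "mirnas.fasta"),
        transcript_fasta=str(panel_dir / "transcripts.fasta"),
        genomes_fasta=str(panel_dir / "genomes.fasta"),
        bulks_yaml=str(panel_dir / "bulks.yaml"),
        out_dir=str(Path(tmp) / "out"),
    ))

print("\npipeline summary:")
print(yaml.safe_dump(result.summary, sort_keys=False).rstrip())

print("selected candidates:",
      sorted((c.band.pair_name, int(c.band.size_bin)) for c in result.candidates))
print("planted truth     :", sorted(panel.discriminative_bands()))
# A correct run selects exactly the planted tolerance-linked bands: zero
# false positives and zero false negatives at zero scoring noise.
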