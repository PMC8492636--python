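"""End-to-end orchestration: design → pairing → ePCR → binning → statistics →
clustering → bulked-sample selection, with TSV/Newick/YAML outputs.

Every stage is a thin call into the library modules; the pipeline adds file
I/O, stage logging and a machine-readable summary.  Two runs with the same
config and inputs produce byte-identical outputs (logs aside).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bands as bands_mod
from . import cluster as cluster_mod
from . import epcr as epcr_mod
from . import primers as primers_mod
from . import ssr as ssr_mod
from .bands import BandMatrix
from .cluster import BulkDesign
from .seqio import NucleotideSequence, parse_mirna_fasta, read_fasta

log = logging.getLogger("mirmark")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """All paths and parameters of a full run; defaults match the module
    defaults documented in each library module."""

    mirna_fasta: str = ""
    transcript_fasta: str = ""
    genomes_fasta: str = ""
    bulks_yaml: str = ""
    gene_activity_tsv: str = ""
    out_dir: str = "mirmark_out"
    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(ssr_mod.DEFAULT_MIN_REPEATS)
    )
    k_per_unit: int = 2
    unit_lengths: tuple[int, ...] = (2, 3, 5)
    anchor_len: int = 2
    issr_target_len: int = 18
    max_mismatch: int = epcr_mod.DEFAULT_MAX_MISMATCH
    seed_len: int = epcr_mod.DEFAULT_SEED_LEN
    min_len: int = epcr_mod.DEFAULT_MIN_LEN
    max_len: int = epcr_mod.DEFAULT_MAX_LEN
    rel_tol: float = 0.02
    pic_mode: str = "multiallelic"
    clusters: int = 3
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["unit_lengths"] = list(self.unit_lengths)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "min_repeats" in data:
            data["min_repeats"] = {int(k): int(v) for k, v in data["min_repeats"].items()}
        if "unit_lengths" in data:
            data["unit_lengths"] = tuple(data["unit_lengths"])
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix: BandMatrix
    pairs: list
    newick: str
    clusters: dict[str, int]
    candidates: list
    summary: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full marker pipeline on files named in the config."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mirnas = _stage("load-mirnas")(parse_mirna_fasta)(cfg.mirna_fasta)
    transcripts = _stage("load-transcripts")(read_fasta)(cfg.transcript_fasta)
    genomes = _stage("load-genomes")(read_fasta)(cfg.genomes_fasta)
    if not genomes:
        raise PipelineError("stage 'load-genomes' failed: no genome sequences found")
    with open(cfg.bulks_yaml) as handle:
        design = BulkDesign.from_dict(yaml.safe_load(handle))
    activity = (
        ssr_mod.read_gene_activity(cfg.gene_activity_tsv)
        if cfg.gene_activity_tsv
        else None
    )

    mirna_primers = _stage("design-mirna")(
        lambda: [primers_mod.design_mirna_primer(m) for m in mirnas]
    )()

    thresholds = ssr_mod.SSRThresholds(cfg.min_repeats)
    loci = _stage("mine-ssr")(ssr_mod.find_ssrs_many)(transcripts, thresholds)
    ssr_mod.write_misa_tsv(loci, out / "ssr_loci.tsv")
    freq = ssr_mod.motif_frequency(loci)
    freq.to_csv(out / "motif_frequency.tsv", sep="\t", index=False)

    def _design_issr():
        motifs = ssr_mod.select_motifs(
            freq,
            gene_activity=activity,
            loci=loci,
            k_per_unit=cfg.k_per_unit,
            unit_lengths=cfg.unit_lengths,
        )
        suffixes = "CDTSLOABEFGH"
        return [
            primers_mod.design_issr_primer(
                m,
                transcripts,
                anchor_len=cfg.anchor_len,
                target_len=cfg.issr_target_len,
                name=f"ISSR-Pv{suffixes[i % len(suffixes)]}",
                thresholds=thresholds,
            )
            for i, m in enumerate(motifs)
        ]

    issr_primers = _stage("design-issr")(_design_issr)()

    def _combine():
        pairs = primers_mod.combine_within(mirna_primers)
        if issr_primers:
            pairs += primers_mod.combine_across(mirna_primers, issr_primers)
        return pairs

    pairs = _stage("combine")(_combine)()
    primers_mod.write_primer_tsv(mirna_primers + issr_primers, out / "primers.tsv")

    def _epcr():
        if not genomes:
            raise ValueError("no genome sequences to amplify")
        return epcr_mod.amplify_panel(
            genomes, pairs, cfg.min_len, cfg.max_len, cfg.max_mismatch, cfg.seed_len
        )

    amplicons = _stage("epcr")(_epcr)()
    all_amps = [a for amps in amplicons.values() for a in amps]
    epcr_mod.write_amplicon_tsv(all_amps, out / "amplicons.tsv")

    def _score():
        obs = [
            (a.pair_name, gid, float(a.length))
            for gid, amps in amplicons.items()
            for a in amps
        ]
        return bands_mod.bin_bands(obs, rel_tol=cfg.rel_tol,
                                   samples=[g.id for g in genomes])

    matrix = _stage("score")(_score)()
    matrix.to_tsv(out / "band_matrix.tsv")

    def _stats():
        pic_results = bands_mod.pic(matrix, mode=cfg.pic_mode)
        bands_mod.pic_table(pic_results).to_csv(out / "pic.tsv", sep="\t", index=False)
        flags, pct_pairs, pct_loci = bands_mod.percent_polymorphic(matrix)
        return pic_results, flags, pct_pairs, pct_loci

    pic_results, poly_flags, pct_pairs, pct_loci = _stage("stats")(_stats)()

    def _cluster():
        sim = cluster_mod.jaccard_similarity(matrix)
        sim.to_csv(out / "jaccard.tsv", sep="\t")
        tree = cluster_mod.upgma(sim)
        newick = tree.to_newick()
        (out / "dendrogram.nwk").write_text(newick + "\n")
        k = min(cfg.clusters, len(matrix.samples))
        assignment = cluster_mod.cut_clusters(tree, k)
        pd.DataFrame(
            sorted(assignment.items()), columns=["sample", "cluster"]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        return newick, assignment

    newick, assignment = _stage("cluster")(_cluster)()

    def _bsa():
        selected, undetermined = cluster_mod.select_candidate_markers(
            matrix, design, return_undetermined=True
        )
        pd.DataFrame(
            [
                {
                    "band": c.band.label,
                    "pair_name": c.band.pair_name,
                    "size": c.band.size_bin,
                }
                for c in selected
            ],
            columns=["band", "pair_name", "size"],
        ).to_csv(out / "bsa_candidates.tsv", sep="\t", index=False)
        return selected, undetermined

    candidates, undetermined = _stage("bsa-select")(_bsa)()

    pic_values = [r.pic for r in pic_results if not np.isnan(r.pic)]
    summary = {
        "n_mirna_primers": len(mirna_primers),
        "n_issr_primers": len(issr_primers),
        "n_pairs": len(pairs),
        "n_mirna_mirna_pairs": len(mirna_primers) * (len(mirna_primers) - 1) // 2,
        "n_mirna_issr_pairs": len(mirna_primers) * len(issr_primers),
        "n_ssr_loci": len(loci),
        "n_genomes": len(genomes),
        "n_bands": len(matrix.bands),
        "n_polymorphic_pairs": int(sum(poly_flags.values())),
        "pct_polymorphic_pairs": float(pct_pairs),
        "pct_polymorphic_loci": float(pct_loci),
        "mean_pic": round(float(np.mean(pic_values)), 4) if pic_values else None,
        "n_clusters": len(set(assignment.values())),
        "n_bsa_candidates": len(candidates),
        "n_bsa_undetermined": len(undetermined),
    }
    with open(out / "summary.yaml", "w") as handle:
        yaml.safe_dump(summary, handle, sort_keys=False)

    return PipelineResult(
        config=cfg,
        matrix=matrix,
        pairs=pairs,
        newick=newick,
        clusters=assignment,
        candidates=candidates,
        summary=summary,
    )
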