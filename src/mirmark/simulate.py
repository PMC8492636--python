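"""Deterministic synthetic genotype panels for end-to-end testing.

The generator emulates the study design this toolkit targets: a set of
genotypes grouped into tolerant and sensitive bulks, genomes carrying
planted miRNA primer-site pairs, SSR tracts, and insertion/deletion
polymorphisms, plus a transcript set with planted SSR tracts from which the
ISSR primers are derived.  Everything is reproducible byte-for-byte from the
seed.

Marker loci are planted as cassettes: a forward primer site, a spacer, and
the reverse complement of a second primer's site, so in-silico PCR recovers
one product of known size per cassette.  Four locus kinds are planted:

* ``shared`` — carried by every genotype (monomorphic band);
* ``presence`` — carried by a random subset (presence/absence band);
* ``shift`` — carried by all, but a random subset holds an extra 50–400 bp
  insertion in the spacer (two size bins for one pair);
* ``discriminative`` — carried by every tolerant-bulk genotype and no
  sensitive genotype: the trait-linked loci that bulked-sample selection
  must recover.

Neutral loci are neutral by construction: carrier sets whose pooled-bulk
pattern would satisfy the selection rule (band in every tolerant bulk,
absent from every sensitive bulk) are resampled.  Background gaps between
cassettes exceed the amplicon window, so no spurious cross-cassette
products arise.  Background GC content is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .bands import BandMatrix
from .cluster import BulkDesign
from .primers import (
    Primer,
    PrimerPair,
    combine_across,
    combine_within,
    design_issr_primer,
    design_mirna_primer,
)
from .seqio import (
    Arm,
    MatureMiRNA,
    NucleotideSequence,
    reverse_complement,
    write_fasta,
    write_mirna_fasta,
)
from .ssr import SSRThresholds, find_ssrs_many, motif_frequency, select_motifs

#: default miRNA panel: eight salt-responsive miRNA families with arms
DEFAULT_MIRNAS: tuple[tuple[str, str], ...] = (
    ("mir171g", "5p"), ("mir393e", "3p"), ("mir172b", "5p"), ("mir166k", "3p"),
    ("mir399a", "5p"), ("mir827", "3p"), ("mir482b", "5p"), ("mir164h", "3p"),
)

#: default SSR plan: (motif, repeat count, number of transcripts carrying it)
DEFAULT_SSR_PLAN: tuple[tuple[str, int, int], ...] = (
    ("TC", 8, 4), ("AG", 7, 3), ("GAA", 6, 3),
    ("CCA", 6, 2), ("GACCA", 5, 2), ("CTACT", 5, 1),
)

_ISSR_SUFFIXES = "CDTSLOABEFGH"  # ISSR-PvC, ISSR-PvD, ... naming sequence
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Panel-generation parameters; identical configs give identical bytes."""

    seed: int = 0
    n_tolerant_bulks: int = 2
    n_sensitive_bulks: int = 1
    genotypes_per_bulk: int = 3
    mirnas: tuple[tuple[str, str], ...] = DEFAULT_MIRNAS
    mirna_length: int = 21
    ssr_plan: tuple[tuple[str, int, int], ...] = DEFAULT_SSR_PLAN
    transcript_pad: int = 250
    n_shared_loci: int = 4
    n_presence_loci: int = 3
    n_shift_loci: int = 2
    n_discriminative_loci: int = 3
    amplicon_size_range: tuple[int, int] = (250, 1100)
    shift_range: tuple[int, int] = (50, 400)
    gap_range: tuple[int, int] = (3100, 3600)
    anchor_len: int = 2
    issr_target_len: int = 18
    band_dropout: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.band_dropout < 1:
            raise ValueError("band_dropout must be in [0, 1)")
        if self.gap_range[0] <= 3000:
            raise ValueError("gaps must exceed the amplicon window (3000 bp)")


@dataclass(frozen=True)
class MarkerTruth:
    """Ground truth for one planted marker locus."""

    name: str
    kind: str  # shared | presence | shift | discriminative
    pair_name: str
    base_size: int
    carriers: tuple[str, ...]
    shift: int = 0
    shift_carriers: tuple[str, ...] = ()


@dataclass
class SimulatedPanel:
    """A generated panel: genomes, truth, inputs for every pipeline stage."""

    config: SimConfig
    bulk_design: BulkDesign
    genomes: list[NucleotideSequence]
    mirnas: list[MatureMiRNA]
    transcripts: list[NucleotideSequence]
    mirna_primers: list[Primer]
    issr_primers: list[Primer]
    pairs: list[PrimerPair]
    marker_truth: list[MarkerTruth]
    feature_truth: pd.DataFrame  # genotype, feature, name, start, end (1-based)

    @property
    def samples(self) -> list[str]:
        return [g.id for g in self.genomes]

    def expected_observations(self) -> list[tuple[str, str, float]]:
        """The (pair_name, sample, size) records ideal scoring would produce."""
        obs: list[tuple[str, str, float]] = []
        for m in self.marker_truth:
            for sample in m.carriers:
                size = m.base_size + (m.shift if sample in m.shift_carriers else 0)
                obs.append((m.pair_name, sample, float(size)))
        return obs

    def discriminative_bands(self) -> set[tuple[str, int]]:
        return {
            (m.pair_name, m.base_size)
            for m in self.marker_truth
            if m.kind == "discriminative"
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genomes, out / "genomes.fasta")
        write_mirna_fasta(self.mirnas, out / "mirnas.fasta")
        write_fasta(self.transcripts, out / "transcripts.fasta")
        self.feature_truth.to_csv(out / "feature_truth.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "name": m.name, "kind": m.kind, "pair_name": m.pair_name,
                    "base_size": m.base_size, "shift": m.shift,
                    "carriers": ",".join(m.carriers),
                    "shift_carriers": ",".join(m.shift_carriers),
                }
                for m in self.marker_truth
            ]
        ).to_csv(out / "marker_truth.tsv", sep="\t", index=False)
        with open(out / "bulks.yaml", "w") as handle:
            yaml.safe_dump(self.bulk_design.to_dict(), handle, sort_keys=False)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return _random_dna(rng, length).replace("T", "U")


def _pick_base(rng: np.random.Generator, excluded: set[str]) -> str:
    choices = [b for b in "ACGT" if b not in excluded]
    return choices[int(rng.integers(0, len(choices)))]


def _bulk_pattern_selected(carriers: set[str], design: BulkDesign) -> bool:
    """True when a carrier set realises the BSA selection pattern."""
    in_every_tolerant = all(
        any(s in carriers for s in bulk) for bulk in design.tolerant_bulks
    )
    in_no_sensitive = all(
        all(s not in carriers for s in bulk) for bulk in design.sensitive_bulks
    )
    return in_every_tolerant and in_no_sensitive


def _neutral_subset(
    rng: np.random.Generator, samples: Sequence[str], design: BulkDesign
) -> tuple[str, ...]:
    """A random proper non-empty subset whose pattern is NOT selectable."""
    n = len(samples)
    while True:
        mask = rng.random(n) < rng.uniform(0.2, 0.8)
        carriers = {s for s, m in zip(samples, mask) if m}
        if not carriers or len(carriers) == n:
            continue
        if _bulk_pattern_selected(carriers, design):
            continue
        return tuple(s for s in samples if s in carriers)


def simulate_panel(cfg: SimConfig) -> SimulatedPanel:
    """Generate a full synthetic panel from one config (deterministic)."""
    rng = np.random.default_rng(cfg.seed)

    tolerant = tuple(
        tuple(f"T{b + 1}_g{i + 1}" for i in range(cfg.genotypes_per_bulk))
        for b in range(cfg.n_tolerant_bulks)
    )
    sensitive = tuple(
        tuple(f"S{b + 1}_g{i + 1}" for i in range(cfg.genotypes_per_bulk))
        for b in range(cfg.n_sensitive_bulks)
    )
    design = BulkDesign(tolerant_bulks=tolerant, sensitive_bulks=sensitive)
    samples = design.all_samples
    tolerant_samples = [s for bulk in tolerant for s in bulk]

    # --- miRNAs and their primers -------------------------------------------
    arm_map = {"5p": Arm.FIVE_PRIME, "3p": Arm.THREE_PRIME}
    mirnas = [
        MatureMiRNA(name, _random_rna(rng, cfg.mirna_length), arm_map[arm])
        for name, arm in cfg.mirnas
    ]
    mirna_primers = [design_mirna_primer(m) for m in mirnas]

    # --- transcripts with planted SSR tracts, then ISSR primers -------------
    anchors: dict[str, str] = {}
    for motif, _, _ in cfg.ssr_plan:
        first = _pick_base(rng, {motif[0]})
        anchors[motif] = first + _pick_base(rng, set())
    transcripts: list[NucleotideSequence] = []
    gene_no = 0
    for motif, reps, n_transcripts in cfg.ssr_plan:
        for _ in range(n_transcripts):
            gene_no += 1
            guard = _pick_base(rng, {motif[-1]})
            seq = (
                _random_dna(rng, cfg.transcript_pad)
                + guard
                + motif * reps
                + anchors[motif]
                + _random_dna(rng, cfg.transcript_pad)
            )
            transcripts.append(NucleotideSequence(id=f"gene{gene_no:03d}", residues=seq))

    loci = find_ssrs_many(transcripts, SSRThresholds())
    freq = motif_frequency(loci)
    chosen = select_motifs(freq, k_per_unit=2, unit_lengths=(2, 3, 5))
    issr_primers = [
        design_issr_primer(
            motif,
            transcripts,
            anchor_len=cfg.anchor_len,
            target_len=cfg.issr_target_len,
            name=f"ISSR-Pv{_ISSR_SUFFIXES[i]}",
        )
        for i, motif in enumerate(chosen)
    ]

    pairs = combine_within(mirna_primers) + combine_across(mirna_primers, issr_primers)

    # --- marker cassettes ----------------------------------------------------
    n_loci = (
        cfg.n_shared_loci + cfg.n_presence_loci + cfg.n_shift_loci
        + cfg.n_discriminative_loci
    )
    if n_loci > len(pairs):
        raise ValueError(f"{n_loci} loci requested but only {len(pairs)} pairs exist")
    pair_idx = rng.choice(len(pairs), size=n_loci, replace=False)
    kinds = (
        ["shared"] * cfg.n_shared_loci
        + ["presence"] * cfg.n_presence_loci
        + ["shift"] * cfg.n_shift_loci
        + ["discriminative"] * cfg.n_discriminative_loci
    )
    lo, hi = cfg.amplicon_size_range
    truth: list[MarkerTruth] = []
    cassette_parts: list[tuple[str, str, int]] = []  # (front, spacer-insert point handled below)
    cassettes: list[dict] = []
    for i, (kind, p_i) in enumerate(zip(kinds, pair_idx)):
        pair = pairs[int(p_i)]
        fwd, rev = pair.primer_a, pair.primer_b
        size = int(rng.integers(lo, hi + 1))
        fill_len = size - len(fwd) - len(rev)
        fill = _random_dna(rng, fill_len)
        base_seq = fwd.sequence + fill + reverse_complement(rev.sequence)
        shift = 0
        shift_carriers: tuple[str, ...] = ()
        insert_at = len(fwd.sequence) + fill_len // 2
        insert_seq = ""
        if kind == "shared":
            carriers = tuple(samples)
        elif kind == "presence":
            carriers = _neutral_subset(rng, samples, design)
        elif kind == "shift":
            carriers = tuple(samples)
            shift = int(rng.integers(cfg.shift_range[0], cfg.shift_range[1] + 1))
            insert_seq = _random_dna(rng, shift)
            while True:
                shift_carriers = _neutral_subset(rng, samples, design)
                others = set(samples) - set(shift_carriers)
                if not _bulk_pattern_selected(others, design):
                    break
        else:  # discriminative
            carriers = tuple(tolerant_samples)
        truth.append(
            MarkerTruth(
                name=f"locus{i + 1:02d}",
                kind=kind,
                pair_name=pair.pair_name,
                base_size=size,
                carriers=carriers,
                shift=shift,
                shift_carriers=shift_carriers,
            )
        )
        cassettes.append(
            {
                "seq": base_seq,
                "insert_at": insert_at,
                "insert_seq": insert_seq,
                "truth": truth[-1],
            }
        )

    # --- genome block layout (identical backgrounds; absence = deletion) ----
    blocks: list[tuple[str, object]] = []
    for cassette in cassettes:
        blocks.append(("bg", _random_dna(rng, int(rng.integers(*cfg.gap_range)))))
        blocks.append(("cassette", cassette))
    for motif, reps, _ in cfg.ssr_plan:
        blocks.append(("bg", _random_dna(rng, int(rng.integers(*cfg.gap_range)))))
        pre = _pick_base(rng, {motif[-1]})
        post = _pick_base(rng, {motif[0], anchors[motif][0]})
        blocks.append(("ssr", (motif, reps, pre + motif * reps + post)))
    blocks.append(("bg", _random_dna(rng, int(rng.integers(*cfg.gap_range)))))

    genomes: list[NucleotideSequence] = []
    feature_rows: list[dict] = []
    for sample in samples:
        parts: list[str] = []
        pos = 0
        for kind, payload in blocks:
            if kind == "bg":
                parts.append(payload)  # type: ignore[arg-type]
                pos += len(payload)  # type: ignore[arg-type]
            elif kind == "ssr":
                motif, reps, block = payload  # type: ignore[misc]
                parts.append(block)
                feature_rows.append(
                    {
                        "genotype": sample, "feature": "ssr", "name": motif,
                        "start": pos + 2, "end": pos + 1 + len(motif) * reps,
                    }
                )
                pos += len(block)
            else:
                cassette = payload  # type: ignore[assignment]
                m: MarkerTruth = cassette["truth"]
                if sample not in m.carriers:
                    continue
                seq = cassette["seq"]
                if sample in m.shift_carriers:
                    at = cassette["insert_at"]
                    seq = seq[:at] + cassette["insert_seq"] + seq[at:]
                parts.append(seq)
                feature_rows.append(
                    {
                        "genotype": sample, "feature": "marker", "name": m.name,
                        "start": pos + 1, "end": pos + len(seq),
                    }
                )
                pos += len(seq)
        genomes.append(NucleotideSequence(id=sample, residues="".join(parts)))

    feature_truth = pd.DataFrame(
        feature_rows, columns=["genotype", "feature", "name", "start", "end"]
    )

    _verify_truth(genomes, feature_truth, {c["truth"].name: c for c in cassettes})

    return SimulatedPanel(
        config=cfg,
        bulk_design=design,
        genomes=genomes,
        mirnas=mirnas,
        transcripts=transcripts,
        mirna_primers=mirna_primers,
        issr_primers=issr_primers,
        pairs=pairs,
        marker_truth=truth,
        feature_truth=feature_truth,
    )


def _verify_truth(
    genomes: Sequence[NucleotideSequence],
    feature_truth: pd.DataFrame,
    cassettes_by_name: dict[str, dict],
) -> None:
    """Check recorded coordinates against the assembled genomes."""
    by_id = {g.id: g.residues for g in genomes}
    for row in feature_truth.itertuples(index=False):
        segment = by_id[row.genotype][row.start - 1: row.end]
        if row.feature == "ssr":
            motif = row.name
            reps = (row.end - row.start + 1) // len(motif)
            assert segment == motif * reps, f"SSR truth mismatch at {row}"
        else:
            cassette = cassettes_by_name[row.name]
            expected = cassette["seq"]
            if len(segment) != len(expected):
                at = cassette["insert_at"]
                expected = expected[:at] + cassette["insert_seq"] + expected[at:]
            assert segment == expected, f"marker truth mismatch at {row}"


def degrade_bands(
    matrix: BandMatrix, dropout: float, seed: int | None = None
) -> BandMatrix:
    """Flip presence calls to absence independently with probability ``dropout``.

    Models gel scoring noise (faint bands missed); absences and NA are left
    untouched.  Reproducible under ``seed``.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    arr = values.to_numpy()
    flips = (arr == 1.0) & (rng.random(arr.shape) < dropout)
    arr[flips] = 0.0
    values.iloc[:, :] = arr
    return BandMatrix(matrix.bands, matrix.samples, values)
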