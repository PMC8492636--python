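"""miRNA-derived and semi-random anchored ISSR primer construction.

The miRNA rule: a mature miRNA from the 5' arm of its precursor is
back-transcribed and reverse-complemented; a 3'-arm miRNA is only
back-transcribed.  Both then read 5'→3' as synthesizable DNA primers whose
genomic target sites are the miRNA/miRNA* positions, so two such primers
flanking a locus amplify the sequence between neighbouring miRNA sites.

ISSR primers are a repeat block (the selected SSR motif, enough units to
reach the target length) plus a short 3' anchor.  The anchor is
"semi-random": not arbitrary, but the most frequent k-mer observed
immediately 3' of that motif's tracts in the supplied template genes,
excluding k-mers that would merely extend the repeat.
"""

from __future__ import annotations

import enum
import itertools
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import (
    Arm,
    MatureMiRNA,
    NucleotideSequence,
    SequenceError,
    reverse_complement,
    rna_to_dna,
)
from .ssr import SSRThresholds, find_ssrs


class PrimerKind(str, enum.Enum):
    MIRNA = "miRNA"
    ISSR = "ISSR"


@dataclass(frozen=True)
class Primer:
    """A single-stranded DNA primer, 5'→3', with its provenance.

    For miRNA primers ``provenance`` is ``(source miRNA name, arm)``; for
    ISSR primers it is ``(motif, n_repeat_units, anchor, anchor_source)``.
    """

    name: str
    sequence: str
    kind: PrimerKind
    provenance: tuple = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 15:
            raise SequenceError(f"primer {self.name!r}: length {len(seq)} < 15")
        if not set(seq) <= set("ACGT"):
            raise SequenceError(
                f"primer {self.name!r}: primers must be unambiguous DNA (no N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        """GC fraction, reported for information only (no Tm screening)."""
        return (self.sequence.count("G") + self.sequence.count("C")) / len(self)


@dataclass(frozen=True)
class PrimerPair:
    """An unordered pair of distinct primers defining one marker assay."""

    primer_a: Primer
    primer_b: Primer

    def __post_init__(self) -> None:
        if self.primer_a.name == self.primer_b.name:
            raise ValueError(f"primer pair requires two distinct primers, got {self.primer_a.name!r} twice")
        # canonical order by name so pair(a,b) == pair(b,a)
        if self.primer_b.name < self.primer_a.name:
            a, b = self.primer_a, self.primer_b
            object.__setattr__(self, "primer_a", b)
            object.__setattr__(self, "primer_b", a)

    @property
    def pair_name(self) -> str:
        return f"{self.primer_a.name} + {self.primer_b.name}"

    @property
    def primers(self) -> tuple[Primer, Primer]:
        return (self.primer_a, self.primer_b)


def design_mirna_primer(mirna: MatureMiRNA) -> Primer:
    """Build the DNA primer for one mature miRNA according to its arm.

    5'-arm miRNAs are reverse-complemented (after U→T); 3'-arm miRNAs are
    used as-is (after U→T).
    """
    dna = rna_to_dna(mirna.sequence)
    if mirna.arm is Arm.FIVE_PRIME:
        seq = reverse_complement(dna)
    else:
        seq = dna
    return Primer(
        name=mirna.name,
        sequence=seq,
        kind=PrimerKind.MIRNA,
        provenance=(mirna.name, mirna.arm.value),
    )


def design_issr_primer(
    motif: str,
    templates: Sequence[NucleotideSequence],
    anchor_len: int = 2,
    target_len: int = 18,
    name: str | None = None,
    thresholds: SSRThresholds | None = None,
) -> Primer:
    """Design a 3'-anchored ISSR primer for one selected SSR motif.

    The repeat block holds ``n = ceil((target_len - anchor_len)/len(motif))``
    units.  The anchor is the most frequent ``anchor_len``-mer immediately 3'
    of the motif's tracts in ``templates``; candidates starting with the next
    repeat base (which would extend the tract) or containing N are excluded.
    Ties break lexicographically for reproducibility.
    """
    motif = motif.upper()
    if not 1 <= anchor_len <= 4:
        raise ValueError("anchor_len must be between 1 and 4")
    if target_len <= anchor_len:
        raise ValueError("target_len must exceed anchor_len")

    flank_counts: Counter[str] = Counter()
    n_tracts = 0
    for template in templates:
        for locus in find_ssrs(template, thresholds):
            if locus.motif != motif:
                continue
            n_tracts += 1
            flank = template.residues[locus.end: locus.end + anchor_len]
            if len(flank) < anchor_len or "N" in flank:
                continue
            if flank[0] == motif[0]:  # would extend the repeat
                continue
            flank_counts[flank] += 1
    if n_tracts == 0:
        raise ValueError(f"motif {motif!r} has no qualifying SSR tract in the templates")
    if not flank_counts:
        raise ValueError(
            f"motif {motif!r}: every observed flank extends the repeat; "
            f"try a longer anchor_len"
        )
    anchor = min(flank_counts, key=lambda k: (-flank_counts[k], k))
    n_units = math.ceil((target_len - anchor_len) / len(motif))
    sequence = motif * n_units + anchor
    return Primer(
        name=name or f"ISSR-{motif}",
        sequence=sequence,
        kind=PrimerKind.ISSR,
        provenance=(motif, n_units, anchor, tuple(sorted({t.id for t in templates}))),
    )


def _check_unique_names(primers: Sequence[Primer]) -> None:
    names = [p.name for p in primers]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate primer names: {sorted(dupes)}")


def combine_within(primers: Sequence[Primer]) -> list[PrimerPair]:
    """All unordered pairs of distinct primers: n primers → n(n−1)/2 pairs."""
    if len(primers) < 2:
        raise ValueError("need at least two primers to combine")
    _check_unique_names(primers)
    ordered = sorted(primers, key=lambda p: p.name)
    return [PrimerPair(a, b) for a, b in itertools.combinations(ordered, 2)]


def combine_across(
    set_a: Sequence[Primer],
    set_b: Sequence[Primer],
    subsample: int | None = None,
    seed: int | None = None,
) -> list[PrimerPair]:
    """Full cross product of two primer sets: |a|×|b| pairs.

    ``subsample`` with a ``seed`` draws a reproducible random subset,
    realising "randomly combined" designs of a given size.
    """
    if not set_a or not set_b:
        raise ValueError("both primer sets must be non-empty")
    overlap = {p.name for p in set_a} & {p.name for p in set_b}
    if overlap:
        raise ValueError(f"primer sets share names: {sorted(overlap)}")
    _check_unique_names(list(set_a) + list(set_b))
    pairs = [
        PrimerPair(a, b)
        for a in sorted(set_a, key=lambda p: p.name)
        for b in sorted(set_b, key=lambda p: p.name)
    ]
    pairs.sort(key=lambda p: p.pair_name)
    if subsample is not None:
        if subsample > len(pairs):
            raise ValueError(f"cannot subsample {subsample} of {len(pairs)} pairs")
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(pairs), size=subsample, replace=False))
        pairs = [pairs[i] for i in idx]
    return pairs


def primer_table(primers: Iterable[Primer]) -> pd.DataFrame:
    """Primer report: name, kind, sequence, length, GC%, provenance."""
    rows = []
    for p in primers:
        rows.append(
            {
                "name": p.name,
                "kind": p.kind.value,
                "sequence": p.sequence,
                "length": len(p),
                "gc_percent": round(100 * p.gc_fraction, 1),
                "provenance": ";".join(str(x) for x in p.provenance),
            }
        )
    return pd.DataFrame(
        rows, columns=["name", "kind", "sequence", "length", "gc_percent", "provenance"]
    )


def write_primer_tsv(primers: Iterable[Primer], path: str | Path) -> None:
    primer_table(primers).to_csv(path, sep="\t", index=False)
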