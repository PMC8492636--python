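"""Perfect-microsatellite (SSR) mining with MISA-compatible semantics.

Detects maximal perfect tandem repeats of unit length 2–6 in DNA sequences,
applying per-unit minimum repeat counts (default 6,5,5,4,4 for di- through
hexa-nucleotide motifs).  A motif that is itself a tandem repetition of a
shorter unit is reported at the shorter unit (``ATATATAT`` is an AT repeat,
never an ATAT repeat), which also suppresses duplicate reports of one tract
at several unit sizes.  Mononucleotide runs are never reported.  ``N``
matches nothing and breaks a tract.

Coordinates in :class:`SSRLocus` are 1-based inclusive, matching MISA
output; adjacent loci within 100 nt are additionally reported as compound
annotations but counted individually in motif frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import DNA_ALPHABET, NucleotideSequence, SequenceError

#: MISA thresholds used throughout: minimum repeat counts per unit length.
DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 4, 6: 4}


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum repeat count per motif unit length (2–6)."""

    min_repeats: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {2, 3, 4, 5, 6}:
            raise ValueError("min_repeats keys must be exactly {2,3,4,5,6}")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("minimum repeat counts must be >= 2")


@dataclass(frozen=True, order=True)
class SSRLocus:
    """One perfect tandem repeat locus (1-based inclusive coordinates)."""

    sequence_id: str
    start: int
    end: int
    motif: str
    repeat_count: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.repeat_count:
            raise ValueError(
                f"locus {self.sequence_id}:{self.start}-{self.end}: span "
                f"inconsistent with {self.motif} x {self.repeat_count}"
            )

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def is_primitive_motif(motif: str) -> bool:
    """True if the motif is not a tandem repetition of any shorter unit.

    ``AT`` is primitive; ``ATAT`` and ``AA`` are not.
    """
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def find_ssrs(
    seq: NucleotideSequence | str,
    thresholds: SSRThresholds | None = None,
    sequence_id: str | None = None,
) -> list[SSRLocus]:
    """Find all maximal perfect SSR loci in one DNA sequence.

    Returns loci sorted left-to-right (then by unit length).  Within a
    maximal run of period ``u`` only whole repeat units are reported, so a
    13-nt AG-run yields ``(AG)6`` covering 12 nt, as MISA does.
    """
    if isinstance(seq, NucleotideSequence):
        residues, seq_id = seq.residues, seq.id
    else:
        residues, seq_id = seq.upper(), sequence_id or "seq"
    if not set(residues) <= DNA_ALPHABET:
        bad = sorted(set(residues) - DNA_ALPHABET)
        raise SequenceError(f"find_ssrs requires DNA; illegal characters {bad}")
    thresholds = thresholds or SSRThresholds()

    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    not_n = arr != ord("N")
    loci: list[SSRLocus] = []
    for u, min_rep in thresholds.min_repeats.items():
        if n < u * min_rep:
            continue
        # eq[k] marks residue positions k+u that repeat the base u earlier
        eq = (arr[u:] == arr[:-u]) & not_n[u:] & not_n[:-u]
        # run boundaries in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive, in eq coordinates
        for s, e in zip(starts, ends):
            tract_start = s          # first base of the run (eq index k ↔ base k+u)
            tract_len = (e - s) + u  # bases covered by the periodic run
            count = tract_len // u
            if count < min_rep:
                continue
            motif = residues[tract_start:tract_start + u]
            if "N" in motif or not is_primitive_motif(motif):
                continue
            loci.append(
                SSRLocus(
                    sequence_id=seq_id,
                    start=tract_start + 1,
                    end=tract_start + count * u,
                    motif=motif,
                    repeat_count=count,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def find_ssrs_many(
    seqs: Iterable[NucleotideSequence],
    thresholds: SSRThresholds | None = None,
) -> list[SSRLocus]:
    """Mine every sequence of a collection; loci keep their sequence ids."""
    out: list[SSRLocus] = []
    for s in seqs:
        out.extend(find_ssrs(s, thresholds))
    return out


def compound_ssrs(loci: Sequence[SSRLocus], max_gap: int = 100) -> list[tuple[SSRLocus, ...]]:
    """Group adjacent loci of one sequence within ``max_gap`` nt (compound SSRs).

    Loci are still counted individually in frequencies; this is annotation
    only, mirroring MISA's compound reporting.
    """
    groups: list[tuple[SSRLocus, ...]] = []
    by_seq: dict[str, list[SSRLocus]] = {}
    for locus in sorted(loci, key=lambda l: (l.sequence_id, l.start)):
        by_seq.setdefault(locus.sequence_id, []).append(locus)
    for seq_loci in by_seq.values():
        current = [seq_loci[0]]
        for locus in seq_loci[1:]:
            if locus.start - current[-1].end - 1 <= max_gap:
                current.append(locus)
            else:
                if len(current) > 1:
                    groups.append(tuple(current))
                current = [locus]
        if len(current) > 1:
            groups.append(tuple(current))
    return groups


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest cyclic rotation (reverse complements NOT merged)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def motif_frequency(loci: Sequence[SSRLocus], canonicalize: bool = False) -> pd.DataFrame:
    """Tabulate locus counts per motif.

    Columns ``motif, unit_length, locus_count``, sorted by unit length then
    descending count (ties lexicographic).  With ``canonicalize`` cyclic
    rotations are merged to their lexicographic representative; reverse
    complements are never merged (TC and AG stay distinct selections).
    """
    counts: dict[str, int] = {}
    for locus in loci:
        key = canonical_rotation(locus.motif) if canonicalize else locus.motif
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"motif": m, "unit_length": len(m), "locus_count": c}
        for m, c in counts.items()
    ]
    table = pd.DataFrame(rows, columns=["motif", "unit_length", "locus_count"])
    if len(table):
        table = table.sort_values(
            ["unit_length", "locus_count", "motif"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return table


def exclusive_transcripts(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """Split two gene-id sets into (only_a, only_b, shared) — Venn partition."""
    a, b = set(set_a), set(set_b)
    return a - b, b - a, a & b


def select_motifs(
    freq: pd.DataFrame,
    gene_activity: Mapping[str, float] | None = None,
    loci: Sequence[SSRLocus] | None = None,
    k_per_unit: int = 1,
    unit_lengths: Sequence[int] = (2, 3, 5),
    w_abund: float = 1.0,
    w_act: float = 0.0,
) -> list[str]:
    """Pick the top motifs per unit length for ISSR design.

    Score per motif = ``w_abund * rank_norm(locus_count) + w_act *
    rank_norm(mean activity of host genes)``, where rank_norm maps ranks
    within one unit length to [0, 1].  With no activity table the choice
    reduces to abundance; activity (when given, together with the mined
    ``loci`` to know host genes) breaks abundance ties.  Di-, tri- and
    penta-nucleotide motifs are considered by default.
    """
    if freq is None or not len(freq):
        raise ValueError("motif frequency table is empty")
    if gene_activity is not None and w_act == 0.0:
        w_act = 1.0  # supplying a table implies it should matter

    activity_per_motif: dict[str, float] = {}
    if gene_activity is not None and loci is not None:
        sums: dict[str, list[float]] = {}
        for locus in loci:
            score = gene_activity.get(locus.sequence_id)
            if score is not None:
                sums.setdefault(locus.motif, []).append(float(score))
        activity_per_motif = {m: float(np.mean(v)) for m, v in sums.items()}

    def rank_norm(values: list[float]) -> list[float]:
        if len(values) == 1:
            return [1.0]
        order = pd.Series(values).rank(method="average")
        return list((order - 1) / (len(values) - 1))

    chosen: list[str] = []
    for u in unit_lengths:
        sub = freq[freq["unit_length"] == u]
        if not len(sub):
            continue
        motifs = list(sub["motif"])
        ab = rank_norm([float(c) for c in sub["locus_count"]])
        act = rank_norm([activity_per_motif.get(m, 0.0) for m in motifs])
        scored = sorted(
            zip(motifs, ab, act),
            key=lambda t: (-(w_abund * t[1] + w_act * t[2]), -t[2], t[0]),
        )
        k = k_per_unit
        if k > len(scored):
            warnings.warn(
                f"requested {k} motifs of unit length {u}, only {len(scored)} available",
                stacklevel=2,
            )
            k = len(scored)
        chosen.extend(m for m, _, _ in scored[:k])
    return chosen


def write_misa_tsv(loci: Sequence[SSRLocus], path: str | Path) -> None:
    """Write loci as a MISA-style TSV (1-based inclusive coordinates)."""
    rows = []
    counter: dict[str, int] = {}
    for locus in sorted(loci, key=lambda l: (l.sequence_id, l.start)):
        counter[locus.sequence_id] = counter.get(locus.sequence_id, 0) + 1
        rows.append(
            {
                "sequence_id": locus.sequence_id,
                "ssr_nr": counter[locus.sequence_id],
                "motif": f"({locus.motif}){locus.repeat_count}",
                "size": locus.length,
                "start": locus.start,
                "end": locus.end,
            }
        )
    pd.DataFrame(
        rows, columns=["sequence_id", "ssr_nr", "motif", "size", "start", "end"]
    ).to_csv(path, sep="\t", index=False)


def read_gene_activity(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (gene_id, score) into a mapping.

    The score is typically |log2 fold-change| from a differential-expression
    table; any non-negative per-gene activity works.
    """
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, score)")
    gene_col, score_col = frame.columns[:2]
    return dict(zip(frame[gene_col].astype(str), frame[score_col].astype(float)))
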