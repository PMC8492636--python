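"""In-silico PCR: primer binding-site search and amplicon prediction.

A primer binds the plus strand where its sequence matches the template
left-to-right (3' end pointing right); it binds the minus strand where its
reverse complement matches the template (3' end pointing left).  Matching
tolerates up to ``max_mismatch`` mismatches but the 3'-terminal seed
(default 3 nt) must be exact — polymerases do not extend 3' mismatches.
``N`` in the template matches nothing.

An amplicon is any convergent combination of a plus-strand site and a
minus-strand site downstream of it, drawn from either primer of the pair
(both from the same primer is single-primer amplification, as seen for
stem-loop products), with a product length inside the configured window and
no overlap of the two primer footprints.

All reported coordinates are 1-based inclusive; ``position`` of a binding
site is the leftmost template base of the footprint on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import DNA_ALPHABET, NucleotideSequence, SequenceError, reverse_complement
from .primers import Primer, PrimerPair

#: defaults: exact matching keeps predictions deterministic; the product
#: window is generous around typically observed 200–1200 bp products.
DEFAULT_MAX_MISMATCH = 0
DEFAULT_SEED_LEN = 3
DEFAULT_MIN_LEN = 100
DEFAULT_MAX_LEN = 3000


@dataclass(frozen=True)
class BindingSite:
    """One primer annealing site; position is 1-based, leftmost footprint base."""

    template_id: str
    position: int
    strand: str  # '+' or '-'
    mismatches: int
    primer_name: str
    primer_length: int

    @property
    def footprint_end(self) -> int:
        """Rightmost template base covered (1-based inclusive)."""
        return self.position + self.primer_length - 1


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product spanning the outermost primer bases."""

    template_id: str
    start: int
    end: int
    forward_site: BindingSite
    reverse_site: BindingSite
    pair_name: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _template_array(template: NucleotideSequence | str) -> tuple[np.ndarray, str, str]:
    if isinstance(template, NucleotideSequence):
        residues, tid = template.residues, template.id
    else:
        residues, tid = template.upper(), "template"
    if not set(residues) <= DNA_ALPHABET:
        bad = sorted(set(residues) - DNA_ALPHABET)
        raise SequenceError(f"template must be DNA; illegal characters {bad}")
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8), residues, tid


def _scan(
    template_arr: np.ndarray, query: str, max_mismatch: int, seed: str, seed_at_end: bool
) -> list[tuple[int, int]]:
    """All 0-based offsets where ``query`` matches with ≤ max_mismatch and an
    exact seed; returns (offset, mismatches).  ``seed_at_end`` places the
    exact-seed constraint at the right end of the window (plus strand),
    otherwise at the left end (minus strand)."""
    m = len(query)
    n = len(template_arr)
    if m > n:
        return []
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(template_arr, m)
    # N never matches: count N positions as mismatches
    mism = (windows != q).sum(axis=1) + ((windows == ord("N")) & (windows == q)).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatch)
    out: list[tuple[int, int]] = []
    s = len(seed)
    seed_arr = np.frombuffer(seed.encode("ascii"), dtype=np.uint8)
    for off in hits:
        window = windows[off]
        part = window[m - s:] if seed_at_end else window[:s]
        if np.array_equal(part, seed_arr) and not np.any(part == ord("N")):
            out.append((int(off), int(mism[off])))
    return out


def find_binding_sites(
    template: NucleotideSequence | str,
    primer: Primer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    seed_len: int = DEFAULT_SEED_LEN,
) -> list[BindingSite]:
    """All annealing sites of one primer on both strands of a template."""
    arr, residues, tid = _template_array(template)
    sites: list[BindingSite] = []
    m = len(primer)
    seed = primer.sequence[-seed_len:]
    # plus strand: primer sequence appears as-is; 3' seed at window right end
    for off, mm in _scan(arr, primer.sequence, max_mismatch, seed, seed_at_end=True):
        sites.append(BindingSite(tid, off + 1, "+", mm, primer.name, m))
    # minus strand: reverse complement appears; primer 3' end maps to window left end
    rc = reverse_complement(primer.sequence)
    rc_seed = rc[:seed_len]  # = revcomp of the primer's 3' seed
    for off, mm in _scan(arr, rc, max_mismatch, rc_seed, seed_at_end=False):
        sites.append(BindingSite(tid, off + 1, "-", mm, primer.name, m))
    sites.sort(key=lambda s: (s.position, s.strand, s.primer_name))
    return sites


def predict_amplicons(
    template: NucleotideSequence | str,
    pair: PrimerPair,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    seed_len: int = DEFAULT_SEED_LEN,
    sites: Sequence[BindingSite] | None = None,
) -> list[Amplicon]:
    """Predict all products of a primer pair on one template.

    ``sites`` may carry precomputed binding sites (e.g. from a panel-level
    cache); otherwise both primers are scanned here.  Zero amplicons is a
    valid result.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    if sites is None:
        sites = []
        for primer in pair.primers:
            sites.extend(find_binding_sites(template, primer, max_mismatch, seed_len))
    tid = sites[0].template_id if sites else (
        template.id if isinstance(template, NucleotideSequence) else "template"
    )
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    out: list[Amplicon] = []
    for fwd in plus:
        for rev in minus:
            if rev.position <= fwd.position:
                continue
            start, end = fwd.position, rev.footprint_end
            length = end - start + 1
            if length < fwd.primer_length + rev.primer_length:
                continue  # overlapping footprints cannot both prime
            if not (min_len <= length <= max_len):
                continue
            out.append(Amplicon(tid, start, end, fwd, rev, pair.pair_name))
    out.sort(key=lambda a: (a.template_id, a.start, a.end,
                            a.forward_site.primer_name, a.reverse_site.primer_name))
    return out


def binding_site_cache(
    template: NucleotideSequence,
    primers: Iterable[Primer],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    seed_len: int = DEFAULT_SEED_LEN,
) -> dict[str, list[BindingSite]]:
    """Scan each distinct primer once; reuse across the pairs that share it."""
    return {
        p.name: find_binding_sites(template, p, max_mismatch, seed_len)
        for p in {p.name: p for p in primers}.values()
    }


def amplify_panel(
    genomes: Iterable[NucleotideSequence],
    pairs: Sequence[PrimerPair],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    seed_len: int = DEFAULT_SEED_LEN,
) -> dict[str, list[Amplicon]]:
    """Run every pair against every genome; returns genome id → amplicons.

    Primer scans are shared across pairs, so the cost is O(genomes × primers)
    scans rather than O(genomes × pairs × 2).
    """
    all_primers = {p.name: p for pair in pairs for p in pair.primers}
    result: dict[str, list[Amplicon]] = {}
    for genome in genomes:
        cache = binding_site_cache(genome, all_primers.values(), max_mismatch, seed_len)
        amps: list[Amplicon] = []
        for pair in pairs:
            pair_sites = list(cache[pair.primer_a.name]) + list(cache[pair.primer_b.name])
            amps.extend(
                predict_amplicons(genome, pair, min_len, max_len, sites=pair_sites)
            )
        result[genome.id] = amps
    return result


def amplicon_table(amplicons: Iterable[Amplicon]) -> pd.DataFrame:
    rows = [
        {
            "template_id": a.template_id,
            "pair_name": a.pair_name,
            "start": a.start,
            "end": a.end,
            "length": a.length,
            "fwd_primer": a.forward_site.primer_name,
            "rev_primer": a.reverse_site.primer_name,
            "mismatches": a.forward_site.mismatches + a.reverse_site.mismatches,
        }
        for a in amplicons
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "template_id", "pair_name", "start", "end", "length",
            "fwd_primer", "rev_primer", "mismatches",
        ],
    )


def write_amplicon_tsv(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    amplicon_table(amplicons).to_csv(path, sep="\t", index=False)


def write_amplicon_bed(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    """BED export: 0-based half-open conversion of the 1-based inclusive spans."""
    with open(path, "w") as handle:
        for a in amplicons:
            handle.write(f"{a.template_id}\t{a.start - 1}\t{a.end}\t{a.pair_name}\n")
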