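"""Band matrices and marker statistics: PIC, percent polymorphism, transferability.

Gel band sizes are approximate, so observed sizes are binned per primer pair
by single-linkage clustering with a relative tolerance (default 2%).  The
resulting :class:`BandMatrix` holds presence (1) / absence (0) calls per
sample, with NA for whole-reaction amplification failures (a failed PCR for
a pair in a sample says nothing about any of that pair's bands).

PIC follows 1 − Σ p_i².  The default ``multiallelic`` mode treats each
distinct band of a primer pair as one allele class of a single multi-allelic
locus (p_i = share of that band among all presence calls of the pair), which
is the reading consistent with reported pair-level PIC values above the 0.5
ceiling of dominant biallelic scoring.  The ``dominant`` mode scores each
band as a biallelic dominant locus (1 − p² − (1−p)², ≤ 0.5) and averages
over the pair's bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Band:
    """A size-binned band of one primer pair."""

    pair_name: str
    bin_id: int
    size_bin: float  # representative (median) product length in bp

    @property
    def label(self) -> str:
        return f"{self.pair_name}:{self.bin_id}:{int(round(self.size_bin))}"


class BandMatrix:
    """Binary presence/absence of bands per sample (NaN encodes NA).

    Rows are bands, columns samples.  The underlying frame is available as
    ``.values`` for direct pandas work.
    """

    def __init__(self, bands: Sequence[Band], samples: Sequence[str], values: pd.DataFrame):
        if list(values.columns) != list(samples) or len(values) != len(bands):
            raise ValueError("matrix dimensions inconsistent with bands/samples")
        self.bands = list(bands)
        self.samples = list(samples)
        self.values = values.astype(float)
        self.values.index = [b.label for b in self.bands]

    def __repr__(self) -> str:
        return f"BandMatrix({len(self.bands)} bands x {len(self.samples)} samples)"

    @property
    def pair_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.bands:
            seen.setdefault(b.pair_name, None)
        return list(seen)

    def pair_rows(self, pair_name: str) -> pd.DataFrame:
        mask = [b.pair_name == pair_name for b in self.bands]
        return self.values.loc[mask]

    def subset_samples(self, samples: Sequence[str]) -> "BandMatrix":
        missing = [s for s in samples if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return BandMatrix(self.bands, list(samples), self.values[list(samples)].copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "band", [b.label for b in self.bands])
        frame = out.set_index("band")
        frame = frame.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BandMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        bands = []
        for label in frame.index:
            pair_name, bin_id, size = str(label).rsplit(":", 2)
            bands.append(Band(pair_name, int(bin_id), float(size)))
        return cls(bands, list(frame.columns), frame.reset_index(drop=True))

    @classmethod
    def from_records(
        cls,
        records: Mapping[str, Mapping[str, int | float | None]],
    ) -> "BandMatrix":
        """Build from {band_label: {sample: 0/1/None}} (None = NA); labels
        must follow the ``pair:bin:size`` convention."""
        labels = list(records)
        samples = list(next(iter(records.values())))
        bands = []
        for label in labels:
            pair_name, bin_id, size = label.rsplit(":", 2)
            bands.append(Band(pair_name, int(bin_id), float(size)))
        data = pd.DataFrame(
            [[np.nan if records[l][s] is None else float(records[l][s]) for s in samples]
             for l in labels],
            columns=samples,
        )
        return cls(bands, samples, data)


def bin_bands(
    observations: Iterable[tuple[str, str, float | None]],
    rel_tol: float = 0.02,
    samples: Sequence[str] | None = None,
) -> BandMatrix:
    """Bin observed (pair_name, sample, size) records into a band matrix.

    Sizes of one pair are clustered by single linkage: two sizes fall in the
    same bin when their gap is within ``rel_tol`` of the smaller size (chained
    transitively).  The bin representative is the member median.  A record
    with size ``None`` declares whole-reaction failure of that pair in that
    sample (NA for all of the pair's bands); samples with no record for a
    pair that amplified elsewhere simply lack those bands (0).
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    obs = list(observations)
    sample_ids: list[str] = list(samples) if samples is not None else []
    if samples is None:
        for _, sample, _ in obs:
            if sample not in sample_ids:
                sample_ids.append(sample)
    by_pair: dict[str, list[tuple[str, float]]] = {}
    failed: set[tuple[str, str]] = set()
    for pair_name, sample, size in obs:
        if sample not in sample_ids:
            raise KeyError(f"sample {sample!r} not in declared sample list")
        if size is None:
            failed.add((pair_name, sample))
            continue
        if size <= 0:
            raise ValueError(f"band size must be positive, got {size}")
        by_pair.setdefault(pair_name, []).append((sample, float(size)))

    bands: list[Band] = []
    rows: list[list[float]] = []
    for pair_name in sorted(set(by_pair) | {p for p, _ in failed}):
        sized = sorted(by_pair.get(pair_name, []), key=lambda t: t[1])
        clusters: list[list[tuple[str, float]]] = []
        for sample, size in sized:
            if clusters and size - clusters[-1][-1][1] <= rel_tol * clusters[-1][-1][1]:
                clusters[-1].append((sample, size))
            else:
                clusters.append([(sample, size)])
        for bin_id, members in enumerate(clusters, start=1):
            size_bin = float(np.median([s for _, s in members]))
            bands.append(Band(pair_name, bin_id, size_bin))
            present = {s for s, _ in members}
            row = []
            for sample in sample_ids:
                if (pair_name, sample) in failed:
                    row.append(np.nan)
                else:
                    row.append(1.0 if sample in present else 0.0)
            rows.append(row)
    values = pd.DataFrame(rows, columns=sample_ids, dtype=float)
    return BandMatrix(bands, sample_ids, values)


@dataclass(frozen=True)
class PICResult:
    pair_name: str
    pic: float  # NaN when undefined (zero presence calls)
    n_bands: int
    mode: str


def pic(matrix: BandMatrix, mode: str = "multiallelic") -> list[PICResult]:
    """Polymorphism information content per primer pair, PIC = 1 − Σ p_i².

    See module docstring for the two modes.  NA samples are excluded from
    every denominator; a pair with zero presence calls gets PIC = NaN with a
    warning.
    """
    if mode not in ("multiallelic", "dominant"):
        raise ValueError(f"unknown PIC mode {mode!r}")
    results: list[PICResult] = []
    for pair_name in matrix.pair_names:
        rows = matrix.pair_rows(pair_name)
        n_bands = len(rows)
        scored = rows.notna()
        if int(scored.any(axis=0).sum()) < 2:
            raise ValueError(f"pair {pair_name!r}: need >= 2 samples with non-NA data")
        total_presence = float(rows.sum(axis=1, skipna=True).sum())
        if total_presence == 0:
            warnings.warn(f"pair {pair_name!r}: no presence calls, PIC undefined",
                          stacklevel=2)
            results.append(PICResult(pair_name, float("nan"), n_bands, mode))
            continue
        if mode == "multiallelic":
            p = rows.sum(axis=1, skipna=True).to_numpy() / total_presence
            value = 1.0 - float(np.sum(p**2))
        else:
            per_band = []
            for _, row in rows.iterrows():
                valid = row.dropna()
                if not len(valid):
                    continue
                f = float(valid.mean())
                per_band.append(1.0 - f**2 - (1.0 - f) ** 2)
            value = float(np.mean(per_band))
        results.append(PICResult(pair_name, value, n_bands, mode))
    return results


def percent_polymorphic(matrix: BandMatrix) -> tuple[dict[str, bool], float, float]:
    """Polymorphism flags per pair, plus percent of pairs and percent of loci.

    A band (locus) is polymorphic iff it is present in at least one and
    absent in at least one non-NA sample; a pair is polymorphic iff any of
    its bands is.  Percentages are rounded to one decimal.
    """
    if not matrix.bands:
        raise ValueError("empty band matrix")
    band_poly: list[bool] = []
    for _, row in matrix.values.iterrows():
        valid = row.dropna()
        band_poly.append(bool((valid == 1).any() and (valid == 0).any()))
    pair_flags: dict[str, bool] = {}
    for band, poly in zip(matrix.bands, band_poly):
        pair_flags[band.pair_name] = pair_flags.get(band.pair_name, False) or poly
    pct_pairs = round(100.0 * sum(pair_flags.values()) / len(pair_flags), 1)
    pct_loci = round(100.0 * sum(band_poly) / len(band_poly), 1)
    return pair_flags, pct_pairs, pct_loci


def transferability(
    matrix: BandMatrix,
    focal_samples: Sequence[str],
    species_samples: Mapping[str, Sequence[str]],
) -> dict[str, int]:
    """Cross-species amplification rate of the marker set.

    For each species: 100 × (pairs with ≥1 band in that species) / (pairs
    with ≥1 band in the focal samples), rounded to the nearest integer.
    """
    def amplified_pairs(samples: Sequence[str]) -> set[str]:
        sub = matrix.values[list(samples)]
        pairs: set[str] = set()
        for band, (_, row) in zip(matrix.bands, sub.iterrows()):
            if (row == 1).any():
                pairs.add(band.pair_name)
        return pairs

    focal = amplified_pairs(focal_samples)
    if not focal:
        raise ValueError("no primer pair amplified in the focal samples")
    out: dict[str, int] = {}
    for species, samples in species_samples.items():
        out[species] = int(round(100.0 * len(amplified_pairs(samples) & focal) / len(focal)))
    return out


def pic_table(results: Iterable[PICResult]) -> pd.DataFrame:
    """Report frame with PIC rounded to 2 decimals (report convention)."""
    return pd.DataFrame(
        [
            {
                "pair_name": r.pair_name,
                "pic": round(r.pic, 2) if not np.isnan(r.pic) else np.nan,
                "n_bands": r.n_bands,
                "mode": r.mode,
            }
            for r in results
        ],
        columns=["pair_name", "pic", "n_bands", "mode"],
    )
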