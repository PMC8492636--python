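"""Jaccard similarity, UPGMA dendrograms and bulked-sample marker selection.

Similarity between two band profiles is Jaccard's coefficient
J = a/(a+b+c) over bands where both samples are scored (a shared presences,
b and c private presences); clustering runs on the distance d = 1 − J.

UPGMA merges the closest pair of clusters, recomputing distances as the
size-weighted arithmetic mean over members; node heights are d/2 (the
standard ultrametric convention) and ties break deterministically on the
lexicographically smallest member ids so Newick output is reproducible.

Bulked-sample analysis (BSA) selects candidate trait-linked bands: those
present in every tolerant bulk and absent from every sensitive bulk.  A
bulk models pooled DNA, so a band is present in a bulk when any member
carries it and absent only when all members lack it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import Band, BandMatrix


def jaccard_similarity(matrix: BandMatrix) -> pd.DataFrame:
    """Pairwise Jaccard similarity between samples (symmetric, diagonal 1).

    Bands where either sample is NA are ignored for that pair of samples.
    By convention J = 1 when neither sample shows any band over the
    co-scored set (two blank profiles are indistinguishable).  A sample pair
    with zero co-scored bands is an error.
    """
    samples = matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    vals = matrix.values.to_numpy()
    n = len(samples)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = vals[:, i], vals[:, j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if not ok.any():
                raise ValueError(
                    f"samples {samples[i]!r} and {samples[j]!r} share no co-scored bands"
                )
            a = float(np.sum((x[ok] == 1) & (y[ok] == 1)))
            b = float(np.sum((x[ok] == 1) & (y[ok] == 0)))
            c = float(np.sum((x[ok] == 0) & (y[ok] == 1)))
            union = a + b + c
            sim[i, j] = sim[j, i] = a / union if union > 0 else 1.0
    return pd.DataFrame(sim, index=samples, columns=samples)


@dataclass
class DendrogramNode:
    """Node of the UPGMA tree; leaves have height 0 and a sample name."""

    height: float
    name: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return self.children[0].leaves + self.children[1].leaves


@dataclass
class Dendrogram:
    """UPGMA tree with merge heights (halved cophenetic distances)."""

    root: DendrogramNode
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = self.root.leaves

    @property
    def merge_heights(self) -> list[float]:
        heights: list[float] = []

        def visit(node: DendrogramNode) -> None:
            if not node.is_leaf:
                heights.append(node.height)
                for child in node.children:
                    visit(child)

        visit(self.root)
        return sorted(heights)

    def to_newick(self) -> str:
        """Newick string; branch length = parent height − child height."""

        def render(node: DendrogramNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{blen:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{blen:.6g}"

        if self.root.is_leaf:
            return f"{self.root.name};"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def cophenetic_distance(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (2 × height of the lowest common ancestor)."""
        n = len(self.samples)
        idx = {s: i for i, s in enumerate(self.samples)}
        dist = np.zeros((n, n))

        def visit(node: DendrogramNode) -> list[str]:
            if node.is_leaf:
                return [node.name]  # type: ignore[list-item]
            left = visit(node.children[0])
            right = visit(node.children[1])
            for a in left:
                for b in right:
                    dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = 2 * node.height
            return left + right

        visit(self.root)
        return pd.DataFrame(dist, index=self.samples, columns=self.samples)


def upgma(similarity: pd.DataFrame) -> Dendrogram:
    """UPGMA clustering of a Jaccard similarity matrix (distance = 1 − J).

    Deterministic: among equally close cluster pairs, the pair whose sorted
    smallest member ids are lexicographically least is merged first.
    """
    if list(similarity.index) != list(similarity.columns):
        raise ValueError("similarity matrix must have identical row/column labels")
    arr = similarity.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("similarity matrix is not symmetric")
    samples = [str(s) for s in similarity.index]
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(samples):
        for j in range(i + 1, len(samples)):
            dist[frozenset((a, samples[j]))] = 1.0 - arr[i, j]

    clusters: dict[str, tuple[DendrogramNode, int, list[str]]] = {
        s: (DendrogramNode(0.0, name=s), 1, [s]) for s in samples
    }
    # cluster key = lexicographically smallest member id
    cdist: dict[frozenset[str], float] = dict(dist)
    while len(clusters) > 1:
        best_key = min(
            cdist,
            key=lambda k: (cdist[k], tuple(sorted(k))),
        )
        d_merge = cdist[best_key]
        ka, kb = sorted(best_key)
        node_a, size_a, members_a = clusters.pop(ka)
        node_b, size_b, members_b = clusters.pop(kb)
        new_node = DendrogramNode(d_merge / 2.0, children=(node_a, node_b))
        new_key = min(ka, kb)
        new_size = size_a + size_b
        for other in list(clusters):
            d = (
                size_a * cdist.pop(frozenset((ka, other)))
                + size_b * cdist.pop(frozenset((kb, other)))
            ) / new_size
            cdist[frozenset((new_key, other))] = d
        cdist.pop(best_key, None)
        clusters[new_key] = (new_node, new_size, members_a + members_b)
    root = next(iter(clusters.values()))[0]
    return Dendrogram(root=root, samples=samples)


def cut_clusters(tree: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into exactly k clusters (remove the k−1 highest merges).

    Cluster ids are numbered 1..k by smallest member sample id.  When a tie
    in merge heights makes the k-cluster cut ambiguous, an error lists the
    tied heights.
    """
    n = len(tree.samples)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    heights = sorted(tree.merge_heights, reverse=True)
    if 0 < k - 1 < len(heights) and heights[k - 2] == heights[k - 1]:
        raise ValueError(
            f"cut into {k} clusters is ambiguous: tied merge heights {heights[k - 2]!r}"
        )
    threshold = heights[k - 2] if k > 1 else float("inf")

    groups: list[list[str]] = []

    def visit(node: DendrogramNode) -> None:
        if not node.is_leaf and node.height >= threshold:
            for child in node.children:
                visit(child)
        else:
            groups.append(node.leaves)

    visit(tree.root)
    assert len(groups) == k, f"internal error: cut produced {len(groups)} clusters"
    groups.sort(key=lambda g: min(g))
    assignment: dict[str, int] = {}
    for cid, group in enumerate(groups, start=1):
        for sample in group:
            assignment[sample] = cid
    return assignment


@dataclass(frozen=True)
class BulkDesign:
    """Sample groups forming the tolerant and sensitive bulks."""

    tolerant_bulks: tuple[tuple[str, ...], ...]
    sensitive_bulks: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "tolerant_bulks", tuple(tuple(b) for b in self.tolerant_bulks)
        )
        object.__setattr__(
            self, "sensitive_bulks", tuple(tuple(b) for b in self.sensitive_bulks)
        )
        if not self.tolerant_bulks or not self.sensitive_bulks:
            raise ValueError("need at least one tolerant and one sensitive bulk")
        seen: set[str] = set()
        for bulk in self.tolerant_bulks + self.sensitive_bulks:
            if not bulk:
                raise ValueError("bulks must be non-empty")
            overlap = seen & set(bulk)
            if overlap:
                raise ValueError(f"samples in more than one bulk: {sorted(overlap)}")
            seen |= set(bulk)

    @property
    def all_samples(self) -> list[str]:
        out: list[str] = []
        for bulk in self.tolerant_bulks + self.sensitive_bulks:
            out.extend(bulk)
        return out

    def to_dict(self) -> dict:
        return {
            "tolerant_bulks": [list(b) for b in self.tolerant_bulks],
            "sensitive_bulks": [list(b) for b in self.sensitive_bulks],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "BulkDesign":
        return cls(
            tolerant_bulks=tuple(tuple(b) for b in data["tolerant_bulks"]),
            sensitive_bulks=tuple(tuple(b) for b in data["sensitive_bulks"]),
        )


@dataclass(frozen=True)
class CandidateMarker:
    """A band present in every tolerant bulk and absent from every sensitive bulk."""

    band: Band
    present_in: tuple[str, ...]
    absent_in: tuple[str, ...]


def _bulk_presence(row: pd.Series, bulk: Sequence[str]) -> float:
    """Pooled-bulk call: 1 if any member carries the band, 0 if all lack it,
    NaN if any member is NA (the pooled call is then indeterminate)."""
    sub = row[list(bulk)]
    if sub.isna().any():
        return float("nan")
    return 1.0 if (sub == 1).any() else 0.0


def select_candidate_markers(
    matrix: BandMatrix,
    design: BulkDesign,
    return_undetermined: bool = False,
) -> list[CandidateMarker] | tuple[list[CandidateMarker], list[Band]]:
    """BSA selection: bands common to all tolerant bulks, absent from all
    sensitive bulks.  NA inside any bulk disqualifies the band (reported
    separately when ``return_undetermined``).  Output is sorted by pair name
    then band size, independent of sample or band order.
    """
    missing = [s for s in design.all_samples if s not in matrix.samples]
    if missing:
        raise KeyError(f"bulk samples not in matrix: {missing}")
    tol_names = [f"T{i + 1}" for i in range(len(design.tolerant_bulks))]
    sen_names = [f"S{i + 1}" for i in range(len(design.sensitive_bulks))]
    selected: list[CandidateMarker] = []
    undetermined: list[Band] = []
    for band, (_, row) in zip(matrix.bands, matrix.values.iterrows()):
        tol = [_bulk_presence(row, b) for b in design.tolerant_bulks]
        sen = [_bulk_presence(row, b) for b in design.sensitive_bulks]
        if any(np.isnan(v) for v in tol + sen):
            undetermined.append(band)
            continue
        if all(v == 1.0 for v in tol) and all(v == 0.0 for v in sen):
            selected.append(
                CandidateMarker(band, tuple(tol_names), tuple(sen_names))
            )
    selected.sort(key=lambda c: (c.band.pair_name, c.band.size_bin))
    if return_undetermined:
        return selected, undetermined
    return selected
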