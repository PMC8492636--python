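"""Jaccard similarity, UPGMA trees and bulked-sample candidate selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from mirmark.bands import BandMatrix
from mirmark.cluster import (
    BulkDesign,
    cut_clusters,
    jaccard_similarity,
    select_candidate_markers,
    upgma,
)


def matrix_from(rows, samples=None):
    samples = samples or [f"s{i + 1}" for i in range(len(next(iter(rows.values()))))]
    return BandMatrix.from_records(
        {label: dict(zip(samples, vals)) for label, vals in rows.items()}
    )


class TestJaccard:
    def test_identical_profiles(self):
        m = matrix_from({"p:1:500": [1, 1], "p:2:300": [0, 0], "q:1:200": [1, 1]})
        assert jaccard_similarity(m).iloc[0, 1] == 1.0

    def test_disjoint_presences(self):
        m = matrix_from({"p:1:500": [1, 0], "p:2:300": [0, 1]})
        assert jaccard_similarity(m).iloc[0, 1] == 0.0

    def test_hand_enumerated_example(self):
        # x=(1,1,0,1), y=(1,0,1,1): a=2, b=1, c=1 -> J = 0.5
        m = matrix_from(
            {
                "p:1:500": [1, 1], "p:2:400": [1, 0],
                "p:3:300": [0, 1], "p:4:200": [1, 1],
            }
        )
        assert jaccard_similarity(m).iloc[0, 1] == pytest.approx(0.5)

    def test_blank_profiles_similar_by_convention(self):
        m = matrix_from({"p:1:500": [0, 0, 1]})
        assert jaccard_similarity(m).iloc[0, 1] == 1.0

    def test_na_bands_excluded_pairwise(self):
        m = matrix_from({"p:1:500": [1, None, 1], "q:1:300": [1, 1, 0]})
        sim = jaccard_similarity(m)
        assert sim.iloc[0, 1] == 1.0  # only q co-scored, both present

    def test_no_co_scored_bands_is_an_error(self):
        m = matrix_from({"p:1:500": [1, None], "q:1:300": [None, 1]})
        with pytest.raises(ValueError, match="co-scored"):
            jaccard_similarity(m)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        rows = {f"p{i}:1:{200 + i}": rng.integers(0, 2, 6).tolist() for i in range(12)}
        m = matrix_from(rows)
        perm = ["s4", "s1", "s6", "s2", "s5", "s3"]
        sim = jaccard_similarity(m)
        sim_perm = jaccard_similarity(m.subset_samples(perm))
        assert np.allclose(sim.loc[perm, perm].to_numpy(), sim_perm.to_numpy())

    def test_jaccard_distance_triangle_inequality(self):
        rng = np.random.default_rng(8)
        rows = {f"p{i}:1:{200 + i}": rng.integers(0, 2, 8).tolist() for i in range(25)}
        d = 1.0 - jaccard_similarity(matrix_from(rows)).to_numpy()
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def sim_frame(data, labels):
    return pd.DataFrame(data, index=labels, columns=labels, dtype=float)


class TestUPGMA:
    def test_two_leaves(self):
        tree = upgma(sim_frame([[1.0, 0.6], [0.6, 1.0]], ["A", "B"]))
        assert tree.root.height == pytest.approx(0.2)
        assert tree.to_newick() == "(A:0.2,B:0.2);"

    def test_three_leaf_hand_example(self):
        # d(A,B)=0.2, d(A,C)=d(B,C)=0.6: merge (A,B) at 0.1, then C at 0.3
        sim = sim_frame(
            [[1.0, 0.8, 0.4], [0.8, 1.0, 0.4], [0.4, 0.4, 1.0]], ["A", "B", "C"]
        )
        tree = upgma(sim)
        assert tree.to_newick() == "((A:0.1,B:0.1):0.2,C:0.3);"
        assert tree.merge_heights == pytest.approx([0.1, 0.3])

    def test_heights_monotone(self, panel):
        from mirmark.bands import bin_bands
        from mirmark.epcr import amplify_panel
        amps = amplify_panel(panel.genomes, panel.pairs)
        obs = [(a.pair_name, g, float(a.length)) for g, al in amps.items() for a in al]
        m = bin_bands(obs, samples=panel.samples)
        tree = upgma(jaccard_similarity(m))
        heights = tree.merge_heights
        assert heights == sorted(heights) and all(h >= 0 for h in heights)

    def test_ultrametric_input_reproduced_exactly(self):
        # cophenetic distances of an ultrametric are recovered exactly
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.4],
                [0.6, 0.6, 0.4, 0.0],
            ]
        )
        tree = upgma(sim_frame(1 - d, labels))
        coph = tree.cophenetic_distance().loc[labels, labels].to_numpy()
        assert np.allclose(coph, d)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(5)
        n = 10
        raw = rng.uniform(0.05, 0.95, size=(n, n))
        d = np.triu(raw, 1) + np.triu(raw, 1).T  # distinct entries: no ties
        labels = [f"g{i:02d}" for i in range(n)]
        tree = upgma(sim_frame(1 - d, labels))
        link = average(squareform(d))
        ours = tree.cophenetic_distance().to_numpy()
        theirs = squareform(cophenet(link))
        assert np.allclose(ours, theirs)

    def test_asymmetric_input_rejected(self):
        bad = sim_frame([[1.0, 0.2], [0.4, 1.0]], ["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            upgma(bad)

    def test_deterministic_tie_break(self):
        # three equidistant leaves: A,B merge first (lexicographic rule)
        sim = sim_frame(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]], ["C", "A", "B"]
        )
        assert upgma(sim).to_newick() == "((A:0.25,B:0.25):0,C:0.25);"


class TestCutClusters:
    @pytest.fixture()
    def tree(self):
        sim = sim_frame(
            [[1.0, 0.8, 0.4], [0.8, 1.0, 0.4], [0.4, 0.4, 1.0]], ["A", "B", "C"]
        )
        return upgma(sim)

    def test_k_one_and_k_n(self, tree):
        assert cut_clusters(tree, 1) == {"A": 1, "B": 1, "C": 1}
        assert cut_clusters(tree, 3) == {"A": 1, "B": 2, "C": 3}

    def test_k_two_separates_outgroup(self, tree):
        assert cut_clusters(tree, 2) == {"A": 1, "B": 1, "C": 2}

    def test_tied_heights_rejected(self):
        sim = sim_frame(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]], ["A", "B", "C"]
        )
        tree = upgma(sim)
        with pytest.raises(ValueError, match="ambiguous"):
            cut_clusters(tree, 2)

    def test_bad_k_rejected(self, tree):
        with pytest.raises(ValueError):
            cut_clusters(tree, 0)
        with pytest.raises(ValueError):
            cut_clusters(tree, 4)


class TestBulkSelection:
    DESIGN = BulkDesign(tolerant_bulks=(("T1",), ("T2",)), sensitive_bulks=(("S",),))

    def test_band_in_both_tolerant_not_sensitive_selected(self):
        m = matrix_from({"p:1:500": [1, 1, 0]}, samples=["T1", "T2", "S"])
        selected = select_candidate_markers(m, self.DESIGN)
        assert [c.band.label for c in selected] == ["p:1:500"]

    def test_band_missing_one_tolerant_not_selected(self):
        m = matrix_from({"p:1:500": [1, 0, 0]}, samples=["T1", "T2", "S"])
        assert select_candidate_markers(m, self.DESIGN) == []

    def test_band_present_in_sensitive_not_selected(self):
        m = matrix_from({"p:1:500": [1, 1, 1]}, samples=["T1", "T2", "S"])
        assert select_candidate_markers(m, self.DESIGN) == []

    def test_na_in_a_bulk_disqualifies(self):
        m = matrix_from({"p:1:500": [1, None, 0]}, samples=["T1", "T2", "S"])
        selected, undetermined = select_candidate_markers(
            m, self.DESIGN, return_undetermined=True
        )
        assert selected == [] and [b.label for b in undetermined] == ["p:1:500"]

    def test_pooled_bulk_semantics(self):
        # a bulk carries the band when any member does
        design = BulkDesign(
            tolerant_bulks=(("T1a", "T1b"), ("T2a", "T2b")), sensitive_bulks=(("Sa", "Sb"),)
        )
        m = matrix_from(
            {"p:1:500": [1, 0, 0, 1, 0, 0]},
            samples=["T1a", "T1b", "T2a", "T2b", "Sa", "Sb"],
        )
        assert len(select_candidate_markers(m, design)) == 1

    def test_independent_of_sample_and_band_order(self):
        rows = {
            "b:1:400": [1, 1, 0], "a:1:500": [1, 1, 0], "c:1:300": [1, 0, 1],
        }
        m = matrix_from(rows, samples=["T1", "T2", "S"])
        shuffled = matrix_from(
            {k: rows[k] for k in ["c:1:300", "a:1:500", "b:1:400"]},
            samples=["T1", "T2", "S"],
        ).subset_samples(["S", "T2", "T1"])
        sel_a = [c.band.label for c in select_candidate_markers(m, self.DESIGN)]
        sel_b = [c.band.label for c in select_candidate_markers(shuffled, self.DESIGN)]
        assert sel_a == sel_b == ["a:1:500", "b:1:400"]

    def test_adding_sensitive_bulk_only_shrinks(self):
        rng = np.random.default_rng(21)
        samples = ["T1", "T2", "S1", "S2"]
        rows = {
            f"p{i}:1:{200 + i}": rng.integers(0, 2, 4).tolist() for i in range(40)
        }
        m = matrix_from(rows, samples=samples)
        small = BulkDesign(tolerant_bulks=(("T1",), ("T2",)), sensitive_bulks=(("S1",),))
        big = BulkDesign(
            tolerant_bulks=(("T1",), ("T2",)), sensitive_bulks=(("S1",), ("S2",))
        )
        sel_small = {c.band.label for c in select_candidate_markers(m, small)}
        sel_big = {c.band.label for c in select_candidate_markers(m, big)}
        assert sel_big <= sel_small

    def test_bulk_design_validation(self):
        with pytest.raises(ValueError, match="more than one bulk"):
            BulkDesign(tolerant_bulks=(("A",),), sensitive_bulks=(("A",),))
        with pytest.raises(ValueError):
            BulkDesign(tolerant_bulks=(), sensitive_bulks=(("S",),))
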