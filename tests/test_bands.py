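"""Band binning, PIC, percent polymorphism and transferability."""

import numpy as np
import pytest

from mirmark.bands import (
    BandMatrix,
    bin_bands,
    percent_polymorphic,
    pic,
    pic_table,
    transferability,
)


def matrix_from(rows, samples=None):
    """rows: {band_label: [0/1/None per sample]} with labels 'pair:bin:size'."""
    samples = samples or [f"s{i + 1}" for i in range(len(next(iter(rows.values()))))]
    return BandMatrix.from_records(
        {label: dict(zip(samples, vals)) for label, vals in rows.items()}
    )


class TestBinBands:
    def test_sizes_within_tolerance_share_a_bin(self):
        m = bin_bands([("p", "s1", 498.0), ("p", "s2", 503.0)])
        assert len(m.bands) == 1
        assert m.bands[0].size_bin == pytest.approx(500.5)

    def test_distant_sizes_split(self):
        m = bin_bands([("p", "s1", 300.0), ("p", "s2", 400.0)])
        assert len(m.bands) == 2
        assert m.values.iloc[0].tolist() == [1.0, 0.0]

    def test_failed_reaction_marks_na_block(self):
        m = bin_bands(
            [("p", "s1", 300.0), ("p", "s1", 400.0), ("p", "s2", None)],
            samples=["s1", "s2"],
        )
        assert m.values["s2"].isna().all()
        assert m.values["s1"].tolist() == [1.0, 1.0]

    def test_missing_record_is_absence_not_na(self):
        m = bin_bands([("p", "s1", 300.0)], samples=["s1", "s2"])
        assert m.values["s2"].tolist() == [0.0]

    def test_single_linkage_chains(self):
        # 300, 305, 310 chain into one bin even though 300 vs 310 exceed 2%
        m = bin_bands([("p", "s1", 300.0), ("p", "s2", 305.0), ("p", "s3", 310.0)])
        assert len(m.bands) == 1

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            bin_bands([("p", "s1", 300.0)], rel_tol=0.0)


class TestPIC:
    def test_monomorphic_single_band_is_zero(self):
        m = matrix_from({"p:1:500": [1, 1, 1, 1]})
        assert pic(m)[0].pic == pytest.approx(0.0)

    def test_two_equifrequent_bands(self):
        m = matrix_from({"p:1:500": [1, 1, 0, 0], "p:2:300": [0, 0, 1, 1]})
        assert pic(m)[0].pic == pytest.approx(0.5)

    def test_four_equifrequent_bands(self):
        rows = {
            f"p:{i}:{100 * i}": [1 if j == i - 1 else 0 for j in range(4)]
            for i in range(1, 5)
        }
        assert pic(matrix_from(rows))[0].pic == pytest.approx(0.75)

    def test_three_bands_half_quarter_quarter(self):
        rows = {
            "p:1:500": [1, 1, 0, 0],
            "p:2:400": [0, 0, 1, 0],
            "p:3:300": [0, 0, 0, 1],
        }
        assert pic(matrix_from(rows))[0].pic == pytest.approx(0.625)

    def test_dominant_mode_capped_at_half(self):
        m = matrix_from({"p:1:500": [1, 1, 0, 0], "p:2:300": [1, 0, 1, 0]})
        res = pic(m, mode="dominant")[0]
        assert res.pic == pytest.approx(0.5)
        assert res.mode == "dominant"

    def test_na_excluded_from_frequencies(self):
        with_na = matrix_from({"p:1:500": [1, 1, 0, None]})
        without = matrix_from({"p:1:500": [1, 1, 0]})
        assert pic(with_na, "dominant")[0].pic == pytest.approx(
            pic(without, "dominant")[0].pic
        )

    def test_zero_presence_is_undefined_with_warning(self):
        m = matrix_from({"p:1:500": [0, 0, 0]})
        with pytest.warns(UserWarning, match="undefined"):
            res = pic(m)
        assert np.isnan(res[0].pic)

    def test_multiallelic_bounded_by_one_minus_inverse_k(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            k = int(rng.integers(1, 6))
            rows = {
                f"p:{i}:{100 + 50 * i}": rng.integers(0, 2, 8).tolist()
                for i in range(1, k + 1)
            }
            if not any(any(v) for v in rows.values()):
                continue
            value = pic(matrix_from(rows))[0].pic
            assert value <= 1 - 1 / k + 1e-12

    def test_equality_at_equifrequency(self):
        rows = {f"p:{i}:{100 * i}": [1] * 4 for i in range(1, 6)}
        assert pic(matrix_from(rows))[0].pic == pytest.approx(1 - 1 / 5)

    def test_invariant_under_sample_and_band_reordering(self):
        rows = {"p:1:500": [1, 0, 1, 0], "p:2:300": [0, 1, 1, 0], "q:1:200": [1, 1, 0, 1]}
        m = matrix_from(rows)
        shuffled = matrix_from(
            {k: rows[k] for k in ["q:1:200", "p:2:300", "p:1:500"]}
        ).subset_samples(["s1", "s2", "s3", "s4"][::-1])
        base = {r.pair_name: r.pic for r in pic(m)}
        perm = {r.pair_name: r.pic for r in pic(shuffled)}
        assert base == pytest.approx(perm)

    def test_pair_needs_two_scored_samples(self):
        m = matrix_from({"p:1:500": [1, None, None]})
        with pytest.raises(ValueError, match="non-NA"):
            pic(m)


class TestPercentPolymorphic:
    @staticmethod
    def _matrix_with_poly_pairs(n_poly, n_total):
        rows = {}
        for i in range(n_total):
            poly = i < n_poly
            rows[f"pair{i:02d}:1:500"] = [1, 0, 1] if poly else [1, 1, 1]
        return matrix_from(rows)

    def test_twenty_of_twentyeight_rounds_to_71_4(self):
        _, pct_pairs, _ = percent_polymorphic(self._matrix_with_poly_pairs(20, 28))
        assert pct_pairs == 71.4

    def test_thirtyfour_of_fortyeight_rounds_to_70_8(self):
        _, pct_pairs, _ = percent_polymorphic(self._matrix_with_poly_pairs(34, 48))
        assert pct_pairs == 70.8

    def test_all_monomorphic_is_zero(self):
        _, pct_pairs, pct_loci = percent_polymorphic(self._matrix_with_poly_pairs(0, 5))
        assert pct_pairs == 0.0 and pct_loci == 0.0

    def test_pair_polymorphic_if_any_band_is(self):
        m = matrix_from({"p:1:500": [1, 1, 1], "p:2:300": [1, 0, 1]})
        flags, pct_pairs, pct_loci = percent_polymorphic(m)
        assert flags == {"p": True} and pct_pairs == 100.0 and pct_loci == 50.0

    def test_na_sample_does_not_make_band_polymorphic(self):
        m = matrix_from({"p:1:500": [1, 1, None]})
        flags, _, _ = percent_polymorphic(m)
        assert flags == {"p": False}

    def test_empty_matrix_rejected(self):
        m = matrix_from({"p:1:500": [1, 1]})
        m.bands = []
        with pytest.raises(ValueError):
            percent_polymorphic(m)


class TestTransferability:
    def _matrix(self, hits_species_a, hits_species_b):
        rows = {}
        for i in range(3):
            rows[f"pair{i}:1:500"] = [
                1, 1,  # focal samples
                1 if i < hits_species_a else 0,
                1 if i < hits_species_b else 0,
            ]
        return matrix_from(rows, samples=["f1", "f2", "spA", "spB"])

    def test_full_and_one_third_transfer(self):
        out = transferability(
            self._matrix(3, 1), ["f1", "f2"], {"A": ["spA"], "B": ["spB"]}
        )
        assert out == {"A": 100, "B": 33}

    def test_zero_transfer(self):
        out = transferability(self._matrix(0, 0), ["f1", "f2"], {"A": ["spA"]})
        assert out == {"A": 0}

    def test_no_focal_amplification_rejected(self):
        m = matrix_from({"p:1:500": [0, 1]}, samples=["f1", "spA"])
        with pytest.raises(ValueError):
            transferability(m, ["f1"], {"A": ["spA"]})


def test_tsv_round_trip(tmp_path):
    m = matrix_from({"p:1:500": [1, 0, None], "q:1:300": [0, 1, 1]})
    path = tmp_path / "m.tsv"
    m.to_tsv(path)
    back = BandMatrix.from_tsv(path)
    assert back.samples == m.samples
    assert [b.label for b in back.bands] == [b.label for b in m.bands]
    assert back.values.equals(m.values)


def test_pic_table_rounds_to_two_decimals():
    m = matrix_from(
        {"p:1:500": [1, 1, 0, 0], "p:2:400": [0, 0, 1, 0], "p:3:300": [0, 0, 0, 1]}
    )
    table = pic_table(pic(m))
    assert table.loc[0, "pic"] == 0.62  # 0.625 banker's-rounded in reports
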