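import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loki import stbank_io as sio


def toy_slide():
    return sio.SpotSlide(
        spot_ids=np.array(["a", "b", "c"], dtype=object),
        coords=np.array([[0.0, 0.0], [100.0, 0.0], [50.0, 86.6]]),
        counts=np.array([[10, 0, 3, 1], [0, 5, 2, 0], [1, 1, 1, 1]]),
        gene_symbols=np.array(["G1", "G2", "G3", "G4"], dtype=object),
    )


class TestReadWriteSlide:
    def test_round_trip_is_bit_exact(self, tmp_path):
        slide = toy_slide()
        sio.write_slide(slide, tmp_path)
        back = sio.read_slide(
            tmp_path / "matrix.mtx", tmp_path / "features.tsv",
            tmp_path / "barcodes.tsv", tmp_path / "positions.csv",
        )
        assert back.counts.shape == (3, 4)
        np.testing.assert_array_equal(back.counts, slide.counts)
        np.testing.assert_array_equal(back.coords, slide.coords)
        assert list(back.gene_symbols) == list(slide.gene_symbols)
        assert list(back.spot_ids) == list(slide.spot_ids)

    def test_extra_barcode_raises_format_error(self, tmp_path):
        slide = toy_slide()
        sio.write_slide(slide, tmp_path)
        with open(tmp_path / "barcodes.tsv", "a") as fh:
            fh.write("extra\n")
        with pytest.raises(sio.FormatError, match="matrix"):
            sio.read_slide(tmp_path / "matrix.mtx", tmp_path / "features.tsv",
                           tmp_path / "barcodes.tsv", tmp_path / "positions.csv")

    def test_missing_position_drops_spot(self, tmp_path):
        slide = toy_slide()
        sio.write_slide(slide, tmp_path)
        pos = pd.read_csv(tmp_path / "positions.csv")
        pos.iloc[:-1].to_csv(tmp_path / "positions.csv", index=False)
        back = sio.read_slide(tmp_path / "matrix.mtx", tmp_path / "features.tsv",
                              tmp_path / "barcodes.tsv", tmp_path / "positions.csv")
        assert back.n_spots == 2
        assert list(back.spot_ids) == ["a", "b"]

    def test_non_integer_counts_rejected(self, tmp_path):
        slide = toy_slide()
        sio.write_slide(slide, tmp_path)
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n3 4 1\n1 1 2.5\n"
        )
        with pytest.raises(ValueError, match="non-integer"):
            sio.read_slide(tmp_path / "matrix.mtx", tmp_path / "features.tsv",
                           tmp_path / "barcodes.tsv", tmp_path / "positions.csv")


class TestQCFilter:
    def test_threshold_is_strict(self):
        counts = np.zeros((2, 300), dtype=int)
        counts[0, :201] = 1  # 201 expressed genes: retained
        counts[1, :200] = 1  # exactly 200: removed
        slide = sio.SpotSlide(
            spot_ids=np.array(["keep", "drop"], dtype=object),
            coords=np.zeros((2, 2)),
            counts=counts,
            gene_symbols=np.array([f"g{i}" for i in range(300)], dtype=object),
        )
        out = sio.qc_filter_spots(slide, min_genes=200)
        assert list(out.spot_ids) == ["keep"]

    def test_min_genes_zero_keeps_expressing_spots(self):
        out = sio.qc_filter_spots(toy_slide(), min_genes=0)
        assert out.n_spots == 3

    def test_idempotent(self, small_slide):
        slide, _ = small_slide
        once = sio.qc_filter_spots(slide, min_genes=30)
        twice = sio.qc_filter_spots(once, min_genes=30)
        np.testing.assert_array_equal(once.counts, twice.counts)
        assert list(once.spot_ids) == list(twice.spot_ids)


class TestGeneSentence:
    SYMBOLS = np.array(["CAMK4", "CKB", "ENO2", "GRIN2C", "SNAP25", "ACTB"], dtype=object)

    def test_rank_order_matches_expression(self):
        # SNAP25 > ENO2 > CKB > GRIN2C > CAMK4, ACTB silent
        expr = np.array([1.0, 3.0, 4.0, 2.0, 5.0, 0.0])
        s = sio.build_gene_sentence(expr, self.SYMBOLS)
        assert s.text == "SNAP25 ENO2 CKB GRIN2C CAMK4"

    def test_only_nonzero_genes_kept(self):
        expr = np.array([0, 2, 0, 1, 3, 0], dtype=float)
        s = sio.build_gene_sentence(expr, self.SYMBOLS, top_n=50)
        assert len(s) == 3

    def test_ties_break_alphabetically(self):
        expr = np.array([2.0, 2.0, 0, 0, 5.0, 0])
        s = sio.build_gene_sentence(expr, self.SYMBOLS)
        assert s.tokens == ("SNAP25", "CAMK4", "CKB")

    def test_housekeeping_removed_and_ids_converted(self):
        maps = sio.GeneMaps(ensembl_to_symbol={"ENSG1": "MYGENE"}, housekeeping={"ACTB"})
        symbols = np.array(["ENSG1", "ACTB"], dtype=object)
        s = sio.build_gene_sentence(np.array([1.0, 99.0]), symbols, maps)
        assert s.text == "MYGENE"

    def test_all_zero_profile_raises(self):
        with pytest.raises(ValueError, match="no nonzero"):
            sio.build_gene_sentence(np.zeros(6), self.SYMBOLS)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 20))
    def test_length_bounded_and_no_housekeeping(self, seed, top_n):
        rng = np.random.default_rng(seed)
        n = 40
        symbols = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        hk = set(rng.choice(symbols, size=5, replace=False))
        expr = rng.poisson(2.0, n).astype(float)
        maps = sio.GeneMaps(housekeeping=hk)
        try:
            s = sio.build_gene_sentence(expr, symbols, maps, top_n=top_n)
        except ValueError:
            return  # profile had no usable gene
        assert len(s) <= top_n
        assert not set(s.tokens) & hk


class TestNormalize:
    def test_closed_form(self):
        slide = sio.SpotSlide(
            spot_ids=np.array(["s"], dtype=object), coords=np.zeros((1, 2)),
            counts=np.array([[10, 0]]), gene_symbols=np.array(["a", "b"], dtype=object),
        )
        out = sio.normalize_counts(slide, target_sum=10)
        np.testing.assert_allclose(out.normalized[0], [np.log(11), 0.0])

    def test_zero_spot_flagged_all_zero(self):
        slide = sio.SpotSlide(
            spot_ids=np.array(["s", "z"], dtype=object), coords=np.zeros((2, 2)),
            counts=np.array([[5, 5], [0, 0]]), gene_symbols=np.array(["a", "b"], dtype=object),
        )
        out = sio.normalize_counts(slide)
        assert out.zero_library[1] and not out.zero_library[0]
        np.testing.assert_array_equal(out.normalized[1], 0.0)

    def test_row_sums_recover_target(self, small_slide):
        slide, _ = small_slide
        out = sio.normalize_counts(slide, target_sum=1e4)
        sums = (np.expm1(out.normalized)).sum(axis=1)
        np.testing.assert_allclose(sums[~out.zero_library], 1e4, rtol=1e-9)


class TestPseudoSpots:
    def test_identical_cells_average_to_cell_profile(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0]])
        counts = np.array([[4, 2], [4, 2]])
        slide, membership = sio.bin_pseudo_spots(coords, counts, pitch_um=100, diameter_um=55)
        assert slide.n_spots == 1
        np.testing.assert_array_equal(slide.counts[0], [4, 2])
        assert list(membership) == [0, 0]

    def test_boundary_cell_is_inclusive(self):
        coords = np.array([[0.0, 0.0], [27.5, 0.0]])  # second exactly on the circle
        counts = np.array([[2, 0], [4, 0]])
        slide, membership = sio.bin_pseudo_spots(coords, counts, pitch_um=100, diameter_um=55)
        assert (membership >= 0).sum() == 2

    def test_assignment_fraction_matches_area_ratio(self, rng):
        n = 4000
        coords = rng.uniform(0, 1000, (n, 2))
        counts = np.ones((n, 1), dtype=int)
        pitch, diam = 100.0, 55.0
        slide, membership = sio.bin_pseudo_spots(coords, counts, pitch, diam)
        # brute-force point-in-circle count against the module's grid
        from loki.stbank_io import hex_grid

        centers = hex_grid(coords[:, 0].min(), coords[:, 0].max(),
                           coords[:, 1].min(), coords[:, 1].max(), pitch)
        inside = np.zeros(n, dtype=bool)
        for c in centers:
            inside |= np.linalg.norm(coords - c, axis=1) <= diam / 2 + 1e-9
        assert (membership >= 0).sum() == inside.sum()
        area_ratio = np.pi * 27.5**2 / (pitch * pitch * np.sqrt(3) / 2)
        assert abs((membership >= 0).mean() - area_ratio) < 0.05

    def test_cells_conserved(self, rng):
        coords = rng.uniform(0, 500, (300, 2))
        counts = rng.poisson(3, (300, 5))
        _, membership = sio.bin_pseudo_spots(coords, counts)
        assert (membership >= 0).sum() <= 300  # each cell at most once


class TestExtractPatches:
    def test_center_patch_shape_and_values(self):
        image = np.arange(100 * 100 * 3, dtype=np.uint8).reshape(100, 100, 3)
        patches, padded = sio.extract_patches(image, [[50.0, 50.0]], 1.0, 55.0)
        assert patches.shape == (1, 55, 55, 3)
        assert not padded[0]

    def test_corner_patch_padded_and_flagged(self):
        image = np.full((100, 100, 3), 7, dtype=np.uint8)
        patches, padded = sio.extract_patches(image, [[0.0, 0.0]], 1.0, 55.0)
        assert padded[0]
        assert patches[0, 0, 0, 0] == 0  # zero padding in the out-of-bounds corner
        assert patches[0, -1, -1, 0] == 7

    def test_patch_centers_track_coordinates(self):
        image = np.zeros((300, 300, 3), dtype=np.uint8)
        image[100, 100] = 255
        image[100, 200] = 255
        patches, _ = sio.extract_patches(image, [[100.0, 100.0], [200.0, 100.0]], 1.0, 11.0)
        assert patches[0, 5, 5, 0] == 255
        assert patches[1, 5, 5, 0] == 255

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            sio.extract_patches(np.zeros((10, 10, 3)), [[1.0, 1.0]], 0.0, 55.0)
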