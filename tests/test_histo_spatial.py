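import numpy as np
import pandas as pd
import pytest

from femri.exceptions import InputError
from femri.histo_spatial import (
    CELL_CLASS,
    IRON_CLASS,
    HistoRaster,
    count_cells_per_deposit,
    detect_iron_pixels,
    downsample_to_mri,
    watershed_deposits,
)
from femri.phantom import HistoPhantomConfig, generate_histo_phantom


def cell_table(rows):
    return pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "iron"])


class TestDetectIronPixels:
    def test_pure_blue_is_iron(self):
        rgb = np.zeros((1, 1, 3), dtype=np.uint8)
        rgb[0, 0] = (0, 0, 255)
        assert detect_iron_pixels(HistoRaster(rgb)).all()

    def test_white_background_is_not_iron(self):
        rgb = np.full((1, 1, 3), 255, dtype=np.uint8)
        assert not detect_iron_pixels(HistoRaster(rgb)).any()

    def test_black_pixel_is_not_iron(self):
        # zero total intensity: ratio undefined, treated as background
        rgb = np.zeros((1, 1, 3), dtype=np.uint8)
        assert not detect_iron_pixels(HistoRaster(rgb)).any()

    def test_label_raster_bypasses_color_logic(self):
        labels = np.array([[0, CELL_CLASS, IRON_CLASS]], dtype=np.uint8)
        np.testing.assert_array_equal(
            detect_iron_pixels(HistoRaster(labels)), [[False, False, True]]
        )

    def test_bad_raster_shapes_rejected(self):
        with pytest.raises(InputError):
            HistoRaster(np.zeros((2, 2, 4), dtype=np.uint8))
        with pytest.raises(InputError):
            detect_iron_pixels(HistoRaster(np.zeros((2, 2), dtype=float)))


class TestDownsample:
    def test_aligned_block_gives_unit_density(self):
        mask = np.zeros((1000, 1000), dtype=bool)
        mask[100:200, 300:400] = True
        density = downsample_to_mri(mask, 100)
        assert density.shape == (10, 10)
        assert density[1, 3] == 1.0
        assert density.sum() == 1.0

    def test_all_zero_mask(self):
        assert downsample_to_mri(np.zeros((200, 200), bool), 100).sum() == 0.0

    def test_half_tile_area_fraction(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[0:50, 0:50] = True  # quarter of the single tile
        density = downsample_to_mri(mask, 100)
        assert density[0, 0] == pytest.approx(0.25)

    def test_mass_conservation_on_exact_multiples(self, rng):
        mask = rng.random((800, 600)) < 0.1
        density = downsample_to_mri(mask, 100)
        assert density.sum() * 100**2 == pytest.approx(mask.sum(), abs=1e-9)

    def test_factor_larger_than_raster_rejected(self):
        with pytest.raises(InputError):
            downsample_to_mri(np.zeros((50, 50), bool), 100)


class TestWatershed:
    def blob(self, shape, center, value=0.3, radius=2):
        out = np.zeros(shape)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        out[np.hypot(rr - center[0], cc - center[1]) <= radius] = value
        return out

    def test_two_separated_blobs(self):
        density = self.blob((30, 30), (8, 8)) + self.blob((30, 30), (22, 22))
        labels = watershed_deposits(density)
        assert labels.max() == 2

    def test_bridged_blobs_split_at_the_neck(self):
        density = self.blob((30, 30), (10, 10)) + self.blob((30, 30), (10, 18))
        density[10, 13:16] = 0.02  # 1-px-high low-density bridge
        labels = watershed_deposits(density)
        assert labels.max() == 2
        # the two strong centers carry different labels
        assert labels[10, 10] != labels[10, 18]

    def test_empty_density_gives_no_labels(self):
        assert watershed_deposits(np.zeros((20, 20))).max() == 0

    def test_min_area_drops_specks(self):
        density = np.zeros((20, 20))
        density[5, 5] = 1.0
        assert watershed_deposits(density, smoothing_sigma=0.0,
                                  min_density=0.5, min_area=2).max() == 0

    def test_labels_deterministically_ordered(self):
        density = self.blob((40, 40), (30, 5)) + self.blob((40, 40), (5, 30))
        labels = watershed_deposits(density)
        rr_1, _ = np.nonzero(labels == 1)
        rr_2, _ = np.nonzero(labels == 2)
        assert rr_1.min() < rr_2.min()  # label 1 is the topmost region

    def test_out_of_range_density_rejected(self):
        with pytest.raises(InputError):
            watershed_deposits(np.full((5, 5), 1.5))


class TestCountCells:
    def test_single_deposit_counts_planted_cells(self):
        deposits = np.zeros((10, 10), dtype=np.int32)
        deposits[4:6, 4:6] = 1
        cells = cell_table(
            [(i, 450.0 + 10 * i, 450.0, True) for i in range(5)]
        )
        out = count_cells_per_deposit(deposits, cells, factor=100)
        assert out.table.iron_cell_count.tolist() == [5]
        assert out.n_unassigned == 0

    def test_background_cells_unassigned(self):
        deposits = np.zeros((10, 10), dtype=np.int32)
        cells = cell_table([(1, 50.0, 50.0, True), (2, 500.0, 500.0, True)])
        out = count_cells_per_deposit(deposits, cells, factor=100)
        assert len(out.table) == 0
        assert out.n_unassigned == 2

    def test_out_of_raster_cells_skipped_with_count(self):
        deposits = np.ones((5, 5), dtype=np.int32)
        cells = cell_table([(1, 250.0, 250.0, True), (2, 10_000.0, 250.0, True)])
        out = count_cells_per_deposit(deposits, cells, factor=100)
        assert out.n_skipped == 1
        assert out.table.iron_cell_count.tolist() == [1]

    def test_iron_negative_cells_ignored(self):
        deposits = np.ones((5, 5), dtype=np.int32)
        cells = cell_table([(1, 250.0, 250.0, True), (2, 250.0, 250.0, False)])
        out = count_cells_per_deposit(deposits, cells, factor=100)
        assert out.table.iron_cell_count.tolist() == [1]

    def test_count_conservation(self):
        """assigned + unassigned + skipped covers every iron+ cell."""
        rng = np.random.default_rng(3)
        deposits = np.zeros((20, 20), dtype=np.int32)
        deposits[2:5, 2:5] = 1
        deposits[10:12, 14:17] = 2
        cells = cell_table(
            [(i, float(rng.uniform(-100, 2100)), float(rng.uniform(-100, 2100)),
              True) for i in range(200)]
        )
        out = count_cells_per_deposit(deposits, cells, factor=100)
        total = out.table.iron_cell_count.sum() + out.n_unassigned + out.n_skipped
        assert total == 200


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [0, 2, 3])
    def test_deposit_count_and_cellularity_recovered(self, seed):
        """Phantom colonies are recovered 1:1 with faithful mean cell counts."""
        cfg = HistoPhantomConfig(seed=seed)
        histo, truth = generate_histo_phantom(cfg)
        density = downsample_to_mri(detect_iron_pixels(histo), 100)
        deposits = watershed_deposits(density)
        out = count_cells_per_deposit(deposits, truth.cell_table, 100,
                                      cfg.microns_per_pixel)
        assert int(deposits.max()) == cfg.n_deposits
        true_mean = truth.deposit_table.n_cells.mean()
        assert abs(out.table.iron_cell_count.mean() - true_mean) <= 1.0
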