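import numpy as np
import pandas as pd
import pytest

from oracles import (
    brute_edge_cells,
    brute_edge_length,
    brute_enn_mean,
    brute_mean_edge_distance,
    flood_fill_labels,
)
from urbexbio.fragmentation import (
    class_metrics,
    edge_cells,
    edge_distance_series,
    fragmentation_in_buffer,
    label_patches,
    urban_buffer,
)
from urbexbio.habitat_accounting import reclass_table_from_legend, reclassify
from urbexbio.raster_core import CategoricalGrid, GridSpec, ZoneMap
from urbexbio.synthetic_data import ScenarioStack


def _mask(coords, shape):
    m = np.zeros(shape, dtype=bool)
    for r, c in coords:
        m[r, c] = True
    return m


class TestLabeling:
    def test_diagonal_cells_eight_connectivity_one_patch(self):
        m = _mask([(0, 0), (1, 1)], (3, 3))
        assert label_patches(m, 8).n_patches == 1

    def test_diagonal_cells_four_connectivity_two_patches(self):
        m = _mask([(0, 0), (1, 1)], (3, 3))
        assert label_patches(m, 4).n_patches == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_masks_match_flood_fill(self, connectivity, rng):
        for _ in range(10):
            m = rng.random((30, 30)) < 0.4
            ours = label_patches(m, connectivity)
            oracle = flood_fill_labels(m, connectivity)
            assert ours.n_patches == oracle.max()
            # same partition up to label permutation
            pairs = set(zip(ours.labels[m].tolist(), oracle[m].tolist()))
            assert len(pairs) == ours.n_patches


class TestClassMetrics:
    def test_two_patch_fixture(self):
        """6x6 grid, 100 m cells: L-patch of 3 + square of 4."""
        m = _mask([(0, 0), (0, 1), (1, 0), (4, 4), (4, 5), (5, 4), (5, 5)], (6, 6))
        extent = np.ones((6, 6), dtype=bool)
        metrics = class_metrics(label_patches(m, 8), extent, 100.0)
        assert metrics["n_patches"] == 2
        assert metrics["mps_ha"] == pytest.approx(3.5)
        assert metrics["ed_m_per_ha"] == pytest.approx(800 / 36, abs=0.01)
        assert metrics["enn_mn_m"] == pytest.approx(500.0)

    def test_single_patch_filling_extent(self):
        m = np.ones((4, 4), dtype=bool)
        extent = np.ones((4, 4), dtype=bool)
        metrics = class_metrics(label_patches(m, 8), extent, 100.0)
        assert metrics["ed_m_per_ha"] == 0.0
        assert np.isnan(metrics["enn_mn_m"])

    def test_single_cell_patch_in_3x3(self):
        m = _mask([(1, 1)], (3, 3))
        extent = np.ones((3, 3), dtype=bool)
        metrics = class_metrics(label_patches(m, 8), extent, 100.0)
        # 400 m of edge over a 9-cell (9 ha) extent
        assert metrics["ed_m_per_ha"] == pytest.approx(400 / 9, abs=0.01)

    def test_no_patches_flagged_undefined(self):
        m = np.zeros((3, 3), dtype=bool)
        metrics = class_metrics(label_patches(m, 8), np.ones((3, 3), bool), 100.0)
        assert not metrics["defined"]

    def test_edge_and_enn_match_oracles_on_random_masks(self, rng):
        for _ in range(8):
            m = rng.random((20, 20)) < 0.3
            extent = np.ones((20, 20), dtype=bool)
            patches = label_patches(m, 8)
            assert np.array_equal(edge_cells(m, extent), brute_edge_cells(m, extent))
            metrics = class_metrics(patches, extent, 100.0)
            if patches.n_patches == 0:
                continue
            # 400 cells at 100 m = 400 ha of extent
            expected_ed = brute_edge_length(m, extent, 100.0) / 400.0
            assert metrics["ed_m_per_ha"] == pytest.approx(expected_ed, abs=1e-9)
            enn = brute_enn_mean(patches.labels, extent, 100.0)
            if np.isnan(enn):
                assert np.isnan(metrics["enn_mn_m"])
            else:
                assert metrics["enn_mn_m"] == pytest.approx(enn, abs=1e-9)

    def test_translation_invariance(self):
        base = _mask([(1, 1), (1, 2), (4, 4)], (8, 8))
        shifted = np.roll(base, (2, 2), axis=(0, 1))
        extent = np.ones((8, 8), dtype=bool)
        m1 = class_metrics(label_patches(base, 8), extent, 100.0)
        m2 = class_metrics(label_patches(shifted, 8), extent, 100.0)
        for key in ("mps_ha", "ed_m_per_ha", "enn_mn_m"):
            assert m1[key] == pytest.approx(m2[key])


class TestBuffer:
    def test_single_cell_radius_2_5(self):
        m = _mask([(5, 5)], (11, 11))
        buf = urban_buffer(m, 2500.0, 1000.0)
        assert buf.sum() == 20  # 5x5 square minus center minus 4 corners
        assert not buf[5, 5]

    def test_radius_below_cell_size_empty(self):
        m = _mask([(2, 2)], (5, 5))
        assert urban_buffer(m, 500.0, 1000.0).sum() == 0

    def test_all_urban_empty_buffer(self):
        m = np.ones((4, 4), dtype=bool)
        assert urban_buffer(m, 3000.0, 1000.0).sum() == 0

    def test_buffer_monotone_in_urban(self, rng):
        u1 = rng.random((20, 20)) < 0.05
        u2 = u1 | (rng.random((20, 20)) < 0.05)
        b1 = urban_buffer(u1, 3000.0, 1000.0)
        b2 = urban_buffer(u2, 3000.0, 1000.0)
        assert np.all((b1 & ~u2) <= b2 | u2)
        # buffered-or-urban area grows monotonically
        assert (b2 | u2).sum() >= (b1 | u1).sum()


def _strip_world():
    """1x8 strip, 100 m cells: urban cols 0-1, other 2-3, forest 4-6, other 7."""
    legend = {0: "urban", 1: "other", 2: "forest"}
    codes = np.array([[0, 0, 1, 1, 2, 2, 2, 1]], dtype=np.int32)
    grid = CategoricalGrid(GridSpec(1, 8, 100.0), codes, legend)
    return reclassify(grid, reclass_table_from_legend(legend))


class TestEdgeDistance:
    def test_strip_mean_distance_300m(self):
        habitat, natural = _strip_world()
        urban = np.array([[1, 1, 0, 0, 0, 0, 0, 0]], dtype=bool)
        stack = ScenarioStack("S", (2015,), [urban], habitat.spec)
        df = edge_distance_series(stack, habitat, natural)
        forest = df[(df.habitat_class == "forest") & (df.epoch == 2015)]
        assert forest.iloc[0]["mean_distance_m"] == pytest.approx(300.0)

    def test_adjacent_urban_distance_one_cell(self):
        legend = {0: "urban", 1: "forest"}
        codes = np.array([[0, 1, 1, 1]], dtype=np.int32)
        grid = CategoricalGrid(GridSpec(1, 4, 100.0), codes, legend)
        habitat, natural = reclassify(grid, reclass_table_from_legend(legend))
        urban = np.array([[1, 0, 0, 0]], dtype=bool)
        stack = ScenarioStack("S", (2015,), [urban], habitat.spec)
        df = edge_distance_series(stack, habitat, natural)
        forest = df[(df.habitat_class == "forest")]
        assert forest.iloc[0]["mean_distance_m"] == pytest.approx(100.0)

    def test_urban_growth_toward_habitat_positive_effect(self):
        habitat, natural = _strip_world()
        u0 = np.array([[1, 1, 0, 0, 0, 0, 0, 0]], dtype=bool)
        u1 = np.array([[1, 1, 1, 0, 0, 0, 0, 0]], dtype=bool)
        stack = ScenarioStack("S", (2015, 2020), [u0, u1], habitat.spec)
        df = edge_distance_series(stack, habitat, natural)
        forest = df[df.habitat_class == "forest"].sort_values("epoch")
        assert forest.iloc[0]["mean_distance_m"] == pytest.approx(300.0)
        assert forest.iloc[1]["mean_distance_m"] == pytest.approx(200.0)
        assert forest.iloc[1]["effect_change_m"] == pytest.approx(+100.0)

    def test_random_worlds_match_brute_force(self, rng):
        for _ in range(5):
            codes = rng.integers(0, 3, size=(12, 12)).astype(np.int32)
            legend = {0: "urban", 1: "cropland", 2: "forest"}
            grid = CategoricalGrid(GridSpec(12, 12, 100.0), codes, legend)
            habitat, natural = reclassify(grid, reclass_table_from_legend(legend))
            urban = codes == 0
            stack = ScenarioStack("S", (2015,), [urban], habitat.spec)
            df = edge_distance_series(stack, habitat, natural)
            row = df[(df.habitat_class == "forest") & (df.epoch == 2015)].iloc[0]
            extent = np.ones((12, 12), dtype=bool)
            expect = brute_mean_edge_distance(urban, (codes == 2) & ~urban, extent, 100.0)
            if np.isnan(expect):
                assert not row["defined"]
            else:
                assert row["mean_distance_m"] == pytest.approx(expect, abs=1e-9)


class TestFragmentationInBuffer:
    def _zone_all(self, shape, cell=1000.0):
        codes = np.ones(shape, dtype=np.int32)
        return ZoneMap(
            "z",
            CategoricalGrid(GridSpec(*shape, cell), codes, {1: "z1"}),
            pd.DataFrame({"zone_id": [1], "name": ["z1"]}),
        )

    def test_no_urban_no_defined_records(self):
        shape = (10, 10)
        natural = np.ones(shape, dtype=bool)
        stack = ScenarioStack(
            "S", (2015, 2020), [np.zeros(shape, bool)] * 2, GridSpec(*shape, 1000.0)
        )
        df = fragmentation_in_buffer(natural, stack, self._zone_all(shape))
        assert not df["defined"].any()

    def test_urban_splitting_patch_halves_mps(self):
        shape = (3, 9)
        natural = np.zeros(shape, dtype=bool)
        natural[1, 1:8] = True  # one 7-cell strip
        u0 = np.zeros(shape, dtype=bool)
        u0[0, 4] = True  # urban seed near the strip
        u1 = u0.copy()
        u1[1, 4] = True  # splits the strip into two 3-cell halves
        stack = ScenarioStack("S", (2015, 2020), [u0, u1], GridSpec(*shape, 1000.0))
        df = fragmentation_in_buffer(
            natural, stack, self._zone_all(shape), radius_m=9000.0
        )
        by_epoch = df.set_index("epoch")
        assert by_epoch.loc[2015, "n_patches"] == 1
        assert by_epoch.loc[2020, "n_patches"] == 2
        assert by_epoch.loc[2020, "mps_ha"] == pytest.approx(
            by_epoch.loc[2015, "mps_ha"] * 3 / 7
        )

    def test_ed_nondecreasing_for_growing_urban_block(self):
        """A centrally growing urban block on all-natural land carves an
        ever longer habitat-urban edge: ED rises monotonically."""
        shape = (20, 20)
        natural = np.ones(shape, dtype=bool)
        masks = []
        for k in (1, 2, 3, 4):
            u = np.zeros(shape, dtype=bool)
            u[10 - k : 10 + k, 10 - k : 10 + k] = True
            masks.append(u)
        stack = ScenarioStack("S", (2015, 2020, 2030, 2040), masks, GridSpec(*shape, 1000.0))
        df = fragmentation_in_buffer(
            natural, stack, self._zone_all(shape), radius_m=30_000.0
        )
        ed = df.sort_values("epoch")["ed_m_per_ha"].to_numpy()
        assert np.all(np.diff(ed) >= 0) and ed[0] > 0
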