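import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ocdsim.cells import (CellField, diffuse_msc, effective_capacity,
                          init_cells, update_populations)
from ocdsim.config import RunConfig, build_defect_lattice, scaled_fixture_config
from ocdsim.mechanics import BONE, CARTILAGE, FIBROUS, RESORPTION

CFG = RunConfig()
SMALL = scaled_fixture_config()


def empty_field(shape):
    z = np.zeros(shape)
    return CellField(z.copy(), z.copy(), z.copy(), z.copy())


class TestInit:
    def test_base_row_seeded_at_capacity(self, lattice):
        cells = init_cells(lattice, CFG)
        assert np.all(cells.msc[0] == 100.0)
        assert np.count_nonzero(cells.msc) == 40
        assert cells.msc.sum() == pytest.approx(4000.0)
        assert cells.osteoblast.sum() == 0.0

    def test_small_fixture_seeds_its_base_row(self):
        lat = build_defect_lattice(SMALL)
        cells = init_cells(lat, SMALL)
        assert np.count_nonzero(cells.msc) == 8

    def test_effective_capacity_reduced_by_scaffold(self):
        n = np.zeros((4, 4)); n[:, 1] = 0.5
        cap = effective_capacity(CFG, n, (4, 4))
        assert np.all(cap[:, 1] == 50.0)
        assert np.all(cap[:, 0] == 100.0)


class TestDiffusion:
    def test_uniform_field_with_closed_boundaries_is_stationary(self):
        cells = empty_field((8, 8))
        cells.msc[:] = 42.0
        d = np.full((8, 8), 0.8)
        out = diffuse_msc(cells, d, 1.0, SMALL, base_source=False)
        assert np.allclose(out.msc, 42.0)

    def test_mass_conservation_with_closed_boundaries(self):
        rng = np.random.default_rng(7)
        cells = empty_field((8, 8))
        cells.msc[:] = rng.uniform(0, 100, (8, 8))
        d = rng.uniform(0.01, 0.8, (8, 8))
        total0 = cells.msc.sum()
        for _ in range(5):
            cells = diffuse_msc(cells, d, 1.0, SMALL, base_source=False)
        assert cells.msc.sum() == pytest.approx(total0, rel=1e-10)

    def test_source_makes_every_count_non_decreasing(self):
        """Maximum principle: with the base source active and no sinks,
        MSC counts can only grow."""
        lat = build_defect_lattice(SMALL)
        cells = init_cells(lat, SMALL)
        d = np.full(cells.msc.shape, 0.8)
        for _ in range(6):
            out = diffuse_msc(cells, d, 1.0, SMALL)
            assert np.all(out.msc >= cells.msc - 1e-9)
            cells = out

    def test_counts_clipped_to_capacity(self):
        lat = build_defect_lattice(SMALL)
        cells = init_cells(lat, SMALL)
        cap = np.full(cells.msc.shape, 30.0)
        out = diffuse_msc(cells, np.full(cells.msc.shape, 0.8), 1.0, SMALL,
                          capacity=cap)
        assert np.all(out.msc <= 30.0 + 1e-12)

    def test_non_positive_dt_rejected(self):
        cells = empty_field((4, 4))
        with pytest.raises(ValueError):
            diffuse_msc(cells, np.full((4, 4), 0.8), 0.0, SMALL)


class TestPopulationRules:
    def test_cartilage_class_differentiation_and_growth(self):
        """MSC-only element under the cartilage stimulus: 5 cells become
        chondrocytes; MSC mitosis is clipped by the remaining room."""
        cells = empty_field((1, 1))
        cells.msc[0, 0] = 100.0
        cls = np.full((1, 1), CARTILAGE)
        out = update_populations(cells, cls, CFG)
        assert out.chondrocyte[0, 0] == pytest.approx(5.0)
        assert out.msc[0, 0] == pytest.approx(95.0)  # 95*1.15 clipped
        assert out.total[0, 0] <= 100.0 + 1e-9

    def test_resorption_reduces_osteoblasts_by_10_percent(self):
        cells = empty_field((1, 1))
        cells.osteoblast[0, 0] = 50.0
        out = update_populations(cells, np.full((1, 1), RESORPTION), CFG)
        assert out.osteoblast[0, 0] == pytest.approx(45.0)

    def test_empty_element_stays_empty(self):
        cells = empty_field((2, 2))
        out = update_populations(cells, np.full((2, 2), BONE), CFG)
        assert np.all(out.total == 0.0)

    def test_mismatched_phenotypes_undergo_apoptosis(self):
        cells = empty_field((1, 1))
        cells.osteoblast[0, 0] = 40.0
        cells.fibroblast[0, 0] = 20.0
        out = update_populations(cells, np.full((1, 1), CARTILAGE), CFG)
        assert out.osteoblast[0, 0] == pytest.approx(40.0 * 0.85)
        assert out.fibroblast[0, 0] == pytest.approx(20.0 * 0.85)

    def test_resorption_decay_is_exactly_geometric(self):
        """With zero diffusivity and resorption everywhere, osteoblast
        counts decay as 0.9^d."""
        cells = empty_field((3, 3))
        cells.osteoblast[:] = 80.0
        cls = np.full((3, 3), RESORPTION)
        for d in range(1, 8):
            cells = update_populations(cells, cls, CFG)
            assert np.allclose(cells.osteoblast, 80.0 * 0.9**d)

    def test_differentiation_conserves_cells_at_transfer(self):
        """With all mitosis/apoptosis rates zeroed, the MSC -> phenotype
        transfer leaves the total unchanged."""
        cfg = dataclasses.replace(CFG, tissue_mitosis_rate=0.0,
                                  apoptosis_rate=0.0, msc_mitosis_rate=0.0,
                                  resorption_rate=0.0)
        cells = empty_field((2, 2))
        cells.msc[:] = 60.0
        cells.osteoblast[:] = 10.0
        cls = np.array([[BONE, CARTILAGE], [FIBROUS, RESORPTION]])
        out = update_populations(cells, cls, cfg)
        assert np.allclose(out.total, 70.0)
        assert out.osteoblast[0, 0] == pytest.approx(13.0)  # 10 + 5% of 60

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_bounds_hold_for_random_states_and_stimuli(self, seed):
        """Non-negativity and the capacity bound survive arbitrary class
        fields and admissible initial populations."""
        rng = np.random.default_rng(seed)
        shape = (6, 6)
        scaffold = rng.uniform(0.0, 0.5, shape) * rng.integers(0, 2, shape)
        cap = effective_capacity(CFG, scaffold, shape)
        raw = rng.uniform(0, 1, (4,) + shape)
        raw *= cap / np.maximum(raw.sum(axis=0), 1e-9) * rng.uniform(0, 1)
        cells = CellField(*raw)
        cls = rng.integers(0, 4, shape)
        out = update_populations(cells, cls, CFG, capacity=cap)
        for arr in (out.msc, out.osteoblast, out.chondrocyte, out.fibroblast):
            assert np.all(arr >= 0.0)
        assert np.all(out.total <= cap + 1e-9)
        out2 = diffuse_msc(out, rng.uniform(0.01, 0.8, shape), 1.0, SMALL,
                           capacity=cap)
        assert np.all(out2.msc >= 0.0)
        assert np.all(out2.total <= cap + 1e-6)
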