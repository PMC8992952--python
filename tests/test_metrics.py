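import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rbedose.grids import StructureMask, VoxelGrid
from rbedose.metrics import (
    d_hot_volume,
    dvh,
    letd_histogram,
    line_profile,
    mean_dose,
    v_threshold,
)
from rbedose.rbe import model_spec, rbe_field


def grid_and_mask(values, spacing=(2.0, 2.0, 2.0), selected=None, units="Gy"):
    grid = VoxelGrid(values=np.asarray(values, dtype=float), spacing_mm=spacing, units=units)
    sel = np.ones(grid.shape, bool) if selected is None else selected
    return grid, StructureMask(name="s", selected=sel, grid_ref=grid)


class TestMeanDose:
    def test_constant_field(self):
        grid, mask = grid_and_mask(np.full((2, 2, 1), 2.0))
        assert mean_dose(grid, mask) == 2.0

    def test_hand_mean(self):
        grid, mask = grid_and_mask(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1))
        assert mean_dose(grid, mask) == 2.5

    def test_constant_rbe_weighting_scales_heart_mean(self, default_case):
        heart = default_case.mask("heart")
        weighted = rbe_field(default_case, model_spec("constant_1p1")).weighted_dose
        assert mean_dose(weighted, heart) == pytest.approx(
            1.1 * mean_dose(default_case.physical_dose, heart), rel=1e-12
        )

    def test_empty_mask_rejected(self):
        grid, _ = grid_and_mask(np.ones((2, 2, 2)))
        empty = StructureMask(name="e", selected=np.zeros((2, 2, 2), bool), grid_ref=grid)
        with pytest.raises(ValueError, match="no voxels"):
            mean_dose(grid, empty)


class TestVThreshold:
    def test_explicit_count(self):
        grid, mask = grid_and_mask(np.arange(10.0).reshape(10, 1, 1))
        assert v_threshold(grid, mask, 5.0) == 50.0  # doses 5..9 of 0..9

    def test_threshold_zero_is_everything(self):
        grid, mask = grid_and_mask(np.arange(10.0).reshape(10, 1, 1))
        assert v_threshold(grid, mask, 0.0) == 100.0

    def test_threshold_above_max_is_nothing(self):
        grid, mask = grid_and_mask(np.arange(10.0).reshape(10, 1, 1))
        assert v_threshold(grid, mask, 9.5) == 0.0


class TestDHotVolume:
    def test_sorted_accumulation(self):
        # spacing 5 x 5 x 2 mm -> 0.05 cc per voxel; hottest 0.1 cc = 2 voxels
        grid, mask = grid_and_mask(
            np.array([9.0, 8.0, 7.0, 6.0, 5.0]).reshape(5, 1, 1), spacing=(5, 5, 2)
        )
        assert d_hot_volume(grid, mask, 0.1) == 8.0

    def test_full_volume_gives_minimum(self):
        grid, mask = grid_and_mask(
            np.array([9.0, 8.0, 7.0]).reshape(3, 1, 1), spacing=(5, 5, 2)
        )
        assert d_hot_volume(grid, mask, 0.15) == 7.0

    def test_uniform_field(self):
        grid, mask = grid_and_mask(np.full((4, 1, 1), 3.0), spacing=(5, 5, 2))
        for v in (0.01, 0.05, 0.2):
            assert d_hot_volume(grid, mask, v) == 3.0

    def test_oversized_volume_rejected(self):
        grid, mask = grid_and_mask(np.ones((2, 1, 1)), spacing=(5, 5, 2))
        with pytest.raises(ValueError, match="exceeds structure volume"):
            d_hot_volume(grid, mask, 0.2)

    def test_non_increasing_in_volume(self):
        rng = np.random.default_rng(5)
        grid, mask = grid_and_mask(rng.random((4, 4, 4)) * 50, spacing=(2, 2, 2))
        volumes = np.linspace(0.01, 0.5, 20)
        doses = [d_hot_volume(grid, mask, v) for v in volumes]
        assert all(a >= b for a, b in zip(doses, doses[1:]))


class TestDVH:
    def test_uniform_step(self):
        grid, mask = grid_and_mask(np.full((2, 2, 1), 2.0))
        curve = dvh(grid, mask, bin_width=0.5)
        for edge, vf in zip(curve.dose_edges, curve.volume_fraction):
            assert vf == (100.0 if edge <= 2.0 else 0.0)

    def test_two_voxel_median_edge(self):
        grid, mask = grid_and_mask(np.array([1.0, 3.0]).reshape(2, 1, 1))
        assert dvh(grid, mask, bin_width=0.5).at(2.0) == 50.0

    def test_matches_v_threshold_on_every_edge(self, default_case):
        heart = default_case.mask("heart")
        curve = dvh(default_case.physical_dose, heart, bin_width=0.5)
        for edge, vf in zip(curve.dose_edges[::7], curve.volume_fraction[::7]):
            assert vf == pytest.approx(
                v_threshold(default_case.physical_dose, heart, edge), abs=1e-9
            )

    def test_monotone_non_increasing(self, default_case):
        curve = dvh(default_case.physical_dose, default_case.mask("CTV"))
        assert np.all(np.diff(curve.volume_fraction) <= 1e-12)
        assert curve.volume_fraction[0] == 100.0


class TestLetdHistogram:
    def test_manual_binning(self):
        letd, mask = grid_and_mask(np.array([2.0, 2.0, 8.0]).reshape(3, 1, 1),
                                   units="keV/um")
        dose, _ = grid_and_mask(np.full((3, 1, 1), 5.0))
        h = letd_histogram(letd, dose, mask, dose_cutoff_Gy=0.0, bin_width=1.0)
        bin_of_2 = np.searchsorted(h.bin_edges, 2.0, side="right") - 1
        assert h.percent[bin_of_2] == pytest.approx(200.0 / 3.0, abs=1e-9)
        assert h.n_counted == 3

    def test_cutoff_above_max_dose_flags_empty(self):
        letd, mask = grid_and_mask(np.array([2.0, 8.0]).reshape(2, 1, 1), units="keV/um")
        dose, _ = grid_and_mask(np.full((2, 1, 1), 5.0))
        h = letd_histogram(letd, dose, mask, dose_cutoff_Gy=50.0)
        assert h.empty
        assert h.percent.sum() == 0.0

    def test_dose_cutoffs_nest(self, default_case):
        heart = default_case.mask("heart")
        counts = [
            letd_histogram(default_case.letd, default_case.physical_dose, heart,
                           dose_cutoff_Gy=c).n_counted
            for c in (1.0, 20.0, 40.0)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestLineProfile:
    def test_constant_grid(self):
        grid, _ = grid_and_mask(np.full((5, 5, 5), 7.0))
        prof = line_profile(grid, (0, 0, 0), (8, 8, 8), step_mm=1.0)
        np.testing.assert_allclose(prof.values, 7.0)

    def test_axis_through_voxel_centers_is_exact(self):
        vals = np.zeros((5, 1, 1))
        vals[:, 0, 0] = [1.0, 4.0, 2.0, 8.0, 3.0]
        grid = VoxelGrid(values=vals, spacing_mm=(2, 2, 2), units="Gy")
        prof = line_profile(grid, (0, 0, 0), (8, 0, 0), step_mm=2.0)
        np.testing.assert_allclose(prof.values, vals[:, 0, 0])

    def test_out_of_bounds_endpoint_rejected(self):
        grid, _ = grid_and_mask(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="outside the grid"):
            line_profile(grid, (0, 0, 0), (0, 0, 99))

    def test_letd_peak_lands_just_beyond_ctv(self, default_case, default_spec):
        """The LETd profile through the target peaks 1-3 mm inside the heart side."""
        cx, cy = default_spec.center_xy_mm
        prof = line_profile(default_case.letd, (cx, cy, 10.0), (cx, cy, 60.0),
                            step_mm=0.5)
        z_peak = 10.0 + prof.distance_mm[np.argmax(prof.values)]
        assert 1.0 <= z_peak - default_spec.ctv_distal_z_mm <= 3.0


@settings(deadline=None, max_examples=40, derandomize=True)
@given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 10))
def test_mean_dose_is_linear(scale, seed):
    rng = np.random.default_rng(seed)
    vals = rng.random((3, 3, 3)) * 10
    grid, mask = grid_and_mask(vals)
    scaled, _ = grid_and_mask(scale * vals)
    assert mean_dose(scaled, mask) == pytest.approx(scale * mean_dose(grid, mask), rel=1e-12)


def test_variable_rbe_metrics_dominate_constant(default_case):
    """With heart LETd above 2 keV/um, every variable-RBE model's metrics are at
    least the constant-1.1 metrics (the regime reported for distal-edge hearts)."""
    weighted = {
        name: rbe_field(default_case, model_spec(name)).weighted_dose
        for name in ("constant_1p1", "mcmahon_linear", "mcnamara", "wedenberg")
    }
    for structure in ("heart", "ventricles", "LAD"):
        mask = default_case.mask(structure)
        base_mean = mean_dose(weighted["constant_1p1"], mask)
        base_v5 = v_threshold(weighted["constant_1p1"], mask, 5.0)
        for name in ("mcmahon_linear", "mcnamara", "wedenberg"):
            assert mean_dose(weighted[name], mask) >= base_mean - 1e-12
            assert v_threshold(weighted[name], mask, 5.0) >= base_v5 - 1e-12
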