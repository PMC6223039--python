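"""Volume, shape factor, solidity, channel volume and peripherality."""

import math

import numpy as np
import pytest
from scipy import ndimage

from nucarch.core import GridSpec, NuclearMask
from nucarch.morphometry import (
    channel_volume,
    classify_invaginated,
    nuclear_shape_factor,
    nuclear_volume,
    peripherality_index,
    solidity,
)
from nucarch.synthetic import NucleusShapeParams, make_nucleus_mask

from conftest import mask_from_voxels, random_blob_mask


class TestNuclearVolume:
    def test_voxel_count_times_voxel_volume(self):
        m = np.zeros((12, 12, 12), dtype=bool)
        m[1:11, 1:11, 1:11] = True  # 1000 voxels
        mask = NuclearMask(m, GridSpec((12, 12, 12), (0.5, 0.5, 0.5)))
        assert nuclear_volume(mask) == pytest.approx(125.0)

    def test_digital_sphere_near_analytic(self, sphere_mask):
        assert nuclear_volume(sphere_mask) == pytest.approx(
            4 / 3 * math.pi * 27, rel=0.03
        )

    def test_matches_explicit_voxel_count_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = random_blob_mask(rng)
            count = 0
            for k in range(mask.grid.shape[0]):
                for j in range(mask.grid.shape[1]):
                    for i in range(mask.grid.shape[2]):
                        count += bool(mask.mask[k, j, i])
            assert nuclear_volume(mask) == pytest.approx(
                count * mask.grid.voxel_volume
            )


class TestNuclearShapeFactor:
    def test_sphere_anchor(self, sphere_mask):
        # r = 3 µm at 0.125 µm isotropic spacing is the sphere anchor:
        # a perfect sphere scores 1 within the mesh tolerance.
        assert nuclear_shape_factor(sphere_mask) == pytest.approx(1.0, abs=0.02)

    def test_prolate_spheroid_matches_closed_form(self):
        grid = GridSpec((80, 44, 44), (0.2, 0.2, 0.2))
        mask = make_nucleus_mask(
            NucleusShapeParams(radius=3.0, axis_ratios=(2.0, 1.0, 1.0)),
            grid,
            seed=0,
        )
        a, c = 3.0, 6.0  # equatorial and polar semi-axes
        e = math.sqrt(1 - a * a / (c * c))
        area = 2 * math.pi * a * a * (1 + c / (a * e) * math.asin(e))
        vol = 4 / 3 * math.pi * a * a * c
        psi = math.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area
        assert nuclear_shape_factor(mask) == pytest.approx(psi, rel=0.03)

    def test_strictly_decreasing_with_invagination_depth(self, iso_grid_fine):
        values = []
        for depth in (0.0, 0.5, 1.0, 1.5, 2.0):
            m = make_nucleus_mask(
                NucleusShapeParams(
                    radius=3.0,
                    invagination_count=1,
                    invagination_depth=depth,
                    invagination_radius=1.0,
                ),
                iso_grid_fine,
                seed=11,
            )
            values.append(nuclear_shape_factor(m))
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_small_mask_rejected_with_threshold_in_message(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[3:5, 3:5, 3:5] = True
        mask = NuclearMask(m, GridSpec((8, 8, 8), (0.25, 0.25, 0.25)))
        with pytest.raises(ValueError, match="100"):
            nuclear_shape_factor(mask)

    def test_invariant_under_whole_voxel_translation(self, sphere_mask):
        shifted = NuclearMask(
            np.roll(sphere_mask.mask, (1, 2, -1), axis=(0, 1, 2)),
            sphere_mask.grid,
        )
        assert nuclear_shape_factor(shifted) == pytest.approx(
            nuclear_shape_factor(sphere_mask), abs=1e-9
        )


class TestSolidity:
    def test_convex_sphere_above_098(self, sphere_mask):
        assert solidity(sphere_mask) >= 0.98

    def test_deeper_pockets_monotonically_lower_solidity(self, iso_grid_fine):
        values = []
        for depth in (0.5, 1.0, 1.5, 2.0):
            m = make_nucleus_mask(
                NucleusShapeParams(
                    radius=3.0,
                    invagination_count=1,
                    invagination_depth=depth,
                    invagination_radius=1.0,
                ),
                iso_grid_fine,
                seed=5,
            )
            values.append(solidity(m))
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_planar_mask_rejected(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[4, 2:6, 2:6] = True
        mask = NuclearMask(m, GridSpec((8, 8, 8), (0.25, 0.25, 0.25)))
        with pytest.raises(ValueError, match="planar|degenerate"):
            solidity(mask)

    def test_classification_uses_cutoff(self):
        assert classify_invaginated(0.90, cutoff=0.92)
        assert not classify_invaginated(0.95, cutoff=0.92)


class TestChannelVolume:
    def _shell_mask(self, grid):
        mask = make_nucleus_mask(NucleusShapeParams(radius=3.0), grid, seed=0)
        return mask

    def test_binary_shell_volume_is_exact(self):
        grid = GridSpec((26, 26, 26), (0.3, 0.3, 0.3))
        mask = self._shell_mask(grid)
        shell = mask.mask & ~ndimage.binary_erosion(mask.mask, iterations=2)
        channel = 800.0 * shell
        expected = shell.sum() * grid.voxel_volume
        assert channel_volume(channel, mask) == pytest.approx(expected)

    def test_zero_channel_returns_zero_not_error(self, sphere_mask):
        assert channel_volume(np.zeros(sphere_mask.grid.shape), sphere_mask) == 0.0

    def test_doubled_shell_thickness_doubles_volume(self):
        from nucarch.synthetic import NoiseParams, SceneConfig, render_scene

        vols = []
        for thickness in (0.4, 0.8):
            cfg = SceneConfig(
                channel_names=("dapi", "lamin"),
                lamin_shell_thickness=thickness,
                noise=NoiseParams(),
                psf_sigma=(0.1, 0.1, 0.1),
            )
            volume, truth = render_scene(cfg, seed=2)
            vols.append(
                channel_volume(volume.channel("lamin").astype(float), truth.mask)
            )
        assert vols[1] / vols[0] == pytest.approx(2.0, rel=0.10)


class TestPeripheralityIndex:
    def test_all_intensity_in_boundary_shell_scores_one(self, sphere_mask):
        edt = ndimage.distance_transform_edt(
            sphere_mask.mask, sampling=sphere_mask.grid.spacing
        )
        channel = ((edt > 0) & (edt <= 0.5)).astype(float)
        assert peripherality_index(channel, sphere_mask, 0.5) == 1.0

    def test_central_point_scores_zero(self, sphere_mask):
        channel = np.zeros(sphere_mask.grid.shape)
        center = tuple(
            (np.argwhere(sphere_mask.mask).mean(axis=0)).round().astype(int)
        )
        channel[center] = 100.0
        assert peripherality_index(channel, sphere_mask, 0.5) == 0.0

    def test_uniform_intensity_equals_shell_volume_fraction(self, sphere_mask):
        channel = np.ones(sphere_mask.grid.shape)
        got = peripherality_index(channel, sphere_mask, 0.5)
        edt = ndimage.distance_transform_edt(
            sphere_mask.mask, sampling=sphere_mask.grid.spacing
        )
        frac = ((edt > 0) & (edt <= 0.5)).sum() / sphere_mask.voxel_count
        assert got == pytest.approx(frac)
        # Complement: shell fraction + core fraction = 1 exactly.
        core = ((sphere_mask.mask) & (edt > 0.5)).sum() / sphere_mask.voxel_count
        assert frac + core == pytest.approx(1.0)

    def test_nonpositive_shell_depth_rejected(self, sphere_mask):
        with pytest.raises(ValueError):
            peripherality_index(
                np.ones(sphere_mask.grid.shape), sphere_mask, 0.0
            )
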