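"""Engulfment assay: masking, object segmentation, index, loci."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from _oracles import bfs_component_sizes
from engulf3d.core import BinaryMask, Engulf3dError, VoxelVolume
from engulf3d.engulfment import (
    detect_spots,
    engulfment_index,
    engulfment_loci,
    internalized_objects,
    mask_internal_channel,
    quantify_engulfment,
)
from engulf3d.reconstruct import CellSurface, reconstruct_cell
from engulf3d.synthetic import SceneSpec, generate_scene

SPACING = (0.3, 0.132, 0.132)


def surface_from(mask: np.ndarray, soma=(0.0, 0.0, 0.0)) -> CellSurface:
    return CellSurface(mask=BinaryMask(mask, SPACING), soma_center_um=soma)


class TestMaskInternalChannel:
    def test_all_false_yields_zeros(self, rng):
        target = VoxelVolume(rng.random((4, 8, 8)), SPACING)
        out = mask_internal_channel(target, surface_from(np.zeros((4, 8, 8), bool)))
        assert not out.data.any()

    def test_all_true_is_identity(self, rng):
        target = VoxelVolume(rng.random((4, 8, 8)), SPACING)
        out = mask_internal_channel(target, surface_from(np.ones((4, 8, 8), bool)))
        assert np.array_equal(out.data, target.data)

    def test_sum_matches_bruteforce_over_mask(self, rng):
        data = rng.random((5, 10, 10))
        mask = rng.random((5, 10, 10)) > 0.5
        target = VoxelVolume(data, SPACING)
        out = mask_internal_channel(target, surface_from(mask))
        brute = sum(
            data[z, y, x]
            for z in range(5)
            for y in range(10)
            for x in range(10)
            if mask[z, y, x]
        )
        assert out.data.sum() == pytest.approx(brute, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        target = VoxelVolume(rng.random((4, 8, 8)), SPACING)
        with pytest.raises(Engulf3dError, match="shape"):
            mask_internal_channel(target, surface_from(np.ones((4, 9, 8), bool)))


class TestInternalizedObjects:
    def test_noiseless_inside_puncta_counted_exactly(self):
        spec = SceneSpec(
            rng_seed=9, puncta_counts={"inside": 5, "contacting": 0, "outside": 7}
        ).without_noise()
        channels, truth = generate_scene(spec)
        roles = {c.channel_role: c for c in channels}
        surface = reconstruct_cell(roles["cell"], soma_seed_um=truth.soma_center_um)
        masked = mask_internal_channel(roles["presyn"], surface)
        objects = internalized_objects(masked)
        assert len(objects) == 5
        truth_vol = truth.puncta.query("placement_class == 'inside'").true_volume_um3.sum()
        assert objects.df.volume_um3.sum() == pytest.approx(truth_vol, rel=0.10)

    def test_empty_masked_volume_gives_empty_set_and_zero_index(self):
        masked = VoxelVolume(np.zeros((4, 8, 8)), SPACING)
        objects = internalized_objects(masked)
        assert objects.empty
        surface = surface_from(np.ones((4, 8, 8), bool))
        result = engulfment_index(surface, objects)
        assert result.engulfment_index == 0.0

    def test_single_background_voxel_separates_objects(self):
        data = np.zeros((3, 3, 9))
        data[1, 1, 1:3] = 10.0
        data[1, 1, 4:6] = 10.0  # gap at x=3
        objects = internalized_objects(VoxelVolume(data, SPACING), threshold=5.0)
        assert len(objects) == 2

    def test_min_voxel_floor_drops_single_voxel_noise(self):
        data = np.zeros((3, 8, 8))
        data[1, 2, 2] = 10.0
        data[1, 5, 5:7] = 10.0
        objects = internalized_objects(VoxelVolume(data, SPACING), threshold=5.0)
        assert len(objects) == 1
        assert objects.df.voxel_count.iloc[0] == 2


class TestEngulfmentIndex:
    def test_zero_cell_volume_rejected(self):
        surface = surface_from(np.zeros((3, 4, 4), bool))
        with pytest.raises(Engulf3dError, match="volume"):
            engulfment_index(surface, internalized_objects(VoxelVolume(np.zeros((3, 4, 4)), SPACING)))

    def test_dilated_objects_strictly_increase_index(self):
        mask = np.ones((6, 12, 12), bool)
        surface = surface_from(mask)
        data = np.zeros((6, 12, 12))
        data[2:4, 4:6, 4:6] = 10.0
        small = internalized_objects(VoxelVolume(data, SPACING), threshold=5.0)
        dilated = np.zeros_like(data)
        dilated[1:5, 3:7, 3:7] = 10.0
        big = internalized_objects(VoxelVolume(dilated, SPACING), threshold=5.0)
        r_small = engulfment_index(surface, small)
        r_big = engulfment_index(surface, big)
        assert r_big.engulfment_index > r_small.engulfment_index

    def test_index_invariant_under_intensity_rescaling(self, clean_scene, clean_surface):
        channels, _ = clean_scene
        r1 = quantify_engulfment(clean_surface, channels["presyn"])
        scaled = channels["presyn"].with_data(channels["presyn"].data * 3.7)
        r2 = quantify_engulfment(clean_surface, scaled)
        assert r1.engulfment_index == pytest.approx(r2.engulfment_index, rel=1e-12)

    def test_oracle_equivalence_noiseless(self, clean_scene, clean_surface):
        """Index equals independent BFS voxel counting, exactly."""
        channels, _ = clean_scene
        result = quantify_engulfment(clean_surface, channels["presyn"])
        masked = np.where(clean_surface.mask.data, channels["presyn"].data, 0.0)
        sizes = bfs_component_sizes(masked > 0, min_voxels=2)
        voxvol = float(np.prod(SPACING))
        assert result.internalized_volume_um3 == pytest.approx(
            sum(sizes) * voxvol, rel=1e-12
        )
        assert result.n_objects == len(sizes)


class TestDetectSpots:
    def test_clean_flat_spheres_recovered_exactly(self, clean_scene):
        channels, truth = clean_scene
        spots = detect_spots(channels["presyn"])
        assert len(spots) == len(truth.puncta)
        got = sorted(spots.df.voxel_count.tolist())
        want = sorted(truth.puncta.voxel_count.tolist())
        assert got == want

    def test_empty_input(self):
        assert detect_spots(VoxelVolume(np.zeros((3, 4, 4)), SPACING)).empty


class TestEngulfmentLoci:
    def _objects(self, positions_um, volumes=None):
        n = len(positions_um)
        volumes = volumes or [0.1] * n
        df = pd.DataFrame(
            {
                "id": range(1, n + 1),
                "z_um": [p[0] for p in positions_um],
                "y_um": [p[1] for p in positions_um],
                "x_um": [p[2] for p in positions_um],
                "voxel_count": [19] * n,
                "volume_um3": volumes,
                "sum_intensity": [100.0] * n,
                "mean_intensity": [5.0] * n,
            }
        )
        from engulf3d.core import PunctumSet

        return PunctumSet(df=df, spacing=SPACING)

    def test_close_puncta_merge_into_one_locus(self):
        surface = surface_from(np.ones((4, 8, 8), bool))
        loci, bbox = engulfment_loci(
            self._objects([(1, 1, 1), (1, 1, 1.5)]), surface, spot_diameter_um=2.0
        )
        assert len(loci) == 1
        assert bbox is None
        assert loci.df.n_members.iloc[0] == 2

    def test_distant_puncta_stay_separate_with_bbox(self):
        surface = surface_from(np.ones((4, 50, 8), bool), soma=(1.0, 1.0, 1.0))
        loci, bbox = engulfment_loci(
            self._objects([(1, 1, 1), (1, 6, 1)]), surface, spot_diameter_um=2.0
        )
        assert len(loci) == 2
        assert bbox == pytest.approx((0.0, 5.0, 0.0))
        d = sorted(loci.df.distance_to_soma_um)
        assert d[0] == pytest.approx(0.0, abs=1e-9)
        assert d[1] == pytest.approx(5.0, abs=1e-9)

    def test_empty_objects_give_empty_loci(self):
        from engulf3d.core import PunctumSet

        surface = surface_from(np.ones((4, 8, 8), bool))
        loci, bbox = engulfment_loci(PunctumSet.empty_set(SPACING), surface)
        assert loci.empty and bbox is None

    def test_locus_position_is_volume_weighted(self):
        surface = surface_from(np.ones((4, 8, 8), bool))
        loci, _ = engulfment_loci(
            self._objects([(1, 1, 1), (1, 1, 2)], volumes=[0.3, 0.1]),
            surface,
            spot_diameter_um=3.0,
        )
        assert loci.df.x_um.iloc[0] == pytest.approx((0.3 * 1 + 0.1 * 2) / 0.4)


class TestRecoverySlope:
    def test_recovered_vs_true_index_slope_near_unity(self):
        """Across simulated cells at default SNR the regression of recovered
        on true engulfment index has slope close to 1."""
        true_idx, rec_idx = [], []
        for i in range(10):
            spec = SceneSpec(
                rng_seed=300 + i,
                puncta_counts={"inside": (3 * i) % 13, "contacting": 4, "outside": 6},
            )
            channels, truth = generate_scene(spec)
            roles = {c.channel_role: c for c in channels}
            surface = reconstruct_cell(roles["cell"], soma_seed_um=truth.soma_center_um)
            res = quantify_engulfment(surface, roles["presyn"])
            t = (
                truth.puncta.query("placement_class == 'inside'").true_volume_um3.sum()
                / truth.cell_mask.volume_um3
            )
            true_idx.append(t)
            rec_idx.append(res.engulfment_index)
        slope = np.polyfit(true_idx, rec_idx, 1)[0]
        assert 0.85 <= slope <= 1.15
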