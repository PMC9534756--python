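"""Generator contracts: determinism, truth consistency, bleaching, FISH."""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import bfs_component_sizes
from engulf3d.synthetic import (
    SceneError,
    SceneSpec,
    generate_fish_field,
    generate_scene,
    generate_timelapse,
)


class TestSceneConstruction:
    def test_seed_determinism_bit_identical(self):
        spec = SceneSpec(rng_seed=42)
        a, _ = generate_scene(spec)
        b, _ = generate_scene(spec)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.data, cb.data)

    def test_truth_counts_match_spec(self, clean_scene):
        _, truth = clean_scene
        spec_counts = SceneSpec().puncta_counts
        assert truth.counts_by_class() == spec_counts

    def test_placement_classes_consistent_with_signed_distance(self, clean_scene):
        _, truth = clean_scene
        df = truth.puncta
        inside = df[df.placement_class == "inside"].true_signed_distance_um
        contacting = df[df.placement_class == "contacting"].true_signed_distance_um
        outside = df[df.placement_class == "outside"].true_signed_distance_um
        assert (inside < 0).all()
        max_half_voxel = max(SceneSpec().spacing) / 2
        assert (contacting.abs() <= max_half_voxel).all()
        assert (outside > 0).all()

    def test_requested_class_counts_only(self):
        spec = SceneSpec(
            rng_seed=5, puncta_counts={"inside": 5, "contacting": 0, "outside": 10}
        ).without_noise()
        _, truth = generate_scene(spec)
        df = truth.puncta
        assert (df.placement_class == "inside").sum() == 5
        assert (df[df.placement_class == "inside"].true_signed_distance_um < 0).all()
        assert (df.placement_class == "contacting").sum() == 0

    def test_true_volume_equals_blob_voxel_count(self, clean_scene):
        _, truth = clean_scene
        voxvol = float(np.prod(truth.cell_mask.spacing))
        for _, row in truth.puncta.iterrows():
            blob = truth.punctum_labels == row.id
            assert row.voxel_count == blob.sum()
            assert row.true_volume_um3 == pytest.approx(blob.sum() * voxvol, abs=1e-12)

    def test_quench_one_makes_reporters_identical(self):
        spec = SceneSpec(rng_seed=2, make_reporter=True, quench_factor=1.0).without_noise()
        channels, _ = generate_scene(spec)
        roles = {c.channel_role: c for c in channels}
        assert np.array_equal(roles["reporter_green"].data, roles["reporter_red"].data)

    def test_quench_linearity_inside_lysosomes(self):
        for q in (0.1, 0.5):
            spec = SceneSpec(rng_seed=3, make_reporter=True, quench_factor=q).without_noise()
            channels, truth = generate_scene(spec)
            roles = {c.channel_role: c for c in channels}
            lyso = truth.lysosome_mask.data
            g = roles["reporter_green"].data[lyso].mean()
            r = roles["reporter_red"].data[lyso].mean()
            assert g / r == pytest.approx(q, abs=1e-6)

    def test_impossible_placement_names_class(self):
        spec = SceneSpec(
            rng_seed=0,
            shape=(16, 48, 48),
            soma_radii_um=(2.0, 2.5, 2.5),
            puncta_counts={"inside": 200, "contacting": 0, "outside": 0},
        )
        with pytest.raises(SceneError, match="inside"):
            generate_scene(spec)


class TestTimelapse:
    def test_no_bleach_no_noise_frames_identical(self):
        spec = SceneSpec(rng_seed=1, n_frames=3, n_lysosomes=0).without_noise(blur=True)
        tl, _ = generate_timelapse(spec)
        f = tl["presyn"].frames
        assert np.array_equal(f[0].data, f[1].data)
        assert np.array_equal(f[0].data, f[2].data)

    def test_bleaching_matches_closed_form(self):
        spec = SceneSpec(
            rng_seed=1, n_frames=30, bleach_rate_per_frame=0.05, n_lysosomes=0
        ).without_noise(blur=True)
        tl, _ = generate_timelapse(spec)
        f = tl["presyn"].frames
        ratio = f[29].data.sum() / f[0].data.sum()
        assert ratio == pytest.approx(np.exp(-0.05 * 29), rel=1e-6)

    def test_scripted_disappearance_removes_punctum(self):
        spec = SceneSpec(
            rng_seed=4, n_frames=12, n_lysosomes=0, disappearances=[(1, 10)]
        ).without_noise(blur=True)
        tl, truth = generate_timelapse(spec)
        blob = truth.punctum_labels == 1
        assert blob.any()
        before = tl["presyn"].frames[9].data[blob].sum()
        after = tl["presyn"].frames[10].data[blob].sum()
        assert before > 0
        assert after == pytest.approx(0.0, abs=1e-9)
        assert (1, 10) in truth.disappearances

    def test_requires_two_frames(self):
        with pytest.raises(SceneError):
            generate_timelapse(SceneSpec(n_frames=1))

    def test_unknown_disappearance_id_rejected(self):
        spec = SceneSpec(rng_seed=4, n_frames=3, disappearances=[(999, 1)])
        with pytest.raises(SceneError, match="999"):
            generate_timelapse(spec)


class TestFishField:
    def test_truth_counts_by_construction(self):
        _, truth = generate_fish_field(
            2, {"A": [6, 3]}, gaussian_noise_sd=0.0, apply_blur=False, rng_seed=1
        )
        counts = truth.counts.set_index("nucleus_id")["count"]
        assert sorted(counts.tolist()) == [3, 6]

    def test_touching_nuclei_still_two_in_truth(self):
        ch, truth = generate_fish_field(
            2,
            {"A": [4, 7]},
            nucleus_centers_um=[[3.0, 8.0, 7.0], [3.0, 8.0, 11.2]],
            gaussian_noise_sd=0.0,
            apply_blur=False,
            rng_seed=5,
        )
        assert len(np.unique(truth.nucleus_labels)) == 3  # background + 2 nuclei
        # the nuclei actually touch: one connected foreground blob
        assert len(bfs_component_sizes(ch["nuclei"].data > 0)) == 1

    def test_total_molecules_equal_probe_components(self):
        ch, truth = generate_fish_field(
            3, {"A": [6, 3, 5]}, gaussian_noise_sd=0.0, apply_blur=False, rng_seed=2
        )
        n_components = len(bfs_component_sizes(ch["A"].data > 0))
        assert n_components == truth.counts["count"].sum() == 14

    def test_per_gene_count_length_checked(self):
        with pytest.raises(SceneError, match="counts"):
            generate_fish_field(3, {"A": [1, 2]})
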