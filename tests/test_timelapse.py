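"""Input classification against the cell surface and bleaching normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from engulf3d.core import Engulf3dError, PunctumSet
from engulf3d.engulfment import detect_objects
from engulf3d.reconstruct import reconstruct_cell
from engulf3d.synthetic import SceneSpec, generate_scene, generate_timelapse
from engulf3d.timelapse import (
    classify_inputs,
    classify_label,
    classify_timelapse,
    contact_census,
    normalize_timecourse,
)

SPACING = (0.3, 0.132, 0.132)


def punctum_frame(volumes_by_class):
    """Build a classified PunctumSet directly from (class → volumes)."""
    rows = []
    i = 0
    for cls, vols in volumes_by_class.items():
        for v in vols:
            i += 1
            rows.append(
                {
                    "id": i,
                    "z_um": 0.0,
                    "y_um": 0.0,
                    "x_um": 0.0,
                    "voxel_count": 10,
                    "volume_um3": v,
                    "sum_intensity": 1.0,
                    "mean_intensity": 0.1,
                    "signed_distance_um": np.nan,
                    "class_label": cls,
                }
            )
    return PunctumSet(df=pd.DataFrame(rows), spacing=SPACING)


class TestClassifyLabel:
    @pytest.mark.parametrize(
        "distance,expected",
        [
            (1.3, "noncontacting"),
            (1e-9, "noncontacting"),
            (0.0, "contacting"),
            (-0.1, "contacting"),
            (-0.270, "contacting"),
            (-0.271, "engulfed"),
            (-0.30, "engulfed"),
        ],
    )
    def test_three_way_partition(self, distance, expected):
        assert classify_label(distance, 0.270) == expected

    def test_threshold_monotone_in_engulfed_distance(self):
        distances = np.linspace(-1.0, 0.0, 50)
        for small, large in [(0.1, 0.27), (0.27, 0.5)]:
            n_small = sum(classify_label(d, small) == "engulfed" for d in distances)
            n_large = sum(classify_label(d, large) == "engulfed" for d in distances)
            assert n_large <= n_small


class TestClassifyInputs:
    def test_noiseless_scene_matches_truth_classes(self, clean_scene, clean_surface):
        channels, truth = clean_scene
        puncta = detect_objects(channels["presyn"])
        classified = classify_inputs(puncta, clean_surface)
        mapping = {"inside": "engulfed", "contacting": "contacting", "outside": "noncontacting"}
        tc = truth.puncta[["z_um", "y_um", "x_um"]].to_numpy(float)
        for _, row in classified.df.iterrows():
            j = int(
                np.argmin(
                    np.linalg.norm(tc - np.array([row.z_um, row.y_um, row.x_um]), axis=1)
                )
            )
            assert mapping[truth.puncta.placement_class.iloc[j]] == row.class_label

    def test_classes_invariant_under_intensity_scaling(self, clean_scene, clean_surface):
        channels, _ = clean_scene
        p1 = detect_objects(channels["presyn"])
        p2 = detect_objects(channels["presyn"].with_data(channels["presyn"].data * 11.0))
        c1 = classify_inputs(p1, clean_surface)
        c2 = classify_inputs(p2, clean_surface)
        assert c1.df.class_label.tolist() == c2.df.class_label.tolist()

    def test_requires_label_image(self, clean_surface):
        ps = punctum_frame({"noncontacting": [0.1]})
        with pytest.raises(Engulf3dError, match="label image"):
            classify_inputs(ps, clean_surface)


class TestNormalizeTimecourse:
    def test_single_frame_noncontacting_self_normalizes_to_one(self):
        ci = normalize_timecourse([punctum_frame({"noncontacting": [0.2, 0.4]})])
        assert ci.trace("noncontacting").iloc[0] == pytest.approx(1.0)

    def test_no_noncontacting_anywhere_rejected(self):
        with pytest.raises(Engulf3dError, match="noncontacting"):
            normalize_timecourse([punctum_frame({"engulfed": [0.1]})])

    def test_engulfed_at_half_volume_normalizes_to_half(self):
        frames = [
            punctum_frame({"noncontacting": [0.2, 0.2], "engulfed": [0.1, 0.1]})
            for _ in range(5)
        ]
        ci = normalize_timecourse(frames)
        assert np.allclose(ci.trace("engulfed"), 0.5)

    def test_per_frame_mode_cancels_common_decay(self):
        frames = []
        for t in range(10):
            decay = np.exp(-0.05 * t)
            frames.append(
                punctum_frame(
                    {"noncontacting": [0.2 * decay], "engulfed": [0.1 * decay]}
                )
            )
        ci = normalize_timecourse(frames, mode="per_frame")
        assert np.allclose(ci.trace("noncontacting"), 1.0)
        assert np.allclose(ci.trace("engulfed"), 0.5)

    def test_pooled_mode_preserves_decay(self):
        frames = []
        for t in range(10):
            decay = np.exp(-0.1 * t)
            frames.append(punctum_frame({"noncontacting": [0.2 * decay]}))
        ci = normalize_timecourse(frames, mode="pooled")
        trace = ci.trace("noncontacting").to_numpy()
        assert trace[0] > trace[-1]
        grand_mean_ratio = np.mean([0.2 * np.exp(-0.1 * t) for t in range(10)]) / 0.2
        assert trace[0] == pytest.approx(1.0 / grand_mean_ratio, rel=1e-9)


class TestSimulatedBleaching:
    def test_raw_decays_normalized_flat(self):
        spec = SceneSpec(
            rng_seed=8,
            n_frames=15,
            bleach_rate_per_frame=0.05,
            n_lysosomes=0,
            puncta_counts={"inside": 4, "contacting": 4, "outside": 8},
        )
        tl, truth = generate_timelapse(spec)
        surface = reconstruct_cell(tl["cell"].frames[0], soma_seed_um=truth.soma_center_um)
        classified = classify_timelapse(tl["presyn"], surface)
        ci = normalize_timecourse(classified)
        raw = ci.trace("noncontacting", normalized=False).dropna()
        norm = ci.trace("noncontacting", normalized=True).dropna()
        assert raw.iloc[-3:].mean() < 0.8 * raw.iloc[:3].mean()
        assert np.allclose(norm, 1.0)


class TestContactCensus:
    def test_empty(self):
        census = contact_census(PunctumSet.empty_set(SPACING))
        assert census == {
            "n_contacting_or_engulfed": 0,
            "n_engulfed": 0,
            "any_internal": False,
        }

    def test_counts_from_truth_scene(self, clean_scene, clean_surface):
        channels, truth = clean_scene
        classified = classify_inputs(detect_objects(channels["presyn"]), clean_surface)
        census = contact_census(classified)
        want = truth.counts_by_class()
        assert census["n_engulfed"] == want["inside"]
        assert census["n_contacting_or_engulfed"] == want["inside"] + want["contacting"]
        assert census["any_internal"] is True

    def test_cohort_internal_material_rate(self):
        """A cohort in which 9 of 10 cells carry internal puncta yields a 90%
        contains-material rate."""
        flags = []
        for seed in range(10):
            n_inside = 0 if seed == 0 else 2
            spec = SceneSpec(
                rng_seed=700 + seed,
                puncta_counts={"inside": n_inside, "contacting": 3, "outside": 5},
            ).without_noise()
            channels, truth = generate_scene(spec)
            roles = {c.channel_role: c for c in channels}
            surface = reconstruct_cell(roles["cell"], soma_seed_um=truth.soma_center_um)
            classified = classify_inputs(detect_objects(roles["presyn"]), surface)
            flags.append(contact_census(classified)["any_internal"])
        assert sum(flags) == 9
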