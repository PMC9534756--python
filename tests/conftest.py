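"""Shared fixtures: cached synthetic scenes and channel lookups."""

from __future__ import annotations

import numpy as np
import pytest

from engulf3d.reconstruct import reconstruct_cell
from engulf3d.synthetic import SceneSpec, generate_scene


def by_role(channels):
    return {c.channel_role: c for c in channels}


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, unblurred default scene: (channels-by-role, truth)."""
    spec = SceneSpec(rng_seed=0).without_noise(blur=False)
    channels, truth = generate_scene(spec)
    return by_role(channels), truth


@pytest.fixture(scope="session")
def clean_surface(clean_scene):
    channels, truth = clean_scene
    return reconstruct_cell(channels["cell"], soma_seed_um=truth.soma_center_um)


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-SNR scene (PSF blur + Poisson + Gaussian noise)."""
    spec = SceneSpec(rng_seed=1)
    channels, truth = generate_scene(spec)
    return by_role(channels), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


#: truth placement class → expected pipeline classification label
PLACEMENT_TO_CLASS = {
    "inside": "engulfed",
    "contacting": "contacting",
    "outside": "noncontacting",
}


def match_to_truth(detected_centroids, truth_df):
    """Index of the nearest truth punctum for each detected centroid."""
    tc = truth_df[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    out = []
    for c in detected_centroids:
        out.append(int(np.argmin(np.linalg.norm(tc - c, axis=1))))
    return out
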