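"""Intact-synapse detection by pre/post colocalization, and voxelwise Pearson.

An intact synapse is a voxel region where the presynaptic and postsynaptic
channels *both* exceed their channel-mean thresholds. Objects segmented from
that colocalization channel are scored against a reconstructed cell surface:
a synapse counts as internalized when its centroid lies more than the
interiority threshold (default 0.132 µm, i.e. more than one lateral pixel)
inside the surface — strictly less than −0.132 µm in the signed distance
convention, so a centroid at exactly −0.132 µm is *not* internalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import BinaryMask, Engulf3dError, VoxelVolume
from .engulfment import detect_objects
from .reconstruct import CellSurface


@dataclass
class ColocChannel:
    """Colocalization channel: min(pre, post) where both exceed their means."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    thresholds_used: tuple[float, float]  # (mean_pre, mean_post)

    def as_volume(self) -> VoxelVolume:
        return VoxelVolume(data=self.data, spacing=self.spacing)


@dataclass
class IntactSynapseReport:
    """Counts of intact synapses and the fraction internalized by the cell."""

    n_total_synapses: int
    n_internalized: int
    percent_internalized: Optional[float]

    def to_record(self) -> dict:
        return {
            "n_total_synapses": self.n_total_synapses,
            "n_internalized": self.n_internalized,
            "percent_internalized": (
                np.nan if self.percent_internalized is None else self.percent_internalized
            ),
        }


def coloc_channel(pre: VoxelVolume, post: VoxelVolume) -> ColocChannel:
    """Build the colocalization channel from pre- and postsynaptic markers.

    The mean intensity of each parent channel (over the whole crop) is its
    threshold; voxels where both parents exceed their means carry
    ``min(pre, post)``, all others are zero. Only the support — not the
    voxel value — affects downstream synapse counts.
    """
    if pre.shape != post.shape:
        raise Engulf3dError(f"shape mismatch: pre {pre.shape} vs post {post.shape}")
    if pre.spacing != post.spacing:
        raise Engulf3dError("pre and post channels must share voxel spacing")
    mean_pre = float(pre.data.mean())
    mean_post = float(post.data.mean())
    support = (pre.data > mean_pre) & (post.data > mean_post)
    data = np.where(support, np.minimum(pre.data, post.data), 0.0)
    return ColocChannel(data=data, spacing=pre.spacing, thresholds_used=(mean_pre, mean_post))


def is_internalized(signed_distance_um: float, interiority_threshold_um: float = 0.132) -> bool:
    """True when a point lies strictly more than the threshold inside the cell.

    ``signed_distance_um`` is negative inside; −0.132 µm at the default
    threshold is *not* internalized, −0.133 µm is.
    """
    return signed_distance_um < -interiority_threshold_um


def intact_synapses(
    coloc: ColocChannel,
    surface: CellSurface,
    interiority_threshold_um: float = 0.132,
    min_voxels: int = 1,
) -> IntactSynapseReport:
    """Count intact synapses and those internalized by the cell.

    Coloc objects are reduced to centroids; a synapse is internalized when
    the signed distance at its centroid is strictly below
    ``−interiority_threshold_um``. With zero total synapses the percentage
    is undefined and reported as missing.
    """
    if coloc.data.shape != surface.mask.shape:
        raise Engulf3dError("coloc channel and surface shapes differ")
    objects = detect_objects(coloc.as_volume(), threshold=0.0, min_voxels=min_voxels)
    n_total = len(objects)
    if n_total == 0:
        return IntactSynapseReport(0, 0, None)
    sdf = surface.signed_distance_um
    spacing = np.asarray(coloc.spacing)
    shape = np.asarray(coloc.data.shape)
    n_internal = 0
    for _, row in objects.df.iterrows():
        vox = np.clip(
            np.round(np.array([row.z_um, row.y_um, row.x_um]) / spacing).astype(int),
            0,
            shape - 1,
        )
        if is_internalized(float(sdf[tuple(vox)]), interiority_threshold_um):
            n_internal += 1
    return IntactSynapseReport(
        n_total_synapses=n_total,
        n_internalized=n_internal,
        percent_internalized=100.0 * n_internal / n_total,
    )


def pearson_voxel_correlation(
    a: VoxelVolume,
    b: VoxelVolume,
    roi: Optional[BinaryMask] = None,
) -> float:
    """Pearson correlation of two channels over all (or ROI) voxels.

    Returns NaN when either channel has zero variance within the ROI (the
    coefficient is undefined there, e.g. for constant images).
    """
    if a.shape != b.shape:
        raise Engulf3dError("channels must share shape")
    if roi is not None:
        if roi.shape != a.shape:
            raise Engulf3dError("roi shape must match channels")
        if roi.voxel_count == 0:
            raise Engulf3dError("roi is empty")
        x = a.data[roi.data].astype(np.float64)
        y = b.data[roi.data].astype(np.float64)
    else:
        x = a.data.ravel().astype(np.float64)
        y = b.data.ravel().astype(np.float64)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mean_pearson(pairs: list[tuple[VoxelVolume, VoxelVolume]]) -> float:
    """Mean Pearson coefficient across images (NaN-propagating)."""
    if not pairs:
        raise Engulf3dError("mean_pearson requires at least one image pair")
    return float(np.mean([pearson_voxel_correlation(a, b) for a, b in pairs]))
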