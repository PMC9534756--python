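"""Single-cell reconstruction and signed distance fields.

The interactive surface-creation workflow used on engulfment stacks is
replaced by a deterministic rule: threshold the (preprocessed) cell-marker
channel, label 26-connected components, and keep only the component that can
be traced back to the soma seed. Discarding detached blobs automates the
manual pruning of fragments that cannot be traced to the soma.

The signed distance field follows the convention: positive outside the cell,
zero on boundary voxels (mask voxels with an outside 6-neighbor), negative in
the interior. Distances are Euclidean and anisotropic (computed with the
physical voxel spacing), because the axial step is typically much larger than
the lateral pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import BinaryMask, Engulf3dError, VoxelVolume
from .preprocess import gaussian_blur

#: 26-connectivity structuring element for component labeling.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
#: 6-connectivity structuring element (faces only), used for boundary voxels.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class ReconstructionError(Engulf3dError):
    """Raised when no cell can be reconstructed from the input."""


def signed_distance(mask: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Anisotropic signed Euclidean distance to the mask boundary, in µm.

    Boundary voxels — mask voxels with at least one outside 6-neighbor — are
    at distance exactly 0; interior voxels are negative and outside voxels
    positive, each measured to the nearest boundary voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise Engulf3dError("signed_distance of an empty mask is undefined")
    interior = ndimage.binary_erosion(mask, structure=STRUCT_6, border_value=0)
    boundary = mask & ~interior
    # Distance of every voxel to the nearest boundary voxel.
    dist = ndimage.distance_transform_edt(~boundary, sampling=spacing)
    out = np.where(mask, -dist, dist)
    return out


@dataclass
class CellSurface:
    """A reconstructed cell: binary mask, soma seed, and derived geometry."""

    mask: BinaryMask
    soma_center_um: tuple[float, float, float]
    threshold_used: Optional[float] = None
    _sdf: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.mask.spacing

    @property
    def volume_um3(self) -> float:
        return self.mask.volume_um3

    @property
    def signed_distance_um(self) -> np.ndarray:
        """Cached signed distance field of the mask, in µm."""
        if self._sdf is None:
            self._sdf = signed_distance(self.mask.data, self.mask.spacing)
        return self._sdf


def _intensity_centroid_um(
    data: np.ndarray, mask: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[float, float, float]:
    idx = np.nonzero(mask)
    w = data[idx].astype(float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    return tuple(float((idx[a] * w).sum() / w.sum() * spacing[a]) for a in range(3))


def default_soma_seed(vol: VoxelVolume, smooth_sigma_um: float = 2.0) -> tuple[float, float, float]:
    """Soma seed: intensity centroid of the largest blob after heavy smoothing.

    Smoothing at sigma 2 µm erases thin processes and puncta so the largest
    surviving blob is the soma.
    """
    smoothed = gaussian_blur(vol, smooth_sigma_um).data
    thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any():
        raise ReconstructionError("no foreground found while seeking a soma seed")
    labels, n = ndimage.label(fg, structure=STRUCT_26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    return _intensity_centroid_um(smoothed, labels == largest, vol.spacing)


def reconstruct_cell(
    vol: VoxelVolume,
    threshold: Optional[float] = None,
    soma_seed_um: Optional[tuple[float, float, float]] = None,
    max_seed_distance_um: float = 10.0,
) -> CellSurface:
    """Reconstruct a single cell from its (preprocessed) marker channel.

    Voxels above ``threshold`` (default: Otsu) are binarized and labeled with
    26-connectivity; only the component containing — or nearest to, within
    ``max_seed_distance_um`` — the soma seed is kept. Every other component
    is discarded, automating the rule that fragments not traceable to the
    soma are not part of the cell.
    """
    data = vol.data
    thr = float(threshold) if threshold is not None else float(threshold_otsu(data))
    fg = data > thr
    if not fg.any():
        raise ReconstructionError(
            f"threshold {thr:.6g} leaves no foreground (image max {data.max():.6g})"
        )
    labels, n = ndimage.label(fg, structure=STRUCT_26)

    if soma_seed_um is None:
        soma_seed_um = default_soma_seed(vol)
    seed_vox = tuple(
        int(np.clip(round(soma_seed_um[a] / vol.spacing[a]), 0, data.shape[a] - 1))
        for a in range(3)
    )
    picked = labels[seed_vox]
    if picked == 0:
        # Seed fell in background: take the nearest foreground voxel.
        dist, (iz, iy, ix) = ndimage.distance_transform_edt(
            labels == 0, sampling=vol.spacing, return_indices=True
        )
        d = float(dist[seed_vox])
        if d > max_seed_distance_um:
            raise ReconstructionError(
                f"soma seed is {d:.2f} µm from the nearest foreground "
                f"(limit {max_seed_distance_um} µm)"
            )
        picked = labels[iz[seed_vox], iy[seed_vox], ix[seed_vox]]

    mask = labels == picked
    return CellSurface(
        mask=BinaryMask(mask, vol.spacing),
        soma_center_um=tuple(float(c) for c in soma_seed_um),
        threshold_used=thr,
    )
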