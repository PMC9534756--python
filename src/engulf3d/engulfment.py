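"""The engulfment assay: internalized volume, index, and spatial loci.

The assay masks a target channel (e.g. a presynaptic marker) with a
reconstructed cell surface, segments the signal retained inside the cell
into discrete objects, and reports the engulfment index — internalized
volume divided by cell volume, a dimensionless per-cell measure of how much
synaptic material the cell has taken up. Internalized objects are then
grouped into engulfment "loci" (clusters within a 2 µm diameter), whose
distances to the soma and axis-aligned bounding box describe the spatial
distribution of engulfment across the cell's arbor.

Lysosome-content quantification is the same pipeline with the lysosome mask
substituted for the cell mask; the ROI is a parameter, not a separate code
path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu

from .core import Engulf3dError, PunctumSet, VoxelVolume
from .reconstruct import STRUCT_26, CellSurface


def mask_internal_channel(target: VoxelVolume, surface: CellSurface) -> VoxelVolume:
    """Retain target intensities inside the cell mask, zero elsewhere."""
    if target.shape != surface.mask.shape:
        raise Engulf3dError(
            f"target shape {target.shape} does not match surface {surface.mask.shape}"
        )
    return target.with_data(np.where(surface.mask.data, target.data, 0.0))


def detect_objects(
    vol: VoxelVolume,
    threshold: Optional[float] = None,
    min_voxels: int = 2,
) -> PunctumSet:
    """Threshold → 26-connected components → object table.

    The default threshold is Otsu computed over the *nonzero* voxels, which
    makes detection insensitive to how much empty (masked-away) background
    surrounds the signal. Components below ``min_voxels`` are dropped to
    suppress single-voxel noise. An input with no nonzero voxels yields an
    empty set, not an error.
    """
    data = vol.data
    nz = data[data > 0]
    if nz.size == 0:
        return PunctumSet.empty_set(vol.spacing)
    if threshold is None:
        threshold = float(threshold_otsu(nz)) if np.unique(nz).size > 1 else 0.0
    fg = data > threshold
    if not fg.any():
        return PunctumSet.empty_set(vol.spacing)
    labels, n = ndimage.label(fg, structure=STRUCT_26)
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
    keep = counts >= min_voxels
    if not keep.any():
        return PunctumSet.empty_set(vol.spacing)
    # Relabel surviving components 1..K in scan order for determinism.
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[idx[keep]] = np.arange(1, keep.sum() + 1)
    labels = remap[labels]
    k = int(keep.sum())
    idx = np.arange(1, k + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
    sums = ndimage.sum_labels(data, labels, index=idx)
    # Intensity-weighted centroid of voxel centers, in physical µm.
    com = ndimage.center_of_mass(data, labels, index=idx)
    com = np.asarray(com, dtype=float) * np.asarray(vol.spacing)
    voxel_volume = float(np.prod(vol.spacing))
    df = pd.DataFrame(
        {
            "id": idx,
            "z_um": com[:, 0],
            "y_um": com[:, 1],
            "x_um": com[:, 2],
            "voxel_count": counts.astype(int),
            "volume_um3": counts * voxel_volume,
            "sum_intensity": sums,
            "mean_intensity": sums / counts,
            "signed_distance_um": np.nan,
            "class_label": pd.Series([None] * k, dtype=object),
        }
    )
    return PunctumSet(df=df, spacing=vol.spacing, labels=labels)


def internalized_objects(
    masked: VoxelVolume,
    threshold: Optional[float] = None,
    min_voxels: int = 2,
) -> PunctumSet:
    """Segment the signal retained inside the cell into discrete objects."""
    return detect_objects(masked, threshold=threshold, min_voxels=min_voxels)


def robust_background_threshold(data: np.ndarray, k: float = 5.0) -> float:
    """Background-statistics threshold: median + k × MAD-σ of nonzero voxels.

    Puncta occupy a vanishing fraction of a masked channel, so the median
    and MAD of the nonzero voxels estimate the background level and spread
    essentially uncontaminated by signal. When the MAD is zero (e.g. clean
    synthetic data whose only nonzero voxels are signal) half the median is
    returned, which separates flat objects from empty background exactly.
    """
    nz = data[data > 0]
    if nz.size == 0:
        return 0.0
    med = float(np.median(nz))
    sd = 1.4826 * float(np.median(np.abs(nz - med)))
    if sd == 0:
        return med / 2.0
    return med + k * sd


def detect_spots(
    vol: VoxelVolume,
    seed_k: float = 5.0,
    peak_fraction: float = 0.5,
    min_voxels: int = 2,
) -> PunctumSet:
    """Detect puncta with per-object half-peak (FWHM) volume estimation.

    Seeds are voxels above the robust background threshold; each seed
    component is then grown to the contour at ``peak_fraction`` × its peak
    intensity. For a uniform-density object imaged through a symmetric PSF
    the half-peak contour sits at the true object boundary, so the measured
    volume is an (approximately) unbiased estimate of the physical punctum
    volume, independent of the absolute intensity scale — which plain
    fixed-threshold segmentation of blurred spots is not.
    """
    data = vol.data
    seed_thr = robust_background_threshold(data, k=seed_k)
    seeds = data > seed_thr
    if not seeds.any():
        return PunctumSet.empty_set(vol.spacing)
    seed_labels, n = ndimage.label(seeds, structure=STRUCT_26)
    boxes = ndimage.find_objects(seed_labels)
    out_labels = np.zeros(data.shape, dtype=np.int32)
    next_id = 0
    rows = []
    voxel_volume = float(np.prod(vol.spacing))
    spacing = np.asarray(vol.spacing)
    pad = 4
    for k_obj, box in enumerate(boxes, start=1):
        if box is None:
            continue
        sl = tuple(
            slice(max(0, s.start - pad), min(dim, s.stop + pad))
            for s, dim in zip(box, data.shape)
        )
        local = data[sl]
        obj = seed_labels[sl] == k_obj
        if obj.sum() < min_voxels:
            continue
        peak = float(local[obj].max())
        region = local >= peak_fraction * peak
        rl, _ = ndimage.label(region, structure=STRUCT_26)
        ids = np.unique(rl[obj])
        grown = np.isin(rl, ids[ids > 0])
        grown &= out_labels[sl] == 0  # first-come assignment on rare overlaps
        count = int(grown.sum())
        if count < min_voxels:
            continue
        next_id += 1
        out_labels[sl][grown] = next_id
        w = local[grown]
        idx = np.nonzero(grown)
        com = np.array(
            [
                ((idx[a] + sl[a].start) * w).sum() / w.sum() * spacing[a]
                for a in range(3)
            ]
        )
        rows.append(
            {
                "id": next_id,
                "z_um": com[0],
                "y_um": com[1],
                "x_um": com[2],
                "voxel_count": count,
                "volume_um3": count * voxel_volume,
                "sum_intensity": float(w.sum()),
                "mean_intensity": float(w.mean()),
                "signed_distance_um": np.nan,
                "class_label": None,
            }
        )
    if not rows:
        return PunctumSet.empty_set(vol.spacing)
    df = pd.DataFrame(rows)
    df["class_label"] = df["class_label"].astype(object)
    return PunctumSet(df=df, spacing=vol.spacing, labels=out_labels)


@dataclass
class EngulfmentResult:
    """Per-cell engulfment record."""

    cell_id: str
    cell_volume_um3: float
    internalized_volume_um3: float
    engulfment_index: float
    n_objects: int
    n_loci: int
    loci: Optional[PunctumSet] = None
    loci_bbox_extent_um: Optional[tuple[float, float, float]] = None
    threshold_used: Optional[float] = None

    def to_record(self) -> dict:
        ext = self.loci_bbox_extent_um
        return {
            "cell_id": self.cell_id,
            "cell_volume_um3": self.cell_volume_um3,
            "internalized_volume_um3": self.internalized_volume_um3,
            "engulfment_index": self.engulfment_index,
            "n_objects": self.n_objects,
            "n_loci": self.n_loci,
            "bbox_extent_z_um": ext[0] if ext else np.nan,
            "bbox_extent_y_um": ext[1] if ext else np.nan,
            "bbox_extent_x_um": ext[2] if ext else np.nan,
            "threshold_used": self.threshold_used,
        }


def engulfment_index(
    surface: CellSurface,
    objects: PunctumSet,
    cell_id: str = "cell",
    threshold_used: Optional[float] = None,
) -> EngulfmentResult:
    """Internalized volume normalized to the cell volume."""
    cell_volume = surface.volume_um3
    if cell_volume <= 0:
        raise Engulf3dError("cell volume is zero; engulfment index undefined")
    internal = float(objects.df["volume_um3"].sum()) if not objects.empty else 0.0
    return EngulfmentResult(
        cell_id=cell_id,
        cell_volume_um3=cell_volume,
        internalized_volume_um3=internal,
        engulfment_index=internal / cell_volume,
        n_objects=len(objects),
        n_loci=0,
        threshold_used=threshold_used,
    )


def engulfment_loci(
    objects: PunctumSet,
    surface: CellSurface,
    spot_diameter_um: float = 2.0,
) -> tuple[PunctumSet, Optional[tuple[float, float, float]]]:
    """Group internalized objects into loci and measure their distribution.

    Objects are merged by single-linkage clustering at ``spot_diameter_um``,
    so each locus captures one *or more* puncta within the grouping diameter.
    Each locus is placed at the volume-weighted centroid of its members and
    annotated with its Euclidean distance to the soma center; the per-axis
    extents of the axis-aligned bounding box over locus positions summarize
    the range of the cell's engulfment activity (reported as missing when
    fewer than two loci exist).
    """
    if spot_diameter_um <= 0:
        raise Engulf3dError("spot_diameter_um must be > 0")
    if objects.empty:
        return PunctumSet.empty_set(objects.spacing), None

    pts = objects.centroids_um()
    vols = objects.df["volume_um3"].to_numpy(dtype=float)
    n = len(pts)
    if n == 1:
        assign = np.array([1])
    else:
        assign = fcluster(
            linkage(pdist(pts), method="single"), t=spot_diameter_um, criterion="distance"
        )
    soma = np.asarray(surface.soma_center_um, dtype=float)
    rows = []
    for locus_id in sorted(np.unique(assign)):
        sel = assign == locus_id
        w = vols[sel]
        pos = (pts[sel] * w[:, None]).sum(axis=0) / w.sum()
        rows.append(
            {
                "id": int(locus_id),
                "z_um": pos[0],
                "y_um": pos[1],
                "x_um": pos[2],
                "voxel_count": int(objects.df["voxel_count"].to_numpy()[sel].sum()),
                "volume_um3": float(w.sum()),
                "sum_intensity": float(objects.df["sum_intensity"].to_numpy()[sel].sum()),
                "mean_intensity": float(
                    objects.df["sum_intensity"].to_numpy()[sel].sum()
                    / objects.df["voxel_count"].to_numpy()[sel].sum()
                ),
                "n_members": int(sel.sum()),
                "distance_to_soma_um": float(np.linalg.norm(pos - soma)),
            }
        )
    df = pd.DataFrame(rows)
    loci = PunctumSet(df=df, spacing=objects.spacing)
    if len(df) < 2:
        bbox = None
    else:
        p = df[["z_um", "y_um", "x_um"]].to_numpy()
        ext = p.max(axis=0) - p.min(axis=0)
        bbox = (float(ext[0]), float(ext[1]), float(ext[2]))
    return loci, bbox


def quantify_engulfment(
    surface: CellSurface,
    target: VoxelVolume,
    threshold: Optional[float] = None,
    spot_diameter_um: float = 2.0,
    min_voxels: int = 2,
    cell_id: str = "cell",
) -> EngulfmentResult:
    """Full per-cell engulfment assay: mask → segment → index → loci.

    With no explicit ``threshold`` the masked channel is segmented by
    :func:`detect_spots` (robust seed threshold + per-object half-peak
    volumes), which is exact on clean data and approximately unbiased under
    PSF blur and noise. Passing a threshold selects plain fixed-threshold
    segmentation instead, with the value recorded in the result.
    """
    masked = mask_internal_channel(target, surface)
    if threshold is None:
        objects = detect_spots(masked, min_voxels=min_voxels)
    else:
        objects = internalized_objects(masked, threshold=threshold, min_voxels=min_voxels)
    result = engulfment_index(surface, objects, cell_id=cell_id, threshold_used=threshold)
    loci, bbox = engulfment_loci(objects, surface, spot_diameter_um=spot_diameter_um)
    result.loci = loci
    result.n_loci = len(loci)
    result.loci_bbox_extent_um = bbox
    return result
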