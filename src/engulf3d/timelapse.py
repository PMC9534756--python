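"""Classification of synaptic inputs against a cell surface, over time.

Inputs detected in a volume are partitioned into three mutually exclusive
classes by their signed distance to the cell surface: *noncontacting*
(entirely outside, distance > 0), *contacting* (touching the surface,
distance in [−d_eng, 0]), and *engulfed* (most-interior voxel deeper than
the engulfment threshold d_eng, default 0.270 µm ≡ 270 nm). Because an
extended object rarely sits at exactly zero distance, "contact" is
necessarily an interval; the most-interior voxel of each input decides its
class.

For time-lapse data, per-class mean volumes are tracked per frame and
normalized to the mean volume of noncontacting inputs, which removes the
apparent volume loss caused by photobleaching (all classes bleach alike, so
the ratio is stationary when geometry is static).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CLASS_LABELS, Engulf3dError, PunctumSet, TimelapseVolume
from .engulfment import detect_objects
from .reconstruct import CellSurface


def classify_label(signed_distance_um: float, engulfed_distance_um: float = 0.270) -> str:
    """Three-way partition of a signed distance (µm; negative = interior)."""
    if signed_distance_um > 0:
        return "noncontacting"
    if signed_distance_um < -engulfed_distance_um:
        return "engulfed"
    return "contacting"


def classify_inputs(
    puncta: PunctumSet,
    surface: CellSurface,
    engulfed_distance_um: float = 0.270,
) -> PunctumSet:
    """Assign noncontacting/contacting/engulfed labels to detected inputs.

    Each punctum's signed distance is the minimum (most interior) signed
    distance over its voxels, so any overlap with the surface boundary makes
    it at least "contacting". Requires the punctum label image; geometry
    alone decides the class, so the result is invariant to global intensity
    scaling.
    """
    if puncta.empty:
        df = puncta.df.copy()
        return PunctumSet(df=df, spacing=puncta.spacing, labels=puncta.labels)
    if puncta.labels is None:
        raise Engulf3dError("classify_inputs requires the punctum label image")
    if puncta.labels.shape != surface.mask.shape:
        raise Engulf3dError("punctum labels and surface shapes differ")
    sdf = surface.signed_distance_um
    ids = puncta.df["id"].to_numpy(dtype=int)
    mins = ndimage.minimum(sdf, labels=puncta.labels, index=ids)
    df = puncta.df.copy()
    df["signed_distance_um"] = np.asarray(mins, dtype=float)
    df["class_label"] = [
        classify_label(d, engulfed_distance_um) for d in df["signed_distance_um"]
    ]
    return PunctumSet(df=df, spacing=puncta.spacing, labels=puncta.labels)


@dataclass
class ClassifiedInputs:
    """Per-frame per-class volume summary of classified inputs."""

    table: pd.DataFrame  # frame, class_label, n, mean_volume_um3, mean_volume_normalized
    normalizer_mode: Optional[str] = None

    def trace(self, class_label: str, normalized: bool = True) -> pd.Series:
        col = "mean_volume_normalized" if normalized else "mean_volume_um3"
        sub = self.table[self.table["class_label"] == class_label]
        return sub.set_index("frame")[col]


def summarize_frames(per_frame: Sequence[PunctumSet]) -> pd.DataFrame:
    """Per-frame per-class counts and mean volumes from classified puncta."""
    rows = []
    for t, ps in enumerate(per_frame):
        for cls in CLASS_LABELS:
            sel = ps.df[ps.df["class_label"] == cls] if not ps.empty else ps.df
            rows.append(
                {
                    "frame": t,
                    "class_label": cls,
                    "n": len(sel),
                    "mean_volume_um3": (
                        float(sel["volume_um3"].mean()) if len(sel) else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def normalize_timecourse(
    per_frame: Sequence[PunctumSet],
    mode: Literal["per_frame", "pooled"] = "per_frame",
) -> ClassifiedInputs:
    """Normalize per-class mean volumes to the noncontacting baseline.

    ``per_frame`` holds one classified :class:`PunctumSet` per frame. In the
    default ``per_frame`` mode every class's mean volume in frame t is
    divided by the noncontacting mean volume of the same frame, so the
    noncontacting trace is identically 1 and photobleaching (which shrinks
    the apparent volume of every class alike) cancels from the other traces.
    In ``pooled`` mode the divisor is instead the grand mean noncontacting
    volume over the whole imaging period, which preserves the common decay.

    Raises when the video contains no noncontacting input at all (the
    normalizer is undefined); individual frames without noncontacting inputs
    get missing normalized values in ``per_frame`` mode.
    """
    table = summarize_frames(per_frame)
    nc = table[table["class_label"] == "noncontacting"].set_index("frame")["mean_volume_um3"]
    if nc.isna().all():
        raise Engulf3dError(
            "no noncontacting inputs in the entire video; normalizer undefined"
        )
    if mode == "pooled":
        all_nc = pd.concat(
            [
                ps.df[ps.df["class_label"] == "noncontacting"]["volume_um3"]
                for ps in per_frame
                if not ps.empty
            ]
        )
        denom = float(all_nc.mean())
        table["mean_volume_normalized"] = table["mean_volume_um3"] / denom
    elif mode == "per_frame":
        table["mean_volume_normalized"] = table.apply(
            lambda r: r["mean_volume_um3"] / nc.loc[r["frame"]]
            if pd.notna(nc.loc[r["frame"]])
            else np.nan,
            axis=1,
        )
    else:
        raise Engulf3dError(f"unknown normalization mode {mode!r}")
    return ClassifiedInputs(table=table, normalizer_mode=mode)


def classify_timelapse(
    inputs: TimelapseVolume,
    surface: CellSurface,
    engulfed_distance_um: float = 0.270,
    detection_threshold: Optional[float] = None,
    min_voxels: int = 2,
) -> list[PunctumSet]:
    """Detect and classify inputs in every frame of a time-lapse.

    Detection uses a single absolute threshold for the whole video
    (default: robust background threshold of frame 0), mirroring the
    constant-creation-parameters rule: the same segmentation settings apply
    to every frame, so photobleaching shows up as shrinking object volumes
    rather than as a moving threshold — exactly the artifact the
    noncontacting-baseline normalization then removes.
    """
    if detection_threshold is None:
        from .engulfment import robust_background_threshold

        detection_threshold = robust_background_threshold(inputs.frames[0].data)
    out = []
    for frame in inputs.frames:
        puncta = detect_objects(frame, threshold=detection_threshold, min_voxels=min_voxels)
        out.append(classify_inputs(puncta, surface, engulfed_distance_um))
    return out


def contact_census(classified: PunctumSet) -> dict:
    """Per-cell census: interacting inputs and presence of internal material.

    Interacting = contacting + engulfed; ``any_internal`` flags whether the
    cell contains at least one engulfed input.
    """
    if classified.empty:
        return {"n_contacting_or_engulfed": 0, "n_engulfed": 0, "any_internal": False}
    labels = classified.df["class_label"]
    n_eng = int((labels == "engulfed").sum())
    n_con = int((labels == "contacting").sum())
    return {
        "n_contacting_or_engulfed": n_con + n_eng,
        "n_engulfed": n_eng,
        "any_internal": n_eng > 0,
    }
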