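"""Core data model and I/O for multi-channel volumetric images.

Axis order is fixed to ``(z, y, x)`` throughout the package, and every
physical quantity is carried in micrometres (µm) or cubic micrometres (µm³).
Fluorescence stacks are anisotropic — the axial step is typically several
times the lateral pixel size — so every distance/volume computation takes the
per-axis spacing into account rather than assuming isotropic voxels.
"""

from __future__ import annotations

import dataclasses
import json
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, model_validator

#: Channel roles understood by the pipeline.
CHANNEL_ROLES = (
    "cell",
    "presyn",
    "postsyn",
    "lysosome",
    "reporter_green",
    "reporter_red",
    "nuclei",
    "fish_probe",
)

#: Input-classification labels (relation of a punctum to the cell surface).
CLASS_LABELS = ("noncontacting", "contacting", "engulfed")


class Engulf3dError(Exception):
    """Base class for data and analysis errors raised by this package."""


def _validate_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise Engulf3dError(f"spacing must have 3 components (z, y, x), got {spacing!r}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise Engulf3dError(f"all spacing components must be > 0, got {spacing!r}")
    return spacing


@dataclass
class VoxelVolume:
    """One channel of a 3D image with physical voxel spacing.

    Parameters
    ----------
    data
        3D scalar intensity grid, axis order ``(z, y, x)``; finite, ≥ 0.
    spacing
        Physical size of one voxel along ``(z, y, x)`` in µm.
    channel_role
        Optional role tag, one of :data:`CHANNEL_ROLES`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel_role: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise Engulf3dError(
                f"VoxelVolume requires a 3D (z, y, x) array, got ndim={self.data.ndim}"
            )
        self.spacing = _validate_spacing(self.spacing)
        if self.channel_role is not None and self.channel_role not in CHANNEL_ROLES:
            raise Engulf3dError(f"unknown channel_role {self.channel_role!r}")
        if not np.all(np.isfinite(self.data)):
            raise Engulf3dError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise Engulf3dError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of a single voxel in µm³."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        """Return a copy carrying ``data`` but the same spacing and role."""
        return VoxelVolume(data=data, spacing=self.spacing, channel_role=self.channel_role)


@dataclass
class BinaryMask:
    """A 3D boolean mask sharing shape and spacing with its parent volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise Engulf3dError("BinaryMask requires a 3D array")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_um3(self) -> float:
        """Physical volume: voxel count × (spacing_z · spacing_y · spacing_x)."""
        return self.voxel_count * float(np.prod(self.spacing))


@dataclass
class TimelapseVolume:
    """Ordered sequence of equally shaped frames acquired at fixed cadence."""

    frames: list[VoxelVolume]
    frame_interval_min: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise Engulf3dError("TimelapseVolume requires at least one frame")
        if self.frame_interval_min <= 0:
            raise Engulf3dError("frame_interval_min must be > 0")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if f.shape != ref.shape or f.spacing != ref.spacing:
                raise Engulf3dError("all frames must share shape and spacing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.frames[0].spacing


#: Canonical column order for punctum tables.
PUNCTUM_COLUMNS = [
    "id",
    "z_um",
    "y_um",
    "x_um",
    "voxel_count",
    "volume_um3",
    "sum_intensity",
    "mean_intensity",
    "signed_distance_um",
    "class_label",
]


@dataclass
class PunctumSet:
    """Labeled discrete objects (puncta / FISH molecules / loci).

    ``df`` holds one row per object with physical centroids (µm) and volume
    statistics; ``labels`` optionally retains the integer label image so that
    per-voxel statistics (e.g. the most-interior signed distance of a
    punctum) remain computable.
    """

    df: pd.DataFrame
    spacing: Optional[tuple[float, float, float]] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for col in ("id", "z_um", "y_um", "x_um", "voxel_count", "volume_um3"):
            if col not in self.df.columns:
                raise Engulf3dError(f"PunctumSet table missing column {col!r}")
        ids = self.df["id"].to_numpy()
        if len(ids) != len(np.unique(ids)):
            raise Engulf3dError("PunctumSet ids must be unique")
        if self.spacing is not None:
            self.spacing = _validate_spacing(self.spacing)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def empty(self) -> bool:
        return len(self.df) == 0

    def centroids_um(self) -> np.ndarray:
        """(n, 3) array of centroids in µm, axis order (z, y, x)."""
        return self.df[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)

    @classmethod
    def empty_set(cls, spacing: Optional[Sequence[float]] = None) -> "PunctumSet":
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in PUNCTUM_COLUMNS})
        df["id"] = df["id"].astype(int)
        return cls(df=df, spacing=tuple(spacing) if spacing is not None else None)


class AssayParams(BaseModel):
    """Numerical parameters of the quantification assays.

    All length thresholds are stored in µm regardless of how they may be
    quoted elsewhere in nm (e.g. the engulfed-class threshold 0.270 µm ≡
    270 nm), to avoid unit drift.
    """

    saturation_fraction: float = Field(0.001, gt=0, lt=1)
    mean_filter_radius_um: float = Field(1.5, gt=0)
    spot_diameter_um: float = Field(2.0, gt=0)
    interiority_threshold_um: float = Field(0.132, gt=0)
    engulfed_distance_um: float = Field(0.270, gt=0)
    lysosome_surface_coeff: float = Field(0.75, gt=0)
    fish_positivity_count: int = Field(5, gt=0)
    rout_q: float = Field(0.01, gt=0, lt=0.5)

    @model_validator(mode="after")
    def _check(self) -> "AssayParams":
        return self


# ---------------------------------------------------------------------------
# TIFF / OME-TIFF I/O
# ---------------------------------------------------------------------------


def _spacing_from_ome(tf: tifffile.TiffFile) -> Optional[tuple[float, float, float]]:
    try:
        meta = tifffile.xml2dict(tf.ome_metadata) if tf.ome_metadata else None
    except Exception:  # malformed metadata is treated as absent
        return None
    if not meta:
        return None
    try:
        img = meta["OME"]["Image"]
        if isinstance(img, list):
            img = img[0]
        px = img["Pixels"]
        sz = float(px["PhysicalSizeZ"])
        sy = float(px["PhysicalSizeY"])
        sx = float(px["PhysicalSizeX"])
        return (sz, sy, sx)
    except (KeyError, TypeError, ValueError):
        return None


def read_volume(
    path: str | Path,
    spacing_override: Optional[Sequence[float]] = None,
    channel_roles: Optional[Sequence[Optional[str]]] = None,
) -> list[VoxelVolume]:
    """Read a multi-channel z-stack from TIFF/OME-TIFF as one volume per channel.

    Axis order is normalized to ``(z, y, x)``. Spacing comes from OME
    metadata (PhysicalSizeZ/Y/X) unless ``spacing_override`` is given; a file
    without spacing metadata and without an override is an error, because no
    physical measurement downstream would be meaningful.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        spacing = _spacing_from_ome(tf)

    if spacing_override is not None:
        spacing = _validate_spacing(spacing_override)
    if spacing is None:
        raise Engulf3dError(
            f"{path}: no physical voxel spacing in metadata; pass spacing_override=(z, y, x) µm"
        )

    # Normalize axes to (C, Z, Y, X). Plain TIFF stacks come back with an
    # anonymous series axis (Q/I), which for a z-stack is the z axis.
    axes = axes.replace("S", "C")
    if "Z" not in axes:
        for anon in ("Q", "I"):
            if anon in axes:
                axes = axes.replace(anon, "Z", 1)
                break
    if "Z" not in axes or data.ndim < 3:
        raise Engulf3dError(f"{path}: 3D z-stack required (axes {axes!r} found)")
    if "C" not in axes:
        data = data[np.newaxis]
        axes = "C" + axes
    order = [axes.index(a) for a in "CZYX" if a in axes]
    extra = [i for i in range(data.ndim) if i not in order]
    if extra:  # squeeze singleton axes such as T=1
        if any(data.shape[i] != 1 for i in extra):
            raise Engulf3dError(f"{path}: unsupported axes {axes!r}")
        data = np.squeeze(data, axis=tuple(extra))
        axes = "".join(a for i, a in enumerate(axes) if i not in extra)
        order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    n_channels = data.shape[0]
    if channel_roles is not None and len(channel_roles) != n_channels:
        raise Engulf3dError(
            f"{path}: {n_channels} channels but {len(channel_roles)} channel_roles given"
        )
    roles = channel_roles if channel_roles is not None else [None] * n_channels
    return [
        VoxelVolume(data=np.ascontiguousarray(data[c]), spacing=spacing, channel_role=roles[c])
        for c in range(n_channels)
    ]


def write_volume(path: str | Path, channels: Sequence[VoxelVolume]) -> None:
    """Write channels to a single OME-TIFF with physical spacing metadata."""
    if not channels:
        raise Engulf3dError("write_volume requires at least one channel")
    ref = channels[0]
    for c in channels[1:]:
        if c.shape != ref.shape or c.spacing != ref.spacing:
            raise Engulf3dError("all channels must share shape and spacing")
    stack = np.stack([c.data for c in channels], axis=0)  # (C, Z, Y, X)
    sz, sy, sx = ref.spacing
    # Fixed UUID + no DateTime tag: identical inputs yield byte-identical
    # files, so full-pipeline runs are reproducible down to the artifacts.
    content_uuid = uuid.uuid5(uuid.NAMESPACE_URL, "engulf3d://" + Path(path).name)
    tifffile.imwrite(
        Path(path),
        stack,
        ome=True,
        datetime=False,
        metadata={
            "axes": "CZYX",
            "UUID": f"urn:uuid:{content_uuid}",
            "PhysicalSizeZ": sz,
            "PhysicalSizeY": sy,
            "PhysicalSizeX": sx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


# ---------------------------------------------------------------------------
# Tidy-table output
# ---------------------------------------------------------------------------


def _to_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, PunctumSet):
        return obj.df
    if dataclasses.is_dataclass(obj):
        return pd.DataFrame([_record_of(obj)])
    if isinstance(obj, Iterable):
        rows = []
        for item in obj:
            rows.append(_record_of(item) if dataclasses.is_dataclass(item) else dict(item))
        return pd.DataFrame(rows)
    raise Engulf3dError(f"cannot convert {type(obj).__name__} to a table")


def _record_of(dc) -> dict:
    rec = {}
    for f in dataclasses.fields(dc):
        v = getattr(dc, f.name)
        if isinstance(v, (int, float, str, bool)) or v is None:
            rec[f.name] = v
        elif isinstance(v, (tuple, list)) and all(
            isinstance(x, (int, float)) for x in v
        ):
            for ax, x in zip("zyx", v):
                rec[f"{f.name}_{ax}"] = x
    return rec


def write_tables(
    results: Mapping[str, object],
    out_dir: str | Path,
    params: Optional[AssayParams] = None,
) -> dict[str, Path]:
    """Write per-cell / per-punctum result tables as CSV with a JSON sidecar.

    ``results`` maps table names to DataFrames, PunctumSets, dataclass
    records or iterables thereof. Floats are written in µm / µm³. The sidecar
    ``params.json`` records the :class:`AssayParams` in force so every run is
    auditable and replayable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, obj in results.items():
        frame = _to_frame(obj)
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False, lineterminator="\n")
        written[name] = p
    if params is not None:
        sidecar = out_dir / "params.json"
        sidecar.write_text(json.dumps(params.model_dump(), indent=2, sort_keys=True) + "\n")
        written["params"] = sidecar
    return written
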