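"""Ground-truthed synthetic microscopy scenes.

The generator builds multi-channel 3D scenes that emulate the imaging
conditions the analysis assumes: a ramified glial cell (ellipsoidal
"bean-shaped" soma plus branched tubular processes), presynaptic puncta
placed with known geometric relation to the cell surface (inside /
contacting / outside), lysosomes strictly inside the cell, a dual
green/red digestion reporter whose green signal is quenched inside
lysosomes, anisotropic voxels, PSF blur, Poisson and Gaussian noise, and
exponential photobleaching for time-lapse. Ground truth — per-punctum
placement class, true volumes, signed distances, masks, quench factor,
bleach rates — is recorded *before* blur and noise are applied, so every
downstream quantification can be validated against construction.

Placement classes are defined on the true cell mask's signed distance
field: inside puncta are fully interior (deepest voxel well below the
engulfed-class threshold), contacting puncta are centered on a boundary
voxel (signed distance exactly 0 by construction), and outside puncta
keep a clearance of at least two voxels from the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .core import BinaryMask, Engulf3dError, TimelapseVolume, VoxelVolume
from .reconstruct import signed_distance


class SceneError(Engulf3dError):
    """Raised when a requested scene cannot be constructed."""


class SceneSpec(BaseModel):
    """Parameters of one synthetic scene (all lengths in µm)."""

    shape: tuple[int, int, int] = (32, 160, 160)
    spacing: tuple[float, float, float] = (0.3, 0.132, 0.132)

    soma_center_um: Optional[tuple[float, float, float]] = None
    soma_radii_um: tuple[float, float, float] = (2.5, 4.5, 3.5)
    n_processes: int = Field(5, ge=0)
    process_length_um: tuple[float, float] = (5.0, 9.0)
    process_radius_um: tuple[float, float] = (0.4, 0.7)

    puncta_counts: dict[str, int] = Field(
        default_factory=lambda: {"inside": 6, "contacting": 6, "outside": 8}
    )
    punctum_radius_um: tuple[float, float] = (0.15, 0.25)
    punctum_amplitude: float = 150.0
    cell_amplitude: float = 100.0

    n_lysosomes: int = Field(3, ge=0)
    lysosome_radius_um: tuple[float, float] = (0.5, 0.9)
    lysosome_amplitude: float = 120.0
    quench_factor: float = Field(0.25, ge=0.0, le=1.0)
    make_reporter: bool = False

    make_postsyn: bool = False
    postsyn_offset_um: float = 0.1

    psf_sigma_um: tuple[float, float, float] = (0.2, 0.08, 0.08)
    apply_blur: bool = True
    poisson_scale: float = Field(1.0, ge=0.0)  # photons per intensity unit; 0 = off
    gaussian_noise_sd: float = Field(6.0, ge=0.0)

    bleach_rate_per_frame: float | dict[str, float] = 0.0
    n_frames: int = Field(1, ge=1)
    frame_interval_min: float = Field(1.0, gt=0)
    disappearances: list[tuple[int, int]] = Field(default_factory=list)  # (punctum_id, frame)

    rng_seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "SceneSpec":
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        for r, e in zip(self.soma_radii_um, extent):
            if 2 * r >= e:
                raise ValueError(f"soma radii {self.soma_radii_um} do not fit inside {extent}")
        for key, n in self.puncta_counts.items():
            if key not in ("inside", "contacting", "outside"):
                raise ValueError(f"unknown punctum class {key!r}")
            if n < 0:
                raise ValueError("puncta counts must be ≥ 0")
        return self

    def without_noise(self, blur: bool = False) -> "SceneSpec":
        """Copy of this spec with noise (and optionally blur) disabled."""
        return self.model_copy(
            update={"poisson_scale": 0.0, "gaussian_noise_sd": 0.0, "apply_blur": blur}
        )

    def bleach_rate(self, role: str) -> float:
        if isinstance(self.bleach_rate_per_frame, dict):
            return float(self.bleach_rate_per_frame.get(role, 0.0))
        return float(self.bleach_rate_per_frame)


@dataclass
class SceneTruth:
    """Ground truth recorded before blur/noise."""

    cell_mask: BinaryMask
    soma_center_um: tuple[float, float, float]
    puncta: pd.DataFrame  # id, placement_class, centroid, radius, volume, signed distance
    punctum_labels: np.ndarray
    lysosome_mask: BinaryMask
    quench_factor: float
    bleach_rate_per_frame: float | dict[str, float]
    disappearances: list[tuple[int, int]] = dc_field(default_factory=list)

    def counts_by_class(self) -> dict[str, int]:
        return self.puncta["placement_class"].value_counts().to_dict()


@dataclass
class FishTruth:
    """Ground truth for a FISH field: nuclei and per-nucleus molecule counts."""

    nucleus_labels: np.ndarray
    nucleus_centers_um: np.ndarray
    counts: pd.DataFrame  # nucleus_id, gene, count
    molecules: pd.DataFrame  # gene, nucleus_id, z_um, y_um, x_um


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def _local_box(
    center_um: np.ndarray,
    radius_um: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    pad_vox: int = 1,
) -> tuple[tuple[slice, ...], np.ndarray]:
    """Slices of a bounding box around a ball, plus the distance grid (µm)."""
    lo, hi, axes = [], [], []
    for a in range(3):
        c = center_um[a] / spacing[a]
        r = radius_um / spacing[a]
        lo.append(max(0, int(np.floor(c - r)) - pad_vox))
        hi.append(min(shape[a], int(np.ceil(c + r)) + pad_vox + 1))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    grids = np.ogrid[sl]
    d2 = sum(
        ((g * spacing[a]) - center_um[a]) ** 2 for a, g in enumerate(grids)
    )
    return sl, np.sqrt(d2)


def _stamp_ball(
    mask: np.ndarray,
    center_um: Sequence[float],
    radius_um: float,
    spacing: tuple[float, float, float],
) -> None:
    sl, dist = _local_box(np.asarray(center_um, float), radius_um, mask.shape, spacing)
    mask[sl] |= dist <= radius_um


def _stamp_blob(
    channel: np.ndarray,
    center_um: Sequence[float],
    radius_um: float,
    amplitude: float,
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Add a uniform-density sphere of the given amplitude.

    Sub-resolution fluorescent objects are modeled as constant-density
    spheres; their familiar Gaussian appearance in images arises from PSF
    convolution, which the scene pipeline applies separately. Returns the
    blob's voxel mask alongside mutating ``channel``."""
    center = np.asarray(center_um, float)
    sl, dist = _local_box(center, radius_um, channel.shape, spacing)
    blob = dist <= radius_um
    channel[sl] += np.where(blob, amplitude, 0.0)
    full = np.zeros(channel.shape, dtype=bool)
    full[sl] = blob
    return full


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_um: Sequence[float],
    radii_um: Sequence[float],
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(
        (((g * spacing[a]) - center_um[a]) / radii_um[a]) ** 2 for a, g in enumerate(grids)
    )
    return d2 <= 1.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 1.0, 0.0])


def _grow_cell_mask(spec: SceneSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Soma ellipsoid plus branched tubular processes; returns (mask, soma center)."""
    shape, spacing = spec.shape, spec.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    center = (
        np.asarray(spec.soma_center_um, float)
        if spec.soma_center_um is not None
        else extent / 2.0
    )
    mask = _ellipsoid_mask(shape, spacing, center, spec.soma_radii_um)

    # Processes start just inside the soma surface so connectivity to the
    # soma is guaranteed; direction changes are small and mostly lateral
    # (the axial extent of the volume is shallow).
    aniso = np.array([0.35, 1.0, 1.0])
    for _ in range(spec.n_processes):
        direction = _unit(rng.standard_normal(3) * aniso)
        radii = np.asarray(spec.soma_radii_um)
        r_dir = 1.0 / np.sqrt(np.sum((direction / radii) ** 2))
        point = center + direction * 0.8 * r_dir
        length = rng.uniform(*spec.process_length_um)
        tube_r = rng.uniform(*spec.process_radius_um)
        n_seg = 3
        step = min(spacing) / 2.0
        margin = tube_r + np.asarray(spacing)
        for _seg in range(n_seg):
            direction = _unit(direction + 0.25 * rng.standard_normal(3) * aniso)
            for _s in range(int(length / n_seg / step)):
                nxt = point + direction * step
                for a in range(3):  # reflect at the padded volume border
                    if nxt[a] < margin[a] or nxt[a] > extent[a] - margin[a]:
                        direction[a] = -direction[a]
                        nxt[a] = np.clip(nxt[a], margin[a], extent[a] - margin[a])
                point = nxt
                _stamp_ball(mask, point, tube_r, spacing)
    return mask, center


def _sample_center(
    eligible: np.ndarray,
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
    existing: list[np.ndarray],
    min_sep_um: float,
    margin_um: np.ndarray,
    extent: np.ndarray,
    what: str,
    max_tries: int = 300,
) -> np.ndarray:
    flat = np.flatnonzero(eligible)
    if flat.size == 0:
        raise SceneError(f"no eligible voxels to place a {what} punctum/object")
    for _ in range(max_tries):
        idx = np.unravel_index(rng.choice(flat), eligible.shape)
        center = np.array([idx[a] * spacing[a] for a in range(3)])
        if np.any(center < margin_um) or np.any(center > extent - margin_um):
            continue
        if all(np.linalg.norm(center - e) >= min_sep_um for e in existing):
            return center
    raise SceneError(
        f"could not place a {what} object without overlap after {max_tries} retries"
    )


def _apply_noise(
    data: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    out = data
    if spec.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_noise_sd > 0:
        out = out + rng.normal(0.0, spec.gaussian_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None).astype(np.float64)


def _blur(data: np.ndarray, spec: SceneSpec) -> np.ndarray:
    if not spec.apply_blur or all(s == 0 for s in spec.psf_sigma_um):
        return data.astype(np.float64)
    sigma_vox = np.asarray(spec.psf_sigma_um) / np.asarray(spec.spacing)
    return ndimage.gaussian_filter(data.astype(np.float64), sigma=sigma_vox, mode="reflect")


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

#: Depth margin (µm) added below the engulfed-class threshold when placing
#: inside puncta, so their deepest voxel is unambiguously interior.
_INSIDE_DEPTH_MARGIN = 0.45


def _build_clean_scene(spec: SceneSpec):
    """Construct noiseless, unblurred channels plus truth (internal helper)."""
    rng = np.random.default_rng(spec.rng_seed)
    shape, spacing = spec.shape, spec.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])

    cell_mask, soma_center = _grow_cell_mask(spec, rng)
    sdf = signed_distance(cell_mask, spacing)
    max_sp = max(spacing)

    counts = {"inside": 0, "contacting": 0, "outside": 0} | dict(spec.puncta_counts)
    centers: list[np.ndarray] = []
    punctum_rows = []
    punctum_labels = np.zeros(shape, dtype=np.int32)
    presyn = np.zeros(shape, dtype=np.float64)
    pid = 0
    for cls in ("inside", "contacting", "outside"):
        for _ in range(counts[cls]):
            pid += 1
            r = rng.uniform(*spec.punctum_radius_um)
            if cls == "inside":
                eligible = sdf <= -(r + _INSIDE_DEPTH_MARGIN)
            elif cls == "contacting":
                eligible = sdf == 0.0
            else:
                eligible = sdf >= r + 2 * max_sp + 0.1
            margin = np.full(3, r + 0.6)
            center = _sample_center(
                eligible, spacing, rng, centers, min_sep_um=1.4,
                margin_um=margin, extent=extent, what=cls,
            )
            centers.append(center)
            blob = _stamp_blob(presyn, center, r, spec.punctum_amplitude, spacing)
            punctum_labels[blob] = pid
            cz = tuple(int(round(center[a] / spacing[a])) for a in range(3))
            punctum_rows.append(
                {
                    "id": pid,
                    "placement_class": cls,
                    "z_um": center[0],
                    "y_um": center[1],
                    "x_um": center[2],
                    "radius_um": r,
                    "voxel_count": int(blob.sum()),
                    "true_volume_um3": float(blob.sum() * np.prod(spacing)),
                    "true_signed_distance_um": float(sdf[cz]),
                }
            )
    puncta = pd.DataFrame(
        punctum_rows,
        columns=[
            "id", "placement_class", "z_um", "y_um", "x_um", "radius_um",
            "voxel_count", "true_volume_um3", "true_signed_distance_um",
        ],
    )

    # Lysosomes: strictly inside the cell. The first ones wrap inside
    # puncta (engulfed material sits in lysosomes, which is what quenches
    # the green reporter there); extras are placed in free interior space.
    lyso_mask = np.zeros(shape, dtype=bool)
    lysosome = np.zeros(shape, dtype=np.float64)
    inside_rows = puncta[puncta["placement_class"] == "inside"]
    lyso_centers: list[np.ndarray] = []
    n_wrapped = min(spec.n_lysosomes, len(inside_rows))
    for i in range(n_wrapped):
        row = inside_rows.iloc[i]
        c = np.array([row.z_um, row.y_um, row.x_um])
        lr = float(row.radius_um) + 0.25
        blob = _stamp_blob(lysosome, c, lr, spec.lysosome_amplitude, spacing)
        lyso_mask |= blob
        lyso_centers.append(c)
    for _ in range(spec.n_lysosomes - n_wrapped):
        lr = rng.uniform(*spec.lysosome_radius_um)
        eligible = sdf <= -(lr + 0.2)
        others = [
            np.array([row.z_um, row.y_um, row.x_um])
            for _, row in puncta.iterrows()
            if row.placement_class != "inside"
        ]
        c = _sample_center(
            eligible, spacing, rng, lyso_centers + others,
            min_sep_um=lr + spec.punctum_radius_um[1] + 0.4,
            margin_um=np.full(3, lr + 0.4), extent=extent, what="lysosome",
        )
        blob = _stamp_blob(lysosome, c, lr, spec.lysosome_amplitude, spacing)
        lyso_mask |= blob
        lyso_centers.append(c)

    channels: dict[str, np.ndarray] = {
        "cell": cell_mask.astype(np.float64) * spec.cell_amplitude,
        "presyn": presyn,
    }
    if spec.make_postsyn:
        postsyn = np.zeros(shape, dtype=np.float64)
        offset = np.array([0.0, 0.0, spec.postsyn_offset_um])
        for _, row in puncta.iterrows():
            c = np.array([row.z_um, row.y_um, row.x_um]) + offset
            c = np.clip(c, row.radius_um + 0.3, extent - row.radius_um - 0.3)
            _stamp_blob(postsyn, c, float(row.radius_um), spec.punctum_amplitude, spacing)
        channels["postsyn"] = postsyn
    if spec.n_lysosomes > 0:
        channels["lysosome"] = lysosome
    if spec.make_reporter:
        red = presyn.copy()
        green = red * np.where(lyso_mask, spec.quench_factor, 1.0)
        channels["reporter_green"] = green
        channels["reporter_red"] = red

    truth = SceneTruth(
        cell_mask=BinaryMask(cell_mask, spacing),
        soma_center_um=tuple(float(c) for c in soma_center),
        puncta=puncta,
        punctum_labels=punctum_labels,
        lysosome_mask=BinaryMask(lyso_mask, spacing),
        quench_factor=spec.quench_factor,
        bleach_rate_per_frame=spec.bleach_rate_per_frame,
        disappearances=list(spec.disappearances),
    )
    return channels, truth, rng


def generate_scene(spec: SceneSpec) -> tuple[list[VoxelVolume], SceneTruth]:
    """Generate one multi-channel scene and its ground truth.

    Deterministic given ``spec.rng_seed``. Channels are PSF-blurred and then
    corrupted with Poisson and Gaussian noise (each step individually
    switchable); truth reflects the clean geometry.
    """
    channels, truth, rng = _build_clean_scene(spec)
    out = []
    for role, data in channels.items():
        data = _blur(data, spec)
        data = _apply_noise(data, spec, rng)
        out.append(VoxelVolume(data=data, spacing=spec.spacing, channel_role=role))
    return out, truth


def generate_timelapse(spec: SceneSpec) -> tuple[dict[str, TimelapseVolume], SceneTruth]:
    """Generate a bleaching time-lapse: frame t is scaled by exp(−rate·t).

    Geometry is static unless ``spec.disappearances`` lists
    ``(punctum_id, frame)`` events, after which the named punctum is absent
    from the presynaptic/reporter channels (emulating inputs that disappear
    during an imaging session). Bleaching is applied to the clean signal
    before noise; PSF blur is linear, so it is computed once per unique
    geometry and scaled per frame.
    """
    if spec.n_frames < 2:
        raise SceneError("generate_timelapse requires n_frames ≥ 2")
    channels, truth, rng = _build_clean_scene(spec)
    blurred = {role: _blur(data, spec) for role, data in channels.items()}

    removal_frame = {int(p): int(f) for p, f in spec.disappearances}
    unknown = set(removal_frame) - set(truth.puncta["id"].astype(int))
    if unknown:
        raise SceneError(f"disappearance for unknown punctum ids {sorted(unknown)}")

    # Per-punctum blurred contribution, for channels that carry puncta.
    contrib: dict[int, dict[str, np.ndarray]] = {}
    if removal_frame:
        spacing = spec.spacing
        for pid_, f_ in removal_frame.items():
            row = truth.puncta.set_index("id").loc[pid_]
            single = np.zeros(spec.shape, dtype=np.float64)
            _stamp_blob(
                single,
                np.array([row.z_um, row.y_um, row.x_um]),
                float(row.radius_um),
                spec.punctum_amplitude,
                spacing,
            )
            per_role = {"presyn": _blur(single, spec)}
            if spec.make_reporter:
                in_lyso = truth.lysosome_mask.data
                per_role["reporter_red"] = per_role["presyn"]
                per_role["reporter_green"] = _blur(
                    single * np.where(in_lyso, spec.quench_factor, 1.0), spec
                )
            contrib[pid_] = per_role

    frames: dict[str, list[VoxelVolume]] = {role: [] for role in blurred}
    for t in range(spec.n_frames):
        for role, base in blurred.items():
            clean_t = base
            for pid_, f_ in removal_frame.items():
                if t >= f_ and role in contrib[pid_]:
                    clean_t = clean_t - contrib[pid_][role]
            clean_t = np.clip(clean_t, 0.0, None) * np.exp(-spec.bleach_rate(role) * t)
            noisy = _apply_noise(clean_t, spec, rng)
            frames[role].append(
                VoxelVolume(data=noisy, spacing=spec.spacing, channel_role=role)
            )
    out = {
        role: TimelapseVolume(frames=fs, frame_interval_min=spec.frame_interval_min)
        for role, fs in frames.items()
    }
    return out, truth


# ---------------------------------------------------------------------------
# FISH fields
# ---------------------------------------------------------------------------


def generate_fish_field(
    n_nuclei: int,
    molecules_per_nucleus: Mapping[str, Sequence[int]],
    spacing: tuple[float, float, float] = (0.3, 0.132, 0.132),
    shape: tuple[int, int, int] = (20, 128, 128),
    nucleus_radius_um: float = 2.2,
    nucleus_centers_um: Optional[Sequence[Sequence[float]]] = None,
    molecule_radius_um: float = 0.15,
    apply_blur: bool = True,
    psf_sigma_um: tuple[float, float, float] = (0.2, 0.08, 0.08),
    gaussian_noise_sd: float = 3.0,
    rng_seed: int = 0,
) -> tuple[dict[str, VoxelVolume], FishTruth]:
    """Generate a DAPI-like nucleus channel plus single-molecule FISH channels.

    ``molecules_per_nucleus`` maps gene name → per-nucleus molecule counts
    (one entry per nucleus). Nuclei may be placed explicitly (possibly
    touching, to exercise watershed splitting); by default they are placed
    randomly with clear separation. Truth records the nucleus label image
    (touching nuclei are resolved to the nearest center) and per-nucleus
    per-gene counts.
    """
    rng = np.random.default_rng(rng_seed)
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    for gene, per_nuc in molecules_per_nucleus.items():
        if len(per_nuc) != n_nuclei:
            raise SceneError(
                f"gene {gene!r}: {len(per_nuc)} counts given for {n_nuclei} nuclei"
            )

    if nucleus_centers_um is not None:
        centers = [np.asarray(c, float) for c in nucleus_centers_um]
        if len(centers) != n_nuclei:
            raise SceneError("nucleus_centers_um length must equal n_nuclei")
    else:
        centers = []
        margin = np.full(3, nucleus_radius_um + 0.4)
        margin[0] = min(margin[0], extent[0] / 2 - spacing[0])  # shallow stacks
        all_eligible = np.ones(shape, dtype=bool)
        for _ in range(n_nuclei):
            centers.append(
                _sample_center(
                    all_eligible, spacing, rng, centers,
                    min_sep_um=2 * nucleus_radius_um + 1.0,
                    margin_um=margin, extent=extent, what="nucleus",
                )
            )

    # Nuclei are flattened ellipsoids (shallow z), as in tissue sections.
    radii = np.array([min(nucleus_radius_um, extent[0] / 2 - spacing[0]),
                      nucleus_radius_um, nucleus_radius_um])
    dapi = np.zeros(shape, dtype=np.float64)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    dist_to = np.full(shape, np.inf)
    for k, c in enumerate(centers, start=1):
        m = _ellipsoid_mask(shape, spacing, c, radii)
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        d2 = sum((((g * spacing[a]) - c[a]) / radii[a]) ** 2 for a, g in enumerate(grids))
        closer = m & (d2 < dist_to)
        nucleus_labels[closer] = k
        dist_to = np.where(closer, d2, dist_to)
        dapi[m] = 100.0

    mol_rows = []
    channels_raw: dict[str, np.ndarray] = {}
    for gene in sorted(molecules_per_nucleus):
        probe = np.zeros(shape, dtype=np.float64)
        for k, c in enumerate(centers, start=1):
            n_mol = int(molecules_per_nucleus[gene][k - 1])
            eligible = ndimage.binary_erosion(
                nucleus_labels == k, iterations=2, border_value=0
            )
            placed: list[np.ndarray] = []
            for _ in range(n_mol):
                pos = _sample_center(
                    eligible, spacing, rng, placed,
                    min_sep_um=2 * molecule_radius_um + 0.45,
                    margin_um=np.full(3, molecule_radius_um + spacing[0]),
                    extent=extent, what=f"{gene} molecule",
                )
                placed.append(pos)
                _stamp_blob(probe, pos, molecule_radius_um, 200.0, spacing)
                mol_rows.append(
                    {"gene": gene, "nucleus_id": k,
                     "z_um": pos[0], "y_um": pos[1], "x_um": pos[2]}
                )
        channels_raw[gene] = probe

    count_rows = [
        {"nucleus_id": k, "gene": gene, "count": int(molecules_per_nucleus[gene][k - 1])}
        for gene in sorted(molecules_per_nucleus)
        for k in range(1, n_nuclei + 1)
    ]
    truth = FishTruth(
        nucleus_labels=nucleus_labels,
        nucleus_centers_um=np.array(centers) if centers else np.zeros((0, 3)),
        counts=pd.DataFrame(count_rows, columns=["nucleus_id", "gene", "count"]),
        molecules=pd.DataFrame(
            mol_rows, columns=["gene", "nucleus_id", "z_um", "y_um", "x_um"]
        ),
    )

    def finish(data: np.ndarray, role: str) -> VoxelVolume:
        if apply_blur and any(s > 0 for s in psf_sigma_um):
            data = ndimage.gaussian_filter(
                data, sigma=np.asarray(psf_sigma_um) / np.asarray(spacing), mode="reflect"
            )
        if gaussian_noise_sd > 0:
            data = data + rng.normal(0.0, gaussian_noise_sd, size=data.shape)
        return VoxelVolume(
            data=np.clip(data, 0.0, None), spacing=spacing, channel_role=role
        )

    channels = {"nuclei": finish(dapi, "nuclei")}
    for gene in sorted(channels_raw):
        channels[gene] = finish(channels_raw[gene], "fish_probe")
    return channels, truth
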