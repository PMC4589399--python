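"""4D image volumes, ROI definition and refinement, TAC extraction, SUV.

Volumes are indexed ``(frame, z, y, x)`` with voxel sizes in mm; voxel
coordinates are 0-based and physical positions refer to voxel centers.
ROIs start as manually placed 3-D ellipsoids and are refined for kinetic
analysis by region growing: starting from the hottest voxel of the
initial ROI, face-connected voxels whose intensity lies within +/- 40%
of the initial ROI's mean (on a time-averaged image) are accepted.

Static uptake is summarized as the standardized uptake value

    SUV = concentration (MBq/mL) / [injected dose (MBq) / body weight (g)]

with SUVmax the hottest ROI voxel on the last frame.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .schedule import FrameSchedule, TimeActivityCurve

__all__ = [
    "ImageVolume4D",
    "ROIMask",
    "SUVRecord",
    "ellipsoid_roi",
    "region_grow_refine",
    "extract_tac",
    "compute_suv",
    "suvmax_static",
    "save_volume",
    "load_volume",
    "save_mask_tsv",
    "load_mask_tsv",
]


@dataclass(frozen=True)
class ImageVolume4D:
    """Dynamic image: activity concentration (MBq/mL) per frame and voxel.

    ``data`` has shape (n_frames, nz, ny, nx); ``voxel_size_mm`` is the
    (z, y, x) voxel edge length in mm.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if data.ndim != 4:
            raise ValueError("data must be 4-D (frame, z, y, x)")
        if data.shape[0] != self.schedule.n_frames:
            raise ValueError(
                f"frame count {data.shape[0]} does not match schedule ({self.schedule.n_frames})"
            )
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive lengths")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        if np.any(data < 0):
            raise ValueError("activity concentrations must be non-negative")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def time_average(self, frame_window: tuple[float, float] | None = None) -> np.ndarray:
        """Duration-weighted mean image over frames overlapping the window.

        ``frame_window`` is a (t0, t1) time range in seconds; default is
        the final frame only.
        """
        if frame_window is None:
            return self.data[-1]
        t0, t1 = frame_window
        starts, ends = self.schedule.starts, self.schedule.ends
        overlap = np.minimum(ends, t1) - np.maximum(starts, t0)
        w = np.clip(overlap, 0.0, None)
        if w.sum() <= 0:
            raise ValueError(f"frame window {frame_window} overlaps no frame")
        return np.tensordot(w / w.sum(), self.data, axes=(0, 0))


@dataclass(frozen=True)
class ROIMask:
    """A set of (z, y, x) voxel indices, stored sorted for determinism."""

    indices: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        idx = np.atleast_2d(np.asarray(self.indices, dtype=np.intp))
        if idx.size == 0:
            raise ValueError("ROI must contain at least one voxel")
        if idx.shape[1] != 3:
            raise ValueError("indices must be (n, 3) triples")
        shape = tuple(int(s) for s in self.shape)
        if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
            raise ValueError("ROI indices outside volume bounds")
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        idx = idx[order]
        if np.any(np.all(np.diff(idx, axis=0) == 0, axis=1)):
            raise ValueError("duplicate voxels in ROI")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "shape", shape)

    @classmethod
    def from_boolean(cls, mask: np.ndarray) -> "ROIMask":
        return cls(np.argwhere(mask), mask.shape)

    def to_boolean(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[tuple(self.indices.T)] = True
        return out

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ROIMask):
            return NotImplemented
        return self.shape == other.shape and np.array_equal(self.indices, other.indices)


@dataclass(frozen=True)
class SUVRecord:
    """Static SUV summary of one ROI on one frame window."""

    suv_mean: float
    suv_max: float
    injected_dose_MBq: float
    body_weight_g: float
    frame_window: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.suv_max >= self.suv_mean >= 0.0):
            raise ValueError("require suv_max >= suv_mean >= 0")


def ellipsoid_roi(
    center: tuple[float, float, float],
    semi_axes_mm: tuple[float, float, float],
    volume: ImageVolume4D,
) -> ROIMask:
    """Voxels whose centers fall inside an ellipsoid.

    ``center`` is in voxel coordinates (z, y, x, may be fractional) and
    ``semi_axes_mm`` in millimetres per axis.  The manual-ROI stand-in.
    """
    if any(a <= 0 for a in semi_axes_mm):
        raise ValueError("semi-axes must be positive")
    nz, ny, nx = volume.spatial_shape
    vs = volume.voxel_size_mm
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    r2 = (
        ((zz - center[0]) * vs[0] / semi_axes_mm[0]) ** 2
        + ((yy - center[1]) * vs[1] / semi_axes_mm[1]) ** 2
        + ((xx - center[2]) * vs[2] / semi_axes_mm[2]) ** 2
    )
    inside = r2 <= 1.0 + 1e-12
    if not inside.any():
        raise ValueError("ellipsoid does not intersect the volume")
    return ROIMask.from_boolean(inside)


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def region_grow_refine(
    volume: ImageVolume4D,
    initial_roi: ROIMask,
    frame_window: tuple[float, float] | None = None,
    band: float = 0.40,
) -> ROIMask:
    """Refine a manual ROI by intensity-band region growing.

    On the time-averaged image over ``frame_window`` (default: last
    frame), the mean intensity m of the initial ROI defines the fixed
    acceptance band [(1-band) m, (1+band) m].  Growth starts from the
    hottest voxel of the initial ROI and proceeds by face (6-neighbor)
    connectivity through in-band voxels.  If even the seed lies outside
    the band the single seed voxel is returned with a warning.
    """
    img = volume.time_average(frame_window)
    roi_idx = tuple(initial_roi.indices.T)
    roi_vals = img[roi_idx]
    m = float(roi_vals.mean())
    seed = tuple(initial_roi.indices[int(np.argmax(roi_vals))])
    lo, hi = (1.0 - band) * m, (1.0 + band) * m
    in_band = (img >= lo) & (img <= hi)
    if not in_band[seed]:
        warnings.warn(
            "seed voxel intensity outside the acceptance band; returning the seed alone",
            stacklevel=2,
        )
        return ROIMask(np.array([seed]), initial_roi.shape)
    labels, _ = ndimage.label(in_band, structure=_FACE_STRUCTURE)
    grown = labels == labels[seed]
    return ROIMask.from_boolean(grown)


def extract_tac(volume: ImageVolume4D, roi: ROIMask) -> TimeActivityCurve:
    """Per-frame mean concentration over the ROI voxels."""
    if roi.shape != volume.spatial_shape:
        raise ValueError("ROI shape does not match the volume")
    z, y, x = roi.indices.T
    values = volume.data[:, z, y, x].mean(axis=1)
    return TimeActivityCurve(volume.schedule, values)


def compute_suv(concentration, injected_dose_MBq: float, body_weight_g: float):
    """SUV = concentration / (injected dose / body weight); dimensionless."""
    if injected_dose_MBq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    return np.asarray(concentration, dtype=float) / (injected_dose_MBq / body_weight_g)


def suvmax_static(
    volume: ImageVolume4D,
    roi: ROIMask,
    injected_dose_MBq: float,
    body_weight_g: float,
) -> SUVRecord:
    """SUVmax and SUVmean of the ROI on the final frame of the acquisition."""
    z, y, x = roi.indices.T
    suv = compute_suv(volume.data[-1, z, y, x], injected_dose_MBq, body_weight_g)
    window = (float(volume.schedule.starts[-1]), float(volume.schedule.ends[-1]))
    return SUVRecord(
        suv_mean=float(suv.mean()),
        suv_max=float(suv.max()),
        injected_dose_MBq=float(injected_dose_MBq),
        body_weight_g=float(body_weight_g),
        frame_window=window,
    )


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes with a JSON frame-schedule sidecar; masks as TSV
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_volume(volume: ImageVolume4D, path: str | Path) -> None:
    """Write a 4-D volume as NIfTI plus a JSON sidecar with frame times.

    NIfTI stores data as (x, y, z, t); the sidecar carries the frame
    starts/durations in seconds, which NIfTI has no native slot for.
    """
    import nibabel as nib

    path = Path(path)
    affine = np.diag([*reversed(volume.voxel_size_mm), 1.0])
    img = nib.Nifti1Image(np.transpose(volume.data, (3, 2, 1, 0)), affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    sidecar = {
        "frame_starts_s": volume.schedule.starts.tolist(),
        "frame_durations_s": volume.schedule.durations.tolist(),
        "units": "MBq/mL",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_volume(path: str | Path) -> ImageVolume4D:
    """Read a volume written by :func:`save_volume`."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar_path(path).read_text())
    schedule = FrameSchedule(
        np.asarray(meta["frame_starts_s"]), np.asarray(meta["frame_durations_s"])
    )
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (3, 2, 1, 0))
    voxel = tuple(float(v) for v in reversed(img.header.get_zooms()[:3]))
    return ImageVolume4D(data, voxel, schedule)


def save_mask_tsv(mask: ROIMask, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# shape\t{mask.shape[0]}\t{mask.shape[1]}\t{mask.shape[2]}\n")
        fh.write("z\ty\tx\n")
        for z, y, x in mask.indices:
            fh.write(f"{z}\t{y}\t{x}\n")


def load_mask_tsv(path: str | Path) -> ROIMask:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# shape"):
        raise ValueError("mask file missing '# shape' header line")
    shape = tuple(int(v) for v in lines[0].split("\t")[1:4])
    rows = [tuple(int(v) for v in ln.split("\t")) for ln in lines[2:] if ln.strip()]
    return ROIMask(np.asarray(rows, dtype=np.intp), shape)
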