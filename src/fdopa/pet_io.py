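"""Dynamic PET input/output and basic temporal operations.

Reads and writes 4D dynamic PET volumes (NIfTI-1) with a PET-BIDS-style
JSON frame-timing sidecar, applies radioisotope decay correction, builds
duration-weighted static (summed) images, and extracts regional
time-activity curves (TACs) from integer-label masks.

All times are handled internally in **minutes** (sidecars store seconds,
following PET-BIDS `FrameTimesStart` / `FrameDuration`); activities are
kBq/mL unless stated otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

_TIME_TOL = 1e-9


class SchemaError(ValueError):
    """Input files or sidecar metadata violate the expected schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame acquisition timing, in minutes since injection.

    Parameters
    ----------
    start : ndarray
        Frame start times (min), strictly increasing.
    duration : ndarray
        Frame durations (min), all positive; frames must not overlap.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or duration.shape != start.shape:
            raise SchemaError("start and duration must be 1D arrays of equal length")
        if start.size == 0:
            raise SchemaError("schedule must contain at least one frame")
        if not np.all(duration > 0):
            raise SchemaError("frame durations must be positive")
        if not np.all(np.diff(start) > 0):
            raise SchemaError("frame starts must be strictly increasing")
        if np.any(start[1:] < start[:-1] + duration[:-1] - _TIME_TOL):
            raise SchemaError("frames must not overlap")

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times (min): start + duration / 2."""
        return self.start + self.duration / 2.0

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def total_duration(self) -> float:
        """Sum of all frame durations (min)."""
        return float(self.duration.sum())

    def __len__(self) -> int:
        return int(self.start.size)

    @classmethod
    def from_durations(cls, durations_min: Sequence[float], t0: float = 0.0) -> "FrameSchedule":
        """Build a contiguous schedule from frame durations (minutes)."""
        duration = np.asarray(durations_min, dtype=float)
        start = t0 + np.concatenate([[0.0], np.cumsum(duration[:-1])])
        return cls(start=start, duration=duration)

    @classmethod
    def from_sidecar(cls, sidecar: Mapping) -> "FrameSchedule":
        """Build from a PET-BIDS-style dict with times in **seconds**."""
        try:
            start_s = np.asarray(sidecar["FrameTimesStart"], dtype=float)
            dur_s = np.asarray(sidecar["FrameDuration"], dtype=float)
        except KeyError as exc:
            raise SchemaError(f"timing sidecar missing field: {exc}") from exc
        if start_s.shape != dur_s.shape:
            raise SchemaError(
                "FrameTimesStart and FrameDuration have different lengths "
                f"({start_s.size} vs {dur_s.size})"
            )
        return cls(start=start_s / 60.0, duration=dur_s / 60.0)

    def to_sidecar(self) -> dict:
        """PET-BIDS-style dict, times in seconds."""
        return {
            "FrameTimesStart": (self.start * 60.0).tolist(),
            "FrameDuration": (self.duration * 60.0).tolist(),
        }


@dataclass(frozen=True)
class DynamicImage:
    """4D dynamic PET series: (x, y, z, frame) activity plus geometry."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    schedule: FrameSchedule
    decay_corrected: bool = False
    units: str = "kBq/mL"
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "voxel_size", vs)
        if data.ndim != 4:
            raise SchemaError(f"dynamic image must be 4D, got shape {data.shape}")
        if data.shape[3] != len(self.schedule):
            raise SchemaError(
                f"frame axis length {data.shape[3]} does not match "
                f"schedule length {len(self.schedule)}"
            )
        if any(v <= 0 for v in vs):
            raise SchemaError("voxel sizes must be positive")
        if not np.all(np.isfinite(data)):
            raise SchemaError("activity values must be finite")
        if self.affine is None:
            aff = np.diag([vs[0], vs[1], vs[2], 1.0])
            object.__setattr__(self, "affine", aff)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def frame(self, i: int) -> np.ndarray:
        return self.data[..., i]


@dataclass(frozen=True)
class LabelVolume:
    """Integer-label ROI volume aligned to a DynamicImage grid.

    Label 0 is background; ``names`` maps each named region to its label.
    """

    labels: np.ndarray
    names: Mapping[str, int]

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise SchemaError("label volume must be integer-valued")
            labels = np.round(labels).astype(np.int32)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 3:
            raise SchemaError("label volume must be 3D")
        present = set(np.unique(labels).tolist())
        for name, lab in self.names.items():
            if lab == 0:
                raise SchemaError(f"region {name!r} maps to background label 0")
            if lab not in present:
                raise SchemaError(f"named label {lab} ({name!r}) absent from grid")

    def mask(self, region: str) -> np.ndarray:
        if region not in self.names:
            raise KeyError(f"unknown region {region!r}; have {sorted(self.names)}")
        return self.labels == self.names[region]


@dataclass(frozen=True)
class TimeActivityCurve:
    """Regional mean activity per frame, sampled at frame mid-times."""

    mid: np.ndarray
    value: np.ndarray
    region: str = ""

    def __post_init__(self):
        mid = np.asarray(self.mid, dtype=float)
        value = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "mid", mid)
        object.__setattr__(self, "value", value)
        if mid.shape != value.shape or mid.ndim != 1:
            raise SchemaError("mid and value must be 1D arrays of equal length")
        if mid.size >= 2 and not np.all(np.diff(mid) > 0):
            raise SchemaError("mid-times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.mid.size)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_dynamic(image_path: str | Path, timing_path: str | Path) -> DynamicImage:
    """Read a 4D NIfTI dynamic series plus its JSON timing sidecar.

    The sidecar must carry PET-BIDS ``FrameTimesStart`` and
    ``FrameDuration`` in seconds; these are converted to minutes.  An
    optional boolean ``DecayCorrected`` field is honoured (default False).
    """
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise SchemaError(f"{image_path}: expected 4D image, got {data.ndim}D")
    with open(timing_path) as fh:
        sidecar = json.load(fh)
    schedule = FrameSchedule.from_sidecar(sidecar)
    if data.shape[3] != len(schedule):
        raise SchemaError(
            f"{image_path}: {data.shape[3]} frames but sidecar describes "
            f"{len(schedule)}"
        )
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(
        data=data,
        voxel_size=tuple(float(z) for z in zooms),
        schedule=schedule,
        decay_corrected=bool(sidecar.get("DecayCorrected", False)),
        units=str(sidecar.get("Units", "kBq/mL")),
        affine=np.asarray(img.affine, dtype=float),
    )


def write_dynamic(img: DynamicImage, image_path: str | Path, timing_path: str | Path,
                  extra_sidecar: Mapping | None = None) -> None:
    """Write a DynamicImage as NIfTI + JSON sidecar (inverse of read_dynamic)."""
    nifti = nib.Nifti1Image(img.data.astype(np.float32), img.affine)
    nifti.header.set_zooms(img.voxel_size + (1.0,))
    nib.save(nifti, str(image_path))
    sidecar = img.schedule.to_sidecar()
    sidecar["DecayCorrected"] = bool(img.decay_corrected)
    sidecar["Units"] = img.units
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    with open(timing_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_labels(label_path: str | Path, names: Mapping[str, int]) -> LabelVolume:
    """Read an integer-label NIfTI volume."""
    img = nib.load(str(label_path))
    labels = np.asanyarray(img.dataobj)
    return LabelVolume(labels=labels, names=dict(names))


def write_labels(labels: LabelVolume, label_path: str | Path,
                 affine: np.ndarray | None = None) -> None:
    aff = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), aff), str(label_path))


def write_volume(volume: np.ndarray, path: str | Path,
                 affine: np.ndarray | None = None) -> None:
    """Write a 3D volume (e.g. a parametric map) as NIfTI."""
    aff = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), aff), str(path))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def decay_correct(img: DynamicImage, half_life: float = F18_HALF_LIFE_MIN) -> DynamicImage:
    """Correct measured activity back to injection time (t = 0).

    Each frame is multiplied by ``2**(mid / half_life)`` using its
    mid-time.  Refuses to run twice on the same image.
    """
    if img.decay_corrected:
        raise ValueError("image is already decay-corrected; refusing to double-correct")
    if half_life <= 0:
        raise ValueError("half-life must be positive")
    factors = np.exp2(img.schedule.mid / half_life)
    data = img.data * factors[np.newaxis, np.newaxis, np.newaxis, :]
    return replace(img, data=data, decay_corrected=True)


def undo_decay_correct(img: DynamicImage, half_life: float = F18_HALF_LIFE_MIN) -> DynamicImage:
    """Inverse of :func:`decay_correct` (mainly for round-trip checks)."""
    if not img.decay_corrected:
        raise ValueError("image is not decay-corrected")
    factors = np.exp2(-img.schedule.mid / half_life)
    data = img.data * factors[np.newaxis, np.newaxis, np.newaxis, :]
    return replace(img, data=data, decay_corrected=False)


def _frames_in_window(schedule: FrameSchedule,
                      window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones(len(schedule), dtype=bool)
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError(f"empty window ({lo}, {hi})")
    mid = schedule.mid
    sel = (mid >= lo) & (mid <= hi)
    if not sel.any():
        raise ValueError(f"window ({lo}, {hi}) min contains no frame mid-times")
    return sel


def sum_frames(img: DynamicImage, window: tuple[float, float] | None = None) -> np.ndarray:
    """Duration-weighted sum of frames whose mid-time falls in ``window``.

    With ``window=None`` the whole scan is summed (the "static" image).
    A frame belongs to the window when its mid-time lies inside it.
    """
    sel = _frames_in_window(img.schedule, window)
    weights = img.schedule.duration[sel]
    return np.tensordot(img.data[..., sel], weights, axes=([3], [0]))


def extract_tac(img: DynamicImage, labels: LabelVolume, region: str) -> TimeActivityCurve:
    """Per-frame mean activity over the voxels of a named region."""
    if labels.labels.shape != img.shape3d:
        raise SchemaError(
            f"label grid {labels.labels.shape} does not match image {img.shape3d}"
        )
    mask = labels.mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    values = img.data[mask].mean(axis=0)
    return TimeActivityCurve(mid=img.schedule.mid, value=values, region=region)


def tacs_to_frame(tacs: Sequence[TimeActivityCurve]) -> pd.DataFrame:
    """Long-format TAC table: region, frame, mid_min, activity."""
    rows = []
    for tac in tacs:
        for i, (m, v) in enumerate(zip(tac.mid, tac.value)):
            rows.append({"region": tac.region, "frame": i,
                         "mid_min": m, "activity": v})
    return pd.DataFrame(rows)


def export_tacs_csv(tacs: Sequence[TimeActivityCurve], path: str | Path) -> None:
    tacs_to_frame(tacs).to_csv(path, index=False)
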