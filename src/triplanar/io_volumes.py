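"""Reading and writing of 4D fMRI volumes, block schedules and labeled samples.

The on-disk formats are deliberately plain:

* volumes are NIfTI-1 (``.nii`` / ``.nii.gz``), read with nibabel;
* block schedules are 3-column tab-separated files with a header line
  ``start_frame  n_frames  label`` — times are 0-based frame indices and
  every block covers the half-open interval ``[start, start + n)``;
* extracted samples travel in a single HDF5 file holding one dataset of
  volumes, one of labels and one of subject ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

#: Label used for rest/baseline blocks.
FIXATION = "FIXATION"

#: The five movement classes, in canonical order: left hand, right hand,
#: left foot, right foot, tongue.
MOVEMENT_CLASSES = ("LH", "RH", "LF", "RF", "T")

ALL_LABELS = (FIXATION,) + MOVEMENT_CLASSES


class VolumeIOError(Exception):
    """Base class for volume / schedule reading failures."""


class NotA4DImageError(VolumeIOError):
    """The NIfTI file does not contain a 4-dimensional image."""


class HeaderReadError(VolumeIOError):
    """The NIfTI header could not be parsed."""


class ScheduleError(ValueError):
    """A block schedule file or block list is invalid."""


@dataclass
class Volume4D:
    """A time series of 3D brain volumes.

    ``data`` has shape ``(dimX, dimY, dimZ, T)`` in native scanner units
    (header scaling already applied); ``affine`` is the 4x4 voxel-to-world
    transform; ``subject_id`` is an opaque identifier.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise NotA4DImageError(
                f"expected 4D data, got {self.data.ndim}D shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxel values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class Block:
    """One schedule entry: frames ``[start, start + n_frames)`` with a label."""

    start: int
    n_frames: int
    label: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ScheduleError(f"negative start frame {self.start}")
        if self.n_frames < 1:
            raise ScheduleError(f"block length must be >= 1, got {self.n_frames}")
        if self.label not in ALL_LABELS:
            raise ScheduleError(
                f"unknown label {self.label!r}; allowed: {', '.join(ALL_LABELS)}"
            )

    @property
    def stop(self) -> int:
        return self.start + self.n_frames

    @property
    def frames(self) -> range:
        return range(self.start, self.stop)


@dataclass
class BlockSchedule:
    """An ordered, non-overlapping list of blocks within ``[0, T)``."""

    blocks: list[Block]
    n_frames_total: int | None = None

    def __post_init__(self) -> None:
        self.blocks = [b if isinstance(b, Block) else Block(*b) for b in self.blocks]
        ordered = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.stop:
                raise ScheduleError(
                    f"blocks overlap: [{a.start},{a.stop}) and [{b.start},{b.stop})"
                )
        if self.n_frames_total is not None:
            for b in self.blocks:
                if b.stop > self.n_frames_total:
                    raise ScheduleError(
                        f"block [{b.start},{b.stop}) extends past T={self.n_frames_total}"
                    )

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def fixation_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.label == FIXATION]

    @property
    def movement_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.label != FIXATION]


@dataclass
class Sample3D:
    """One block-collapsed 3D volume with its movement label and subject id."""

    volume: np.ndarray
    label: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        if self.volume.ndim != 3:
            raise ValueError(f"sample must be 3D, got shape {self.volume.shape}")
        if self.label not in MOVEMENT_CLASSES:
            raise ValueError(f"sample label must be a movement class, got {self.label!r}")


def load_volume4d(path: str | Path, subject_id: str = "") -> Volume4D:
    """Load a 4D NIfTI file, applying any header scaling.

    Raises :class:`FileNotFoundError`, :class:`NotA4DImageError` or
    :class:`HeaderReadError` for the distinct failure modes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        shape = img.shape
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise HeaderReadError(f"cannot read NIfTI header of {path}: {exc}") from exc
    if len(shape) != 4:
        raise NotA4DImageError(f"{path} has {len(shape)} dimensions, expected 4")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return Volume4D(data=data, affine=np.asarray(img.affine), subject_id=subject_id)


def save_volume4d(vol: Volume4D, path: str | Path) -> None:
    """Write a Volume4D as NIfTI-1 (gzip if the suffix says so)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, str(Path(path)))


def load_block_schedule(path: str | Path, n_frames_total: int | None = None) -> BlockSchedule:
    """Parse a tab-separated schedule file (header ``start_frame n_frames label``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    required = {"start_frame", "n_frames", "label"}
    if not required.issubset(df.columns):
        raise ScheduleError(
            f"schedule {path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    blocks = [
        Block(int(r.start_frame), int(r.n_frames), str(r.label).strip())
        for r in df.itertuples(index=False)
    ]
    return BlockSchedule(blocks=blocks, n_frames_total=n_frames_total)


def save_block_schedule(schedule: BlockSchedule, path: str | Path) -> None:
    df = pd.DataFrame(
        [(b.start, b.n_frames, b.label) for b in schedule],
        columns=["start_frame", "n_frames", "label"],
    )
    df.to_csv(Path(path), sep="\t", index=False)


def save_samples(samples: list[Sample3D], path: str | Path) -> None:
    """Write samples to one HDF5 file (datasets: volumes, labels, subject_ids)."""
    shapes = {s.volume.shape for s in samples}
    if len(shapes) > 1:
        raise ValueError(f"samples have mixed shapes: {sorted(shapes)}")
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(Path(path), "w") as f:
        if samples:
            vols = np.stack([s.volume for s in samples]).astype(np.float32)
        else:
            vols = np.zeros((0, 0, 0, 0), dtype=np.float32)
        f.create_dataset("volumes", data=vols, compression="gzip")
        f.create_dataset("labels", data=[s.label for s in samples], dtype=str_dt)
        f.create_dataset("subject_ids", data=[s.subject_id for s in samples], dtype=str_dt)


def load_samples(path: str | Path) -> list[Sample3D]:
    """Inverse of :func:`save_samples`; preserves order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for key in ("volumes", "labels", "subject_ids"):
            if key not in f:
                raise VolumeIOError(f"{path} is not a sample container (missing {key!r})")
        vols = f["volumes"][...]
        labels = [x.decode() if isinstance(x, bytes) else str(x) for x in f["labels"][...]]
        sids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["subject_ids"][...]]
    return [Sample3D(v, lab, sid) for v, lab, sid in zip(vols, labels, sids)]


def save_metrics_csv(rows: list[dict], path: str | Path) -> None:
    """Write per-fold metrics as CSV with columns fold, model, accuracy, precision, f1."""
    pd.DataFrame(rows, columns=["fold", "model", "accuracy", "precision", "f1"]).to_csv(
        Path(path), index=False
    )
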