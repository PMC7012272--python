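"""Deterministic transforms from a 3D sample to each model family's input.

A volume of shape ``(dimX, dimY, dimZ)`` (array axes 0, 1, 2) can be:

* sliced along one axis into a channels-last multichannel 2D image
  (:func:`to_planar_stack`), one slice per channel;
* sliced along all three axes at once (:func:`to_triplanar`), yielding the
  three orthogonal-plane stacks used by the parallel-branch model;
* averaged along axis 2 into a single-channel 2D image
  (:func:`to_mean_value_2d`);
* unrolled into a vector sequence (:func:`to_sequence_1d`) by taking the
  axis-2 slices in order and concatenating them along axis 1, so step
  ``s = z * dimY + y`` carries the ``dimX`` voxels at that (y, z);
* flattened row-major into one long vector (:func:`flatten_for_svm`).

All transforms except the mean projection are permutations of the voxels
and therefore lossless; :func:`reconstruct_from_stack` inverts a stack.

The anatomical names of the three axes (coronal / sagittal / axial) are
used inconsistently across the imaging literature; internally everything
is addressed by array axis index, and anatomical labels appear only in
user-facing help with that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AXIS_NAMES = ("x", "y", "z")


def _check3d(sample: np.ndarray) -> np.ndarray:
    sample = np.asarray(sample)
    if sample.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {sample.shape}")
    return sample


@dataclass
class PlanarStack:
    """Channels-last 2D image ``(H, W, C)``; channel c is the slice at axis=c."""

    data: np.ndarray
    axis: str  # which source axis became the channel axis: "x" | "y" | "z"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class TriplanarInput:
    """The three orthogonal-plane stacks of one volume.

    ``stack_x``: channels along axis 0, image ``(dimY, dimZ)``;
    ``stack_y``: channels along axis 1, image ``(dimX, dimZ)``;
    ``stack_z``: channels along axis 2, image ``(dimX, dimY)``.
    """

    stack_x: PlanarStack
    stack_y: PlanarStack
    stack_z: PlanarStack

    def __iter__(self):
        return iter((self.stack_x, self.stack_y, self.stack_z))


def to_planar_stack(sample: np.ndarray, axis: int | str) -> PlanarStack:
    """Slice along ``axis``, stacking the slices as trailing channels."""
    sample = _check3d(sample)
    if isinstance(axis, str):
        axis = AXIS_NAMES.index(axis)
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    data = np.moveaxis(sample, axis, -1)
    return PlanarStack(data=np.ascontiguousarray(data), axis=AXIS_NAMES[axis])


def reconstruct_from_stack(stack: PlanarStack) -> np.ndarray:
    """Invert :func:`to_planar_stack` exactly."""
    axis = AXIS_NAMES.index(stack.axis)
    return np.ascontiguousarray(np.moveaxis(stack.data, -1, axis))


def to_triplanar(sample: np.ndarray) -> TriplanarInput:
    """All three planar stacks of one volume."""
    sample = _check3d(sample)
    return TriplanarInput(
        stack_x=to_planar_stack(sample, 0),
        stack_y=to_planar_stack(sample, 1),
        stack_z=to_planar_stack(sample, 2),
    )


def to_axial_stack(sample: np.ndarray) -> PlanarStack:
    """The axis-2 stack alone: image ``(dimX, dimY)`` with ``dimZ`` channels."""
    return to_planar_stack(sample, 2)


def to_mean_value_2d(sample: np.ndarray) -> np.ndarray:
    """Average along axis 2: a single-channel ``(dimX, dimY)`` image."""
    return _check3d(sample).mean(axis=2)


def to_sequence_1d(sample: np.ndarray) -> np.ndarray:
    """Unroll into a ``(dimY * dimZ, dimX)`` vector sequence.

    The axis-2 slices are taken in z order and concatenated along axis 1,
    so sequence step ``s = z * dimY + y`` holds feature vector
    ``sample[:, y, z]``.
    """
    sample = _check3d(sample)
    dim_x, dim_y, dim_z = sample.shape
    # (z, y, x) ordering then collapse (z, y) -> steps
    seq = np.transpose(sample, (2, 1, 0)).reshape(dim_z * dim_y, dim_x)
    return np.ascontiguousarray(seq)


def flatten_for_svm(sample: np.ndarray) -> np.ndarray:
    """Row-major (C-order) flattening to a vector of length dimX*dimY*dimZ."""
    return _check3d(sample).reshape(-1)
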