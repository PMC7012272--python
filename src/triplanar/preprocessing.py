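"""Collapse block-design 4D volumes into labeled 3D samples.

Each movement block of a run is reduced to a single 3D image by mean
percent signal change (PSC) against a per-voxel baseline estimated from the
fixation (rest) blocks:

    p[v] = (sum_i y_i[v]) / (ybar[v] * N) * 100

where the sum runs over the N frames of the block, y_i is the voxel value
in the i-th block frame and ybar is the mean of that voxel over all
fixation frames.  Note the ratio convention: a block identical to baseline
scores 100, not 0.  ``psc_convention="centered"`` subtracts 100 to obtain
the conventional (y - ybar)/ybar * 100 definition.

Voxels whose baseline magnitude falls below ``eps`` (typically the air
background outside the head, where the baseline is exactly zero) are set
to 0 and recorded in a mask so callers can report how much of the volume
was unusable.

After extraction, samples are standardized voxel-wise (z-scored) across
the sample axis; voxels with (population) standard deviation below ``eps``
are left at zero after centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_volumes import Block, BlockSchedule, Sample3D, Volume4D

#: Baseline magnitudes below this are treated as "no signal" voxels.
BASELINE_EPS = 1e-8

#: Standard deviations below this are treated as constant voxels.
STD_EPS = 1e-8

PSC_CONVENTIONS = ("ratio", "centered")


class NoFixationError(ValueError):
    """Baseline requested but the schedule has no fixation blocks."""


@dataclass
class BaselineVolume:
    """Per-voxel mean over all frames of all fixation blocks (pooled)."""

    ybar: np.ndarray
    n_frames: int  # number of fixation frames averaged


@dataclass
class NormalizationStats:
    """Per-voxel mean/std for z-scoring, plus which samples they came from."""

    mean: np.ndarray
    std: np.ndarray
    source: str = "all_samples"  # or "train_only"

    @property
    def constant_mask(self) -> np.ndarray:
        """Voxels whose std is below the guard epsilon (flagged, left at 0)."""
        return self.std < STD_EPS


def compute_baseline(vol: Volume4D, schedule: BlockSchedule) -> BaselineVolume:
    """Pool all fixation frames and average per voxel."""
    fix = schedule.fixation_blocks
    if not fix:
        raise NoFixationError("schedule contains no FIXATION block")
    idx = np.concatenate([np.arange(b.start, b.stop) for b in fix])
    ybar = vol.data[..., idx].mean(axis=-1)
    return BaselineVolume(ybar=ybar, n_frames=len(idx))


def mean_psc(
    vol: Volume4D,
    block: Block,
    baseline: BaselineVolume,
    *,
    eps: float = BASELINE_EPS,
    psc_convention: str = "ratio",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean percent signal change of one movement block.

    Returns ``(p, zero_baseline_mask)`` where ``p`` has the volume's spatial
    shape and the mask flags voxels forced to 0 by the baseline guard.
    """
    if psc_convention not in PSC_CONVENTIONS:
        raise ValueError(f"psc_convention must be one of {PSC_CONVENTIONS}")
    ybar = baseline.ybar
    block_sum = vol.data[..., block.start : block.stop].sum(axis=-1)
    bad = np.abs(ybar) < eps
    denom = np.where(bad, 1.0, ybar) * block.n_frames
    p = block_sum / denom * 100.0
    p[bad] = 0.0
    if psc_convention == "centered":
        p = p - 100.0
        p[bad] = 0.0
    return p, bad


def extract_samples(
    vol: Volume4D,
    schedule: BlockSchedule,
    *,
    psc_convention: str = "ratio",
    eps: float = BASELINE_EPS,
) -> list[Sample3D]:
    """One Mean-PSC sample per movement block; fixation blocks yield none."""
    movement = schedule.movement_blocks
    if not movement:
        return []
    baseline = compute_baseline(vol, schedule)
    out = []
    for block in movement:
        p, _ = mean_psc(vol, block, baseline, eps=eps, psc_convention=psc_convention)
        out.append(Sample3D(volume=p, label=block.label, subject_id=vol.subject_id))
    return out


def fit_normalization(samples: list[Sample3D], source: str = "all_samples") -> NormalizationStats:
    """Per-voxel mean and population (divide-by-n) std across samples."""
    if not samples:
        raise ValueError("cannot fit normalization on an empty sample list")
    stack = np.stack([s.volume for s in samples])
    return NormalizationStats(
        mean=stack.mean(axis=0), std=stack.std(axis=0, ddof=0), source=source
    )


def apply_normalization(
    samples: list[Sample3D], stats: NormalizationStats
) -> list[Sample3D]:
    """Z-score each sample; near-constant voxels end up exactly 0."""
    safe_std = np.where(stats.constant_mask, 1.0, stats.std)
    out = []
    for s in samples:
        if s.volume.shape != stats.mean.shape:
            raise ValueError(
                f"sample shape {s.volume.shape} != stats shape {stats.mean.shape}"
            )
        z = (s.volume - stats.mean) / safe_std
        z[stats.constant_mask] = 0.0
        out.append(Sample3D(volume=z, label=s.label, subject_id=s.subject_id))
    return out
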