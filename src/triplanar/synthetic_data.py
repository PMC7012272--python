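"""Synthetic block-design motor-task fMRI generator.

Each generated subject is a 4D volume with the canonical motor-task run
structure: 3 fixation (rest) blocks interleaved with 10 movement blocks,
two per movement class (left hand, right hand, left foot, right foot,
tongue), every block ``frames_per_block`` frames long.  The movement-block
order is shuffled per subject.

The spatial model is deliberately simple:

* a soft-edged ellipsoidal "brain" occupies the middle of the grid; its
  baseline intensity tapers from ``baseline_intensity`` at the centre to
  30% of it at the rim, and is exactly 0 outside (so the zero-baseline
  guard of the percent-signal-change step is exercised, as it is by the
  air background of real scans);
* each class has a fixed spherical region of interest (ROI) of radius
  ``roi_radius``; during that class's movement blocks every ROI voxel is
  scaled by ``1 + amplitude_pct/100``;
* every frame receives i.i.d. Gaussian noise of sd ``noise_sd`` and every
  subject a log-normal global intensity multiplier of log-sd
  ``subject_effect_sd`` (which mean-PSC cancels exactly, as it does the
  scanner-gain differences it mimics).

With ``noise_sd=0`` the mean-PSC samples equal ``100 + amplitude_pct``
inside the class ROI and 100 elsewhere in the brain — the closed form used
throughout the tests.

What this generator does NOT emulate: hemodynamic lag/convolution,
temporal autocorrelation, motion, physiological noise, anatomical
variability.  Passing on it demonstrates pipeline correctness, not
real-data performance.

Generation is fully deterministic given ``(cfg.seed, subject_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_volumes import (
    FIXATION,
    MOVEMENT_CLASSES,
    Block,
    BlockSchedule,
    Sample3D,
    Volume4D,
)
from .preprocessing import extract_samples

#: Fixed per-class ROI centres, as fractions of each grid dimension.
ROI_CENTER_FRACTIONS = {
    "LH": (0.30, 0.38, 0.45),
    "RH": (0.70, 0.38, 0.45),
    "LF": (0.34, 0.66, 0.60),
    "RF": (0.66, 0.66, 0.60),
    "T": (0.50, 0.45, 0.28),
}

#: Block layout of one run: 3 fixation blocks interleaved with 10 movement slots.
_BLOCK_LAYOUT = ("F", "M", "M", "M", "M", "F", "M", "M", "M", "F", "M", "M", "M")


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition knobs of the generator (defaults are the shipped regime)."""

    dims: tuple[int, int, int] = (24, 28, 24)
    frames_per_block: int = 12
    amplitude_pct: float = 30.0  # percent signal change inside the active ROI
    noise_sd: float = 1.0  # additive Gaussian sd, per frame per voxel
    subject_effect_sd: float = 0.1  # log-sd of the per-subject gain multiplier
    roi_radius: float = 3.0  # voxels
    baseline_intensity: float = 1000.0
    seed: int = 7
    roi_centers: dict = field(default_factory=lambda: dict(ROI_CENTER_FRACTIONS))

    @property
    def n_frames_total(self) -> int:
        return len(_BLOCK_LAYOUT) * self.frames_per_block


def brain_mask_and_baseline(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Soft-edged ellipsoid: strictly positive baseline inside, 0 outside."""
    grids = np.meshgrid(*[np.arange(d) for d in cfg.dims], indexing="ij")
    r2 = sum(
        (((g - (d - 1) / 2.0) / (0.45 * d)) ** 2) for g, d in zip(grids, cfg.dims)
    )
    m = np.clip(1.0 - r2, 0.0, None)
    mask = m > 0
    baseline = np.where(mask, cfg.baseline_intensity * (0.3 + 0.7 * m), 0.0)
    return mask, baseline


def class_roi_mask(cfg: SynthConfig, label: str) -> np.ndarray:
    """Boolean sphere of radius ``roi_radius`` at the class's fixed centre."""
    if label not in cfg.roi_centers:
        raise ValueError(f"no ROI defined for label {label!r}")
    center = [f * (d - 1) for f, d in zip(cfg.roi_centers[label], cfg.dims)]
    grids = np.meshgrid(*[np.arange(d) for d in cfg.dims], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    roi = d2 <= cfg.roi_radius**2
    brain, _ = brain_mask_and_baseline(cfg)
    if not roi.any():
        raise ValueError(f"ROI for {label} is empty at radius {cfg.roi_radius}")
    if not (roi <= brain).all():
        raise ValueError(f"ROI for {label} extends outside the brain mask")
    return roi


def make_schedule(cfg: SynthConfig, rng: np.random.Generator) -> BlockSchedule:
    """The 13-block layout with a per-subject shuffle of the movement order."""
    movement = list(MOVEMENT_CLASSES) * 2
    order = rng.permutation(len(movement))
    movement = [movement[i] for i in order]
    blocks, m = [], iter(movement)
    for i, slot in enumerate(_BLOCK_LAYOUT):
        label = FIXATION if slot == "F" else next(m)
        blocks.append(Block(i * cfg.frames_per_block, cfg.frames_per_block, label))
    return BlockSchedule(blocks=blocks, n_frames_total=cfg.n_frames_total)


def generate_subject(cfg: SynthConfig, subject_index: int) -> tuple[Volume4D, BlockSchedule]:
    """One subject's 4D run and its schedule, deterministic in (seed, index)."""
    rng = np.random.default_rng([cfg.seed, subject_index])
    schedule = make_schedule(cfg, rng)
    _, baseline = brain_mask_and_baseline(cfg)
    rois = {lab: class_roi_mask(cfg, lab) for lab in MOVEMENT_CLASSES}
    gain = float(np.exp(cfg.subject_effect_sd * rng.standard_normal()))
    data = np.empty(cfg.dims + (cfg.n_frames_total,), dtype=np.float64)
    for block in schedule:
        signal = baseline * gain
        if block.label != FIXATION:
            signal = signal * (1.0 + (cfg.amplitude_pct / 100.0) * rois[block.label])
        frames = signal[..., None] + cfg.noise_sd * rng.standard_normal(
            cfg.dims + (block.n_frames,)
        )
        data[..., block.start : block.stop] = frames
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    vol = Volume4D(data=data, affine=affine, subject_id=f"sub-{subject_index:03d}")
    return vol, schedule


def generate_dataset(cfg: SynthConfig, n_subjects: int) -> list[tuple[Volume4D, BlockSchedule]]:
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return [generate_subject(cfg, i) for i in range(n_subjects)]


def generate_samples(cfg: SynthConfig, n_subjects: int, **extract_kwargs) -> list[Sample3D]:
    """Generate subjects and collapse them straight to labeled mean-PSC samples."""
    samples: list[Sample3D] = []
    for vol, schedule in generate_dataset(cfg, n_subjects):
        samples.extend(extract_samples(vol, schedule, **extract_kwargs))
    return samples
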