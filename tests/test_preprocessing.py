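import numpy as np
import pytest

from triplanar.io_volumes import Block, BlockSchedule, Sample3D, Volume4D
from triplanar.preprocessing import (
    NoFixationError,
    apply_normalization,
    compute_baseline,
    extract_samples,
    fit_normalization,
    mean_psc,
)


def _volume(frames):
    """Stack per-frame 3D arrays (lists of scalars are broadcast to 1x1x1)."""
    arr = np.array(frames, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None, None, None]
    return Volume4D(data=np.moveaxis(arr, 0, -1))


class TestBaseline:
    def test_constant_fixation_gives_constant_baseline(self):
        vol = _volume([3.0] * 4 + [9.0] * 2)
        sched = BlockSchedule([Block(0, 4, "FIXATION"), Block(4, 2, "LH")])
        base = compute_baseline(vol, sched)
        np.testing.assert_array_equal(base.ybar, 3.0)
        assert base.n_frames == 4

    def test_mean_over_pooled_fixation_frames(self):
        # fixation values 2 and 4 (in two separate blocks) -> ybar = 3
        vol = _volume([2.0, 7.0, 4.0])
        sched = BlockSchedule(
            [Block(0, 1, "FIXATION"), Block(1, 1, "LH"), Block(2, 1, "FIXATION")]
        )
        np.testing.assert_array_equal(compute_baseline(vol, sched).ybar, 3.0)

    def test_single_frame_fixation_is_identity(self, rng):
        frame = rng.random((3, 4, 2))
        data = np.stack([frame, frame * 2], axis=-1)
        sched = BlockSchedule([Block(0, 1, "FIXATION"), Block(1, 1, "RH")])
        base = compute_baseline(Volume4D(data=data), sched)
        np.testing.assert_array_equal(base.ybar, frame)

    def test_no_fixation_raises(self):
        vol = _volume([1.0, 2.0])
        with pytest.raises(NoFixationError):
            compute_baseline(vol, BlockSchedule([Block(0, 2, "LH")]))


class TestMeanPSC:
    def test_block_equal_to_baseline_scores_100(self, rng):
        frame = 1.0 + rng.random((3, 3, 3))
        data = np.stack([frame] * 5, axis=-1)
        vol = Volume4D(data=data)
        sched = BlockSchedule([Block(0, 2, "FIXATION"), Block(2, 3, "LH")])
        base = compute_baseline(vol, sched)
        p, bad = mean_psc(vol, sched.blocks[1], base)
        np.testing.assert_allclose(p, 100.0)
        assert not bad.any()

    def test_worked_arithmetic_ratio_and_centered(self):
        # block frames [2, 4], baseline 2: (2+4)/(2*2)*100 = 150
        vol = _volume([2.0, 2.0, 4.0])
        sched = BlockSchedule([Block(0, 1, "FIXATION"), Block(1, 2, "LH")])
        base = compute_baseline(vol, sched)
        p, _ = mean_psc(vol, sched.blocks[1], base)
        np.testing.assert_allclose(p, 150.0)
        p_c, _ = mean_psc(vol, sched.blocks[1], base, psc_convention="centered")
        np.testing.assert_allclose(p_c, 50.0)

    def test_zero_block_scores_zero(self):
        vol = _volume([5.0, 0.0, 0.0])
        sched = BlockSchedule([Block(0, 1, "FIXATION"), Block(1, 2, "LH")])
        p, _ = mean_psc(vol, sched.blocks[1], compute_baseline(vol, sched))
        np.testing.assert_allclose(p, 0.0)

    def test_zero_baseline_guard_masks_voxel(self):
        data = np.zeros((2, 1, 1, 2))
        data[0, 0, 0] = [4.0, 8.0]  # voxel 1 has baseline exactly 0
        vol = Volume4D(data=data)
        sched = BlockSchedule([Block(0, 1, "FIXATION"), Block(1, 1, "RH")])
        p, bad = mean_psc(vol, sched.blocks[1], compute_baseline(vol, sched))
        assert p[0, 0, 0] == pytest.approx(200.0)
        assert p[1, 0, 0] == 0.0
        assert bad[1, 0, 0] and not bad[0, 0, 0]

    def test_joint_scale_equivariance(self, rng):
        """Scaling all frames and the baseline by c > 0 leaves p unchanged."""
        data = 1.0 + rng.random((3, 3, 2, 6))
        sched = BlockSchedule([Block(0, 3, "FIXATION"), Block(3, 3, "T")])
        vol = Volume4D(data=data)
        scaled = Volume4D(data=data * 7.5)
        p1, _ = mean_psc(vol, sched.blocks[1], compute_baseline(vol, sched))
        p2, _ = mean_psc(scaled, sched.blocks[1], compute_baseline(scaled, sched))
        np.testing.assert_allclose(p1, p2, rtol=1e-12)


class TestExtractSamples:
    def test_motor_schedule_yields_10_samples_2_per_class(self, small_volume, motor_schedule):
        samples = extract_samples(small_volume, motor_schedule)
        assert len(samples) == 10
        labels = sorted(s.label for s in samples)
        assert labels == sorted(["LH", "RH", "LF", "RF", "T"] * 2)
        assert all(s.subject_id == "sub-000" for s in samples)
        assert all(s.volume.shape == small_volume.spatial_shape for s in samples)

    def test_fixation_only_schedule_yields_nothing(self, small_volume):
        sched = BlockSchedule([Block(0, 5, "FIXATION")])
        assert extract_samples(small_volume, sched) == []


class TestNormalization:
    def test_two_samples_z_score_to_plus_minus_one(self):
        a = Sample3D(np.full((2, 2, 2), 1.0), "LH")
        b = Sample3D(np.full((2, 2, 2), 3.0), "RH")
        stats = fit_normalization([a, b])
        out = apply_normalization([a, b], stats)
        np.testing.assert_allclose(out[0].volume, -1.0)  # population std = 1
        np.testing.assert_allclose(out[1].volume, 1.0)

    def test_single_sample_zeroed_by_std_guard(self, rng):
        s = Sample3D(rng.random((3, 3, 3)), "LF")
        out = apply_normalization([s], fit_normalization([s]))
        np.testing.assert_array_equal(out[0].volume, 0.0)

    def test_already_standard_data_unchanged(self, rng):
        vols = rng.standard_normal((5, 3, 3, 3))
        vols = (vols - vols.mean(0)) / vols.std(0)
        samples = [Sample3D(v, "RF") for v in vols]
        out = apply_normalization(samples, fit_normalization(samples))
        for s_in, s_out in zip(samples, out):
            np.testing.assert_allclose(s_out.volume, s_in.volume, atol=1e-10)

    def test_post_normalization_moments(self, rng):
        """After fit+apply, every voxel has mean ~0 and population std ~1."""
        samples = [Sample3D(100 + 5 * rng.random((4, 4, 4)), "T") for _ in range(8)]
        out = apply_normalization(samples, fit_normalization(samples))
        stack = np.stack([s.volume for s in out])
        assert np.abs(stack.mean(axis=0)).max() < 1e-6
        np.testing.assert_allclose(stack.std(axis=0, ddof=0), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        s = Sample3D(rng.random((3, 3, 3)), "LH")
        stats = fit_normalization([s, s])
        with pytest.raises(ValueError, match="shape"):
            apply_normalization([Sample3D(rng.random((2, 2, 2)), "LH")], stats)
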