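"""Registration chain: shift recovery, strip alignment, NCC selection."""

import numpy as np
import pytest

from fovtopo.phantom import (
    MotionModel,
    make_boundary_profiles,
    phenotype_preset,
    render_base_image,
    render_bscan_stack,
)
from fovtopo.register import (
    BScanStack,
    NoUnitsPassError,
    global_register,
    make_strips,
    ncc,
    select_and_average,
    strip_register,
)


@pytest.fixture
def base_contours(control_phenotype, small_grid):
    contours, _ = make_boundary_profiles(
        control_phenotype, grid=small_grid, halfwidth_mm=0.7
    )
    return contours


def _relative_truth(stack):
    """True shift of each frame relative to the reference frame 0."""
    t = stack.true_shifts
    return np.stack(
        [t["axial"] - t["axial"][0], t["lateral"] - t["lateral"][0]], axis=1
    )


class TestGlobalRegister:
    def test_known_shifts_recovered_exactly(self, base_contours):
        motion = MotionModel(lateral_shifts=[0, 5, -2], axial_shifts=[0, -2, 3])
        stack = render_bscan_stack(base_contours, motion, n_frames=3, noise_level=0.0,
                                   seed=0)
        reg = global_register(stack, ref_index=0)
        assert np.array_equal(reg.shifts, -_relative_truth(stack))
        # and the aligned frames actually coincide on the valid region
        for k in (1, 2):
            v = reg.frame_valid[k]
            assert np.array_equal(reg.frames[k][v], reg.frames[0][v])
            assert reg.frame_ncc[k] == pytest.approx(1.0)

    def test_reference_against_itself(self, base_contours):
        stack = render_bscan_stack(base_contours, MotionModel(2, 1), n_frames=4,
                                   noise_level=0.1, seed=1)
        reg = global_register(stack, ref_index=2)
        assert tuple(reg.shifts[2]) == (0, 0)
        assert reg.frame_ncc[2] == 1.0

    def test_speckle_recovery_within_one_pixel(self, base_contours):
        good = 0
        total = 0
        for seed in range(3):
            stack = render_bscan_stack(base_contours, MotionModel(3, 2), n_frames=20,
                                       noise_level=0.2, seed=seed)
            reg = global_register(stack, ref_index=0)
            err = np.abs(reg.shifts + _relative_truth(stack))
            good += int((err.max(axis=1) <= 1).sum())
            total += 20
        assert good / total >= 0.95

    def test_degenerate_frame_flagged(self, base_contours):
        stack = render_bscan_stack(base_contours, MotionModel(0, 0), n_frames=3,
                                   noise_level=0.0, seed=0)
        stack.frames[1] = 0.5  # constant frame: NCC undefined
        reg = global_register(stack, ref_index=0)
        assert np.isnan(reg.frame_ncc[1])
        avg, report = select_and_average(reg)
        assert all(u["frame"] != 1 for u in report["included"])

    def test_single_frame_rejected(self, base_contours):
        stack = render_bscan_stack(base_contours, MotionModel(0, 0), n_frames=1, seed=0)
        with pytest.raises(ValueError):
            global_register(stack)

    def test_shift_equivariance(self, base_contours):
        stack = render_bscan_stack(base_contours, MotionModel(2, 1), n_frames=6,
                                   noise_level=0.1, seed=4)
        avg, rep = select_and_average(global_register(stack, ref_index=0), threshold=0.5)
        rolled = BScanStack(
            frames=np.roll(stack.frames, (4, 7), axis=(1, 2)), meta=stack.meta
        )
        avg_r, rep_r = select_and_average(
            global_register(rolled, ref_index=0), threshold=0.5
        )
        assert [u["frame"] for u in rep_r["included"]] == [
            u["frame"] for u in rep["included"]
        ]
        # equality holds wherever every included frame is valid in both stacks
        # (the wrap-around masks sit at the image edges and do not translate)
        n = rep["n_included"]
        full = (rep_r["coverage"] == n) & (
            np.roll(rep["coverage"], (4, 7), axis=(0, 1)) == n
        )
        expected = np.roll(avg, (4, 7), axis=(0, 1))
        assert full.mean() > 0.8
        assert np.allclose(avg_r[full], expected[full])


class TestStripRegister:
    def test_single_strip_jitter_recovered(self, base_contours):
        stack = render_bscan_stack(base_contours, MotionModel(0, 0), n_frames=2,
                                   noise_level=0.0, seed=0)
        # inject +2 px axial jitter into strip 1 of frame 1
        stack.frames[1][:, 64:128] = np.roll(stack.frames[1][:, 64:128], 2, axis=0)
        reg = strip_register(global_register(stack, ref_index=0), strip_width=64)
        assert reg.strip_shifts[1, 1, 0] == -2
        others = [k for k in range(len(reg.strip_slices)) if k != 1]
        assert np.all(reg.strip_shifts[1, others] == 0)

    def test_identical_frame_all_strips_zero(self, base_contours):
        stack = render_bscan_stack(base_contours, MotionModel(0, 0), n_frames=3,
                                   noise_level=0.0, seed=0)
        reg = strip_register(global_register(stack, ref_index=0), strip_width=64)
        assert np.all(reg.strip_shifts == 0)
        assert np.allclose(reg.strip_ncc, 1.0)

    def test_noise_strip_falls_below_threshold(self, base_contours):
        stack = render_bscan_stack(base_contours, MotionModel(0, 0), n_frames=2,
                                   noise_level=0.0, seed=0)
        rng = np.random.default_rng(0)
        stack.frames[1][:, 0:64] = rng.uniform(0, 0.7, (stack.shape[0], 64))
        reg = strip_register(global_register(stack, ref_index=0), strip_width=64)
        assert reg.strip_ncc[1, 0] < 0.85
        assert np.all(reg.strip_ncc[1, 1:] > 0.99)

    def test_global_plus_strip_correction_recovers_jitter(self, base_contours):
        motion = MotionModel(0, 0, strip_jitter_sd_px=1.5, strip_width_px=64)
        stack = render_bscan_stack(base_contours, motion, n_frames=8, noise_level=0.0,
                                   seed=3)
        reg = strip_register(global_register(stack, ref_index=0), strip_width=64)
        rel = stack.true_shifts["strip_axial"] - stack.true_shifts["strip_axial"][0]
        total_axial = reg.shifts[:, 0][:, None] + reg.strip_shifts[:, :, 0]
        assert np.array_equal(total_axial, -rel)

    def test_narrow_trailing_strip_merged(self):
        strips = make_strips(width=100, strip_width=24, min_width=8)
        assert strips[-1] == slice(96, 100) or strips[-1].stop == 100
        widths = [s.stop - s.start for s in strips]
        assert all(w >= 4 for w in widths)
        strips2 = make_strips(width=130, strip_width=64, min_width=8)
        assert [s.stop - s.start for s in strips2] == [64, 66]


class TestSelection:
    def _stack_with_ncc(self, nccs):
        n = len(nccs)
        frames = np.full((n, 8, 8), 0.5)
        return BScanStack(
            frames=frames,
            ref_index=0,
            frame_ncc=np.asarray(nccs, dtype=float),
            frame_valid=np.ones((n, 8, 8), dtype=bool),
        )

    def test_threshold_arithmetic(self):
        stack = self._stack_with_ncc([0.9, 0.84, 0.86])
        _, report = select_and_average(stack)
        assert [u["frame"] for u in report["included"]] == [0, 2]
        excluded = {e["frame"]: e["reason"] for e in report["excluded"]}
        assert excluded[1] == "below threshold"

    def test_cap_at_max_units(self):
        stack = self._stack_with_ncc(np.linspace(0.86, 0.99, 40))
        _, report = select_and_average(stack, max_units=30)
        assert report["n_included"] == 30
        # highest NCC first
        assert report["included"][0]["frame"] == 39

    def test_ties_broken_by_frame_index(self):
        stack = self._stack_with_ncc([0.9] * 5)
        _, report = select_and_average(stack, max_units=3)
        assert [u["frame"] for u in report["included"]] == [0, 1, 2]

    def test_no_units_pass_raises(self):
        stack = self._stack_with_ncc([0.5, 0.6])
        with pytest.raises(NoUnitsPassError):
            select_and_average(stack)

    def test_identical_frames_average_exactly(self):
        stack = self._stack_with_ncc([1.0, 1.0, 1.0])  # dyadic frame value 0.5
        avg, _ = select_and_average(stack)
        assert np.array_equal(avg, stack.frames[0])

    def test_strip_level_partial_inclusion(self, base_contours):
        stack = render_bscan_stack(base_contours, MotionModel(0, 0), n_frames=4,
                                   noise_level=0.0, seed=0)
        rng = np.random.default_rng(1)
        # ruin one strip of frame 3 only: other strips of frame 3 still usable
        stack.frames[3][:, 0:64] = rng.uniform(0, 0.7, (stack.shape[0], 64))
        reg = strip_register(global_register(stack, ref_index=0), strip_width=64)
        avg, report = select_and_average(reg, level="strip")
        bad = [u for u in report["excluded"] if u["frame"] == 3 and u["strip"] == 0]
        assert bad and bad[0]["reason"] == "below threshold"
        kept = [u for u in report["included"] if u["frame"] == 3]
        assert kept  # parts of frame 3 still contribute

    def test_average_denoises_beyond_best_single_frame(self, base_contours):
        base = render_base_image(base_contours)
        wins = 0
        for seed in range(20):
            stack = render_bscan_stack(base_contours, MotionModel(3, 2), n_frames=40,
                                       noise_level=0.2, seed=seed)
            reg = global_register(stack, ref_index=0)
            avg, _ = select_and_average(reg)
            t = stack.true_shifts
            truth = np.roll(base, (t["axial"][0], t["lateral"][0]), axis=(0, 1))
            m = np.isfinite(avg)
            avg_ncc = ncc(avg[m], truth[m])
            singles = max(
                ncc(
                    stack.frames[i][m],
                    np.roll(base, (t["axial"][i], t["lateral"][i]), axis=(0, 1))[m],
                )
                for i in range(stack.n_frames)
            )
            wins += int(avg_ncc > singles)
        assert wins == 20
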