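"""Rigid NCC registration: exact recovery, tie-breaks, invariances."""

import numpy as np
import pytest

from evoked2p import (
    Movie,
    compute_reference,
    estimate_translation,
    register_movie,
    translate_frame,
)

from conftest import jittered_scene


class TestComputeReference:
    def test_identical_frames_reference_is_that_frame(self, rng):
        frame = rng.random((16, 16))
        movie = Movie(frames=np.stack([frame] * 5), frame_period=33.3)
        ref = compute_reference(movie, stability_quantile=1.0, max_shift=2)
        assert ref.n_frames_used == 5
        np.testing.assert_allclose(ref.image, frame)

    def test_two_uniform_frames_average(self):
        movie = Movie(frames=np.stack([np.zeros((8, 8)), np.full((8, 8), 2.0)]))
        ref = compute_reference(movie, stability_quantile=1.0, max_shift=2)
        np.testing.assert_allclose(ref.image, 1.0)
        assert ref.n_frames_used == 2

    def test_single_frame_warning(self, rng):
        movie = Movie(frames=rng.random((1, 8, 8)))
        ref = compute_reference(movie)
        assert ref.single_frame_warning
        np.testing.assert_allclose(ref.image, movie.frames[0])

    def test_jittered_movie_matches_truth_registered_mean(self):
        """Oracle: register each frame with the ground-truth shifts, then
        average; the two-pass reference must agree on the common support."""
        path = [(0, 0), (2, -1), (-2, 3), (1, 1), (0, -2), (-1, 0)]
        movie, _, truth = jittered_scene(path)
        ref = compute_reference(movie, stability_quantile=1.0, max_shift=4)
        acc = np.zeros(movie.shape)
        common = np.ones(movie.shape, dtype=bool)
        for k, (sx, sy) in enumerate(truth.shifts):
            img, ok = translate_frame(movie.frames[k], -sx, -sy)
            acc += img
            common &= ok
        oracle = acc / movie.n_frames
        assert ref.n_frames_used == movie.n_frames
        np.testing.assert_allclose(ref.image[common], oracle[common], atol=1e-10)

    def test_bad_quantile_rejected(self, rng):
        movie = Movie(frames=rng.random((3, 8, 8)))
        with pytest.raises(ValueError):
            compute_reference(movie, stability_quantile=0.0)


class TestEstimateTranslation:
    def test_identity(self, textured_movie):
        f = textured_movie.frames[0]
        dx, dy, score = estimate_translation(f, f, max_shift=3)
        assert (dx, dy) == (0, 0)
        assert score == pytest.approx(1.0)

    @pytest.mark.parametrize("shift", [(3, -2), (-4, 1), (0, 5)])
    def test_known_shift_recovered(self, textured_movie, shift):
        ref = textured_movie.frames[0]
        moved, _ = translate_frame(ref, *shift)
        # restrict to interior so the zero-filled border cannot bias NCC
        dx, dy, score = estimate_translation(moved, ref, max_shift=6)
        assert (dx, dy) == (-shift[0], -shift[1])
        assert score > 0.9

    def test_known_shift_with_noise(self, textured_movie, rng):
        ref = textured_movie.frames[0]
        moved, _ = translate_frame(ref, 3, -2)
        moved = moved + 0.01 * np.ptp(ref) * rng.standard_normal(ref.shape)
        dx, dy, _ = estimate_translation(moved, ref, max_shift=6)
        assert (dx, dy) == (-3, 2)

    def test_constant_frame_undefined(self):
        dx, dy, score = estimate_translation(np.ones((8, 8)), np.ones((8, 8)), 3)
        assert (dx, dy) == (0, 0)
        assert np.isnan(score)

    def test_tiebreak_prefers_smallest_shift(self):
        # period-2 stripes correlate perfectly at every even x-shift;
        # the tie-break must pick (0, 0)
        stripes = np.tile([0.0, 1.0], (16, 8))
        dx, dy, score = estimate_translation(stripes, stripes, max_shift=4)
        assert (dx, dy) == (0, 0)
        assert score == pytest.approx(1.0)

    def test_affine_intensity_invariance(self, textured_movie):
        ref = textured_movie.frames[0]
        moved, _ = translate_frame(ref, 2, 2)
        for a, b in [(3.0, 10.0), (0.5, 0.0), (7.0, 100.0)]:
            dx, dy, score = estimate_translation(a * moved + b, ref, max_shift=4)
            assert (dx, dy) == (-2, -2)
            assert score > 0.9

    def test_score_bounds(self, textured_movie, rng):
        ref = textured_movie.frames[0]
        noisy = rng.random(ref.shape)
        _, _, score = estimate_translation(noisy, ref, max_shift=2)
        assert -1.0 <= score <= 1.0


class TestRegisterMovie:
    def test_motionless_movie_unchanged(self, textured_movie):
        reg, shifts = register_movie(textured_movie, max_shift=3,
                                     stability_quantile=1.0)
        assert np.all(shifts.dx == 0) and np.all(shifts.dy == 0)
        np.testing.assert_allclose(reg.frames, textured_movie.frames)

    def test_exact_recovery_of_random_paths(self):
        """Property: any integer path within max_shift, zero noise, is
        recovered exactly as its negation."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            path = [(0, 0)] + [tuple(int(v) for v in r.integers(-4, 5, 2))
                               for _ in range(7)]
            movie, _, truth = jittered_scene(path, seed=seed)
            _, shifts = register_movie(movie, max_shift=5, stability_quantile=1.0)
            for (dx, dy), (sx, sy) in zip(zip(shifts.dx, shifts.dy), truth.shifts):
                assert (dx, dy) == (-sx, -sy)

    def test_idempotence(self):
        path = [(0, 0), (2, 1), (-1, -3), (3, 0), (0, 2)]
        movie, _, _ = jittered_scene(path)
        reg, _ = register_movie(movie, max_shift=4, stability_quantile=1.0)
        reg2, shifts2 = register_movie(reg, max_shift=4, stability_quantile=1.0)
        assert np.all(shifts2.dx == 0) and np.all(shifts2.dy == 0)

    def test_exposed_borders_marked_invalid(self):
        path = [(0, 0), (3, -2)]
        movie, _, _ = jittered_scene(path)
        reg, shifts = register_movie(movie, max_shift=4, stability_quantile=1.0)
        assert reg.valid is not None
        # corrected frame 1 was shifted by (-3, +2): 3 columns and 2 rows exposed
        assert not reg.valid[1].all()
        assert reg.valid[0].all()

    def test_low_confidence_flagging(self, rng):
        frames = rng.random((4, 16, 16))  # unrelated noise frames
        movie = Movie(frames=frames)
        _, shifts = register_movie(movie, max_shift=2, score_floor=0.99)
        assert shifts.low_confidence.any()

    def test_shift_series_csv_roundtrip(self, tmp_path):
        path = [(0, 0), (1, 1), (-2, 0)]
        movie, _, _ = jittered_scene(path)
        _, shifts = register_movie(movie, max_shift=3, stability_quantile=1.0)
        f = tmp_path / "shifts.csv"
        shifts.to_csv(f)
        back = type(shifts).from_csv(f)
        np.testing.assert_array_equal(back.dx, shifts.dx)
        np.testing.assert_array_equal(back.dy, shifts.dy)
        np.testing.assert_allclose(back.ncc_score, shifts.ncc_score)
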