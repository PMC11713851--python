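"""Fixation statistics, retinal-image centering, and marginal profiles."""

import numpy as np
import pytest

import eccmap as em
from eccmap.gaze import BODY, FACE, FixationRecord, LabeledFrame


@pytest.fixture
def screen():
    # small monitor model with the study's physical geometry
    return em.ScreenGeometry(597.0, 570.0, 64, 36)


def frame_with(screen, face=None, body=None, clip=0, t=0.0):
    """Frame with optional face/body rectangles given as (r0, r1, c0, c1)."""
    mask = np.zeros((screen.res_y, screen.res_x), dtype=np.uint8)
    if body:
        mask[body[0]:body[1], body[2]:body[3]] = BODY
    if face:
        mask[face[0]:face[1], face[2]:face[3]] = FACE
    return LabeledFrame(mask=mask, frame_time=t, clip_id=clip)


class TestVisualAngle:
    def test_study_monitor_width_rounds_to_55(self):
        assert round(em.visual_angle(597, 570)) == 55

    def test_study_monitor_height_rounds_to_33(self):
        g = em.ScreenGeometry()
        assert round(g.height_deg) == 33

    def test_inverse_identity(self):
        d = 500.0
        assert em.visual_angle(2 * d * np.tan(np.radians(30)), d) == \
            pytest.approx(60.0)

    def test_small_extent_limit(self):
        assert em.visual_angle(1e-9, 570) == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            em.visual_angle(0, 570)


class TestExtractFrames:
    def test_thirty_second_clip_gives_six_frames(self):
        assert len(em.extract_frame_times(30.0, 0.2)) == 6

    def test_cohort_total_is_150_frames(self):
        total = sum(len(em.extract_frame_times(30.0, 0.2)) for _ in range(25))
        assert total == 150

    def test_short_clip_gives_midpoint_frame(self):
        times = em.extract_frame_times(3.0, 0.2)
        assert len(times) == 1
        assert times[0] == pytest.approx(1.5)

    def test_frames_sampled_nearest_target_times(self):
        clip = np.arange(60)[:, None, None] * np.ones((1, 4, 4))
        frames, times = em.extract_frames(clip, 30.0, 0.2)
        assert len(frames) == 6
        assert np.allclose(times, [2.5, 7.5, 12.5, 17.5, 22.5, 27.5])
        # source frames at 2.25 s and 2.75 s tie for t=2.5; first wins
        assert frames[0][0, 0] == pytest.approx(4)

    def test_empty_clip_raises(self):
        with pytest.raises(ValueError, match="empty"):
            em.extract_frame_times(0, 0.2)


class TestFixatedCategory:
    def test_gaze_inside_face(self, screen):
        f = frame_with(screen, face=(5, 15, 10, 20))
        assert em.fixated_category(f, FixationRecord(0, 0, 0, 12, 8)) == "face"

    def test_gaze_on_background(self, screen):
        f = frame_with(screen, face=(5, 15, 10, 20))
        assert em.fixated_category(f, FixationRecord(0, 0, 0, 40, 30)) == "other"

    def test_face_precedence_in_overlap(self, screen):
        f = frame_with(screen, face=(5, 15, 10, 20), body=(10, 30, 5, 25))
        assert em.fixated_category(f, FixationRecord(0, 0, 0, 12, 12)) == "face"

    def test_out_of_bounds_raises(self, screen):
        f = frame_with(screen)
        with pytest.raises(ValueError, match="invalid"):
            em.fixated_category(f, FixationRecord(0, 0, 0, -1, 5))


class TestFractionsAndCoverage:
    def test_fractions_partition_valid_pairs(self, screen):
        frames = [frame_with(screen, face=(0, 10, 0, 10)) for _ in range(4)]
        fixes = [FixationRecord(0, 0, 0, 5, 5), FixationRecord(0, 0, 0, 30, 20),
                 FixationRecord(0, 0, 0, 5, 5), FixationRecord(0, 0, 0, -1, 0)]
        fr = em.fixation_fractions(frames, fixes)
        assert fr == {"other": pytest.approx(1 / 3), "face": pytest.approx(2 / 3),
                      "body": 0.0}
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_all_background_fixations(self, screen):
        frames = [frame_with(screen)] * 3
        fixes = [FixationRecord(0, 0, 0, 1, 1)] * 3
        assert em.fixation_fractions(frames, fixes)["other"] == 1.0

    def test_no_valid_pairs_raises(self, screen):
        with pytest.raises(ValueError, match="no valid"):
            em.fixation_fractions([frame_with(screen)],
                                  [FixationRecord(0, 0, 0, -1, -1, valid=False)])

    def test_pixel_coverage_equals_area_ratio(self, screen):
        f = frame_with(screen, face=(0, 10, 0, 10))  # 100 px of 64*36
        cov = em.pixel_coverage(f)
        assert cov["face"] == pytest.approx(100 / (64 * 36))
        assert sum(cov.values()) == pytest.approx(1.0)


class TestCenterOnFixation:
    def test_fixation_already_at_center_is_identity(self, screen):
        f = frame_with(screen, face=(10, 20, 20, 40))
        cx, cy = screen.center_px
        shifted, seen = em.center_on_fixation(f, FixationRecord(0, 0, 0, cx, cy),
                                              screen)
        assert np.array_equal(shifted, f.mask)
        assert seen.all()

    def test_corner_fixation_moves_content_to_lower_right(self, screen):
        f = frame_with(screen, face=(0, 36, 0, 64))
        shifted, seen = em.center_on_fixation(f, FixationRecord(0, 0, 0, 0, 0),
                                              screen)
        cx, cy = screen.center_px
        assert shifted[cy, cx] == FACE
        assert not seen[: cy - 1, : cx - 1].any()

    def test_single_labeled_pixel_lands_at_center(self, screen):
        f = frame_with(screen)
        f.mask[7, 9] = FACE
        shifted, _ = em.center_on_fixation(f, FixationRecord(0, 0, 0, 9, 7),
                                           screen)
        cx, cy = screen.center_px
        assert shifted[cy, cx] == FACE
        assert (shifted == FACE).sum() == 1

    def test_roundtrip_recovers_overlap_region(self, screen, rng):
        mask = rng.integers(0, 3, size=(screen.res_y, screen.res_x)).astype(np.uint8)
        f = LabeledFrame(mask=mask)
        gx, gy = 10, 30
        shifted, seen = em.center_on_fixation(f, FixationRecord(0, 0, 0, gx, gy),
                                              screen)
        cx, cy = screen.center_px
        inverse = FixationRecord(0, 0, 0, 2 * cx - gx, 2 * cy - gy)
        back, _ = em.center_on_fixation(LabeledFrame(mask=shifted), inverse,
                                        screen)
        # track which output pixels hold twice-shifted original content
        seen_back, _ = em.center_on_fixation(
            LabeledFrame(mask=seen.astype(np.uint8)), inverse, screen)
        overlap = seen_back > 0
        assert overlap.any()
        assert np.array_equal(back[overlap], mask[overlap])

    def test_category_counts_preserved_in_overlap(self, screen):
        f = frame_with(screen, face=(10, 20, 20, 40), body=(20, 30, 10, 50))
        shifted, seen = em.center_on_fixation(f, FixationRecord(0, 0, 0, 30, 18),
                                              screen)
        # shift is small enough that all content stays on canvas
        assert (shifted == FACE).sum() == (f.mask == FACE).sum()
        assert (shifted == BODY).sum() == (f.mask == BODY).sum()


class TestAverageRetinalImage:
    def test_identical_inputs_average_to_single_input(self, screen):
        f = frame_with(screen, face=(10, 20, 20, 40))
        cx, cy = screen.center_px
        fixes = [FixationRecord(0, 0, 0, cx, cy)] * 3
        img = em.average_retinal_image([f] * 3, fixes, screen)
        assert np.array_equal(img.probs["face"], (f.mask == FACE).astype(float))

    def test_half_present_pixel_is_half_probability(self, screen):
        f1 = frame_with(screen, face=(10, 20, 20, 40))
        f2 = frame_with(screen)
        cx, cy = screen.center_px
        fixes = [FixationRecord(0, 0, 0, cx, cy)] * 2
        img = em.average_retinal_image([f1, f2], fixes, screen)
        assert img.probs["face"][15, 30] == pytest.approx(0.5)

    def test_category_images_sum_to_at_most_one(self, screen, rng):
        frames = [LabeledFrame(rng.integers(0, 3, (36, 64)).astype(np.uint8))
                  for _ in range(5)]
        fixes = [FixationRecord(0, 0, 0, int(rng.integers(0, 64)),
                                int(rng.integers(0, 36))) for _ in range(5)]
        img = em.average_retinal_image(frames, fixes, screen)
        total = sum(img.probs[c] for c in ("other", "face", "body"))
        assert total.max() <= 1.0 + 1e-12

    def test_scene_padding_mode_sums_to_one(self, screen):
        f = frame_with(screen, face=(10, 20, 20, 40))
        img = em.average_retinal_image([f], [FixationRecord(0, 0, 0, 5, 5)],
                                       screen, padding="scene")
        total = sum(img.probs[c] for c in ("other", "face", "body"))
        assert np.allclose(total, 1.0)


class TestMarginalProfiles:
    def test_category_below_center_has_negative_peak(self, screen):
        f = frame_with(screen, body=(30, 36, 0, 64))
        cx, cy = screen.center_px
        img = em.average_retinal_image([f], [FixationRecord(0, 0, 0, cx, cy)],
                                       screen)
        prof = em.marginal_profiles(img, axis="y")
        assert prof["body"]["peak_deg"] < 0
        assert prof["body"]["profile"].max() == pytest.approx(1.0)

    def test_uniform_category_tie_breaks_to_center(self, screen):
        mask = np.full((screen.res_y, screen.res_x), FACE, dtype=np.uint8)
        f = LabeledFrame(mask=mask)
        cx, cy = screen.center_px
        img = em.average_retinal_image([f], [FixationRecord(0, 0, 0, cx, cy)],
                                       screen)
        prof = em.marginal_profiles(img, axis="y")
        assert prof["face"]["peak_deg"] == pytest.approx(0.0, abs=1.0 / screen.ppd)

    def test_absent_category_flagged_undefined(self, screen):
        f = frame_with(screen)
        cx, cy = screen.center_px
        img = em.average_retinal_image([f], [FixationRecord(0, 0, 0, cx, cy)],
                                       screen)
        prof = em.marginal_profiles(img, axis="y")
        assert not prof["face"]["defined"]
        assert np.isnan(prof["face"]["peak_deg"])


class TestComparePeaks:
    def test_identical_pairs_give_t_zero_p_one(self):
        r = em.compare_peaks([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p == 1.0

    def test_df_is_n_minus_one(self, rng):
        a = rng.normal(size=25)
        r = em.compare_peaks(a, a + rng.normal(1, 0.5, size=25))
        assert r.df == 24

    def test_constant_nonzero_difference_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            em.compare_peaks([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError, match="3"):
            em.compare_peaks([1.0, 2.0], [2.0, 1.0])

    def test_rejection_rate_matches_analytic_power(self):
        # paired t at alpha 0.05, n=25, delta/sd = 0.5: power from the
        # noncentral t distribution, checked by simulation
        from scipy import stats as sps
        n, delta, sd = 25, 0.5, 1.0
        nc = delta / (sd / np.sqrt(n))
        tcrit = sps.t.ppf(0.975, n - 1)
        power = 1 - sps.nct.cdf(tcrit, n - 1, nc) + sps.nct.cdf(-tcrit, n - 1, nc)
        rng = np.random.default_rng(99)
        rej = 0
        reps = 1000
        for _ in range(reps):
            d = rng.normal(delta, sd, n)
            r = em.compare_peaks(d, np.zeros(n))
            rej += r.p < 0.05
        assert abs(rej / reps - power) < 0.03


def test_pixel_to_degrees_sign_convention():
    g = em.ScreenGeometry(597.0, 570.0, 64, 36)
    dx, dy = g.pixel_to_degrees(32, 0)   # top-center pixel
    assert dx == pytest.approx(0.0)
    assert dy > 0                         # screen-up is positive visual y
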