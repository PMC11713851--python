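"""Determinism and calibration of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

import eccmap as em
from eccmap import synthetic as syn


class TestGenSheet:
    def test_same_seed_identical_tables(self):
        spec = syn.SheetSpec(n_participants=2, vertices_per_roi=10, seed=42)
        pd.testing.assert_frame_equal(syn.gen_sheet(spec), syn.gen_sheet(spec))

    def test_different_seed_differs(self):
        a = syn.gen_sheet(syn.SheetSpec(n_participants=1, vertices_per_roi=10,
                                        seed=1))
        b = syn.gen_sheet(syn.SheetSpec(n_participants=1, vertices_per_roi=10,
                                        seed=2))
        assert not np.allclose(a["ecc_true"], b["ecc_true"])

    def test_parabola_vertex_is_minimum_without_jitter(self):
        spec = syn.SheetSpec(n_participants=1, vertices_per_roi=50,
                             ecc_jitter_sd=0.0, between_sd=0.0, clusters=(),
                             seed=3)
        sheet = syn.gen_sheet(spec)
        expected = spec.e_min + spec.amp * (sheet["a"] - spec.trough_a) ** 2
        assert np.allclose(sheet["ecc_true"], expected)
        nearest = sheet.iloc[(sheet["a"] - spec.trough_a).abs().argmin()]
        assert nearest["ecc_true"] == sheet["ecc_true"].min()

    def test_limb_cluster_biased_to_lower_field(self):
        sheet = syn.gen_sheet(syn.SheetSpec(seed=0))
        limb = sheet[sheet["cluster"] == "OTS-limb"]
        assert len(limb) > 20
        assert (limb["y_true"] < 0).mean() > 0.5

    def test_cluster_mean_eccentricities_near_configured(self):
        sheet = syn.gen_sheet(syn.SheetSpec(seed=0))
        means = sheet[sheet["cluster"] != ""].groupby("cluster")["ecc_true"].mean()
        assert means["OTS-limb"] == pytest.approx(5.8, abs=0.5)
        assert means["pFus-face"] == pytest.approx(3.6, abs=0.5)

    def test_shapes_dial(self):
        for shape in ("u", "linear", "flat"):
            spec = syn.SheetSpec(n_participants=1, vertices_per_roi=5,
                                 shape=shape, seed=1)
            assert len(syn.gen_sheet(spec)) == 35
        with pytest.raises(ValueError, match="shape"):
            syn.SheetSpec(shape="wiggle").ecc_truth(np.array([0.5]))

    def test_invalid_cluster_interval_raises(self):
        with pytest.raises(ValueError, match="interval"):
            syn.ClusterSpec("x", "limb", 0.5, 0.4, ecc_mean=5.0)


class TestGenBold:
    @pytest.fixture(scope="class")
    def small(self, movie_tr):
        spec = syn.SheetSpec(n_participants=1, vertices_per_roi=4, seed=5)
        return syn.gen_sheet(spec), movie_tr

    def test_deterministic_under_seed(self, small):
        sheet, movie_tr = small
        a = syn.gen_bold(sheet, movie_tr, noise_sd=0.5, seed=9)
        b = syn.gen_bold(sheet, movie_tr, noise_sd=0.5, seed=9)
        assert np.array_equal(a, b)

    def test_noiseless_closure_with_fitter(self, small):
        sheet, movie_tr = small
        bold = syn.gen_bold(sheet, movie_tr, noise_sd=0.0, seed=0)
        row = sheet.iloc[0]
        fit = em.fit_prf(bold[:, 0], movie_tr)
        assert np.hypot(fit.params.x - row["x_true"],
                        fit.params.y - row["y_true"]) < 0.25

    def test_doubling_noise_doubles_residual_sd(self, small):
        sheet, movie_tr = small
        clean = syn.gen_bold(sheet, movie_tr, noise_sd=0.0, seed=0)
        n1 = syn.gen_bold(sheet, movie_tr, noise_sd=0.5, seed=3) - clean
        n2 = syn.gen_bold(sheet, movie_tr, noise_sd=1.0, seed=3) - clean
        assert n2.std() == pytest.approx(2 * n1.std(), rel=1e-6)

    def test_zero_gain_vertex_is_pure_noise(self, movie_tr):
        spec = syn.SheetSpec(n_participants=1, vertices_per_roi=2, gain=0.0,
                             seed=5)
        sheet = syn.gen_sheet(spec)
        bold = syn.gen_bold(sheet, movie_tr, noise_sd=0.5, seed=1)
        assert bold.std() > 0
        clean = syn.gen_bold(sheet, movie_tr, noise_sd=0.0, seed=1)
        assert np.allclose(clean, 0)


class TestGenLocalizer:
    def test_cluster_vertices_detected_nonselective_not(self):
        spec = syn.SheetSpec(n_participants=1, vertices_per_roi=40, seed=2)
        sheet = syn.gen_sheet(spec)
        Y, X, names = syn.gen_localizer(sheet, 0, seed=11)
        t = em.glm_contrast(Y, X, syn.contrast_vector(names, "hands"))
        pf = sheet[sheet["participant"] == 0]
        limb = pf["cluster"].values == "OTS-limb"
        assert limb.sum() >= 2
        assert (t[limb] > 3).mean() > 0.8
        assert (t[~limb] > 3).mean() < 0.05


class TestGenMovieDataset:
    def test_deterministic_under_seed(self):
        spec = syn.MovieSpec(n_clips=2, n_participants=2, seed=8)
        a, b = syn.gen_movie_dataset(spec), syn.gen_movie_dataset(spec)
        pd.testing.assert_frame_equal(a.fixations, b.fixations)
        assert all(np.array_equal(x.mask, y.mask)
                   for x, y in zip(a.frames, b.frames))

    def test_all_face_policy_fixates_faces(self):
        spec = syn.MovieSpec(n_clips=2, n_participants=2, p_face=1.0,
                             p_body=0.0, gaze_jitter_px=0.0, tremor_px=0.0,
                             invalid_prob=0.0, seed=4)
        ds = syn.gen_movie_dataset(spec)
        from eccmap.pipeline import participant_pairs
        for pid in (0, 1):
            pairs = participant_pairs(ds, pid)
            cats = [em.fixated_category(f, fx) for f, fx in pairs]
            assert set(cats) == {"face"}

    def test_frame_count_matches_rate(self):
        ds = syn.gen_movie_dataset(syn.MovieSpec(n_clips=3, n_participants=1,
                                                 seed=0))
        assert len(ds.frames) == 3 * 6

    def test_pixel_coverage_near_study_values(self):
        ds = syn.gen_movie_dataset(syn.MovieSpec(n_clips=5, n_participants=1,
                                                 seed=0))
        cov = pd.DataFrame([em.pixel_coverage(f) for f in ds.frames]).mean()
        assert cov["face"] == pytest.approx(0.11, abs=0.02)
        assert cov["body"] == pytest.approx(0.32, abs=0.04)
        assert cov["other"] == pytest.approx(0.57, abs=0.04)

    def test_body_band_below_fixation(self):
        # bodies sit below faces, so with face fixation the average retinal
        # image's body band peaks near the configured offset
        from eccmap.pipeline import gaze_report
        ds = syn.gen_movie_dataset(syn.MovieSpec(n_clips=8, n_participants=4,
                                                 seed=21))
        rep = gaze_report(ds)
        body = rep["peaks"]["body_peak_y"].mean()
        assert body < 0
        assert body == pytest.approx(-11.6, abs=2.6)

    def test_fixation_bias_unbiased_across_seeds(self):
        # estimated p_face should track the generator's p_face
        from eccmap.pipeline import participant_pairs
        errs = []
        for seed in range(10):
            ds = syn.gen_movie_dataset(syn.MovieSpec(
                n_clips=5, n_participants=3, seed=seed))
            fracs = []
            for pid in range(3):
                pairs = participant_pairs(ds, pid)
                fr = em.fixation_fractions([p[0] for p in pairs],
                                           [p[1] for p in pairs])
                fracs.append(fr["face"])
            errs.append(np.mean(fracs) - 0.66)
        assert abs(np.mean(errs)) < 0.02

    def test_oversized_rectangle_raises(self):
        with pytest.raises(ValueError, match="larger than frame"):
            syn.MovieSpec(face_w=10_000)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError, match="sum"):
            syn.MovieSpec(p_face=0.9, p_body=0.3)


def test_gen_ecc_matrix_shapes_and_determinism():
    a = syn.gen_ecc_matrix(10, "flat", seed=3)
    b = syn.gen_ecc_matrix(10, "flat", seed=3)
    pd.testing.assert_frame_equal(a.data, b.data)
    assert a.data.shape == (10, 7)
    u = syn.gen_ecc_matrix(500, "u", cell_noise_sd=0.01, seed=1)
    col_means = u.data.mean().values
    assert col_means.argmin() == 2  # trough ROI: FG-lateral (a0=0.4 -> pos 3.3)
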