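"""Phantom generators: gel vials, mouse abdomen, motion models, gel readout."""

import numpy as np
import pytest

from murt.image import Grid, Modality, difference_image, resample
from murt.phantoms import (GelPhantomSpec, GelResponse, MotionSpec,
                           MousePhantomSpec, apply_motion, gel_mr_after_dose,
                           make_gel_phantom, make_mouse_phantom, organ_cnr,
                           rotational_asymmetry_rms, voxelize_structures)
from murt.phantoms.mouse import Organ, PhantomSpecError
from murt.phantoms.readout import invert_gel_response


class TestGelPhantom:
    def test_vial_visible_in_ct_only(self, gel_small):
        """CT shows gel and glass wall; MR shows the gel alone."""
        ct, mr, truth = gel_small["ct"], gel_small["mr"], gel_small["truth"]
        vial = truth.mask("vial")
        assert ct.voxels[vial].mean() > 1.5 * ct.voxels[truth.mask("gel")].mean()
        # sample MR at vial-interior world positions: background level only
        idx = np.argwhere(vial)[::37]
        w = idx @ truth.affine[:3, :3].T + truth.affine[:3, 3]
        mr_vals = mr.sample_world(w)
        assert np.median(mr_vals) < 200.0  # well below the gel signal (1000)

    def test_same_seed_is_bit_identical(self):
        spec = GelPhantomSpec(ct_spacing_mm=0.5, mr_spacing_mm=0.6, seed=11)
        a = make_gel_phantom(spec)
        b = make_gel_phantom(spec)
        assert np.array_equal(a[0].voxels, b[0].voxels)
        assert np.array_equal(a[1].voxels, b[1].voxels)
        assert np.array_equal(a[2].labels, b[2].labels)

    def test_tilted_meniscus_breaks_rotational_symmetry(self, gel_small):
        truth = gel_small["truth"]
        rms = rotational_asymmetry_rms(truth.mask("gel"), truth.affine)
        assert rms > 2 * gel_small["spec"].ct_spacing_mm

    def test_zero_tilt_is_rotationally_symmetric_and_warns(self):
        spec = GelPhantomSpec(ct_spacing_mm=0.4, mr_spacing_mm=0.5,
                              meniscus_tilt_deg=0.0, seed=3)
        _, _, truth = make_gel_phantom(spec)
        rms = rotational_asymmetry_rms(truth.mask("gel"), truth.affine)
        assert rms < 0.5 * spec.ct_spacing_mm
        assert "warning" in truth.meta


class TestMousePhantom:
    def test_target_contrast_dichotomy(self, mouse_small):
        """Adrenal/tumour invisible in CT (CNR<1), clear in bSSFP (>=5),
        with CPMG giving the best tumour contrast."""
        spec, truth = mouse_small["spec"], mouse_small["truth"]
        sig_mr = spec.contrast["MR_bSSFP"]["body"] / spec.mr_snr
        assert organ_cnr(mouse_small["ct"], truth, "adrenal_L",
                         spec.ct_noise_sigma) < 1.0
        assert organ_cnr(mouse_small["ct"], truth, "tumour",
                         spec.ct_noise_sigma) < 1.0
        cnr_bssfp = organ_cnr(mouse_small["bssfp"], mouse_small["truth_mr"],
                              "adrenal_L", sig_mr)
        assert cnr_bssfp >= 5.0
        t_bssfp = organ_cnr(mouse_small["bssfp"], mouse_small["truth_mr"],
                            "tumour", sig_mr)
        t_cpmg = organ_cnr(mouse_small["cpmg"], mouse_small["truth_mr"],
                           "tumour", spec.contrast["MR_CPMG"]["body"] / spec.mr_snr)
        assert t_cpmg > t_bssfp

    def test_noiseless_means_equal_contrast_table(self):
        spec = MousePhantomSpec(ct_spacing_mm=0.5, mr_spacing_mm=0.5,
                                ct_noise_sigma=0.0, mr_snr=np.inf, seed=1)
        ct, bssfp, _, truth = make_mouse_phantom(spec)
        assert organ_cnr(ct, truth, "liver", 1.0) == pytest.approx(
            abs(spec.contrast["CT"]["liver"] - spec.contrast["CT"]["body"]),
            abs=0.5)

    def test_overlapping_organs_name_the_pair(self):
        spec = MousePhantomSpec(ct_spacing_mm=0.6, mr_spacing_mm=0.6)
        organs = dict(spec.organs)
        organs["tumour"] = Organ((5.8, 2.0, -3.5), (2.5, 2.5, 2.5))  # on kidney_R
        bad = spec.replace(organs=organs)
        with pytest.raises(PhantomSpecError, match="kidney_R|tumour"):
            make_mouse_phantom(bad)

    def test_detectable_tumour_equivalent_diameter(self, mouse_small):
        """Default pancreatic tumour sized like a newly detectable lesion."""
        v = mouse_small["truth"].volume_mm3("tumour")
        d_eq = (6 * v / np.pi) ** (1 / 3)
        assert 4.0 <= d_eq <= 5.0

    def test_rician_bias_small_at_default_snr(self, mouse_small):
        """Background-corrected organ means unbiased within 2% at SNR 20."""
        spec = mouse_small["spec"]
        truth = mouse_small["truth_mr"]
        img = mouse_small["bssfp"]
        from scipy.ndimage import binary_erosion

        for organ in ("kidney_L", "liver", "stomach"):
            m = binary_erosion(truth.mask(organ), iterations=2)
            got = img.voxels[m].mean()
            want = spec.contrast["MR_bSSFP"][organ]
            assert got == pytest.approx(want, rel=0.02)


class TestMotion:
    def test_zero_spec_returns_input_unchanged(self, mouse_small):
        out, truth = apply_motion(mouse_small["bssfp"], MotionSpec(),
                                  "intrinsic", anatomy=mouse_small["truth_mr"])
        assert out is mouse_small["bssfp"]
        assert truth.magnitude().max() == 0.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            MotionSpec(droop_mm=-1.0)

    def test_droop_profile(self, mouse_small):
        """1 mm droop: peak displacement at the free (upper) surface, zero
        at the cradle contact line."""
        truth = mouse_small["truth_mr"]
        _, fld = apply_motion(mouse_small["bssfp"], MotionSpec(droop_mm=1.0),
                              "intrinsic", anatomy=truth)
        mag = fld.magnitude()
        body = truth.labels > 0
        z = mouse_small["bssfp"].world_grid()[..., 2]
        assert mag[body].max() == pytest.approx(1.0, abs=0.02)
        contact = body & (z < z[body].min() + 0.6)
        assert mag[contact].max() < 0.05

    def test_bladder_growth_confines_changes(self, mouse_small):
        """Bladder filling changes the image only near the bladder."""
        from scipy.ndimage import binary_dilation

        truth = mouse_small["truth_mr"]
        img = mouse_small["bssfp"]
        moved, fld = apply_motion(img, MotionSpec(bladder_growth_fraction=0.4),
                                  "intrinsic", anatomy=truth)
        diff = difference_image(img, moved)
        sig = np.abs(diff.voxels) > 40.0     # 2 noise SD
        region = binary_dilation(truth.mask("bladder"), iterations=8)
        assert sig.any()
        assert (sig & ~region).sum() / sig.sum() < 0.02

    def test_extrinsic_pose_recovered_by_rigid_registration(self, mouse_small):
        from murt.registration import rigid_register_intensity

        img = mouse_small["bssfp"]
        moved, t_true = apply_motion(
            img, MotionSpec(jitter_rotation_deg=2.0, jitter_translation_mm=0.5,
                            seed=8), "extrinsic")
        t_rec = rigid_register_intensity(moved, img, metric="MI")
        resid = t_rec.compose(t_true)
        c = img.centre_world()
        assert np.linalg.norm(resid.apply(c) - c) < 0.1
        assert resid.rotation_angle_deg() < 0.1

    def test_distortion_amplitude_and_determinism(self, mouse_small):
        m = MotionSpec(distortion_amplitude_mm=1.5, seed=4)
        _, f1 = apply_motion(mouse_small["bssfp"], m, "mr_distortion")
        _, f2 = apply_motion(mouse_small["bssfp"], m, "mr_distortion")
        assert f1.magnitude().max() == pytest.approx(1.5, rel=1e-6)
        assert np.array_equal(f1.displacements, f2.displacements)


class TestGelReadout:
    def test_zero_dose_returns_input(self, gel_small):
        mr = gel_small["mr"]
        dose = mr.with_voxels(np.zeros(mr.shape), Modality.DOSE)
        out = gel_mr_after_dose(mr, dose)
        assert np.array_equal(out.voxels, mr.voxels)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            GelResponse().signal_change(np.array([-0.5, 1.0]))

    def test_signal_change_monotone_in_dose(self):
        r = GelResponse()
        doses = np.linspace(0, 10, 101)
        ch = r.signal_change(doses)
        assert np.all(np.diff(ch) >= 0)
        assert ch[0] == 0.0

    def test_response_inversion_roundtrip(self):
        r = GelResponse()
        d = np.linspace(0, 8, 33)
        assert np.allclose(r.dose_from_change(r.signal_change(d)), d, atol=1e-9)

    def test_cross_beam_intersection_recoverable(self, gel_small):
        """The readout separates gel / 2 Gy path / 4 Gy intersection: the
        midpoint-threshold segmentation recovers the intersection with
        Dice >= 0.9 against the 3 Gy dose-threshold oracle, and an
        unsupervised three-class Otsu split of the recovered dose map gets
        close (its cut sits slightly below the midpoint)."""
        from scipy.ndimage import gaussian_filter
        from skimage.filters import threshold_multiotsu

        from murt.dose import BeamSpec, compose_cross_beams

        ct, mr = gel_small["ct"], gel_small["mr"]
        target = (3.0, 2.0, 7.0)
        grid = Grid.from_extent((-14, -14, -1), (14, 14, 20), 0.4)
        ba = BeamSpec(kind="static", gantry_deg=90, azimuth_deg=25,
                      collimator_mm=4.0, isocentre=target)
        bb = ba.replace(azimuth_deg=115)
        dose, _ = compose_cross_beams(ct, ba, bb, per_beam_gy=2.0, grid=grid)
        dose_mr = resample(dose, None, mr)
        post = gel_mr_after_dose(mr, dose_mr)
        gel = resample(gel_small["truth"].as_volume(), None, mr).voxels == \
            gel_small["truth"].label_of("gel")
        truth_mask = gel & (dose_mr.voxels > 3.0)

        est = gaussian_filter(invert_gel_response(mr, post), 0.7)
        # canonical segmentation: midpoint between path and sum plateaus
        pred_mid = gel & (est > 3.0)
        dice_mid = 2 * (pred_mid & truth_mask).sum() / (pred_mid.sum()
                                                        + truth_mask.sum())
        assert dice_mid >= 0.9

        # unsupervised check: 3-class Otsu in a box at the crossing
        change = gaussian_filter(mr.voxels - post.voxels, 1.0)
        peak = np.unravel_index(np.argmax(change), change.shape)
        half = int(round(4.5 / mr.spacing[0]))
        sl = tuple(slice(max(0, p - half), p + half + 1) for p in peak)
        box = np.zeros_like(gel)
        box[sl] = True
        roi = box & gel
        cuts = threshold_multiotsu(est[roi], classes=3)
        pred = roi & (est > cuts[1])
        dice = 2 * (pred & truth_mask).sum() / (pred.sum() + truth_mask.sum())
        assert dice >= 0.85

    def test_invert_gel_response_recovers_dose_map(self, gel_small):
        mr = gel_small["mr"]
        rng = np.random.default_rng(2)
        dose = np.zeros(mr.shape)
        dose[30:40, 30:40, 20:30] = 2.0
        dose[34:38, 34:38, 24:28] = 4.0
        dvol = mr.with_voxels(dose, Modality.DOSE)
        post = gel_mr_after_dose(mr, dvol)
        est = invert_gel_response(mr, post)
        gel = resample(gel_small["truth"].as_volume(), None, mr).voxels == \
            gel_small["truth"].label_of("gel")
        hot = gel & (dose == 4.0)
        if hot.any():
            assert np.median(est[hot]) == pytest.approx(4.0, abs=0.5)
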