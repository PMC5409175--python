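"""Registration: region growing, surface extraction, ICP, rigid MI,
MIND descriptors, deformable registration, transform transfer."""

import numpy as np
import pytest

from murt.image import Grid, ImageVolume, Modality, resample
from murt.phantoms import MotionSpec, apply_motion
from murt.registration import (boundary_shell, deformable_register_mind,
                               icp_register, mask_to_surface_points,
                               mind_descriptor, rigid_register_intensity,
                               segment_region_growing, transfer_transform)
from murt.registration.mind import mind_ssd
from murt.registration.segmentation import EmptyMaskError, SeedError
from murt.transforms import DeformationField, RigidTransform


@pytest.fixture(scope="module")
def gel_surface(gel_small):
    seg = segment_region_growing(gel_small["ct"],
                                 (0, 0, gel_small["spec"].gel_height_mm / 2),
                                 (500, 1700), "gel")
    pts = mask_to_surface_points(seg, spacing=0.6,
                                 intensity=gel_small["ct"].voxels)
    return seg, pts


class TestRegionGrowing:
    def test_gel_mask_matches_truth(self, gel_small, gel_surface):
        seg, _ = gel_surface
        truth = gel_small["truth"].mask("gel")
        pred = seg.labels > 0
        dice = 2 * (pred & truth).sum() / (pred.sum() + truth.sum())
        assert dice >= 0.98

    def test_uniform_volume_grows_everywhere(self):
        vol = ImageVolume(np.full((8, 8, 8), 5.0), np.eye(4))
        seg = segment_region_growing(vol, (3, 3, 3), (0, 10))
        assert (seg.labels > 0).all()

    def test_seed_outside_window_raises(self, gel_small):
        with pytest.raises(SeedError):
            segment_region_growing(gel_small["ct"], (0, 0, 5), (2000, 3000))

    def test_background_seed_excludes_gel(self, gel_small):
        ct = gel_small["ct"]
        corner = ct.index_to_world((2, 2, 2))
        seg = segment_region_growing(ct, corner, (-200, 400))
        assert not (seg.labels[gel_small["truth"].mask("gel")] > 0).any()


class TestSurfacePoints:
    def test_sphere_points_lie_on_radius(self):
        g = Grid.from_extent((-8, -8, -8), (8, 8, 8), 0.5)
        w = np.indices(g.shape).reshape(3, -1).T @ g.affine[:3, :3].T + g.affine[:3, 3]
        mask = (np.linalg.norm(w, axis=1) < 5.0).reshape(g.shape)
        pts = mask_to_surface_points(mask, g.affine, spacing=0.5)
        r = np.linalg.norm(pts, axis=1)
        assert np.abs(r - 5.0).mean() <= 0.5

    def test_single_voxel_gives_face_points(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        pts = mask_to_surface_points(mask, np.eye(4))
        assert len(pts) == 6
        assert np.abs(np.linalg.norm(pts - 2.0, axis=1) - 0.5).max() < 1e-9

    def test_point_count_tracks_surface_area(self, gel_small, gel_surface):
        seg, pts = gel_surface
        spec = gel_small["spec"]
        r = spec.inner_diameter_mm / 2
        # cylinder side + bottom + tilted top cap (ellipse)
        tilt = np.deg2rad(spec.meniscus_tilt_deg)
        area = (2 * np.pi * r * spec.gel_height_mm + np.pi * r ** 2
                + np.pi * r ** 2 / np.cos(tilt))
        assert len(pts) == pytest.approx(area / 0.6 ** 2, rel=0.25)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            mask_to_surface_points(np.zeros((4, 4, 4), dtype=bool), np.eye(4))


class TestICP:
    def test_identical_clouds_give_identity(self, gel_surface):
        _, pts = gel_surface
        T, rms = icp_register(pts, pts)
        assert rms < 1e-9
        assert T.rotation_angle_deg() < 1e-6
        assert T.translation_norm() < 1e-6

    def test_known_transform_recovered(self, gel_surface):
        _, pts = gel_surface
        T_true = RigidTransform.from_euler((0, 0, 10), (1.0, 2.0, 3.0))
        moving = T_true.inverse().apply(pts)
        T, rms = icp_register(moving, pts)
        assert rms < 0.05
        assert np.linalg.norm(T.translation - T_true.translation) < 0.1
        assert T.compose(T_true.inverse()).rotation_angle_deg() < 0.2

    def test_outliers_handled_by_trimming(self, gel_surface):
        _, pts = gel_surface
        rng = np.random.default_rng(0)
        T_true = RigidTransform.from_euler((2, -1, 4), (0.5, -1.0, 0.8))
        moving = T_true.inverse().apply(pts)
        junk = rng.uniform(-25, 25, (len(moving) // 5, 3))
        T, _ = icp_register(np.vstack([moving, junk]), pts, trim_fraction=0.25)
        resid = T.compose(T_true.inverse())
        centre = pts.mean(0)
        assert np.linalg.norm(resid.apply(centre) - centre) < 0.3
        assert resid.rotation_angle_deg() < 0.5

    def test_median_recovery_over_random_perturbations(self, gel_surface):
        """50 random rigid perturbations (<=5 deg, <=3 mm) recovered with
        median error < 0.2 mm / 0.3 deg."""
        _, pts = gel_surface
        rng = np.random.default_rng(42)
        t_errs, r_errs = [], []
        for _ in range(50):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.deg2rad(rng.uniform(0, 5))
            K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
            t = rng.uniform(-1, 1, 3)
            t *= rng.uniform(0, 3) / max(np.linalg.norm(t), 1e-9)
            T_true = RigidTransform(R, t)
            moving = T_true.inverse().apply(pts)
            T, _ = icp_register(moving, pts)
            resid = T.compose(T_true.inverse())
            t_errs.append(np.linalg.norm(resid.apply(pts.mean(0)) - pts.mean(0)))
            r_errs.append(resid.rotation_angle_deg())
        assert np.median(t_errs) < 0.2
        assert np.median(r_errs) < 0.3

    def test_degenerate_cloud_warns(self):
        line = np.stack([np.linspace(0, 10, 30)] + [np.zeros(30)] * 2, axis=1)
        with pytest.warns(UserWarning, match="rank-deficient"):
            icp_register(line, line + 0.01, max_iter=3, refine_plane=False)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            icp_register(np.zeros((2, 3)), np.zeros((5, 3)))


class TestRigidIntensity:
    def test_identity_on_identical_inputs(self, mouse_small):
        T = rigid_register_intensity(mouse_small["bssfp"], mouse_small["bssfp"])
        assert T.translation_norm() < 0.05
        assert T.rotation_angle_deg() < 0.05

    def test_known_shift_recovered(self, mouse_small):
        img = mouse_small["bssfp"]
        T_true = RigidTransform(np.eye(3), (1.7, 0.0, 0.0))
        moved = resample(img, T_true, img)
        T = rigid_register_intensity(moved, img, metric="MI")
        c = img.centre_world()
        assert np.linalg.norm(T.apply(T_true.apply(c)) - c) < 0.1

    def test_cross_modality_pose_recovered(self, mouse_small):
        """MR vs CT rendering of the same anatomy under a pose offset."""
        moved, t_true = apply_motion(
            mouse_small["bssfp"],
            MotionSpec(jitter_rotation_deg=3.0, jitter_translation_mm=1.0,
                       seed=5), "extrinsic")
        T = rigid_register_intensity(moved, mouse_small["ct"], metric="MI")
        resid = T.compose(t_true)
        c = mouse_small["ct"].centre_world()
        assert np.linalg.norm(resid.apply(c) - c) < 0.3
        assert resid.rotation_angle_deg() < 0.5

    def test_non_overlapping_volumes_rejected(self, mouse_small):
        from murt.registration.rigid import InitializationError

        img = mouse_small["bssfp"]
        far = ImageVolume(img.voxels, img.affine.copy(), img.modality)
        far.affine[:3, 3] += 500.0
        with pytest.raises(InitializationError):
            rigid_register_intensity(far, img)


@pytest.fixture(scope="module")
def blobs():
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(3)
    img = gaussian_filter(rng.normal(size=(32, 32, 32)), 3.0)
    return (img - img.min()) / (img.max() - img.min()) * 800.0


class TestMINDDescriptor:
    def test_components_in_unit_interval(self, blobs):
        M = mind_descriptor(blobs).descriptors
        assert M.min() > 0.0
        assert M.max() <= 1.0 + 1e-12
        assert np.allclose(M.max(axis=-1), 1.0)

    def test_affine_intensity_invariance(self, blobs):
        a = mind_descriptor(blobs).descriptors
        b = mind_descriptor(3.7 * blobs + 120.0).descriptors
        assert np.abs(a - b).max() < 1e-6

    def test_intensity_inversion_invariance(self, blobs):
        a = mind_descriptor(blobs).descriptors
        b = mind_descriptor(-blobs + 500.0).descriptors
        assert np.abs(a - b).max() < 1e-6

    def test_step_edge_dominates_flat_regions(self):
        img = np.zeros((24, 24, 24))
        img[12:] = 100.0
        M = mind_descriptor(img).descriptors
        edge = np.abs(M[12] - M[11]).mean()
        flat = np.abs(M[4] - M[3]).mean()
        assert edge / max(flat, 1e-12) > 5.0

    def test_white_noise_is_directionally_uniform(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(40, 40, 40))
        M = mind_descriptor(img).descriptors
        means = M[4:-4, 4:-4, 4:-4].reshape(-1, 6).mean(axis=0)
        assert means.max() / means.min() < 1.1

    def test_constant_image_is_well_defined(self):
        M = mind_descriptor(np.full((10, 10, 10), 7.0)).descriptors
        assert np.isfinite(M).all()
        assert M.min() > 0.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            mind_descriptor(np.zeros((5, 5, 5)), sigma_vox=0.0)


class TestDeformable:
    def test_identical_inputs_give_null_field(self, mouse_small):
        fld = deformable_register_mind(mouse_small["ct"], mouse_small["ct"],
                                       levels=2, iterations=10)
        assert fld.magnitude().max() < 0.05 * mouse_small["ct"].spacing[0]

    def test_polynomial_distortion_recovered(self, mouse_small):
        """Known smooth distortions (1.5 mm peak in the body) recovered to
        < 0.3 mm mean inside the body, cross-modality (averaged over three
        independent distortion draws)."""
        img = mouse_small["bssfp"]
        truth = mouse_small["truth_mr"]
        body = truth.labels > 0
        roi = boundary_shell(mouse_small["ct"].voxels > 500.0, 3)
        errs = []
        for draw in (7, 8, 9):
            _, fld0 = apply_motion(
                img, MotionSpec(distortion_amplitude_mm=1.5, seed=draw),
                "mr_distortion")
            scale = 1.5 / fld0.magnitude()[body].max()
            fld_true = DeformationField(fld0.displacements * scale,
                                        fld0.grid_affine)
            distorted = resample(img, fld_true, Grid.of(img))
            fld = deformable_register_mind(distorted, mouse_small["ct"],
                                           model="polynomial", roi=roi)
            inv = fld_true.inverse()
            err = np.linalg.norm(fld.displacements - inv.displacements, axis=-1)
            errs.append(err[body].mean())
        assert np.mean(errs) < 0.3

    def test_droop_correction_improves_overlap_and_ssd(self, mouse_small):
        """Free-field registration of a drooped MR onto CT restores kidney
        overlap and strictly reduces descriptor SSD."""
        img = mouse_small["bssfp"]
        truth = mouse_small["truth_mr"]
        ct = mouse_small["ct"]
        moved, fld_true = apply_motion(
            img, MotionSpec(droop_mm=3.0, gi_amplitude_mm=1.0, seed=6),
            "intrinsic", anatomy=truth)
        fld = deformable_register_mind(moved, ct, model="free",
                                       levels=3, iterations=50)

        def dice(a, b):
            return 2 * (a & b).sum() / (a.sum() + b.sum())

        kid = truth.mask("kidney_L")
        kvol = ImageVolume(kid.astype(float), truth.affine, Modality.LABEL)
        kid_moved = resample(kvol, fld_true, Grid.of(img),
                             interpolation="nearest").voxels > 0.5
        kmv = ImageVolume(kid_moved.astype(float), truth.affine, Modality.LABEL)
        kid_corr = resample(kmv, fld, Grid.of(img),
                            interpolation="nearest").voxels > 0.5
        assert dice(kid_moved, kid) < 0.85          # motion was material
        assert dice(kid_corr, kid) >= 0.85
        # descriptor SSD must drop where the descriptors carry structure
        # (the body outline); over flat noise the global mean only
        # measures interpolation's effect on the noise texture
        from scipy.ndimage import gaussian_filter

        from murt.registration.mind import mind_descriptor

        sm = lambda v: gaussian_filter(v, 1.0)  # noqa: E731
        shell = boundary_shell(ct.voxels > 500.0, 3)
        m_ct = mind_descriptor(sm(ct.voxels)).descriptors

        def shell_ssd(img):
            m = mind_descriptor(sm(img)).descriptors
            return float(np.mean(((m - m_ct) ** 2).sum(-1)[shell]))

        assert shell_ssd(resample(moved, fld, ct).voxels) \
            < shell_ssd(moved.voxels)

    def test_unknown_model_rejected(self, mouse_small):
        with pytest.raises(ValueError):
            deformable_register_mind(mouse_small["ct"], mouse_small["ct"],
                                     model="spline")


class TestTransfer:
    def test_same_volume_matches_direct_resample(self, mouse_small):
        ct, bssfp = mouse_small["ct"], mouse_small["bssfp"]
        T = RigidTransform.from_euler((0, 0, 3), (0.5, -0.2, 0.4))
        out = transfer_transform(T, bssfp, ct)
        direct = resample(bssfp, T, ct)
        assert np.abs(out.voxels - direct.voxels).max() < 1e-9
        assert out.frame == "ct_planning"

    def test_tumour_centroid_lands_on_truth(self, mouse_small):
        """Second contrast carried through the sibling's chain: tumour
        centroid on the CT grid within 0.3 mm of truth geometry."""
        ct = mouse_small["ct"]
        cpmg = mouse_small["cpmg"]
        truth = mouse_small["truth"]
        T = RigidTransform.from_euler((1, 0, 2), (0.7, -0.3, 0.5))
        cpmg_moved = resample(cpmg, T.inverse(), cpmg)  # scanner-frame volume
        out = transfer_transform(T, cpmg_moved, ct)
        tum = truth.mask("tumour")
        # centroid of the bright tumour signal inside the truth neighbourhood
        from scipy.ndimage import binary_dilation

        region = binary_dilation(tum, iterations=4)
        w = ct.world_grid()[region]
        v = out.voxels[region]
        v = np.clip(v - np.percentile(v, 50), 0, None)
        got = (w * v[:, None]).sum(0) / v.sum()
        want = truth.centroid_world("tumour")
        assert np.linalg.norm(got - want) < 0.3

    def test_roundtrip_resampling_stays_within_interpolation_bound(self, mouse_small):
        from scipy.ndimage import gaussian_filter

        ct = mouse_small["ct"]
        smooth = ct.with_voxels(gaussian_filter(ct.voxels, 2.0))
        mr_grid = Grid.of(mouse_small["bssfp"])
        there = resample(smooth, None, mr_grid)
        back = resample(there, None, ct)
        dyn = smooth.voxels.max() - smooth.voxels.min()
        inner = tuple(slice(6, -6) for _ in range(3))
        assert np.abs(back.voxels[inner] - smooth.voxels[inner]).max() < 0.02 * dyn

    def test_frame_mismatch_refused(self, mouse_small):
        from murt.registration import FrameMismatchError

        ct, bssfp, cpmg = (mouse_small["ct"], mouse_small["bssfp"],
                           mouse_small["cpmg"])
        other = ImageVolume(cpmg.voxels, cpmg.affine.copy(), cpmg.modality,
                            frame="scanner_B")
        with pytest.raises(FrameMismatchError):
            transfer_transform(RigidTransform.identity(), other, ct,
                               frame_check=bssfp)


class TestSymmetry:
    def test_forward_backward_icp_are_mutually_inverse(self, gel_surface):
        _, pts = gel_surface
        T_true = RigidTransform.from_euler((1, 2, 3), (1.0, -0.5, 0.8))
        moving = T_true.inverse().apply(pts)
        T_fwd, _ = icp_register(moving, pts)
        T_bwd, _ = icp_register(pts, moving)
        comp = T_fwd.compose(T_bwd)
        centre = pts.mean(0)
        assert np.linalg.norm(comp.apply(centre) - centre) < 0.2
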