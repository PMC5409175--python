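"""Scripted end-to-end experiments: gel targeting accuracy, in-vivo motion
stability, adrenal MR-guided delivery, and the four-plan DVH comparison.

Each function is deterministic for a given seed and returns a plain dict of
metrics (JSON-serialisable) plus, optionally, the heavyweight volumes for
inspection.  Problem sizes (working resolutions, arc control points) are
package defaults chosen to resolve the relevant structures while keeping a
desk-scale runtime; they are exposed as keyword arguments.
"""

from __future__ import annotations

import numpy as np

from .dose import BeamSpec, Plan, arc_dose, compose_cross_beams, normalize_plan, plan_dose
from .image import Grid, ImageVolume, Modality, difference_image, resample
from .phantoms import (GelPhantomSpec, GelResponse, MotionSpec, MousePhantomSpec,
                       apply_motion, gel_mr_after_dose, kpc_dvh_spec,
                       make_gel_phantom, make_mouse_phantom, organ_cnr,
                       voxelize_structures)
from .phantoms.readout import invert_gel_response
from .planning import (TargetingReport, choose_collimator, compute_dvh,
                       define_isocentre, evaluate_targeting,
                       low_dose_volume_fraction, make_comparison_plans,
                       segment_dose_region)
from .registration import (deformable_register_mind, icp_register,
                           mask_to_surface_points, rigid_register_intensity,
                           segment_region_growing)
from .structures import StructureSet
from .transforms import RigidTransform


# ---------------------------------------------------------------------------
# Gel targeting accuracy (the mechanical-accuracy validation)
# ---------------------------------------------------------------------------

def run_gel_targeting(n_runs: int = 5, seed: int = 1,
                      ct_spacing_mm: float = 0.16,
                      mr_spacing_mm: float = 0.27,
                      dose_spacing_mm: float = 0.3,
                      target_beam_mm: float = 2.0,
                      per_beam_gy: float = 2.0,
                      arc_collimator_mm: float = 5.0,
                      arc_prescription_gy: float = 4.0,
                      operator_jitter_mm: float = 0.25,
                      pose_rotation_deg: float = 3.0,
                      pose_translation_mm: float = 1.0,
                      n_control: int = 24,
                      mr_snr: float = 20.0) -> dict:
    """Full MR-guided targeting chain on seeded synthetic gel phantoms.

    Per run: (1) form a cross-beam target with two orthogonal ``2 Gy``
    beams in the irradiator frame; (2) image the gel in a jittered MR
    frame before and after; (3) register MR to CT by gel-surface ICP;
    (4) define the isocentre as the MR-visible intersection centroid
    (plus operator jitter), mapped through the registration; (5) deliver
    a 45-degree conical arc; (6) read out the virtual gel and measure the
    3D offset between the cross-beam centre and the arc dose centre.

    Returns the :class:`TargetingReport` summary over all runs.
    """
    base = np.random.default_rng(seed)
    response = GelResponse()
    report = TargetingReport()
    per_run = []
    for run in range(n_runs):
        run_seed = int(base.integers(0, 2 ** 31 - 1))
        rng = np.random.default_rng(run_seed)
        gspec = GelPhantomSpec(seed=run_seed, ct_spacing_mm=ct_spacing_mm,
                               mr_spacing_mm=mr_spacing_mm, mr_snr=mr_snr,
                               margin_mm=4.0)
        ct, mr, truth = make_gel_phantom(gspec)

        # off-centre, off-axis target avoids mirror-image symmetry
        target = np.array([4.0, 3.0, 7.0]) + rng.uniform(-1.0, 1.0, 3)
        az0 = float(rng.uniform(0.0, 360.0))
        dose_grid = Grid.from_extent(*_gel_bbox(gspec), dose_spacing_mm)
        beam_a = BeamSpec(kind="static", gantry_deg=90.0, azimuth_deg=az0,
                          collimator_mm=target_beam_mm, isocentre=tuple(target))
        beam_b = beam_a.replace(azimuth_deg=az0 + 90.0)
        dose_cross, _ = compose_cross_beams(ct, beam_a, beam_b,
                                            per_beam_gy=per_beam_gy,
                                            grid=dose_grid)

        # gel is re-loaded in the MR scanner with a different pose
        mr_moved, t_pose = apply_motion(
            mr, MotionSpec(jitter_rotation_deg=pose_rotation_deg,
                           jitter_translation_mm=pose_translation_mm,
                           seed=run_seed ^ 0x5EED), "extrinsic")
        pre_mr = mr_moved
        mid_mr = gel_mr_after_dose(
            mr_moved, resample(dose_cross, t_pose, mr_moved), response)

        # surface-driven MR -> CT registration
        gel_seed_ct = (0.0, 0.0, gspec.gel_height_mm / 2.0)
        seg_ct = segment_region_growing(ct, gel_seed_ct, (500.0, 1700.0), "gel")
        pts_ct = mask_to_surface_points(seg_ct, spacing=0.6, intensity=ct.voxels)
        seg_mr = segment_region_growing(mid_mr, t_pose.apply(gel_seed_ct),
                                        (500.0, 1e9), "gel")
        pts_mr = mask_to_surface_points(seg_mr, spacing=0.6,
                                        intensity=mid_mr.voxels)
        t_reg, icp_rms = icp_register(pts_mr, pts_ct)

        # isocentre: MR-visible intersection centroid + operator jitter
        d_est = invert_gel_response(pre_mr, mid_mr, response)
        c_mr = segment_dose_region(d_est, 1.5 * per_beam_gy, pre_mr.affine)
        iso = t_reg.apply(c_mr)
        if operator_jitter_mm > 0:
            iso = iso + rng.normal(0.0, operator_jitter_mm, 3)

        # 45-degree conical arc about the prescribed isocentre
        arc = BeamSpec(kind="conical_arc", gantry_deg=45.0,
                       collimator_mm=arc_collimator_mm,
                       isocentre=tuple(iso), sweep_deg=(0.0, 360.0))
        d_arc = arc_dose(ct, arc, n_control=n_control, grid=dose_grid)
        d_arc = normalize_plan(d_arc, Plan([arc], arc_prescription_gy))

        total = dose_cross.with_voxels(dose_cross.voxels + d_arc.voxels)
        post_mr = gel_mr_after_dose(
            mr_moved, resample(total, t_pose, mr_moved), response)

        evaluate_targeting(pre_mr, mid_mr, post_mr, response,
                           cross_plateau_gy=per_beam_gy,
                           arc_dose_gy=arc_prescription_gy, report=report)
        per_run.append({"seed": run_seed, "icp_rms_mm": float(icp_rms),
                        "offset_mm": report.offsets_mm[-1]})
    out = report.summary()
    out["runs"] = per_run
    return out


def _gel_bbox(spec: GelPhantomSpec):
    ro = spec.inner_diameter_mm / 2.0 + spec.wall_thickness_mm
    top = spec.gel_height_mm + ro * abs(np.tan(np.deg2rad(spec.meniscus_tilt_deg)))
    return (np.array([-ro, -ro, -1.0]), np.array([ro, ro, top + 1.0]))


# ---------------------------------------------------------------------------
# In-vivo stability of body position
# ---------------------------------------------------------------------------

def run_motion_stability(seed: int = 1, spacing_mm: float = 0.4,
                         droop_mm: float = 1.0,
                         bladder_growth: float = 0.3,
                         gi_amplitude_mm: float = 0.5,
                         n_transfers: int = 5) -> dict:
    """Difference-image assessment of intrinsic and extrinsic motion.

    Intrinsic: droop + bladder filling + GI warp between two scans, scored
    as regional percent signal change of the difference image and by
    recovering the injected droop from the dorsal body surface.  Extrinsic:
    repeated cradle-transfer pose jitter corrected by rigid registration,
    scored as residual displacement at the body centre.
    """
    spec = MousePhantomSpec(ct_spacing_mm=spacing_mm, mr_spacing_mm=spacing_mm,
                            seed=seed)
    _, mr, _, _ = make_mouse_phantom(spec)
    truth = voxelize_structures(spec, Grid.of(mr), check=False)

    motion = MotionSpec(droop_mm=droop_mm, bladder_growth_fraction=bladder_growth,
                        gi_amplitude_mm=gi_amplitude_mm, seed=seed + 17)
    moved, field = apply_motion(mr, motion, "intrinsic", anatomy=truth)
    diff, stats = difference_image(mr, moved, truth)

    droop_est = _estimate_droop(mr, moved, truth)
    out = {"intrinsic": {"regional_pct_change": stats,
                         "applied_droop_mm": droop_mm,
                         "recovered_droop_mm": droop_est,
                         "max_truth_displacement_mm": float(field.magnitude().max())},
           "extrinsic": {"residual_mm": [], "applied_mm": []}}

    centre = truth.centroid_world("body")
    for k in range(n_transfers):
        moved_k, t_true = apply_motion(
            mr, MotionSpec(jitter_rotation_deg=2.0, jitter_translation_mm=0.5,
                           seed=seed * 100 + k), "extrinsic")
        t_rec = rigid_register_intensity(moved_k, mr, metric="MI")
        resid = float(np.linalg.norm(t_rec.apply(t_true.apply(centre)) - centre))
        out["extrinsic"]["residual_mm"].append(resid)
        out["extrinsic"]["applied_mm"].append(
            float(np.linalg.norm(t_true.apply(centre) - centre)))
    resid = out["extrinsic"]["residual_mm"]
    out["extrinsic"]["mean_residual_mm"] = float(np.mean(resid)) if resid else 0.0
    return out


def _estimate_droop(before: ImageVolume, after: ImageVolume,
                    truth: StructureSet, level: float = 200.0) -> float:
    """Recover vertical sag from the shift of the dorsal (upper) body
    surface between two scans, averaged over a central patch."""
    z = before.world_grid()[..., 2]

    def top_surface(vol):
        body = vol.voxels > level
        # highest z with tissue in each (x, y) column
        zz = np.where(body, z, -np.inf)
        return zz.max(axis=2)

    t0, t1 = top_surface(before), top_surface(after)
    ok = np.isfinite(t0) & np.isfinite(t1)
    # central third of the footprint, away from lateral edges
    nx, ny = ok.shape
    sel = np.zeros_like(ok)
    sel[nx // 3: 2 * nx // 3, ny // 3: 2 * ny // 3] = True
    ok &= sel
    return float(np.mean(t0[ok] - t1[ok]))


# ---------------------------------------------------------------------------
# Adrenal MR-guided delivery
# ---------------------------------------------------------------------------

def run_adrenal(seed: int = 1, spacing_mm: float = 0.4,
                side: str = "L", dose_gy: float = 10.0,
                distortion_mm: float = 0.8,
                dose_spacing_mm: float = 0.4) -> dict:
    """Target one adrenal gland with a size-matched anterior-posterior beam.

    The adrenal is invisible in CT (CNR < 1) but clear in bSSFP MR; the MR
    is distorted and mis-posed, registered to CT rigidly (MI) and then
    deformably (MIND), and the beam is collimated to the imaged adrenal
    size.  Reports CNRs, registration errors and the dose separation
    between the target and the spared contralateral adrenal.
    """
    spec = MousePhantomSpec(ct_spacing_mm=spacing_mm, mr_spacing_mm=spacing_mm,
                            seed=seed)
    ct, mr, _, truth_ct = make_mouse_phantom(spec)
    truth_mr = voxelize_structures(spec, Grid.of(mr), check=False)
    target_name = f"adrenal_{side}"
    other_name = f"adrenal_{'R' if side == 'L' else 'L'}"

    sigma_mr = spec.contrast["MR_bSSFP"]["body"] / spec.mr_snr
    cnrs = {"ct": organ_cnr(ct, truth_ct, target_name, spec.ct_noise_sigma),
            "mr_bssfp": organ_cnr(mr, truth_mr, target_name, sigma_mr)}

    # MR suffers geometric distortion + a pose offset w.r.t. the CT frame
    mr_d, field_true = apply_motion(
        mr, MotionSpec(distortion_amplitude_mm=distortion_mm, seed=seed + 3),
        "mr_distortion")
    mr_dp, t_true = apply_motion(
        mr_d, MotionSpec(jitter_rotation_deg=2.0, jitter_translation_mm=1.0,
                         seed=seed + 4), "extrinsic")

    t_rigid = rigid_register_intensity(mr_dp, ct, metric="MI")
    mr_rigid = resample(mr_dp, t_rigid, ct)
    # distortion correction: global polynomial field driven by the body
    # outline, the structure visible in both modalities
    from .registration import boundary_shell

    shell = boundary_shell(ct.voxels > 500.0, 3)
    field = deformable_register_mind(mr_rigid, ct, model="polynomial",
                                     roi=shell)

    # carry the target contour through the same chain
    adr_mr = truth_mr.mask(target_name).astype(float)
    adr_vol = ImageVolume(adr_mr, truth_mr.affine, Modality.LABEL)
    adr_d = resample(adr_vol, field_true, Grid.of(mr), interpolation="linear")
    adr_dp = resample(adr_d, t_true, Grid.of(mr), interpolation="linear")
    adr_reg = resample(adr_dp, t_rigid, ct, interpolation="linear")
    adr_fin = resample(adr_reg, field, Grid.of(ct), interpolation="linear")
    target_mask = adr_fin.voxels > 0.5
    if not target_mask.any():
        target_mask = adr_fin.voxels > 0.25

    seg = StructureSet(target_mask.astype(np.int16), ct.affine, {1: target_name})
    collimator = choose_collimator(seg, available=(2.0, 3.0, 5.0, 10.0))
    iso = define_isocentre(seg)

    dose_grid = Grid.of(ct) if dose_spacing_mm == spacing_mm else \
        Grid.from_extent(*_body_bbox(spec), dose_spacing_mm)
    beam = BeamSpec(kind="static", gantry_deg=0.0, collimator_mm=collimator,
                    isocentre=tuple(iso))
    dose = plan_dose(ct, Plan([beam], dose_gy), grid=dose_grid)
    truth_dose = voxelize_structures(spec, dose_grid, check=False)

    tgt_err = float(np.linalg.norm(iso - truth_ct.centroid_world(target_name)))
    return {"cnr": cnrs, "collimator_mm": collimator,
            "isocentre_error_mm": tgt_err,
            "target_mean_gy": float(dose.voxels[truth_dose.mask(target_name)].mean()),
            "contralateral_mean_gy": float(dose.voxels[truth_dose.mask(other_name)].mean()),
            "adjacent_kidney_mean_gy": float(
                dose.voxels[truth_dose.mask(f"kidney_{side}")].mean())}


def _body_bbox(spec: MousePhantomSpec):
    lo, hi = spec.fov()
    return lo, hi


# ---------------------------------------------------------------------------
# Four-plan DVH comparison on the abdominal-tumour phantom
# ---------------------------------------------------------------------------

def run_kpc_dvh(seed: int = 1, prescription_gy: float = 8.0,
                collimator_mm: float = 10.0,
                ct_spacing_mm: float = 0.3,
                dose_spacing_mm: float = 0.4,
                n_control: int = 36,
                bin_width_gy: float = 0.1) -> dict:
    """Compute the four comparative plans and their per-organ DVHs.

    Returns D95/mean-dose metrics and the ordinal plan-comparison summary
    (ipsilateral vs contralateral kidney, low-dose stomach+bowel bath).
    """
    spec = kpc_dvh_spec(ct_spacing_mm=ct_spacing_mm,
                        mr_spacing_mm=max(ct_spacing_mm, 0.3), seed=seed)
    ct, _, _, truth = make_mouse_phantom(spec)
    iso = truth.centroid_world("tumour")
    plans = make_comparison_plans(iso, collimator_mm, prescription_gy)

    dose_grid = Grid.from_extent(*spec.fov(), dose_spacing_mm)
    truth_d = voxelize_structures(spec, dose_grid, check=False)
    tumour = truth_d.mask("tumour")
    sb = truth_d.mask("stomach") | truth_d.mask("bowel")

    out = {"plans": {}, "prescription_gy": prescription_gy}
    doses = {}
    for name, plan in plans.items():
        d = plan_dose(ct, plan, grid=dose_grid, n_control=n_control)
        doses[name] = d
        curves = compute_dvh(d, truth_d, bin_width_gy)
        out["plans"][name] = {
            "tumour_d95_gy": curves["tumour"].dose_at_volume(95.0),
            "kidney_R_mean_gy": curves["kidney_R"].mean_dose(),
            "kidney_L_mean_gy": curves["kidney_L"].mean_dose(),
            "liver_mean_gy": curves["liver"].mean_dose(),
            "spleen_mean_gy": curves["spleen"].mean_dose(),
            "stomach_bowel_low_dose_fraction":
                low_dose_volume_fraction(d, sb, 0.05, 5.0),
        }
    p = out["plans"]
    d95s = [p[k]["tumour_d95_gy"] for k in p]
    arcs = [k for k in p if k != "0deg_beam"]
    out["comparison"] = {
        "tumour_d95_spread_pct": 100.0 * (max(d95s) - min(d95s)) / max(d95s),
        "ipsilateral_kidney_worst_is_0deg": all(
            p["0deg_beam"]["kidney_R_mean_gy"] > p[k]["kidney_R_mean_gy"]
            for k in arcs),
        "contralateral_kidney_best_is_0deg": all(
            p["0deg_beam"]["kidney_L_mean_gy"] < p[k]["kidney_L_mean_gy"]
            for k in arcs),
        "low_dose_bath_2x120_gt_0deg":
            p["2x120deg_arcs"]["stomach_bowel_low_dose_fraction"]
            > p["0deg_beam"]["stomach_bowel_low_dose_fraction"],
    }
    return out
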