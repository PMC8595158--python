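import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from bruisepose.bones import BoneMesh, BruisePatch
from bruisepose.bruise_match import (
    CongruencyConfig,
    congruency_score,
    kabsch_fit,
    reconstruct_pose,
    unicompartmental_diagnostic,
)
from bruisepose.bruise_match import _MatchContext
from bruisepose.errors import EmptyPatch
from bruisepose.geometry import RigidTransform, kabsch
from bruisepose.knee_frames import pose_from_parameters, relative_from_placement
from bruisepose.synthetic_knee import BruiseStampParams, generate_knee, stamp_bruises


def _grid(x0, x1, y0, y1, z, step=2.0):
    xs = np.arange(x0, x1 + step / 2, step)
    ys = np.arange(y0, y1 + step / 2, step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(z))])
    faces = []
    ny = len(ys)
    for i in range(len(xs) - 1):
        for j in range(ny - 1):
            a = i * ny + j
            faces.append([a, a + ny, a + ny + 1])
            faces.append([a, a + ny + 1, a + 1])
    return verts, np.asarray(faces, dtype=np.int64)


def planar_bones(offset: float):
    """Two-compartment flat test patches: tibial planes ``offset`` mm below."""
    blocks = [(-30.0, -10.0, "medial"), (10.0, 30.0, "lateral")]
    bones, patch_sets = {}, {}
    for name, z, landmarks in (
        (
            "femur",
            0.0,
            {
                "medial_epicondyle": np.array([-40.0, 0.0, 0.0]),
                "lateral_epicondyle": np.array([40.0, 0.0, 0.0]),
                "femoral_shaft": np.array([0.0, 0.0, 50.0]),
            },
        ),
        (
            "tibia",
            -offset,
            {
                "medial_plateau_edge": np.array([-40.0, 0.0, 0.0]),
                "lateral_plateau_edge": np.array([40.0, 0.0, 0.0]),
                "tibial_shaft": np.array([0.0, 0.0, -40.0]),
            },
        ),
    ):
        verts_all, faces_all, labels, patches = [], [], [], []
        for x0, x1, comp in blocks:
            v, f = _grid(x0, x1, -10, 10, z)
            base = sum(len(x) for x in verts_all)
            patches.append(
                BruisePatch(bone=name, compartment=comp, vertex_indices=base + np.arange(len(v)))
            )
            verts_all.append(v)
            faces_all.append(f + base)
            labels.append(np.full(len(v), comp, dtype="<U7"))
        mesh = trimesh.Trimesh(np.vstack(verts_all), np.vstack(faces_all), process=False)
        bones[name] = BoneMesh(
            mesh=mesh, landmarks=landmarks, name=name, compartment=np.concatenate(labels)
        )
        patch_sets[name] = patches
    return bones["femur"], bones["tibia"], patch_sets["femur"] + patch_sets["tibia"]


class TestKabschFit:
    def test_recovers_known_transform_exactly(self, rng):
        rot = Rotation.from_rotvec(np.radians(25) * np.array([0.2, 0.5, -0.8])).as_matrix()
        src = rng.normal(scale=15, size=(25, 3))
        fit = kabsch_fit(src, src @ rot.T + np.array([3.0, -2.0, 7.0]))
        assert np.abs(fit.rotation - rot).max() < 1e-9
        assert np.abs(fit.translation - [3.0, -2.0, 7.0]).max() < 1e-9


class TestCongruencyScore:
    def test_coincident_planar_patches_score_zero(self):
        femur, tibia, patches = planar_bones(offset=0.0)
        score = congruency_score(pose_from_parameters(), patches, femur, tibia)
        assert score < 1e-9

    def test_planar_offset_gives_exact_rms(self):
        # planes 5 mm apart along their common normal: every closest-point
        # distance is exactly 5, so the RMS is 5.000 (analytic oracle)
        femur, tibia, patches = planar_bones(offset=5.0)
        score = congruency_score(pose_from_parameters(), patches, femur, tibia)
        assert score == pytest.approx(5.0, abs=1e-9)

    def test_score_nonnegative_at_arbitrary_poses(self, stamped, rng):
        femur, tibia, patches = stamped
        for _ in range(3):
            pose = pose_from_parameters(
                flexion=rng.uniform(0, 90), vv=rng.uniform(-10, 10),
                ie=rng.uniform(-15, 15), ap=rng.uniform(0, 50), pd=rng.uniform(-10, 30),
            )
            assert congruency_score(pose, patches, femur, tibia) >= 0.0

    def test_invariant_to_common_rigid_motion(self, stamped, injury_pose, rng):
        femur, tibia, patches = stamped
        base = congruency_score(injury_pose, patches, femur, tibia)
        move = RigidTransform(
            Rotation.random(random_state=7).as_matrix(), rng.normal(scale=40, size=3)
        )
        moved = []
        for bone in (femur, tibia):
            mesh = trimesh.Trimesh(move.apply(bone.vertices), bone.faces, process=False)
            moved.append(
                BoneMesh(
                    mesh=mesh,
                    landmarks={k: move.apply(v) for k, v in bone.landmarks.items()},
                    name=bone.name,
                    compartment=bone.compartment,
                    articular_faces=bone.articular_faces,
                )
            )
        score = congruency_score(injury_pose, patches, moved[0], moved[1])
        assert score == pytest.approx(base, abs=1e-9)

    def test_missing_patch_pair_raises(self, stamped):
        femur, tibia, patches = stamped
        with pytest.raises(EmptyPatch):
            congruency_score(pose_from_parameters(), patches[:3], femur, tibia)

    def test_empty_patch_cannot_be_constructed(self):
        with pytest.raises(EmptyPatch):
            BruisePatch(bone="femur", compartment="medial", vertex_indices=np.array([]))


class TestReconstructPose:
    def test_fixed_point_from_ground_truth(self, stamped, injury_pose):
        femur, tibia, patches = stamped
        res = reconstruct_pose(femur, tibia, patches, starts=[injury_pose])
        assert res.converged
        p = res.pose
        assert abs(p.flexion - injury_pose.flexion) < 0.5
        assert abs(p.vv - injury_pose.vv) < 0.5
        assert abs(p.ie - injury_pose.ie) < 0.5
        assert abs(p.ap - injury_pose.ap) < 0.5
        assert abs(p.pd - injury_pose.pd) < 0.5

    def test_recovery_from_perturbed_start(self, stamped, injury_pose, rng):
        femur, tibia, patches = stamped
        t = injury_pose
        d = rng.uniform(-1, 1, 5)
        start = pose_from_parameters(
            t.flexion + 10 * d[0], t.vv + 10 * d[1], t.ie + 10 * d[2],
            t.ap + 10 * d[3], t.pd + 10 * d[4],
        )
        res = reconstruct_pose(femur, tibia, patches, starts=[start])
        p = res.pose
        for got, want in (
            (p.flexion, t.flexion), (p.vv, t.vv), (p.ie, t.ie), (p.ap, t.ap), (p.pd, t.pd),
        ):
            assert abs(got - want) < 0.5

    def test_multistart_reports_all_candidates_and_best_score(self, stamped):
        femur, tibia, patches = stamped
        cfg = CongruencyConfig(multistart_offsets=(-8.0, 0.0, 8.0))
        res = reconstruct_pose(femur, tibia, patches, cfg)
        assert len(res.candidates) >= 1
        best = min(c["score_mm"] for c in res.candidates)
        # ties within tolerance resolve toward the heuristic initialization
        assert res.score <= best + cfg.tolerance

    def test_accepted_icp_steps_never_increase_score(self, stamped, injury_pose):
        femur, tibia, patches = stamped
        ctx = _MatchContext(femur, tibia, patches, CongruencyConfig())
        t = injury_pose
        start = pose_from_parameters(t.flexion + 6, t.vv - 4, t.ie + 5, t.ap - 5, t.pd + 4)
        placement = ctx.placement_of(start)
        src, tgt, score = ctx.correspondences(placement)
        scores = [score]
        for _ in range(15):
            placement_new = kabsch(src, tgt)
            src2, tgt2, s2 = ctx.correspondences(placement_new)
            if s2 > scores[-1]:
                break  # the optimizer would reject this step
            scores.append(s2)
            src, tgt = src2, tgt2
        assert all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))
        assert scores[-1] < scores[0]

    def test_mirror_equivariance(self, stamped, injury_pose):
        femur, tibia, patches = stamped
        res = reconstruct_pose(femur, tibia, patches, starts=[injury_pose])
        fm, tm = femur.mirrored(), tibia.mirrored()
        # the mirrored subject's ground truth, in left-knee convention
        M = np.diag([-1.0, 1.0, 1.0])
        pl = ctx_placement(femur, tibia, patches, injury_pose)
        pl_m = RigidTransform(M @ pl.rotation @ M, M @ pl.translation)
        from bruisepose.knee_frames import decompose_relative_transform

        true_m = decompose_relative_transform(
            relative_from_placement(pl_m, fm.anatomical_frame(), tm.anatomical_frame())
        )
        res_m = reconstruct_pose(fm, tm, patches, starts=[true_m])
        assert res_m.pose.flexion == pytest.approx(res.pose.flexion, abs=0.3)
        assert res_m.pose.ap == pytest.approx(res.pose.ap, abs=0.3)
        assert res_m.pose.pd == pytest.approx(res.pose.pd, abs=0.3)
        assert res_m.pose.ie == pytest.approx(-res.pose.ie, abs=0.3)
        assert res_m.pose.vv == pytest.approx(-res.pose.vv, abs=0.3)


def ctx_placement(femur, tibia, patches, pose):
    ctx = _MatchContext(femur, tibia, patches, CongruencyConfig())
    return ctx.placement_of(pose)


@pytest.fixture(scope="module")
def resting_diagnostic(default_knee):
    """IE/VV score maps at a shallow resting contact (round dimple footprints)."""
    femur, tibia = default_knee
    pose = pose_from_parameters(pd=20.0)  # condyles just above their dishes
    patches = stamp_bruises(femur, tibia, pose, BruiseStampParams(threshold=0.6, seed=0))
    medial_only = [p for p in patches if p.compartment == "medial"]
    kwargs = dict(ie_halfspan=8.0, vv_halfspan=3.0, n_ie=5, n_vv=3)
    uni = unicompartmental_diagnostic(femur, tibia, medial_only, **kwargs)
    bi = unicompartmental_diagnostic(femur, tibia, patches, **kwargs)
    return uni, bi


class TestUnicompartmentalDiagnostic:
    def test_single_compartment_rotations_not_identifiable(self, resting_diagnostic):
        # a lone condyle resting in its dish can spin with near-constant
        # congruency; two compartments pin the rotation
        uni, bi = resting_diagnostic
        assert uni["ie_span_deg"] >= 5.0 * max(bi["ie_span_deg"], 1.0)

    def test_bicompartmental_span_is_narrow(self, resting_diagnostic):
        _, bi = resting_diagnostic
        assert bi["ie_span_deg"] <= 4.0

    def test_empty_patch_rejected(self, stamped):
        femur, tibia, patches = stamped
        with pytest.raises(EmptyPatch):
            unicompartmental_diagnostic(femur, tibia, patches[:1])
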