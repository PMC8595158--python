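"""Synthetic knee generator: surrogate bones, bruise stamping, squat motion.

The pipeline's real inputs are patient MRI-derived bone models and RSA squat
trajectories, which cannot be redistributed.  This module generates
analytically-defined surrogates for every input the downstream stages need:

* ``generate_knee`` — a distal femur with two spherical condyles and a
  proximal tibia with two concave, posteriorly sloped plateau compartments,
  each carrying a complete anatomical landmark set and per-vertex
  medial/lateral compartment labels.  Spherical/analytic surfaces keep exact
  oracles available for tests.
* ``stamp_bruises`` — bicompartmental edema footprints: with the tibia
  placed at a known ground-truth injury pose, every surface vertex within a
  proximity threshold of the opposing bone is marked, optionally dilated
  along the surface and perturbed at the boundary.  This makes explicit
  (and perturbable) the assumption that edema marks the bone-to-bone
  impact site.
* ``simulate_squat`` — an RSA-like squat trajectory whose noiseless pose at
  46 deg flexion approximates the matched-flexion squat operating point
  (AP 18.5 mm, PD +26.5 mm, IE +7.6 deg, VV -6.4 deg), with flexion-coupled
  secondary motion and additive Gaussian noise at the RSA repeatability
  scale.
* ``make_cohort_fixture`` — an on-disk cohort; the default 7-subject
  "paper7" fixture draws ground-truth injury poses that, by construction,
  exceed each subject's own squat range anteriorly (7/7), overlap
  proximo-distally (negative PD, 7/7), and split 5/1/1 external/within/
  internal and 5/2 valgus/varus — the qualitative out-of-range pattern the
  full pipeline must recover end-to-end.

Injury-like ground-truth poses are flexed (~46 deg) with a large anterior
tibial translation; at such poses the surface models interpenetrate
(negative PD means proximo-distal overlap), so the stamped footprints form
bands around the surface intersection curves, predominantly on the
posterior tibial plateau.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .bones import BoneMesh, BruisePatch, write_patches
from .errors import NoBicompartmentalContact, OutputExists, ResolutionError
from .geometry import SurfaceIndex
from .knee_frames import JointPose, pose_from_parameters, tibia_placement, write_pose
from .squat_kinematics import KinematicTrajectory, write_trajectory

import pandas as pd

__all__ = [
    "KneeGeometryParams",
    "BruiseStampParams",
    "SquatModelParams",
    "generate_knee",
    "stamp_bruises",
    "simulate_squat",
    "draw_injury_pose",
    "make_cohort_fixture",
    "load_subject",
]


@dataclass(frozen=True)
class KneeGeometryParams:
    """Geometry of one surrogate knee (all lengths mm, angles degrees)."""

    condyle_radius_medial: float = 22.0
    condyle_radius_lateral: float = 21.0
    intercondylar_spacing: float = 46.0  # center-to-center distance of the condyles
    # antero-posterior / proximo-distal offsets of each condyle center (mm):
    # real condyles are not coaxial, and a common rotation axis would leave
    # the flexion direction almost unconstrained by bruise matching
    condyle_offset_medial: tuple = (0.0, 0.0)
    condyle_offset_lateral: tuple = (3.0, -1.5)
    plateau_depth_medial: float = 2.5  # concavity depth of the medial dish
    plateau_depth_lateral: float = 2.0
    plateau_halfwidth: float = 16.0  # radius of each compartment dish
    posterior_slope_deg: float = 7.0
    # the posterior plateau margin curves steeply downward (the
    # "vertically-oriented" region where injury bruises form); quadratic
    # rolloff coefficient (1/mm) starting at posterior_flare_start_mm
    posterior_rolloff: float = 0.05
    posterior_flare_start: float = 22.0
    resolution: float = 1.4  # target edge length
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.condyle_radius_medial, self.condyle_radius_lateral) <= 0:
            raise ValueError("condyle radii must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if min(self.plateau_depth_medial, self.plateau_depth_lateral) <= 0:
            raise ValueError("plateau depths must be positive")


@dataclass(frozen=True)
class BruiseStampParams:
    """How edema footprints are stamped from the ground-truth pose."""

    threshold: float = 0.8  # mm surface-to-surface proximity defining the footprint
    dilation: float = 0.0  # mm of along-surface edema spread beyond contact
    boundary_noise: float = 0.0  # mm SD of per-vertex threshold jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.dilation < 0 or self.boundary_noise < 0:
            raise ValueError("dilation and boundary_noise must be >= 0")


@dataclass(frozen=True)
class SquatModelParams:
    """Flexion-driven squat model: descent then ascent with linear coupling.

    Secondary parameters are linear in flexion, anchored at 46 deg flexion
    (the mean injury flexion of interest) so the noiseless pose there equals
    the anchor values.  Noise defaults to the RSA repeatability scale.
    """

    flexion_start: float = 10.0
    flexion_end: float = 100.0
    n_frames: int = 100
    duration_s: float = 4.0
    anchor_flexion: float = 46.0
    # parameter -> (value at anchor flexion, slope per degree of flexion)
    coupling: dict = field(
        default_factory=lambda: {
            "ap": (18.5, -0.06),
            "pd": (26.5, -0.04),
            "ie": (7.6, 0.10),  # screw-home-like: internal rotation grows with flexion
            "vv": (-6.4, 0.02),
        }
    )
    noise_sd_mm: float = 0.3
    noise_sd_deg: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.flexion_start == self.flexion_end:
            raise ValueError("flexion range is degenerate")


def _icosphere_subdivisions(radius: float, edge: float) -> int:
    # icosahedron edge ~ 1.0514 r, halved per subdivision
    n = int(np.ceil(np.log2(1.0514 * radius / edge)))
    return max(2, n)


def generate_knee(params: KneeGeometryParams = KneeGeometryParams()) -> tuple[BoneMesh, BoneMesh]:
    """Build the surrogate femur and tibia with landmarks and labels.

    Coordinates follow the right-knee convention: x lateral, y anterior,
    z proximal.  The femoral mesh frame doubles as the world frame; the
    condyle sphere centers sit on the x-axis at z = 0.
    """
    r_m = params.condyle_radius_medial
    r_l = params.condyle_radius_lateral
    s = params.intercondylar_spacing
    if params.resolution >= min(r_m, r_l):
        raise ResolutionError(
            f"resolution {params.resolution} mm too coarse for condyle radii "
            f"({r_m}, {r_l}) mm"
        )

    # --- femur: two condyle spheres + shaft cylinder -----------------------
    parts, labels = [], []
    subdiv = _icosphere_subdivisions(max(r_m, r_l), params.resolution)
    for radius, x0, (oy, oz), label in (
        (r_m, -s / 2, params.condyle_offset_medial, "medial"),
        (r_l, +s / 2, params.condyle_offset_lateral, "lateral"),
    ):
        sph = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
        sph.apply_translation([x0, oy, oz])
        parts.append(sph)
        labels.append(np.full(len(sph.vertices), label, dtype="<U7"))
    # shaft: prolate ellipsoid (keeps every face small so spatial pruning works)
    shaft_r = 0.45 * s
    shaft_h = 25.0
    shaft = trimesh.creation.icosphere(
        subdivisions=_icosphere_subdivisions(shaft_h, params.resolution), radius=1.0
    )
    shaft.apply_scale([shaft_r, shaft_r, shaft_h])
    shaft.apply_translation([0.0, 0.0, 35.0])  # spans z in [10, 60]
    parts.append(shaft)
    labels.append(np.full(len(shaft.vertices), "none", dtype="<U7"))
    femur_mesh = trimesh.util.concatenate(parts)
    femur_labels = np.concatenate(labels)
    n_condyle_faces = len(parts[0].faces) + len(parts[1].faces)  # spheres come first
    # epicondylar landmarks on the nominal flexion axis (independent of the
    # small condyle-center offsets, as real epicondyles are of the condyles')
    femur_landmarks = {
        "medial_epicondyle": np.array([-s / 2 - r_m, 0.0, 0.0]),
        "lateral_epicondyle": np.array([s / 2 + r_l, 0.0, 0.0]),
        "femoral_shaft": np.array([0.0, 0.0, 55.0]),
    }
    femur = BoneMesh(
        mesh=trimesh.Trimesh(femur_mesh.vertices, femur_mesh.faces, process=False),
        landmarks=femur_landmarks,
        name="femur",
        compartment=femur_labels,
        articular_faces=np.arange(n_condyle_faces),
    )

    # --- tibia: gridded plateau with two dishes, skirt and bottom ----------
    # the articulating top grid is finer than the nominal resolution; the
    # skirt and bottom stay coarser but still small enough that the spatial
    # index prunes well (no oversized triangles)
    w = params.plateau_halfwidth
    half_width = s / 2 + w + 4.0
    half_depth = 36.0
    top_edge = 0.6 * params.resolution
    nx = int(np.ceil(2 * half_width / top_edge)) + 1
    ny = int(np.ceil(2 * half_depth / top_edge)) + 1
    xs = np.linspace(-half_width, half_width, nx)
    ys = np.linspace(-half_depth, half_depth, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    z = np.tan(np.radians(params.posterior_slope_deg)) * gy  # posterior (y<0) lower
    # steep posterior margin: quadratic rolloff toward the posterior horn
    over = np.maximum(-gy - params.posterior_flare_start, 0.0)
    z = z - params.posterior_rolloff * over**2
    for depth, x0 in ((params.plateau_depth_medial, -s / 2), (params.plateau_depth_lateral, s / 2)):
        rho2 = (gx - x0) ** 2 + gy**2
        r_dish = (w**2 + depth**2) / (2 * depth)
        inside = rho2 < w**2
        z = np.where(
            inside,
            z + (r_dish - np.sqrt(np.maximum(r_dish**2 - rho2, 0.0))) - depth,
            z,
        )
    top_v = np.column_stack([gx.ravel(), gy.ravel(), z.ravel()])

    def vid(i, j):
        return i * ny + j

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append([a, b, c])  # counter-clockwise seen from +z
            faces.append([a, c, d])
    # boundary loop (counter-clockwise seen from above)
    loop = np.array(
        [vid(i, 0) for i in range(nx)]
        + [vid(nx - 1, j) for j in range(1, ny)]
        + [vid(i, ny - 1) for i in range(nx - 2, -1, -1)]
        + [vid(0, j) for j in range(ny - 2, 0, -1)],
        dtype=np.int64,
    )
    base_z = -45.0
    n_top = len(top_v)
    m = len(loop)
    # bottom: flat copy of the top grid, reversed winding
    bottom_v = top_v.copy()
    bottom_v[:, 2] = base_z
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append([n_top + a, n_top + c, n_top + b])
            faces.append([n_top + a, n_top + d, n_top + c])
    # skirt: rings interpolating each boundary vertex down to the bottom
    skirt_step = 2.0 * params.resolution
    n_rings = max(1, int(np.ceil((top_v[loop, 2].max() - base_z) / skirt_step)) - 1)
    ring_start = 2 * n_top
    verts_extra = []
    prev = loop  # indices of the ring above
    for r in range(1, n_rings + 1):
        alpha = r / (n_rings + 1)
        ring_v = top_v[loop] * (1 - alpha) + bottom_v[loop] * alpha
        verts_extra.append(ring_v)
        cur = np.arange(ring_start + (r - 1) * m, ring_start + r * m)
        for k in range(m):
            k2 = (k + 1) % m
            faces.append([prev[k], prev[k2], cur[k2]])
            faces.append([prev[k], cur[k2], cur[k]])
        prev = cur
    bottom_loop = n_top + loop
    for k in range(m):
        k2 = (k + 1) % m
        faces.append([prev[k], prev[k2], bottom_loop[k2]])
        faces.append([prev[k], bottom_loop[k2], bottom_loop[k]])
    tibia_v = np.vstack([top_v, bottom_v] + verts_extra)
    tibia_f = np.asarray(faces, dtype=np.int64)
    # whole plateau top split into compartments at the midline so every
    # articular vertex has a compartment (skirt/bottom stay unlabeled)
    tibia_labels = np.full(len(tibia_v), "none", dtype="<U7")
    plateau = np.zeros(len(tibia_v), dtype=bool)
    plateau[:n_top] = True
    tibia_labels[plateau & (tibia_v[:, 0] < 0)] = "medial"
    tibia_labels[plateau & (tibia_v[:, 0] >= 0)] = "lateral"
    tibia_landmarks = {
        "medial_plateau_edge": np.array([-half_width, 0.0, 0.0]),
        "lateral_plateau_edge": np.array([half_width, 0.0, 0.0]),
        "tibial_shaft": np.array([0.0, 0.0, -40.0]),
    }
    tibia = BoneMesh(
        mesh=trimesh.Trimesh(tibia_v, tibia_f, process=False),
        landmarks=tibia_landmarks,
        name="tibia",
        compartment=tibia_labels,
        articular_faces=np.arange(2 * (nx - 1) * (ny - 1)),  # the plateau top grid
    )
    return femur, tibia


def _vertex_graph(bone: BoneMesh) -> csr_matrix:
    edges = bone.mesh.edges_unique
    lengths = bone.mesh.edges_unique_length
    n = len(bone.vertices)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    d = np.concatenate([lengths, lengths])
    return csr_matrix((d, (i, j)), shape=(n, n))


def _dilate(bone: BoneMesh, seed_idx: np.ndarray, radius: float, label: str) -> np.ndarray:
    """Grow a footprint ``radius`` mm along the surface, staying articular."""
    if radius <= 0 or seed_idx.size == 0:
        return seed_idx
    graph = _vertex_graph(bone)
    dist = dijkstra(graph, directed=False, indices=seed_idx, limit=radius, min_only=True)
    grown = np.flatnonzero(np.isfinite(dist) & (dist <= radius))
    keep = grown[bone.compartment[grown] != "none"]
    return np.union1d(seed_idx, keep)


def stamp_bruises(
    femur: BoneMesh,
    tibia: BoneMesh,
    true_pose: JointPose,
    stamp: BruiseStampParams = BruiseStampParams(),
) -> list[BruisePatch]:
    """Stamp the four edema footprints under a known injury pose.

    A vertex joins a footprint when its distance to the opposing bone's
    surface (tibia placed at ``true_pose``) is at most the proximity
    threshold (plus its own Gaussian jitter when ``boundary_noise`` > 0);
    footprints are then dilated ``dilation`` mm along the surface within
    their compartment.  Returns patches in the order femoral medial,
    femoral lateral, tibial medial, tibial lateral.

    Raises `NoBicompartmentalContact` if any compartment footprint is empty
    — the synthetic analogue of excluding unicompartmental cases.
    """
    placement = tibia_placement(true_pose, femur.anatomical_frame(), tibia.anatomical_frame())
    tibia_world = placement.apply(tibia.vertices)
    # footprints form where the *articular* surfaces meet: proximity to the
    # shaft or to the plateau side walls is not an impact
    fem_av, fem_af = femur.articular_surface()
    tib_av, tib_af = tibia.articular_surface()
    femur_index = SurfaceIndex(fem_av, fem_af)
    tibia_index = SurfaceIndex(placement.apply(tib_av), tib_af)

    rng = np.random.default_rng(stamp.seed)
    max_d = stamp.threshold + 5.0 * stamp.boundary_noise

    def hits(bone: BoneMesh, dists: np.ndarray) -> np.ndarray:
        jitter = (
            rng.normal(0.0, stamp.boundary_noise, size=len(dists))
            if stamp.boundary_noise > 0
            else np.zeros(len(dists))
        )
        return np.flatnonzero(
            (dists <= stamp.threshold + jitter) & (bone.compartment != "none")
        )

    fem_hit = hits(femur, tibia_index.distances(femur.vertices, max_distance=max_d))
    tib_hit = hits(tibia, femur_index.distances(tibia_world, max_distance=max_d))

    # femoral footprints carry the condyle's own compartment; tibial
    # footprints are tagged by the condyle that struck them (a bruise near
    # the midline belongs to whichever compartment's condyle made it)
    fem_tags = femur.compartment[fem_hit]
    cond_index = {}
    for comp in ("medial", "lateral"):
        cmask = femur.compartment[femur.faces].astype("<U7")
        keep = (cmask == comp).any(axis=1)
        cond_index[comp] = SurfaceIndex(femur.vertices, femur.faces[keep])
    if tib_hit.size:
        d_med = cond_index["medial"].distances(tibia_world[tib_hit])
        d_lat = cond_index["lateral"].distances(tibia_world[tib_hit])
        tib_tags = np.where(d_med <= d_lat, "medial", "lateral")
    else:
        tib_tags = np.empty(0, dtype="<U7")

    patches: list[BruisePatch] = []
    for bone, hit_idx, tags in ((femur, fem_hit, fem_tags), (tibia, tib_hit, tib_tags)):
        for comp in ("medial", "lateral"):
            idx = hit_idx[tags == comp]
            idx = _dilate(bone, idx, stamp.dilation, comp)
            if idx.size == 0:
                raise NoBicompartmentalContact(
                    f"no {comp} footprint on the {bone.name}: pose does not "
                    "produce bicompartmental contact"
                )
            patches.append(BruisePatch(bone=bone.name, compartment=comp, vertex_indices=idx))
    return patches


def simulate_squat(
    params: SquatModelParams = SquatModelParams(), subject_id: str = "sim"
) -> KinematicTrajectory:
    """Simulate an RSA-like squat: flexion descent then ascent with coupling."""
    n = params.n_frames
    n_desc = max(2, n // 2)
    descent = np.linspace(params.flexion_start, params.flexion_end, n_desc)
    ascent = np.linspace(params.flexion_end, params.flexion_start, n - n_desc + 1)[1:]
    flexion = np.concatenate([descent, ascent])
    rng = np.random.default_rng(params.seed)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(flexion)),
            "time_s": np.linspace(0.0, params.duration_s, len(flexion)),
        }
    )
    noise = {
        "flexion": params.noise_sd_deg,
        "ie": params.noise_sd_deg,
        "vv": params.noise_sd_deg,
        "ap": params.noise_sd_mm,
        "pd": params.noise_sd_mm,
    }
    df["flexion_deg"] = flexion + (
        rng.normal(0, noise["flexion"], len(flexion)) if noise["flexion"] > 0 else 0.0
    )
    col = {"vv": "vv_deg", "ie": "ie_deg", "ap": "ap_mm", "pd": "pd_mm"}
    for name in ("vv", "ie", "ap", "pd"):
        anchor, slope = params.coupling[name]
        v = anchor + slope * (flexion - params.anchor_flexion)
        if noise[name] > 0:
            v = v + rng.normal(0, noise[name], len(flexion))
        df[col[name]] = v
    return KinematicTrajectory(df, subject_id=subject_id)


def _noiseless_limits(params: SquatModelParams, name: str) -> tuple[float, float]:
    anchor, slope = params.coupling[name]
    ends = [
        anchor + slope * (params.flexion_start - params.anchor_flexion),
        anchor + slope * (params.flexion_end - params.anchor_flexion),
    ]
    return min(ends), max(ends)


# paper7 engineered classes: 5 external / 1 within / 1 internal IE,
# 5 valgus / 2 varus, interleaved so the two classifications decorrelate
_PAPER7_IE = ("external", "external", "within", "external", "internal", "external", "external")
_PAPER7_VV = ("valgus", "varus", "valgus", "valgus", "varus", "valgus", "valgus")


def draw_injury_pose(
    geom: KneeGeometryParams,
    tibia: BoneMesh,
    rng: np.random.Generator,
    squat: SquatModelParams,
    ie_class: str = "external",
    vv_class: str = "valgus",
    target_penetration: tuple[float, float] = (7.0, 11.0),
) -> tuple[JointPose, KneeGeometryParams]:
    """Engineered ground-truth injury pose for one synthetic subject.

    Rotations and the proximo-distal coordinate are drawn relative to the
    subject's own (noiseless) squat limits so the out-of-range pattern holds
    by construction.  The anterior translation is then solved (bisection
    against the analytic medial condyle sphere) so the medial condyle
    indents the posterior plateau margin by a target depth, and the lateral
    condyle's inferior offset is solved likewise — the subject's anatomy is
    chosen such that the injury was bicompartmental, mirroring the study's
    inclusion criterion.  Returns the pose and the adjusted geometry (the
    femur must be regenerated from it; the tibia is unchanged).
    """
    flexion = float(np.clip(rng.normal(46.1, 3.8), 38.0, 54.0))
    pd = float(rng.uniform(-6.0, -1.5))  # proximo-distal overlap, negative
    ie_lo, ie_hi = _noiseless_limits(squat, "ie")
    if ie_class == "external":
        ie = ie_lo - rng.uniform(3.0, 10.0)
    elif ie_class == "internal":
        ie = ie_hi + rng.uniform(2.5, 5.0)
    else:
        ie = 0.5 * (ie_lo + ie_hi) + rng.uniform(-1.0, 1.0)
    vv_lo, vv_hi = _noiseless_limits(squat, "vv")
    if vv_class == "valgus":
        vv = vv_hi + rng.uniform(6.0, 12.0)
    else:
        vv = vv_lo - rng.uniform(2.5, 4.5)
    delta_m = float(rng.uniform(*target_penetration))
    delta_l = float(rng.uniform(*target_penetration))

    s = geom.intercondylar_spacing
    r_m, r_l = geom.condyle_radius_medial, geom.condyle_radius_lateral
    oy_m, oz_m = geom.condyle_offset_medial
    oy_l, _ = geom.condyle_offset_lateral
    # frames are analytic for the surrogate geometry (identity axes)
    from .knee_frames import AnatomicalFrame

    ff = AnatomicalFrame(np.array([(r_l - r_m) / 2, 0.0, 0.0]), np.eye(3))
    tf = tibia.anatomical_frame()
    tav, _ = tibia.articular_surface()
    c_m = np.array([-s / 2, oy_m, oz_m])

    def tib_world(ap: float) -> np.ndarray:
        pose = pose_from_parameters(flexion=flexion, vv=float(vv), ie=float(ie), ap=ap, pd=pd)
        return tibia_placement(pose, ff, tf).apply(tav)

    def pen_medial(ap: float) -> float:
        tw = tib_world(ap)
        return float(r_m - np.linalg.norm(tw - c_m, axis=1).min())

    # medial penetration decreases monotonically with anterior translation
    lo, hi = 36.0, 80.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if pen_medial(mid) > delta_m:
            lo = mid
        else:
            hi = mid
    ap = 0.5 * (lo + hi)

    # lateral condyle inferior offset: lower the sphere until it indents
    # the plateau by its own target depth at the solved pose
    tw = tib_world(ap)
    dxy = np.linalg.norm(tw[:, :2] - np.array([s / 2, oy_l]), axis=1)

    def pen_lateral(oz: float) -> float:
        d = np.sqrt(dxy**2 + (tw[:, 2] - oz) ** 2)
        return float(r_l - d.min())

    lo_z, hi_z = -14.0, 6.0  # lower sphere -> deeper indentation
    for _ in range(30):
        mid = 0.5 * (lo_z + hi_z)
        if pen_lateral(mid) > delta_l:
            lo_z = mid
        else:
            hi_z = mid
    oz_l = 0.5 * (lo_z + hi_z)

    pose = pose_from_parameters(flexion=flexion, vv=float(vv), ie=float(ie), ap=float(ap), pd=pd)
    adjusted = replace(geom, condyle_offset_lateral=(oy_l, float(oz_l)))
    return pose, adjusted


def _subject_geometry(rng: np.random.Generator, resolution: float) -> KneeGeometryParams:
    return KneeGeometryParams(
        condyle_radius_medial=rng.uniform(20.5, 23.0),
        condyle_radius_lateral=rng.uniform(19.5, 22.0),
        intercondylar_spacing=rng.uniform(44.0, 48.0),
        condyle_offset_medial=(rng.uniform(-2.0, 2.0), rng.uniform(-1.0, 1.0)),
        condyle_offset_lateral=(rng.uniform(1.5, 4.5), rng.uniform(-2.5, -0.5)),
        plateau_depth_medial=rng.uniform(2.2, 3.0),
        plateau_depth_lateral=rng.uniform(1.8, 2.6),
        posterior_slope_deg=rng.uniform(5.0, 9.0),
        resolution=resolution,
    )


def _subject_squat(rng: np.random.Generator, seed: int) -> SquatModelParams:
    return SquatModelParams(
        coupling={
            "ap": (18.5 + rng.normal(0, 0.8), -0.06 * rng.uniform(0.8, 1.2)),
            "pd": (26.5 + rng.normal(0, 1.2), -0.04 * rng.uniform(0.8, 1.2)),
            "ie": (7.6 + rng.normal(0, 1.2), 0.10 * rng.uniform(0.8, 1.2)),
            "vv": (-6.4 + rng.normal(0, 0.8), 0.02 * rng.uniform(0.8, 1.2)),
        },
        seed=seed,
    )


def make_cohort_fixture(
    out_dir: str | Path,
    n_subjects: int = 7,
    seed: int = 0,
    overwrite: bool = False,
    stamp: BruiseStampParams | None = None,
    resolution: float = 1.4,
) -> Path:
    """Write an n-subject synthetic cohort to disk; returns the cohort root.

    With ``n_subjects == 7`` the ground-truth poses follow the engineered
    "paper7" out-of-range pattern (anterior 7/7, negative PD 7/7, IE
    5 external / 1 within / 1 internal, VV 5 valgus / 2 varus); for other
    sizes the per-subject IE/VV classes cycle through the same lists.
    Everything is deterministic in (n_subjects, seed).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise OutputExists(f"{out_dir} exists; pass overwrite=True to replace it")
        for p in sorted(out_dir.rglob("*"), reverse=True):
            p.unlink() if p.is_file() else p.rmdir()
    out_dir.mkdir(parents=True, exist_ok=True)
    if stamp is None:
        # edema spreads a little beyond contact and has a fuzzy boundary
        stamp = BruiseStampParams(threshold=0.8, dilation=1.5, boundary_noise=0.3)

    manifest = {"n_subjects": n_subjects, "seed": seed, "subjects": []}
    for k in range(n_subjects):
        rng = np.random.default_rng([seed, k])
        subject = f"subject_{k + 1:02d}"
        sdir = out_dir / subject
        sdir.mkdir()
        geom = _subject_geometry(rng, resolution)
        _, tibia = generate_knee(geom)
        squat_params = _subject_squat(rng, seed=int(rng.integers(2**31 - 1)))
        true_pose, geom = draw_injury_pose(
            geom, tibia, rng, squat_params, _PAPER7_IE[k % 7], _PAPER7_VV[k % 7]
        )
        femur, _ = generate_knee(geom)
        patches = stamp_bruises(
            femur, tibia, true_pose, replace(stamp, seed=int(rng.integers(2**31 - 1)))
        )
        trajectory = simulate_squat(squat_params, subject_id=subject)

        femur.save(sdir)
        tibia.save(sdir)
        write_patches(patches, sdir / "patches.json")
        write_trajectory(trajectory, sdir / "squat.csv")
        write_pose(true_pose, sdir / "true_pose.json")
        manifest["subjects"].append(
            {
                "id": subject,
                "side": "right",
                "age_years": int(np.clip(np.round(rng.normal(19, 5)), 16, 30)),
                "ie_class": _PAPER7_IE[k % 7],
                "vv_class": _PAPER7_VV[k % 7],
            }
        )
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out_dir


def load_subject(subject_dir: str | Path) -> dict:
    """Load one subject directory of the cohort layout."""
    from .bones import read_patches
    from .knee_frames import read_pose
    from .squat_kinematics import read_trajectory

    subject_dir = Path(subject_dir)
    out = {
        "femur": BoneMesh.load(subject_dir, "femur"),
        "tibia": BoneMesh.load(subject_dir, "tibia"),
        "patches": read_patches(subject_dir / "patches.json"),
        "trajectory": read_trajectory(subject_dir / "squat.csv"),
    }
    pose_path = subject_dir / "true_pose.json"
    if pose_path.exists():
        out["true_pose"] = read_pose(pose_path)
    return out


def tree_hash(root: str | Path) -> str:
    """SHA-256 over the sorted relative paths and contents of a directory."""
    root = Path(root)
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
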