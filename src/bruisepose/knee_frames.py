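"""Anatomical coordinate systems and the five-parameter knee-joint description.

The tibiofemoral pose is reported in the floating-axis joint coordinate
system of Grood & Suntay, the convention recommended by the International
Society of Biomechanics for the knee: flexion about the femoral
medio-lateral axis, internal-external (IE) rotation about the tibial
longitudinal axis, and varus-valgus (VV) rotation about the mutual floating
axis perpendicular to both.  Translations are the components of the vector
from the femoral to the tibial anatomical origin along those same three
joint axes.

Sign conventions (right-knee; left knees are mirrored at load time):

=========  =====================================================
flexion    positive = knee flexion (degrees)
vv         positive = valgus (degrees)
ie         positive = internal tibial rotation (degrees)
ap         positive = anterior tibial position (mm)
pd         positive = distracted/distal tibial position (mm);
           negative means the bones overlap along the joint axis
=========  =====================================================

Absolute AP/PD values are coordinates of one anatomical origin relative to
the other and therefore depend on where the landmarks place those origins;
only *differences* between conditions measured with the same landmarks are
convention-free.

Frame axes are stored column-wise as (medio-lateral, antero-posterior,
proximo-distal); for a right knee the ML axis points laterally, AP
anteriorly, PD proximally, forming a right-handed basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometry, MissingLandmark, SingularPose
from .geometry import RigidTransform

__all__ = [
    "FEMUR_LANDMARKS",
    "TIBIA_LANDMARKS",
    "AnatomicalFrame",
    "JointPose",
    "build_anatomical_frame",
    "compose_joint_pose",
    "decompose_joint_pose",
    "decompose_relative_transform",
    "pose_from_parameters",
    "tibia_placement",
    "relative_from_placement",
    "read_landmarks",
    "write_landmarks",
    "mirror_landmarks",
    "pose_to_dict",
    "pose_from_dict",
    "read_pose",
    "write_pose",
]

#: Required landmark names per bone.  The epicondyles / plateau edge points
#: define the medio-lateral axis and the origin (their midpoint); the shaft
#: point orients the longitudinal axis.
FEMUR_LANDMARKS = ("medial_epicondyle", "lateral_epicondyle", "femoral_shaft")
TIBIA_LANDMARKS = ("medial_plateau_edge", "lateral_plateau_edge", "tibial_shaft")

_SINGULARITY_TOL_DEG = 1e-3


@dataclass(frozen=True)
class AnatomicalFrame:
    """Anatomical reference frame: origin (mm) and axes as columns (ML, AP, PD)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        A = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if np.abs(A.T @ A - np.eye(3)).max() > 1e-9:
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("frame must be right-handed")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", A)

    @property
    def ml_axis(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def ap_axis(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def pd_axis(self) -> np.ndarray:
        return self.axes[:, 2]

    def transformed(self, transform: RigidTransform) -> "AnatomicalFrame":
        """Frame after a rigid motion of the underlying bone."""
        return AnatomicalFrame(transform.apply(self.origin), transform.rotation @ self.axes)


@dataclass(frozen=True)
class JointPose:
    """Five-parameter tibiofemoral state plus the underlying rigid transform.

    ``transform`` maps tibia-frame coordinates to femur-frame coordinates
    (i.e. it is the pose of the tibial anatomical frame expressed in the
    femoral one).  ``ml`` is the medio-lateral translation component, carried
    along so that compose/decompose form an exact bijection; it is not part
    of the five reported parameters.
    """

    flexion: float
    vv: float
    ie: float
    ap: float
    pd: float
    transform: RigidTransform
    ml: float = 0.0

    def parameters(self) -> dict[str, float]:
        return {
            "flexion_deg": self.flexion,
            "vv_deg": self.vv,
            "ie_deg": self.ie,
            "ap_mm": self.ap,
            "pd_mm": self.pd,
        }


def _require(landmarks: dict[str, np.ndarray], names: tuple[str, ...]) -> list[np.ndarray]:
    out = []
    for n in names:
        if n not in landmarks:
            raise MissingLandmark(f"landmark {n!r} missing (have {sorted(landmarks)})")
        out.append(np.asarray(landmarks[n], dtype=float).reshape(3))
    return out


def build_anatomical_frame(
    landmarks: dict[str, np.ndarray], bone: str, side: str = "right"
) -> AnatomicalFrame:
    """Construct the ISB-style anatomical frame of a femur or tibia.

    The medio-lateral axis runs from the medial to the lateral landmark of
    the epicondylar (femur) or plateau-edge (tibia) pair — reversed for left
    knees, so that flexion/AP/PD keep their signs on both sides while IE and
    VV flip (the side-invariant clinical convention that lets subjects be
    pooled).  The origin is the midpoint of that pair.  The longitudinal
    axis points proximally toward (femur) or away from (tibia) the shaft
    landmark, orthogonalized against the ML axis; the antero-posterior axis
    completes the right-handed triad.

    Parameters
    ----------
    landmarks
        Mapping of landmark name to position (mm).  Required names are
        `FEMUR_LANDMARKS` or `TIBIA_LANDMARKS`.
    bone
        ``"femur"`` or ``"tibia"``.
    side
        ``"right"`` or ``"left"``.
    """
    if bone == "femur":
        med, lat, shaft = _require(landmarks, FEMUR_LANDMARKS)
    elif bone == "tibia":
        med, lat, shaft = _require(landmarks, TIBIA_LANDMARKS)
    else:
        raise ValueError(f"bone must be 'femur' or 'tibia', got {bone!r}")
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")

    origin = 0.5 * (med + lat)
    ml = (lat - med) if side == "right" else (med - lat)
    ml_norm = np.linalg.norm(ml)
    if ml_norm < 1e-9:
        raise DegenerateGeometry("medial/lateral landmarks coincide")
    ml = ml / ml_norm

    # femoral shaft landmark lies proximal to the joint; tibial one distal
    proximal_raw = (shaft - origin) if bone == "femur" else (origin - shaft)
    pd = proximal_raw - (proximal_raw @ ml) * ml
    pd_norm = np.linalg.norm(pd)
    if pd_norm < 1e-9 * max(1.0, np.linalg.norm(proximal_raw)):
        raise DegenerateGeometry("shaft landmark collinear with the medio-lateral axis")
    pd = pd / pd_norm
    ap = np.cross(pd, ml)
    return AnatomicalFrame(origin, np.column_stack([ml, ap, pd]))


def _joint_axes(r_rel: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint axes (femoral ML, floating, tibial PD) in femur-frame coords."""
    e1 = np.array([1.0, 0.0, 0.0])
    e3 = r_rel @ np.array([0.0, 0.0, 1.0])
    f = np.cross(e3, e1)
    n = np.linalg.norm(f)
    if n < np.sin(np.radians(_SINGULARITY_TOL_DEG)):
        raise SingularPose("femoral ML and tibial PD axes (anti)parallel: VV at +/-90 deg")
    return e1, f / n, e3


def compose_joint_pose(
    flexion: float = 0.0,
    vv: float = 0.0,
    ie: float = 0.0,
    ap: float = 0.0,
    pd: float = 0.0,
    ml_offset: float = 0.0,
) -> RigidTransform:
    """Rigid transform (tibia frame w.r.t. femur frame) from joint parameters.

    Rotations follow the floating-axis sequence (flexion about femoral ML,
    then VV about the floating axis, then IE about the tibial long axis);
    translations place the tibial origin so that its components along the
    femoral ML, floating, and tibial longitudinal axes equal ``ml_offset``,
    ``ap`` and ``-pd`` respectively (distraction positive).

    All angles in degrees, translations in mm.  Zero everywhere yields the
    identity transform.
    """
    for name, v in (("flexion", flexion), ("vv", vv), ("ie", ie), ("ap", ap), ("pd", pd)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if 90.0 - abs(vv) < _SINGULARITY_TOL_DEG:
        raise SingularPose(f"vv = {vv} deg is at the gimbal singularity")
    # intrinsic x-y'-z'' sequence; signs map anatomical directions onto the
    # right-knee basis (ML lateral, AP anterior, PD proximal)
    r = Rotation.from_euler("XYZ", [-flexion, -vv, ie], degrees=True).as_matrix()
    e1, e2, e3 = _joint_axes(r)
    # e2 is orthogonal to e1 and e3; only the e1/e3 pair is oblique
    c = float(e1 @ e3)
    alpha, beta = np.linalg.solve(np.array([[1.0, c], [c, 1.0]]), [ml_offset, -pd])
    t = ap * e2 + alpha * e1 + beta * e3
    return RigidTransform(r, t)


def decompose_relative_transform(transform: RigidTransform) -> JointPose:
    """Joint parameters of a tibia-w.r.t.-femur rigid transform."""
    r = transform.rotation
    # sin(vv) = R[0, 2] for the X(-f) Y(-v) Z(i) sequence
    if 1.0 - abs(r[0, 2]) < np.sin(np.radians(_SINGULARITY_TOL_DEG)) ** 2 / 2:
        raise SingularPose("relative pose at the VV gimbal singularity")
    a, b, cang = Rotation.from_matrix(r).as_euler("XYZ", degrees=True)
    flexion, vv, ie = -a, -b, cang
    e1, e2, e3 = _joint_axes(r)
    t = transform.translation
    return JointPose(
        flexion=float(flexion),
        vv=float(vv),
        ie=float(ie),
        ap=float(t @ e2),
        pd=float(-(t @ e3)),
        ml=float(t @ e1),
        transform=transform,
    )


def decompose_joint_pose(femur_frame: AnatomicalFrame, tibia_frame: AnatomicalFrame) -> JointPose:
    """Five-parameter pose of the tibia relative to the femur.

    Both frames must be expressed in a common (world) coordinate system;
    the returned ``transform`` maps tibia-frame to femur-frame coordinates.
    """
    r_rel = femur_frame.axes.T @ tibia_frame.axes
    t_rel = femur_frame.axes.T @ (tibia_frame.origin - femur_frame.origin)
    return decompose_relative_transform(RigidTransform(r_rel, t_rel))


def pose_from_parameters(
    flexion: float = 0.0,
    vv: float = 0.0,
    ie: float = 0.0,
    ap: float = 0.0,
    pd: float = 0.0,
    ml_offset: float = 0.0,
) -> JointPose:
    """JointPose carrying both the parameters and their composed transform."""
    t = compose_joint_pose(flexion, vv, ie, ap, pd, ml_offset)
    return JointPose(flexion, vv, ie, ap, pd, transform=t, ml=ml_offset)


def tibia_placement(
    pose: JointPose | RigidTransform,
    femur_frame: AnatomicalFrame,
    tibia_frame: AnatomicalFrame,
) -> RigidTransform:
    """World placement of the tibia mesh realizing a joint pose.

    ``femur_frame``/``tibia_frame`` are the anatomical frames in each bone's
    own mesh coordinates (femur mesh coordinates double as world).  Returns
    the rigid transform to apply to tibia mesh vertices.
    """
    rel = pose.transform if isinstance(pose, JointPose) else pose
    r = femur_frame.axes @ rel.rotation @ tibia_frame.axes.T
    t = femur_frame.origin + femur_frame.axes @ rel.translation - r @ tibia_frame.origin
    return RigidTransform(r, t)


def relative_from_placement(
    placement: RigidTransform,
    femur_frame: AnatomicalFrame,
    tibia_frame: AnatomicalFrame,
) -> RigidTransform:
    """Inverse of `tibia_placement`: joint transform from a mesh placement."""
    r = femur_frame.axes.T @ placement.rotation @ tibia_frame.axes
    t = femur_frame.axes.T @ (placement.apply(tibia_frame.origin) - femur_frame.origin)
    return RigidTransform(r, t)


def read_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    """Load a landmark JSON file: a list of ``{"name": ..., "xyz": [...]}``."""
    with open(path) as fh:
        items = json.load(fh)
    out = {}
    for item in items:
        xyz = np.asarray(item["xyz"], dtype=float).reshape(3)
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"non-finite landmark {item['name']!r} in {path}")
        out[item["name"]] = xyz
    return out


def write_landmarks(landmarks: dict[str, np.ndarray], path: str | Path) -> None:
    items = [{"name": n, "xyz": [float(v) for v in xyz]} for n, xyz in landmarks.items()]
    with open(path, "w") as fh:
        json.dump(items, fh, indent=1)
        fh.write("\n")


def pose_to_dict(pose: JointPose) -> dict:
    return {
        "flexion_deg": pose.flexion,
        "vv_deg": pose.vv,
        "ie_deg": pose.ie,
        "ap_mm": pose.ap,
        "pd_mm": pose.pd,
        "ml_mm": pose.ml,
        "rotation": pose.transform.rotation.tolist(),
        "translation": pose.transform.translation.tolist(),
    }


def pose_from_dict(d: dict) -> JointPose:
    return JointPose(
        flexion=float(d["flexion_deg"]),
        vv=float(d["vv_deg"]),
        ie=float(d["ie_deg"]),
        ap=float(d["ap_mm"]),
        pd=float(d["pd_mm"]),
        ml=float(d.get("ml_mm", 0.0)),
        transform=RigidTransform(np.asarray(d["rotation"]), np.asarray(d["translation"])),
    )


def write_pose(pose: JointPose, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(pose_to_dict(pose), fh, indent=1)
        fh.write("\n")


def read_pose(path: str | Path) -> JointPose:
    with open(path) as fh:
        return pose_from_dict(json.load(fh))


def mirror_landmarks(landmarks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Reflect landmarks across the sagittal (x = 0) plane.

    Used to map left knees into the right-knee sign convention so IE/VV
    signs are side-invariant and subjects can be pooled.
    """
    return {n: np.array([-p[0], p[1], p[2]]) for n, p in landmarks.items()}
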