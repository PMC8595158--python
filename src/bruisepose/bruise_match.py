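"""Reconstruct the tibiofemoral pose at bruise genesis by patch matching.

The injury pose is the rigid placement of the tibia relative to the femur
that maximizes congruency between the paired femoral/tibial bruise patches
of both compartments.  Congruency is measured as a symmetric RMS
point-to-surface distance: femoral-patch vertices to the tibial patch
surface and tibial-patch vertices to the femoral patch surface, over both
compartments.  The optimizer is multi-start ICP: alternating closest-point
correspondence with a least-squares (Kabsch) rigid update, started from a
coarse flexion sweep plus a grid of rotational offsets.

Bicompartmental patches are essential: a single compartment leaves the
rotations (IE in particular) nearly unconstrained, which
`unicompartmental_diagnostic` demonstrates by mapping the score over an
IE/VV grid.

An optional penetration penalty (RMS interpenetration depth of non-patch
vertices, added with a configurable weight) is available in the score;
its weight defaults to zero because genuine injury poses overlap the bone
models proximo-distally — edema marks where the surfaces interpenetrated —
so penalizing overlap would bias the reconstruction away from such poses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bones import BoneMesh, BruisePatch
from .errors import EmptyPatch, MatchFailure
from .geometry import RigidTransform, SurfaceIndex, kabsch
from .knee_frames import (
    JointPose,
    compose_joint_pose,
    decompose_relative_transform,
    pose_from_parameters,
    pose_to_dict,
    relative_from_placement,
    tibia_placement,
)

__all__ = [
    "CongruencyConfig",
    "MatchResult",
    "congruency_score",
    "reconstruct_pose",
    "kabsch_fit",
    "unicompartmental_diagnostic",
]


@dataclass(frozen=True)
class CongruencyConfig:
    """Parameters of the congruency score and the multi-start ICP."""

    correspondence_mode: str = "point-to-surface"
    penetration_weight: float = 0.0  # weight of the RMS interpenetration term
    tolerance: float = 1e-4  # mm of score change defining convergence
    max_iterations: int = 60
    # multi-start grid: offsets (degrees) applied to flexion / IE / VV around
    # the heuristic initialization
    multistart_offsets: tuple = (-10.0, 0.0, 10.0)
    coarse_flexion_sweep: tuple = tuple(float(f) for f in range(0, 91, 10))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.correspondence_mode != "point-to-surface":
            raise ValueError("only point-to-surface correspondence is implemented")


@dataclass
class MatchResult:
    """Outcome of `reconstruct_pose`."""

    pose: JointPose
    score: float
    per_compartment: dict[str, float]
    iterations: int
    converged: bool
    candidates: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pose": pose_to_dict(self.pose),
            "score_mm": self.score,
            "per_compartment_mm": self.per_compartment,
            "iterations": self.iterations,
            "converged": self.converged,
            "candidates": self.candidates,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def kabsch_fit(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping source points to targets.

    Thin wrapper over the SVD solver; the returned rotation always has
    determinant +1 (reflections rejected).
    """
    return kabsch(source, target)


class _MatchContext:
    """Precomputed patch point sets and spatial indexes for one subject."""

    def __init__(
        self,
        femur: BoneMesh,
        tibia: BoneMesh,
        patches: list[BruisePatch],
        config: CongruencyConfig,
    ):
        self.config = config
        self.femur, self.tibia = femur, tibia
        self.femur_frame = femur.anatomical_frame()
        self.tibia_frame = tibia.anatomical_frame()
        by_key = {}
        for p in patches:
            if len(p) == 0:
                raise EmptyPatch(f"{p.bone} {p.compartment} patch is empty")
            by_key[(p.bone, p.compartment)] = p
        self.compartments = sorted({c for (_, c) in by_key})
        for comp in self.compartments:
            if ("femur", comp) not in by_key or ("tibia", comp) not in by_key:
                raise EmptyPatch(f"compartment {comp!r} lacks a femoral/tibial patch pair")
        # femoral patch data live in world (= femur mesh) coordinates,
        # tibial patch data in tibia-local coordinates: queries against the
        # tibia are done in its local frame so its index is built only once
        self.fem_points = {c: by_key[("femur", c)].points(femur) for c in self.compartments}
        self.tib_points = {c: by_key[("tibia", c)].points(tibia) for c in self.compartments}
        self.fem_index = {
            c: SurfaceIndex(*by_key[("femur", c)].submesh(femur)) for c in self.compartments
        }
        self.tib_index = {
            c: SurfaceIndex(*by_key[("tibia", c)].submesh(tibia)) for c in self.compartments
        }
        if config.penetration_weight > 0:
            self.femur_full = SurfaceIndex(femur.vertices, femur.faces)
            self.tibia_full = SurfaceIndex(tibia.vertices, tibia.faces)
            fem_patch_idx = np.concatenate(
                [by_key[("femur", c)].vertex_indices for c in self.compartments]
            )
            tib_patch_idx = np.concatenate(
                [by_key[("tibia", c)].vertex_indices for c in self.compartments]
            )
            self.fem_off = np.setdiff1d(np.arange(len(femur.vertices)), fem_patch_idx)
            self.tib_off = np.setdiff1d(np.arange(len(tibia.vertices)), tib_patch_idx)
            self.fem_normals = np.asarray(femur.mesh.face_normals)
            self.tib_normals = np.asarray(tibia.mesh.face_normals)

    # -- score ------------------------------------------------------------
    def distances(self, placement: RigidTransform) -> dict[str, np.ndarray]:
        inv = placement.inverse()
        out = {}
        for c in self.compartments:
            d_f = self.tib_index[c].distances(inv.apply(self.fem_points[c]))
            d_t = self.fem_index[c].distances(placement.apply(self.tib_points[c]))
            out[c] = np.concatenate([d_f, d_t])
        return out

    def penetration_rms(self, placement: RigidTransform) -> float:
        """Approximate RMS interpenetration depth of non-patch vertices.

        The sign of the distance is taken from the outward normal at the
        nearest surface point (robust for the locally convex bone shapes;
        the meshes are unions of closed parts, so parity ray tests are not).
        """
        depths = []
        probe = 4.0  # mm: only vertices this close can penetrate meaningfully
        inv = placement.inverse()
        pts_f = inv.apply(self.femur.vertices[self.fem_off])
        d, q, fidx = self.tibia_full.query(pts_f, max_distance=probe)
        near = np.flatnonzero(np.isfinite(d))
        if near.size:
            inside = (
                np.einsum("ij,ij->i", pts_f[near] - q[near], self.tib_normals[fidx[near]]) < 0
            )
            depths.append(d[near][inside])
        pts_t = placement.apply(self.tibia.vertices[self.tib_off])
        d, q, fidx = self.femur_full.query(pts_t, max_distance=probe)
        near = np.flatnonzero(np.isfinite(d))
        if near.size:
            inside = (
                np.einsum("ij,ij->i", pts_t[near] - q[near], self.fem_normals[fidx[near]]) < 0
            )
            depths.append(d[near][inside])
        depths = np.concatenate(depths) if depths else np.empty(0)
        return float(np.sqrt(np.mean(depths**2))) if depths.size else 0.0

    def score(self, placement: RigidTransform) -> tuple[float, dict[str, float]]:
        dists = self.distances(placement)
        alld = np.concatenate(list(dists.values()))
        per = {c: float(np.sqrt(np.mean(d**2))) for c, d in dists.items()}
        s = float(np.sqrt(np.mean(alld**2)))
        if self.config.penetration_weight > 0:
            s += self.config.penetration_weight * self.penetration_rms(placement)
        return s, per

    # -- optimization -----------------------------------------------------
    def correspondences(
        self, placement: RigidTransform
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """(tibia-local sources, world targets, score) at one placement.

        The stacked closest-point pairs double as the score evaluation:
        their distances are exactly the symmetric patch RMS terms.
        """
        inv = placement.inverse()
        sources, targets, sq_sum, n_tot = [], [], 0.0, 0
        for c in self.compartments:
            pf = self.fem_points[c]
            d, q, _ = self.tib_index[c].query(inv.apply(pf))
            sources.append(q)  # on the tibial patch, tibia-local
            targets.append(pf)
            sq_sum += float((d**2).sum())
            n_tot += len(d)
            pt = self.tib_points[c]
            d, q, _ = self.fem_index[c].query(placement.apply(pt))
            sources.append(pt)
            targets.append(q)  # on the femoral patch, world
            sq_sum += float((d**2).sum())
            n_tot += len(d)
        score = float(np.sqrt(sq_sum / n_tot))
        if self.config.penetration_weight > 0:
            score += self.config.penetration_weight * self.penetration_rms(placement)
        return np.vstack(sources), np.vstack(targets), score

    def icp(self, placement: RigidTransform) -> tuple[RigidTransform, float, int, bool]:
        """Monotone ICP from one start; returns (placement, score, iters, converged)."""
        cfg = self.config
        src, tgt, score = self.correspondences(placement)
        converged = False
        it = 0
        for it in range(1, cfg.max_iterations + 1):
            try:
                candidate = kabsch(src, tgt)
            except Exception:
                break
            new_src, new_tgt, new_score = self.correspondences(candidate)
            if new_score > score:  # never accept a worsening step
                converged = abs(new_score - score) < cfg.tolerance
                break
            improved = score - new_score
            placement, score = candidate, new_score
            src, tgt = new_src, new_tgt
            if improved < cfg.tolerance:
                converged = True
                break
        return placement, score, it, converged

    def align_translation(self, placement: RigidTransform) -> RigidTransform:
        """Translate so the mean patch centroids coincide (rotation kept)."""
        cf = np.mean([self.fem_points[c].mean(axis=0) for c in self.compartments], axis=0)
        ct = np.mean(
            [placement.apply(self.tib_points[c]).mean(axis=0) for c in self.compartments], axis=0
        )
        return RigidTransform(placement.rotation, placement.translation + (cf - ct))

    def translation_only_icp(
        self, placement: RigidTransform, iterations: int = 80
    ) -> RigidTransform:
        """Re-optimize only the translation (used by the IE/VV diagnostic)."""
        for _ in range(iterations):
            src, tgt, _ = self.correspondences(placement)
            world_src = placement.apply(src)
            delta = (tgt - world_src).mean(axis=0)
            placement = RigidTransform(placement.rotation, placement.translation + delta)
            if np.linalg.norm(delta) < 1e-4:
                break
        return placement

    def placement_of(self, pose: JointPose | RigidTransform) -> RigidTransform:
        return tibia_placement(pose, self.femur_frame, self.tibia_frame)

    def pose_of(self, placement: RigidTransform) -> JointPose:
        rel = relative_from_placement(placement, self.femur_frame, self.tibia_frame)
        return decompose_relative_transform(rel)


def congruency_score(
    pose: JointPose | RigidTransform,
    patches: list[BruisePatch],
    femur: BoneMesh,
    tibia: BoneMesh,
    config: CongruencyConfig = CongruencyConfig(),
) -> float:
    """Symmetric RMS patch-to-patch distance (mm) at a given joint pose.

    Zero iff the patch surfaces coincide exactly (and, when the penetration
    weight is positive, no non-patch interpenetration occurs).
    """
    ctx = _MatchContext(femur, tibia, patches, config)
    rel = pose if isinstance(pose, RigidTransform) else pose.transform
    placement = tibia_placement(rel, ctx.femur_frame, ctx.tibia_frame)
    return ctx.score(placement)[0]


def _heuristic_start(ctx: _MatchContext) -> RigidTransform:
    """Coarse flexion sweep with centroid alignment; best-scoring start."""
    best, best_score = None, np.inf
    for f in ctx.config.coarse_flexion_sweep:
        placement = ctx.align_translation(
            ctx.placement_of(compose_joint_pose(flexion=f))
        )
        s, _ = ctx.score(placement)
        if s < best_score:
            best, best_score = placement, s
    return best


def reconstruct_pose(
    femur: BoneMesh,
    tibia: BoneMesh,
    patches: list[BruisePatch],
    config: CongruencyConfig = CongruencyConfig(),
    starts: list[JointPose] | None = None,
) -> MatchResult:
    """Find the tibia placement maximizing bruise-patch congruency.

    Multi-start ICP: a heuristic initialization (coarse flexion sweep with
    patch-centroid alignment) is perturbed by a grid of flexion/IE/VV
    offsets; each start runs monotone ICP and the best-scoring candidate
    wins.  Ties within the convergence tolerance go to the candidate
    closest to the heuristic initialization (reproducibility).  Pass
    ``starts`` to replace the grid with explicit initial poses.

    Raises `MatchFailure` if no start yields usable correspondences.
    """
    ctx = _MatchContext(femur, tibia, patches, config)
    n_pairs = sum(len(v) for v in ctx.fem_points.values()) + sum(
        len(v) for v in ctx.tib_points.values()
    )
    if n_pairs < 3:
        raise MatchFailure("fewer than 3 patch vertices in total")

    if starts is not None:
        start_placements = [(ctx.placement_of(p), {"explicit": i}) for i, p in enumerate(starts)]
        ref_params = None
    else:
        base = _heuristic_start(ctx)
        if base is None:
            raise MatchFailure("heuristic initialization failed")
        base_pose = ctx.pose_of(base)
        ref_params = np.array([base_pose.flexion, base_pose.ie, base_pose.vv])
        start_placements = []
        offs = ctx.config.multistart_offsets
        for df in offs:
            for di in offs:
                for dv in offs:
                    try:
                        pose = pose_from_parameters(
                            flexion=base_pose.flexion + df,
                            vv=base_pose.vv + dv,
                            ie=base_pose.ie + di,
                            ap=base_pose.ap,
                            pd=base_pose.pd,
                            ml_offset=base_pose.ml,
                        )
                    except Exception:
                        continue
                    start_placements.append(
                        (
                            ctx.align_translation(ctx.placement_of(pose)),
                            {"offsets_deg": [df, di, dv]},
                        )
                    )
    if not start_placements:
        raise MatchFailure("no valid initial poses")

    # staged multi-start: a short coarse run from every start, then full
    # refinement of the few best — identical winner at a fraction of the cost
    coarse: list[tuple[float, RigidTransform, dict]] = []
    if len(start_placements) > 6:
        # score every start, coarse-run the better half, refine the top 4
        scored = sorted(
            ((ctx.correspondences(pl)[2], pl, lb) for pl, lb in start_placements),
            key=lambda c: c[0],
        )
        for _, placement, label in scored[: max(6, len(scored) // 2)]:
            src_tgt = ctx.correspondences(placement)
            pl, sc = placement, src_tgt[2]
            for _ in range(8):
                try:
                    cand = kabsch(src_tgt[0], src_tgt[1])
                except Exception:
                    break
                nxt = ctx.correspondences(cand)
                if nxt[2] > sc:
                    break
                pl, sc, src_tgt = cand, nxt[2], nxt
            coarse.append((sc, pl, label))
        coarse.sort(key=lambda c: c[0])
        refine = [(pl, label) for _, pl, label in coarse[:4]]
    else:
        refine = start_placements

    candidates = []
    for placement, label in refine:
        final, score, iters, converged = ctx.icp(placement)
        pose = ctx.pose_of(final)
        candidates.append(
            {
                "start": label,
                "score_mm": score,
                "iterations": iters,
                "converged": converged,
                "pose": pose,
                "placement": final,
            }
        )
    best_score = min(c["score_mm"] for c in candidates)
    tied = [c for c in candidates if c["score_mm"] <= best_score + ctx.config.tolerance]
    if ref_params is not None and len(tied) > 1:
        # reproducible tie-break: stay closest to the heuristic initialization
        def dist_to_ref(c):
            p = c["pose"]
            return np.linalg.norm(np.array([p.flexion, p.ie, p.vv]) - ref_params)

        winner = min(tied, key=dist_to_ref)
    else:
        winner = min(tied, key=lambda c: c["score_mm"])
    _, per = ctx.score(winner["placement"])
    summaries = [
        {
            "start": c["start"],
            "score_mm": c["score_mm"],
            "iterations": c["iterations"],
            "converged": c["converged"],
            "pose": c["pose"].parameters(),
        }
        for c in candidates
    ]
    return MatchResult(
        pose=winner["pose"],
        score=winner["score_mm"],
        per_compartment=per,
        iterations=winner["iterations"],
        converged=winner["converged"],
        candidates=summaries,
    )


def unicompartmental_diagnostic(
    femur: BoneMesh,
    tibia: BoneMesh,
    patches: list[BruisePatch],
    config: CongruencyConfig = CongruencyConfig(),
    ie_halfspan: float = 15.0,
    vv_halfspan: float = 10.0,
    n_ie: int = 11,
    n_vv: int = 7,
    rel_tol: float = 0.10,
) -> dict:
    """Map the congruency score over IE/VV offsets around the best fit.

    With patches from a single compartment the near-optimal set spans a wide
    range of rotations (the pose is not identifiable); with bicompartmental
    patches the span collapses.  At each grid offset the translation is
    re-optimized so the comparison isolates the rotational information.

    Returns the grid offsets, scores, and the IE/VV spans (deg) of poses
    whose score is within ``rel_tol`` of the minimum.
    """
    result = reconstruct_pose(femur, tibia, patches, config)
    ctx = _MatchContext(femur, tibia, patches, config)
    base = result.pose
    ie_offsets = np.linspace(-ie_halfspan, ie_halfspan, n_ie)
    vv_offsets = np.linspace(-vv_halfspan, vv_halfspan, n_vv)
    scores = np.full((n_ie, n_vv), np.inf)
    for i, die in enumerate(ie_offsets):
        for j, dvv in enumerate(vv_offsets):
            try:
                pose = pose_from_parameters(
                    flexion=base.flexion,
                    vv=base.vv + dvv,
                    ie=base.ie + die,
                    ap=base.ap,
                    pd=base.pd,
                    ml_offset=base.ml,
                )
            except Exception:
                continue
            placement = ctx.translation_only_icp(ctx.placement_of(pose))
            scores[i, j], _ = ctx.score(placement)
    smin = float(np.nanmin(scores))
    ok = scores <= smin * (1.0 + rel_tol)
    ie_ok = ie_offsets[ok.any(axis=1)]
    vv_ok = vv_offsets[ok.any(axis=0)]
    return {
        "base": result,
        "ie_offsets_deg": ie_offsets,
        "vv_offsets_deg": vv_offsets,
        "scores_mm": scores,
        "ie_span_deg": float(ie_ok.max() - ie_ok.min()) if ie_ok.size else 0.0,
        "vv_span_deg": float(vv_ok.max() - vv_ok.min()) if vv_ok.size else 0.0,
    }
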