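"""End-to-end pipeline stages over an on-disk cohort.

Each stage consumes only the documented artifacts of the previous one:

  simulate     -> subject directories (meshes, landmarks, patches, squat CSV)
  reconstruct  -> match_result.json per subject
  kinematics   -> rom.json + matched_pose.json per subject
  compare      -> report/ bundle (JSON, CSVs, figure)

Stages log per-subject progress and never silently swallow a failure: a
failed subject is recorded and skipped, and the stage result lists it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .bruise_match import CongruencyConfig, MatchResult, reconstruct_pose
from .compare_stats import (
    build_report,
    matched_flexion_comparison,
    range_exceedance,
)
from .errors import BruisePoseError, FlexionOutOfRange
from .knee_frames import pose_from_dict, read_pose
from .squat_kinematics import compute_rom, matched_flexion_pose, read_trajectory
from .synthetic_knee import load_subject, make_cohort_fixture

log = logging.getLogger("bruisepose")

__all__ = ["PipelineConfig", "run_simulate", "run_reconstruct", "run_kinematics", "run_compare", "run_all"]


@dataclass
class PipelineConfig:
    """Configuration shared by the pipeline stages."""

    cohort_dir: Path = Path("cohort")
    n_subjects: int = 7
    seed: int = 0
    overwrite: bool = False
    phase: str = "descent"  # matched-flexion phase
    resolution: float = 1.4  # synthetic mesh target edge length, mm
    congruency: CongruencyConfig = field(default_factory=CongruencyConfig)
    make_figure: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cong = CongruencyConfig(**raw.pop("congruency", {}))
        known = {
            k: raw[k]
            for k in ("n_subjects", "seed", "overwrite", "phase", "resolution", "make_figure")
            if k in raw
        }
        cfg = cls(congruency=cong, **known)
        if "cohort_dir" in raw:
            cfg.cohort_dir = Path(raw["cohort_dir"])
        return cfg


def _subject_dirs(cohort_dir: Path) -> list[Path]:
    return sorted(p for p in Path(cohort_dir).iterdir() if p.is_dir() and p.name.startswith("subject_"))


def run_simulate(config: PipelineConfig) -> Path:
    """Generate the synthetic cohort on disk."""
    t0 = time.time()
    root = make_cohort_fixture(
        config.cohort_dir,
        n_subjects=config.n_subjects,
        seed=config.seed,
        overwrite=config.overwrite,
        resolution=config.resolution,
    )
    log.info("simulate: %d subjects -> %s (%.1fs)", config.n_subjects, root, time.time() - t0)
    return root


def run_reconstruct(config: PipelineConfig) -> dict[str, MatchResult | None]:
    """Reconstruct the injury pose for every subject of the cohort."""
    results: dict[str, MatchResult | None] = {}
    for sdir in _subject_dirs(config.cohort_dir):
        t0 = time.time()
        try:
            data = load_subject(sdir)
            res = reconstruct_pose(
                data["femur"], data["tibia"], data["patches"], config.congruency
            )
            res.save(sdir / "match_result.json")
            results[sdir.name] = res
            log.info(
                "reconstruct %s: score %.3f mm, %d iters, converged=%s (%.1fs)",
                sdir.name, res.score, res.iterations, res.converged, time.time() - t0,
            )
        except (BruisePoseError, OSError, ValueError, KeyError) as exc:
            log.error("reconstruct %s FAILED: %s", sdir.name, exc)
            results[sdir.name] = None
    return results


def run_kinematics(config: PipelineConfig) -> dict[str, dict]:
    """Extract ROM and the matched-flexion squat pose for every subject."""
    out: dict[str, dict] = {}
    for sdir in _subject_dirs(config.cohort_dir):
        match_path = sdir / "match_result.json"
        if not match_path.exists():
            log.warning("kinematics %s: no match_result.json, skipping", sdir.name)
            continue
        with open(match_path) as fh:
            bb_pose = pose_from_dict(json.load(fh)["pose"])
        trajectory = read_trajectory(sdir / "squat.csv", subject_id=sdir.name)
        rom = compute_rom(trajectory)
        record: dict = {"rom": rom.to_dict()}
        try:
            matched = matched_flexion_pose(trajectory, bb_pose.flexion, phase=config.phase)
            record["matched_pose"] = matched.parameters()
        except FlexionOutOfRange as exc:
            log.warning("kinematics %s: %s", sdir.name, exc)
            record["matched_pose"] = None
            record["note"] = str(exc)
        with open(sdir / "kinematics.json", "w") as fh:
            json.dump(record, fh, indent=1)
            fh.write("\n")
        out[sdir.name] = record
        log.info("kinematics %s: matched=%s", sdir.name, record["matched_pose"] is not None)
    return out


def run_compare(config: PipelineConfig) -> dict:
    """Out-of-range and matched-flexion analyses; writes the report bundle."""
    from .knee_frames import JointPose, pose_from_parameters

    exceedances = {}
    bb_poses: dict[str, JointPose] = {}
    squat_poses: dict[str, JointPose] = {}
    excluded: list[str] = []
    for sdir in _subject_dirs(config.cohort_dir):
        match_path = sdir / "match_result.json"
        if not match_path.exists():
            log.warning("compare %s: not reconstructed, skipping", sdir.name)
            continue
        with open(match_path) as fh:
            bb_pose = pose_from_dict(json.load(fh)["pose"])
        trajectory = read_trajectory(sdir / "squat.csv", subject_id=sdir.name)
        rom = compute_rom(trajectory)
        exceedances[sdir.name] = range_exceedance(bb_pose, rom)
        try:
            matched = matched_flexion_pose(trajectory, bb_pose.flexion, phase=config.phase)
        except FlexionOutOfRange as exc:
            log.warning("compare %s excluded from paired comparison: %s", sdir.name, exc)
            excluded.append(sdir.name)
            continue
        bb_poses[sdir.name] = bb_pose
        squat_poses[sdir.name] = matched
    comparisons = matched_flexion_comparison(bb_poses, squat_poses)
    report = build_report(
        exceedances, comparisons, Path(config.cohort_dir) / "report", make_figure=config.make_figure
    )
    if excluded:
        report["excluded_from_paired"] = excluded
        with open(Path(config.cohort_dir) / "report" / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    log.info("compare: %d subjects, %d excluded from paired comparison", len(exceedances), len(excluded))
    return report


def run_all(config: PipelineConfig) -> dict:
    run_simulate(config)
    run_reconstruct(config)
    run_kinematics(config)
    return run_compare(config)
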