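"""Statistical comparison of the bruise pose against squat kinematics.

Two analyses mirror the study design:

1. *Out-of-range assessment* (per subject): each parameter of the
   reconstructed injury pose is classified against the subject's own squat
   range of motion, with a signed distance to the violated limit (positive
   = beyond the limit in the positive-sign direction: more anterior, more
   proximal overlap resolved as sign, more valgus, more internal).
2. *Matched-flexion paired comparison* (cohort): per-subject differences
   between the injury pose and the squat pose at the same flexion angle,
   tested with a paired (one-sample-on-differences) t-test, with 95%
   confidence intervals.

Power machinery uses the exact noncentral t distribution (the G*Power
convention), both for the a-priori required sample size and for post-hoc
achieved power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientData, NoEffect, ReportError
from .knee_frames import JointPose
from .squat_kinematics import RangeOfMotion

__all__ = [
    "RangeExceedance",
    "PairedComparison",
    "PowerSpec",
    "range_exceedance",
    "cohort_out_of_range_summary",
    "paired_t_test",
    "required_sample_size",
    "achieved_power",
    "build_report",
    "format_proportion",
]

#: parameters assessed against the squat range (flexion classified only)
EXCEEDANCE_PARAMETERS = ("ap", "pd", "ie", "vv", "flexion")


@dataclass(frozen=True)
class RangeExceedance:
    """One parameter of one subject classified against the squat ROM."""

    parameter: str
    bb_value: float
    squat_min: float
    squat_max: float
    classification: str  # "within" | "beyond_upper" | "beyond_lower"
    signed_distance: float  # 0 when within; bb - limit otherwise


@dataclass(frozen=True)
class PairedComparison:
    """Cohort-level paired comparison of one parameter."""

    parameter: str
    bb_values: tuple
    squat_values: tuple
    differences: tuple
    bb_mean: float
    bb_sd: float
    squat_mean: float
    squat_sd: float
    mean_difference: float
    sd_difference: float
    ci95: tuple
    t_statistic: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class PowerSpec:
    """Effect specification for paired-t power computations."""

    mean_difference: float
    sd: float
    alpha: float = 0.05
    power: float | None = None
    n: int | None = None
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def effect_size(self) -> float:
        return self.mean_difference / self.sd


def range_exceedance(bb_pose: JointPose, rom: RangeOfMotion) -> list[RangeExceedance]:
    """Classify each parameter of the injury pose against the squat ROM."""
    params = bb_pose.parameters()
    key = {
        "ap": "ap_mm",
        "pd": "pd_mm",
        "ie": "ie_deg",
        "vv": "vv_deg",
        "flexion": "flexion_deg",
    }
    out = []
    for name in EXCEEDANCE_PARAMETERS:
        bb = float(params[key[name]])
        lo, hi = rom.minimum(name), rom.maximum(name)
        if bb > hi:
            cls, dist = "beyond_upper", bb - hi
        elif bb < lo:
            cls, dist = "beyond_lower", bb - lo
        else:
            cls, dist = "within", 0.0
        out.append(
            RangeExceedance(
                parameter=name,
                bb_value=bb,
                squat_min=lo,
                squat_max=hi,
                classification=cls,
                signed_distance=float(dist),
            )
        )
    return out


def cohort_out_of_range_summary(
    subject_exceedances: dict[str, list[RangeExceedance]],
) -> dict[str, dict[str, int]]:
    """Tally classifications per parameter over the cohort."""
    if not subject_exceedances:
        raise InsufficientData("no subjects")
    counts: dict[str, dict[str, int]] = {}
    for recs in subject_exceedances.values():
        for r in recs:
            c = counts.setdefault(
                r.parameter, {"within": 0, "beyond_upper": 0, "beyond_lower": 0}
            )
            c[r.classification] += 1
    return counts


def paired_t_test(differences: np.ndarray, parameter: str = "") -> dict:
    """One-sample t-test of paired differences with a 95% CI.

    Returns mean, SD, t, df, two-tailed p and the CI.  A zero-variance
    sample with nonzero mean is flagged degenerate and its p floored at
    the machine minimum.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise InsufficientData(f"need >= 2 differences, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    degenerate = False
    if sd == 0.0:
        if mean == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if mean > 0 else -np.inf
            p = float(np.nextafter(0, 1))
            degenerate = True
        half = 0.0
    else:
        se = sd / np.sqrt(n)
        t_stat = mean / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
        half = float(stats.t.ppf(0.975, df) * se)
    return {
        "parameter": parameter,
        "n": n,
        "mean": mean,
        "sd": sd,
        "t": float(t_stat),
        "df": df,
        "p": p,
        "ci95": (mean - half, mean + half),
        "degenerate": degenerate,
    }


def _power_at(n: int, d: float, alpha: float, two_sided: bool) -> float:
    """Exact power of the one-sample t at effect size d and sample size n."""
    df = n - 1
    nc = d * np.sqrt(n)
    if two_sided:
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))
    crit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(crit, df, nc))


def required_sample_size(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest n achieving the target power for a paired t-test.

    Power is computed from the noncentral t distribution with df = n - 1
    and noncentrality (mean difference / SD) * sqrt(n).
    """
    if spec.power is None:
        raise ValueError("spec.power (target power) is required")
    if spec.mean_difference == 0:
        raise NoEffect("zero mean difference: sample size undefined")
    d = abs(spec.effect_size)
    for n in range(2, n_max + 1):
        if _power_at(n, d, spec.alpha, spec.two_sided) >= spec.power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")


def achieved_power(spec: PowerSpec) -> float:
    """Post-hoc power of the paired t-test at the spec's fixed n."""
    if spec.n is None:
        raise ValueError("spec.n (sample size) is required")
    if spec.n < 2:
        raise InsufficientData("need n >= 2")
    return _power_at(spec.n, abs(spec.effect_size), spec.alpha, spec.two_sided)


def format_proportion(count: int, total: int) -> str:
    """Render a screening proportion as an integer percentage (7 of 62 -> 11%)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return f"{round(100.0 * count / total):.0f}%"


def format_p_value(p: float, floor: float = 1e-4) -> str:
    """Four-decimal p-value with a '< 0.0001' floor."""
    if p < floor:
        return "< 0.0001"
    return f"{p:.4f}"


def matched_flexion_comparison(
    bb_poses: dict[str, JointPose],
    squat_poses: dict[str, JointPose],
) -> dict[str, PairedComparison]:
    """Per-parameter paired comparison of injury vs matched-flexion squat.

    Differences are computed per subject and then aggregated (paired
    design).  The summary-table mean difference is reported as the magnitude of
    the mean paired difference; its direction survives in the signed
    per-subject columns and the CI.
    """
    subjects = sorted(bb_poses)
    if subjects != sorted(squat_poses):
        raise ReportError("bb and squat pose sets cover different subjects")
    if not subjects:
        raise InsufficientData("no subjects")
    key = {"ap": "ap_mm", "pd": "pd_mm", "ie": "ie_deg", "vv": "vv_deg"}
    out = {}
    for name, k in key.items():
        bb = np.array([bb_poses[s].parameters()[k] for s in subjects])
        sq = np.array([squat_poses[s].parameters()[k] for s in subjects])
        diff = bb - sq
        t = paired_t_test(diff, parameter=name)
        out[name] = PairedComparison(
            parameter=name,
            bb_values=tuple(float(v) for v in bb),
            squat_values=tuple(float(v) for v in sq),
            differences=tuple(float(v) for v in diff),
            bb_mean=float(bb.mean()),
            bb_sd=float(bb.std(ddof=1)) if len(bb) > 1 else 0.0,
            squat_mean=float(sq.mean()),
            squat_sd=float(sq.std(ddof=1)) if len(sq) > 1 else 0.0,
            mean_difference=t["mean"],
            sd_difference=t["sd"],
            ci95=t["ci95"],
            t_statistic=t["t"],
            df=t["df"],
            p_value=t["p"],
            degenerate=t["degenerate"],
        )
    return out


def table_difference(bb_mean: float, squat_mean: float) -> float:
    """Magnitude of the mean condition difference, as printed in summary tables."""
    return abs(bb_mean - squat_mean)


def build_report(
    exceedances: dict[str, list[RangeExceedance]],
    comparisons: dict[str, PairedComparison],
    out_dir: str | Path,
    make_figure: bool = True,
) -> dict:
    """Assemble the cohort report bundle: JSON, two CSV tables, one figure.

    Returns the report dictionary that was written to ``report.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not exceedances:
        raise ReportError("no subjects with out-of-range analysis")
    missing = [s for s in exceedances if not exceedances[s]]
    if missing:
        raise ReportError(f"subjects with empty exceedance records: {missing}")

    # per-subject exceedance table
    rows = []
    for subject in sorted(exceedances):
        for r in exceedances[subject]:
            rows.append(
                {
                    "subject": subject,
                    "parameter": r.parameter,
                    "bb_value": r.bb_value,
                    "squat_min": r.squat_min,
                    "squat_max": r.squat_max,
                    "classification": r.classification,
                    "signed_distance": r.signed_distance,
                }
            )
    exc_df = pd.DataFrame(rows)
    exc_df.to_csv(out_dir / "per_subject_exceedance.csv", index=False)

    # matched-flexion summary table (one row per parameter: AP, PD, IE, VV)
    comp_rows = []
    for name in ("ap", "pd", "ie", "vv"):
        c = comparisons[name]
        comp_rows.append(
            {
                "parameter": name,
                "bb_mean": c.bb_mean,
                "bb_sd": c.bb_sd,
                "squat_mean": c.squat_mean,
                "squat_sd": c.squat_sd,
                "difference": table_difference(c.bb_mean, c.squat_mean),
                "ci95_low": c.ci95[0],
                "ci95_high": c.ci95[1],
                "t": c.t_statistic,
                "df": c.df,
                "p": format_p_value(c.p_value),
            }
        )
    comp_df = pd.DataFrame(comp_rows)
    comp_df.to_csv(out_dir / "paired_comparison.csv", index=False)

    report = {
        "n_subjects": len(exceedances),
        "out_of_range_counts": cohort_out_of_range_summary(exceedances),
        "per_subject_exceedance": rows,
        "paired_comparison": {
            name: {
                "bb_mean": c.bb_mean,
                "bb_sd": c.bb_sd,
                "squat_mean": c.squat_mean,
                "squat_sd": c.squat_sd,
                "differences": list(c.differences),
                "mean_difference": c.mean_difference,
                "sd_difference": c.sd_difference,
                "table_difference": table_difference(c.bb_mean, c.squat_mean),
                "ci95": list(c.ci95),
                "t": c.t_statistic,
                "df": c.df,
                "p": c.p_value,
                "p_rendered": format_p_value(c.p_value),
            }
            for name, c in comparisons.items()
        },
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")

    if make_figure:
        _exceedance_figure(exceedances, out_dir / "out_of_range.png")
    return report


def _exceedance_figure(
    exceedances: dict[str, list[RangeExceedance]], path: Path
) -> None:
    """Signed out-of-range distances per subject per parameter (bar chart)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = ("ap", "pd", "ie", "vv")
    subjects = sorted(exceedances)
    fig, axes = plt.subplots(1, len(params), figsize=(12, 3.2), sharey=False)
    for ax, name in zip(axes, params):
        vals = []
        for s in subjects:
            rec = next(r for r in exceedances[s] if r.parameter == name)
            vals.append(rec.signed_distance)
        ax.bar(range(1, len(subjects) + 1), vals, color="steelblue")
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_title(name.upper())
        ax.set_xlabel("subject")
    axes[0].set_ylabel("distance beyond squat limit\n(mm or deg, signed)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
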