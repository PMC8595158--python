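"""Exception hierarchy for the bruise-pose pipeline."""


class BruisePoseError(Exception):
    """Base class for all pipeline errors."""


class MissingLandmark(BruisePoseError):
    """A required anatomical landmark is absent from the landmark set."""


class DegenerateGeometry(BruisePoseError):
    """Landmarks are collinear/coincident and cannot define a frame."""


class SingularPose(BruisePoseError):
    """Joint angles at (or within tolerance of) the gimbal singularity."""


class ResolutionError(BruisePoseError):
    """Mesh resolution too coarse to represent the requested geometry."""


class NoBicompartmentalContact(BruisePoseError):
    """A pose fails to produce bruise footprints on both compartments."""


class OutputExists(BruisePoseError):
    """Output directory already present and overwrite not requested."""


class EmptyPatch(BruisePoseError):
    """A bruise patch contains no vertices."""


class MatchFailure(BruisePoseError):
    """No initial pose yielded usable bicompartmental correspondences."""


class DegenerateCorrespondence(BruisePoseError):
    """Fewer than three non-collinear point pairs for a rigid fit."""


class FormatError(BruisePoseError):
    """Malformed on-disk table or header."""


class InvariantViolation(BruisePoseError):
    """Input data violate a documented type invariant."""


class FlexionOutOfRange(BruisePoseError):
    """Target flexion angle outside the trajectory's flexion range."""


class PhaseNotFound(BruisePoseError):
    """Requested squat phase absent from the trajectory."""


class InsufficientData(BruisePoseError):
    """Too few observations for the requested statistic."""


class NoEffect(BruisePoseError):
    """Zero effect size: required sample size undefined."""


class ReportError(BruisePoseError):
    """Subject records incomplete for report assembly."""
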