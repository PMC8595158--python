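# Methods

## Problem and model

After a noncontact anterior cruciate ligament (ACL) rupture, MRI often
shows subchondral bone-marrow edema ("bone bruises") on both the femur and
the tibia. If the edema footprints mark where the two bones impacted, then
rigidly re-positioning the tibia so that its footprints coincide with the
femoral ones reconstructs the tibiofemoral pose at the instant of impact.
`bruisepose` implements that reconstruction as an automated optimization
and the downstream comparison of the reconstructed pose against the knee's
own physiological motion (a single-leg squat recorded with dynamic
stereophotogrammetry), asking: does the injury pose lie inside or outside
the envelope of normal motion?

The pipeline requires bruises on **both** the medial and lateral
compartment of **both** bones. A single compartment leaves the rotations
unidentifiable — a lone condyle resting in its plateau compartment can spin
with nearly constant surface congruency — which
`bruise_match.unicompartmental_diagnostic` demonstrates quantitatively.

## Joint coordinates

Poses are expressed in the floating-axis joint coordinate system of Grood &
Suntay, the ISB-recommended convention for the knee:

* flexion about the femoral medio-lateral (ML) axis,
* internal–external (IE) rotation about the tibial longitudinal axis,
* varus–valgus (VV) rotation about the mutual floating axis,
* translations = components of the femoral-origin→tibial-origin vector
  along those three axes.

Anatomical frames are built from six landmarks (medial/lateral femoral
epicondyles + femoral shaft point; medial/lateral tibial plateau edges +
tibial shaft point): ML axis through the paired landmarks, longitudinal
axis toward the shaft point orthogonalized against ML, third axis by cross
product, origin at the ML midpoint.

Signs (side-invariant): flexion positive; valgus positive; internal tibial
rotation positive; anterior tibial position positive; proximo-distal (PD)
positive = distraction, negative = the bone models overlap along the tibial
axis. For left knees the ML axis is reversed (lateral→medial) at frame
construction, which preserves flexion/AP/PD and flips IE/VV — the standard
pooling convention; reconstruction is mirror-equivariant under it (tested).

**Caveat:** absolute AP/PD values are coordinates of one anatomical origin
relative to the other and depend entirely on landmark placement. Only
differences between conditions measured with the same landmarks (injury
pose vs squat pose of the same subject) are convention-free. The package
therefore reports per-subject differences and classifications, never
absolute translations as portable quantities.

The compose/decompose pair is an exact bijection away from the |VV| = 90°
gimbal singularity (round-trip < 1e-6 over the working range; poses within
1e-3° of the singularity raise `SingularPose`).

## Congruency score and optimizer

The congruency of a candidate pose is the symmetric RMS point-to-surface
distance between paired patches: femoral-patch vertices → tibial-patch
surface and tibial-patch vertices → femoral-patch surface, over both
compartments. Distances are exact point-to-triangle (a vectorized closest
point computation behind a k-d-tree candidate index), so the score does not
depend on the opposing mesh's vertex density. A patch's surface is the set
of faces touching any patch vertex; requiring all three vertices would
shred footprints only one or two vertex rows wide.

The optimizer is multi-start iterative closest point (ICP): correspondence
by closest point, update by the Kabsch least-squares rigid fit (reflections
rejected), iterated until the score improves by less than the tolerance
(default 1e-4 mm). Steps that would increase the score are rejected, so the
accepted sequence is monotone. Starts: a heuristic initialization (coarse
flexion sweep with patch-centroid alignment) perturbed by a 3×3×3 grid of
±10° flexion/IE/VV offsets; every start gets a short coarse run and the
best few are refined to convergence. Ties within the tolerance resolve to
the candidate nearest the heuristic initialization, for reproducibility.

The score supports an optional penetration penalty (RMS interpenetration
depth of non-patch vertices, sign taken from the outward normal at the
nearest surface point). Its weight **defaults to zero**: genuine injury
poses overlap the bone models proximo-distally — the edema marks where the
surfaces interpenetrated — so penalizing overlap biases the reconstruction
away from exactly the poses of interest. The penalty remains available for
matching scenarios where non-penetration is a valid prior.

## Synthetic knees

Real inputs are patient MRI segmentations and RSA trajectories that cannot
be redistributed, so `synthetic_knee` generates analytic surrogates:

* **Femur**: two condyle spheres (default radii 22/21 mm, centers 46 mm
  apart) plus an ellipsoidal shaft. The condyle centers are deliberately
  *not* coaxial (the lateral condyle sits ~3 mm posterior and ~1.5 mm
  inferior by default): with exactly coaxial spheres, rotation about the
  common axis is a gauge freedom of bruise matching and flexion becomes
  unidentifiable — an artifact of idealized geometry that real, asymmetric
  condyles do not share.
* **Tibia**: a gridded plateau with two concave spherical dishes (depths
  2.5/2.0 mm), a posterior slope (7°), and a steep quadratic posterior
  rolloff beginning 22 mm behind the dish line — the "vertically oriented"
  posterior margin where impact bruises concentrate. The solid is closed
  (top grid, ring-subdivided skirt, bottom grid) and watertight.
* Landmarks are placed analytically (epicondyles at the ML extremes on the
  nominal flexion axis; plateau edges at deck level), so anatomical frames
  are exact and ground-truth poses are known in closed form.

Default mesh resolution is a 1.4 mm target edge (top plateau grid 0.6×
finer). Coarser meshes (≳2.5 mm) remain usable but roughly double the
reconstruction error through footprint-sampling effects.

**Bruise stamping.** With the tibia placed at a ground-truth pose, a vertex
joins a footprint when its distance to the opposing bone's *articular*
surface (condyle spheres / plateau top — proximity to the shaft or side
walls is not an impact) is at most the proximity threshold (default
0.8 mm, the sub-millimetre scale at which edema is assumed to mark
contact). Footprints can be dilated along the surface (multi-source
Dijkstra over mesh edges) and their boundary perturbed by per-vertex
threshold jitter. Tibial footprints are compartment-tagged by *which
condyle struck them* (nearest femoral compartment surface), not by their
own side of the midline — a bruise made near the eminence by the medial
condyle belongs to the medial pair. Footprints shrink monotonically as the
threshold decreases (tested). Any empty compartment footprint raises
`NoBicompartmentalContact`, mirroring the study's exclusion of
unicompartmental cases.

**Injury poses.** Ground-truth poses are drawn relative to each subject's
own (noiseless) squat limits so the out-of-range pattern holds by
construction: flexion ~ N(46.1°, 3.8°); PD drawn negative (−6 to −1.5 mm,
overlap); IE/VV drawn beyond (or within) the squat limits according to the
subject's assigned class. The anterior translation is then *solved* by
bisection so the medial condyle indents the posterior plateau margin by a
target depth (7–11 mm), and the lateral condyle's inferior offset is solved
likewise — the subject's anatomy is chosen such that the injury produced
bicompartmental contact, mirroring the study's inclusion criterion. The
resulting anterior translations (~40–55 mm beyond neutral) describe an
anteriorly locked subluxation with contact on the posterior plateau.

**Squat model.** Flexion sweeps 10°→100°→10° over 100 frames (4 s);
secondary parameters are linear in flexion, anchored at 46° to
AP 18.5 mm, PD +26.5 mm, IE +7.6°, VV −6.4°, with a screw-home-like IE
slope (+0.10°/°). Additive Gaussian noise defaults to 0.3 mm / 0.3°, the
repeatability scale of dynamic RSA. PD stays positive throughout the squat
(no overlap during physiological motion). Per-subject coupling anchors are
jittered mildly (SD 0.8–1.2 units). The squat table is a kinematic
simulation: it is *not* derived from the surrogate mesh geometry, and its
AP/PD values live in the same origin-dependent coordinates as the injury
pose, so only within-subject comparisons are meaningful.

**The `paper7` cohort** (n = 7, the default fixture) assigns IE classes
5 external / 1 within / 1 internal and VV classes 5 valgus / 2 varus,
interleaved so the two classifications decorrelate; all subjects are
anterior-exceeding and PD-negative by construction. Everything is
deterministic in (n_subjects, seed), down to byte-identical files.

## What the synthetic data do and do not show

Passing tests demonstrate that the *pipeline* — stamping, matching,
decomposition, ROM comparison, statistics — is internally consistent and
recovers known ground truth under controlled conditions. They do not
validate the clinical claim: surrogate bones are spheres and dishes, real
edema is volumetric and signal-graded rather than a clean proximity
footprint, real segmentations carry correlated surface error, and the
engineered cohort pattern is an input, not a discovery. Reconstruction
accuracy on noiseless footprints (≤0.5°/0.5 mm) is an upper bound on what
real data would allow.

## Statistics

* **Out-of-range assessment**: each parameter of the injury pose is
  classified against the subject's own squat min/max with a signed distance
  to the violated limit (0 when within; the sign is the parameter's own
  sign convention). Flexion is classified but carries no clinical distance
  interpretation here.
* **Matched-flexion comparison**: the squat pose at the injury flexion
  angle is isolated by linear interpolation at the first crossing within
  the descent phase (the loading phase analogous to injury; ascent
  available by flag). Differences are computed per subject and tested with
  a one-sample t on differences; 95% CI = mean ± t(0.975, n−1)·SE. Summary
  tables print the magnitude of the mean difference (direction preserved in
  the signed columns), p-values to 4 decimals with a "< 0.0001" floor. A
  subject whose injury flexion falls outside their squat range is excluded
  from the paired table with a logged note.
* **Power**: both `required_sample_size` and `achieved_power` use the exact
  noncentral t distribution (noncentrality d·√n, df n−1), the G*Power
  convention; no normal approximation. Under the anchor effect
  (22 mm / 14 mm, α = 0.05 two-tailed) the smallest n with power ≥ 0.90
  is 7 (power 0.930 at n = 7 vs 0.864 at n = 6).
* Calibration is verified by simulation: type-I error 0.05 ± 0.01 over
  5000 null cohorts of n = 7, CI coverage 95% ± 1.5% over 2000 cohorts.
* No multiplicity correction is applied, matching the study design.

## Numerical choices

* Exact point-to-triangle distances with a two-tree (vertex + triangle
  centroid) index; candidate shortlists are certified by the
  triangle-circumradius bound and fall back to an exhaustive ball query
  when uncertified, so results are exact regardless of pruning.
* Kabsch via SVD with sign correction (det = +1 enforced); < 3 or collinear
  correspondences raise `DegenerateCorrespondence`.
* ICP convergence: score improvement < 1e-4 mm; worsening steps rejected;
  non-convergence is reported (`converged = False`), not raised.
* The IE/VV diagnostic re-optimizes translation at every grid offset
  (to convergence, step < 1e-4 mm) so the map isolates rotational
  information; with a translation refit that is stopped early the
  single-compartment flatness is masked by residual decentering.
* Trajectory CSVs are written at full float precision (round trip < 1e-9);
  trajectories are never resampled or smoothed implicitly (an optional
  moving-average filter exists, off by default).

## Known limitations

* Spherical condyles make IE nearly unidentifiable from a *single*
  compartment by construction; this is intended (it reproduces the
  bicompartmental-requirement argument) but means single-compartment
  behavior should not be quantitatively extrapolated to real anatomy.
* The reconstruction residual (score) has no external reference value; it
  is reported for diagnostics only.
* Absolute AP/PD magnitudes are origin-dependent (see above); the package
  never compares them across landmark conventions.
* The synthetic squat shares no mechanical coupling with the surrogate
  bone geometry; it emulates the statistical structure of RSA output only.
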