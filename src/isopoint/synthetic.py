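"""Synthetic knee-motion fixtures with known ground truth.

Builds a desk-scale parametric femur (two condylar spheres bridged by a
shaft cylinder) with analytic landmarks, a flexion-parameterized patellar
motion whose centroid keeps an exactly known distance law to a planted
surface point, and paired coordinate cohorts with a prescribed proximal
shift -- so the frame construction, the attachment optimization and the
cohort statistics can each be validated against planted truth without any
imaging data.

Defaults mirror the scale of adult knees: an intercondylar width of about
81 mm, a modeled ligament length of about 55 mm, motion over 0-90 degrees
of flexion in 20-30 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    FrameData,
    KneeSequence,
    LandmarkSet,
    SurfaceModel,
    build_surface,
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic knee.

    Lengths in mm, angles in degrees.  ``planted_offset`` is the chord
    distance from the Schottle-style landmark to the planted best-isometry
    surface point P*; it must stay inside the (5, 15) annulus for the
    planted point to be recoverable.
    """

    condyle_radius: float = 22.0
    intercondylar_width: float = 81.0
    shaft_length: float = 120.0
    shaft_radius: float = 14.0
    n_surface_points: int = 1100
    planted_offset: float = 10.0
    ligament_length: float = 55.0
    n_frames: int = 25
    angle_range: tuple[float, float] = (0.0, 90.0)
    noise_sd: float = 0.0
    seed: int = 0
    apply_pose: bool = True  # random rigid scanner pose

    def __post_init__(self):
        if self.intercondylar_width <= 2 * self.condyle_radius * 0.5:
            raise ValueError("intercondylar width too small for the condyle radius")
        if not 0 < self.planted_offset < 2 * self.condyle_radius:
            raise ValueError("planted offset not realizable as a condylar chord")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.angle_range[1] <= self.angle_range[0]:
            raise ValueError("empty angle range")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _cylinder_lattice(radius: float, z0: float, z1: float, n: int) -> np.ndarray:
    """Near-uniform triangular lattice on a cylinder's lateral surface."""
    circ = 2.0 * np.pi * radius
    length = z1 - z0
    h = np.sqrt(circ * length / max(n, 1) * 2.0 / np.sqrt(3.0))
    rows = max(2, int(round(length / (h * np.sqrt(3.0) / 2.0))))
    cols = max(3, int(round(circ / h)))
    pts = []
    for k in range(rows + 1):
        z = z0 + length * k / rows
        ang = 2.0 * np.pi * (np.arange(cols) + 0.5 * (k % 2)) / cols
        pts.append(
            np.column_stack(
                [radius * np.cos(ang), radius * np.sin(ang), np.full(cols, z)]
            )
        )
    return np.vstack(pts)


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


def _random_pose(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A modest random rigid transform standing in for the scanner pose."""
    axis = rng.normal(size=3)
    R = _rotation(axis, rng.uniform(0.0, 0.6))
    t = rng.uniform(-40.0, 40.0, size=3)
    return R, t


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded alongside every generated dataset."""

    p_star: np.ndarray  # scanner coords
    p_star_local: np.ndarray  # anatomical-frame coords
    ligament_length: float
    noise_sd: float
    seed: int
    pose_rotation: np.ndarray
    pose_translation: np.ndarray
    flexion_angles: np.ndarray = field(default=None)


def make_femur(spec: SyntheticSpec) -> tuple[SurfaceModel, LandmarkSet, SyntheticTruth]:
    """Sample the parametric femur and reconstruct its surface.

    The surface is the union of two condylar spheres (extreme +-X points
    are the MFC/LFC landmarks, exactly ``intercondylar_width`` apart) and
    a proximal shaft cylinder capped by a hemisphere.  The Schottle-style
    landmark and the planted point P* are inserted as exact surface
    samples on the medial condyle, ``planted_offset`` mm apart.
    """
    rng = np.random.default_rng(spec.seed)
    rc = spec.condyle_radius
    w = spec.intercondylar_width
    cx = w / 2.0 - rc
    cm = np.array([cx, 0.0, 0.0])  # medial condyle centre (+X medial)
    cl = np.array([-cx, 0.0, 0.0])
    rs = spec.shaft_radius
    zs = spec.shaft_length

    # allocate samples by component area so spacing is globally uniform
    n = spec.n_surface_points
    a_sphere = 4.0 * np.pi * rc**2
    a_shaft = 2.0 * np.pi * rs * zs
    a_cap = 2.0 * np.pi * rs**2
    a_total = 2 * a_sphere + a_shaft + a_cap
    n_sph = max(80, int(round(n * a_sphere / a_total)))
    n_shaft = max(60, int(round(n * a_shaft / a_total)))
    n_cap = max(20, int(round(n * a_cap / a_total)))

    pts = []
    for centre in (cm, cl):
        p = centre + rc * _fibonacci_sphere(n_sph)
        other = cl if centre is cm else cm
        inside_other = np.linalg.norm(p - other, axis=1) < rc - 1e-9
        rad2 = p[:, 0] ** 2 + p[:, 1] ** 2
        inside_shaft = (rad2 < rs**2 - 1e-9) & (p[:, 2] > 0)
        pts.append(p[~inside_other & ~inside_shaft])
    shaft = _cylinder_lattice(rs, 0.0, zs, n_shaft)
    far = (np.linalg.norm(shaft - cm, axis=1) > rc + 1e-9) & (
        np.linalg.norm(shaft - cl, axis=1) > rc + 1e-9
    )
    pts.append(shaft[far])
    # hemispherical top cap
    cap = rs * _fibonacci_sphere(2 * n_cap)
    cap = cap[cap[:, 2] > 0] + np.array([0.0, 0.0, zs])
    pts.append(cap)

    mfc = np.array([w / 2.0, 0.0, 0.0])
    lfc = np.array([-w / 2.0, 0.0, 0.0])
    ra = np.array([0.0, 0.0, zs])

    # Schottle-style landmark: a designated medial-condyle surface point
    ds = np.array([0.92, -0.15, 0.36])
    ds /= np.linalg.norm(ds)
    s_point = cm + rc * ds
    # planted point: rotate the landmark direction about a tangent axis by
    # the angle subtending the requested chord
    tangent = np.cross(ds, rng.normal(size=3))
    tangent /= np.linalg.norm(tangent)
    dtheta = 2.0 * np.arcsin(spec.planted_offset / (2.0 * rc))
    p_star = cm + rc * (_rotation(tangent, dtheta) @ ds)

    cloud = np.vstack(pts + [mfc[None], lfc[None], s_point[None], p_star[None]])

    if spec.apply_pose:
        R, t = _random_pose(rng)
    else:
        R, t = np.eye(3), np.zeros(3)
    cloud = cloud @ R.T + t

    surface = build_surface(cloud)
    landmarks = LandmarkSet(
        mfc=R @ mfc + t, lfc=R @ lfc + t, ra=R @ ra + t, s_point=R @ s_point + t,
        side="right",
    )
    truth = SyntheticTruth(
        p_star=R @ p_star + t,
        p_star_local=p_star - 0.0,  # construction coords == anatomical frame
        ligament_length=spec.ligament_length,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
        pose_rotation=R,
        pose_translation=t,
    )
    return surface, landmarks, truth


# deterministic +- paired ellipsoid offsets: centroid is exactly zero
_PATELLA_AXES = np.array([16.0, 20.0, 9.0])


def _patella_offsets(m: int = 40) -> np.ndarray:
    base = _fibonacci_sphere(m) * _PATELLA_AXES
    return np.vstack([base, -base])


def make_motion(
    spec: SyntheticSpec,
    surface: SurfaceModel,
    landmarks: LandmarkSet,
    truth: SyntheticTruth,
) -> KneeSequence:
    """Sweep a patellar cloud along a flexion arc around the planted point.

    The cloud centroid in frame ``i`` sits at distance ``L* + eps_i`` from
    P*, with ``eps_i ~ N(0, noise_sd)``; at zero noise the planted point
    is exactly isometric.  The cloud itself is a +/- paired ellipsoid
    sample, so its centroid equals the intended centre to rounding error.
    """
    rng = np.random.default_rng(spec.seed + 1)
    angles = np.linspace(spec.angle_range[0], spec.angle_range[1], spec.n_frames)
    R, t = truth.pose_rotation, truth.pose_translation
    p_star_c = truth.p_star_local  # construction coords

    u0 = np.array([0.15, -0.92, 0.36])
    u0 /= np.linalg.norm(u0)
    eps = rng.normal(0.0, spec.noise_sd, spec.n_frames) if spec.noise_sd > 0 else np.zeros(spec.n_frames)
    offsets = _patella_offsets()
    frames = []
    for i, (theta, e) in enumerate(zip(angles, eps)):
        u = _rotation(np.array([1.0, 0.0, 0.0]), -np.deg2rad(theta)) @ u0
        centre = p_star_c + (spec.ligament_length + e) * u
        cloud = (centre + offsets) @ R.T + t
        frames.append(
            FrameData(
                frame_index=i,
                femur=surface,
                patella_points=cloud,
                flexion_angle=float(theta),
            )
        )
    truth.flexion_angles = angles
    return KneeSequence(subject_id=f"synthetic-{spec.seed}", side="right", frames=frames)


def make_knee(spec: SyntheticSpec):
    """Convenience: femur + landmarks + motion sequence + truth."""
    surface, landmarks, truth = make_femur(spec)
    seq = make_motion(spec, surface, landmarks, truth)
    return seq, surface, landmarks, truth


# ---------------------------------------------------------------------------
# Statistical cohort generator

# Cohort-scale defaults: the landmark cloud centre and spread emulate a
# pooled adult cohort in the anatomical frame (mm), with the individual
# point proximally shifted by ~1.9 mm on average.
COHORT_MEAN_S = np.array([39.15, -1.29, 9.32])
COHORT_SD_S = np.array([3.1, 2.1, 2.2])
DEFAULT_DELTA = np.array([-0.38, -0.19, 1.88])


def make_cohort(
    n_subjects: int = 58,
    delta=DEFAULT_DELTA,
    sigma=(0.3, 0.2, 0.5),
    seed: int | None = None,
    mean_s=COHORT_MEAN_S,
    sd_s=COHORT_SD_S,
    paired: bool = True,
) -> pd.DataFrame:
    """Paired S/I coordinate cohort with a prescribed mean shift.

    Per subject the landmark coordinate S is drawn from a diagonal
    Gaussian around ``mean_s``; the individual point is
    ``I = S + delta + noise(sigma)``, preserving the paired structure.

    With ``paired=False`` the I column is instead an independent draw
    with the same marginal distribution (mean ``mean_s + delta``, SD
    ``sqrt(sd_s^2 + sigma^2)``).  Group-exchange permutation tests assume
    exchangeable independent rows, so their type-I calibration must use
    this unpaired mode; the paired default emulates the within-subject
    structure the paired tests consume.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    delta = np.asarray(delta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    sd_s = np.asarray(sd_s, dtype=float)
    S = rng.normal(mean_s, sd_s, size=(n_subjects, 3))
    if paired:
        I = S + delta + rng.normal(0.0, sigma, size=(n_subjects, 3))
    else:
        I = rng.normal(
            np.asarray(mean_s, dtype=float) + delta,
            np.sqrt(sd_s**2 + sigma**2),
            size=(n_subjects, 3),
        )
    return pd.DataFrame(
        {
            "subject_id": [f"subj{k:03d}" for k in range(n_subjects)],
            "Sx": S[:, 0], "Sy": S[:, 1], "Sz": S[:, 2],
            "Ix": I[:, 0], "Iy": I[:, 1], "Iz": I[:, 2],
        }
    )
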