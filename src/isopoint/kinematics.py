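"""Patellar centroid extraction and trajectory fitting over knee flexion.

The patellar reference (C-point) is the geometric centroid of the patellar
point cloud in each frame.  Its path over the motion is fitted with an
independent least-squares polynomial per local coordinate; the raw
per-frame centroids drive the attachment optimization, while the fitted
curve serves angle-grid evaluation (length profiles per 10 degree bin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import FemoralFrame, KneeSequence


def patellar_centroid(patella_points, mask=None) -> np.ndarray:
    """Geometric centroid of the patellar cloud (mm).

    If ``mask`` is given, only the flagged subset (e.g. a labelled
    articular surface) contributes.
    """
    pts = np.asarray(patella_points, dtype=float).reshape(-1, 3)
    if mask is not None:
        pts = pts[np.asarray(mask, dtype=bool)]
    if len(pts) == 0:
        raise ValueError("cannot take the centroid of an empty point set")
    return pts.mean(axis=0)


@dataclass
class Trajectory:
    """Fitted C-point path over the motion.

    ``params`` holds the fitting parameter per frame: flexion angle in
    degrees when available, else the normalized frame index in [0, 1].
    ``points`` are the raw per-frame C-points in the local frame.
    """

    params: np.ndarray
    points: np.ndarray
    coefficients: np.ndarray  # (degree+1, 3), ascending powers of the scaled parameter
    rms_residual: float
    param_kind: str  # "angle" or "index"
    param_shift: float = 0.0  # scaled parameter = (t - shift) / scale
    param_scale: float = 1.0
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.params)

    def __call__(self, t) -> np.ndarray:
        t = (np.atleast_1d(np.asarray(t, dtype=float)) - self.param_shift) / self.param_scale
        powers = t[:, None] ** np.arange(self.coefficients.shape[0])
        return powers @ self.coefficients

    def angles(self) -> np.ndarray:
        """Flexion angle assigned to each frame.

        Uses measured angles when present; otherwise maps normalized
        arc length along the fitted curve linearly onto 0-90 degrees.
        This fallback is a convention of this package, not a measurement.
        """
        if self.param_kind == "angle":
            return self.params.copy()
        grid = np.linspace(self.params[0], self.params[-1], 512)
        curve = self(grid)
        seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        if arc[-1] < 1e-12:
            return np.zeros_like(self.params)
        arc /= arc[-1]
        frame_arc = np.interp(self.params, grid, arc)
        return 90.0 * frame_arc

    def param_for_angle(self, angle) -> np.ndarray:
        """Invert the angle assignment to a fitting parameter value."""
        angle = np.atleast_1d(np.asarray(angle, dtype=float))
        if self.param_kind == "angle":
            return angle
        ang = self.angles()
        return np.interp(angle, ang, self.params)


def fit_trajectory(
    sequence: KneeSequence, frame: FemoralFrame, degree: int = 3
) -> Trajectory:
    """Fit the C-point path with a per-coordinate polynomial.

    Parameterized by per-frame flexion angle when every frame carries one
    (falling back to normalized frame index, with a warning, if angles are
    absent or non-monotone).  Requires at least ``degree + 1`` frames.
    """
    n = sequence.n_frames
    if n <= degree:
        raise ValueError(f"need more than degree={degree} frames, got {n}")
    pts = np.array(
        [patellar_centroid(f.patella_points) for f in sequence.frames]
    )
    local = frame.to_local(pts)
    angles = sequence.flexion_angles
    if angles is not None and np.all(np.diff(angles) >= 0):
        params, kind = angles.astype(float), "angle"
    else:
        if angles is not None:
            warnings.warn(
                "non-monotone flexion angles; falling back to frame-index "
                "parameterization",
                stacklevel=2,
            )
        params = np.linspace(0.0, 1.0, n)
        kind = "index"
    return _fit(params, local, degree, kind)


def fit_points(params, points, degree: int = 3, param_kind: str = "angle") -> Trajectory:
    """Fit a trajectory directly from (parameter, point) pairs."""
    params = np.asarray(params, dtype=float)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(params) <= degree:
        raise ValueError(f"need more than degree={degree} samples")
    return _fit(params, points, degree, param_kind)


def _fit(params, points, degree, kind) -> Trajectory:
    # fit in a parameter scaled to [-1, 1] to keep the Vandermonde system
    # well conditioned over 0-90 degree ranges
    shift = 0.5 * (params.min() + params.max())
    scale = 0.5 * (params.max() - params.min())
    if scale < 1e-12:
        scale = 1.0
    t = (params - shift) / scale
    V = t[:, None] ** np.arange(degree + 1)
    coef, *_ = np.linalg.lstsq(V, points, rcond=None)
    resid = points - V @ coef
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return Trajectory(
        params=params.copy(),
        points=points.copy(),
        coefficients=coef,
        rms_residual=rms,
        param_kind=kind,
        param_shift=float(shift),
        param_scale=float(scale),
    )


def evaluate_trajectory(traj: Trajectory, angles) -> np.ndarray:
    """Evaluate the fitted curve on an angle grid (degrees).

    Evaluation more than 5 degrees beyond the observed range is recorded
    in ``traj.metadata['extrapolated']`` and warned about.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    obs = traj.angles()
    lo, hi = float(obs.min()), float(obs.max())
    out_of_range = angles[(angles < lo - 5.0) | (angles > hi + 5.0)]
    if len(out_of_range) > 0:
        traj.metadata.setdefault("extrapolated", []).extend(out_of_range.tolist())
        warnings.warn(
            f"evaluating >5 deg outside the observed range [{lo:.1f}, {hi:.1f}]",
            stacklevel=2,
        )
    return traj(traj.param_for_angle(angles))
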