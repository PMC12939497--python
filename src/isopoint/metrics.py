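"""Ligament length profiles and normalized length change (MPFL%).

The modeled ligament is the straight segment from a femoral attachment
(Schottle landmark or optimized individual point) to the per-frame
patellar centroid.  Lengths are normalized to a per-knee reference length
(the mean over frames by default) and summarized as MPFL% per 10 degree
flexion bin over 0-90 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinematics import Trajectory, evaluate_trajectory

BIN_CENTERS = np.arange(0, 91, 10, dtype=float)


def length_series(attachment, traj: Trajectory) -> np.ndarray:
    """Per-frame straight-line length attachment -> C-point (mm)."""
    attachment = np.asarray(attachment, dtype=float).reshape(3)
    lengths = np.linalg.norm(traj.points - attachment, axis=1)
    if np.any(lengths < 1e-9):
        warnings.warn(
            "attachment coincides with a patellar centroid (zero length)",
            stacklevel=2,
        )
    return lengths


@dataclass
class LengthProfile:
    """Per-frame lengths and normalized change for one attachment."""

    label: str  # "S" or "I"
    attachment: np.ndarray
    lengths: np.ndarray  # (N,) mm
    reference_length: float  # mm
    percent: np.ndarray = field(init=False)  # per-frame MPFL%

    def __post_init__(self):
        self.attachment = np.asarray(self.attachment, dtype=float).reshape(3)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.percent = 100.0 * (self.lengths - self.reference_length) / self.reference_length

    @property
    def length_sd(self) -> float:
        return float(self.lengths.std())


def mpfl_percent(
    attachment,
    traj: Trajectory,
    reference: str | tuple = "mean",
    label: str = "",
) -> LengthProfile:
    """Normalized length-change profile for an attachment point.

    ``reference`` is ``"mean"`` (per-knee mean length over frames, the
    default) or ``("at_angle", theta)`` to normalize by the fitted length
    at a given flexion angle (for sensitivity analyses).
    """
    lengths = length_series(attachment, traj)
    if np.any(lengths <= 0):
        raise ValueError("non-positive ligament length")
    if reference == "mean":
        ref = float(lengths.mean())
    elif isinstance(reference, tuple) and reference[0] == "at_angle":
        c = evaluate_trajectory(traj, [float(reference[1])])[0]
        ref = float(np.linalg.norm(c - np.asarray(attachment, dtype=float)))
    else:
        raise ValueError(f"unknown reference rule: {reference!r}")
    if ref <= 0:
        raise ValueError("non-positive reference length")
    return LengthProfile(
        label=label, attachment=attachment, lengths=lengths, reference_length=ref
    )


def bin_by_angle(profile: LengthProfile, traj: Trajectory) -> np.ndarray:
    """Mean MPFL% per 10 degree bin centred on 0, 10, ..., 90 degrees.

    Frames are assigned to the half-open bin [theta-5, theta+5) (end bins
    clamped to [0, 90]).  A bin with no frames is filled by evaluating the
    fitted trajectory at its centre.
    """
    angles = traj.angles()
    out = np.empty(len(BIN_CENTERS))
    for k, theta in enumerate(BIN_CENTERS):
        lo = max(theta - 5.0, 0.0) if theta == 0 else theta - 5.0
        hi = min(theta + 5.0, 90.0 + 1e-9) if theta == 90 else theta + 5.0
        m = (angles >= lo) & (angles < hi)
        if theta == 90:
            m |= np.isclose(angles, 90.0)
        if m.any():
            out[k] = profile.percent[m].mean()
        else:
            c = evaluate_trajectory(traj, [theta])[0]
            length = float(np.linalg.norm(c - profile.attachment))
            out[k] = 100.0 * (length - profile.reference_length) / profile.reference_length
    return out


def max_variation(profile: LengthProfile) -> tuple[float, float]:
    """(min, max) of the per-frame MPFL% series."""
    if len(profile.percent) == 0:
        raise ValueError("empty profile")
    return float(profile.percent.min()), float(profile.percent.max())
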