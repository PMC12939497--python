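"""End-to-end composition: sequence -> frame -> optimization -> profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinematics, metrics
from .geometry import FemoralFrame, KneeSequence, LandmarkSet, build_femoral_frame
from .optimizer import OptimizationProblem, OptimizationResult, optimize_ipoint


@dataclass
class RunConfig:
    """Tunable parameters of a full run, serialized with every result."""

    r_min: float = 5.0
    r_max: float = 15.0
    surface_tolerance: float = 0.1
    poly_degree: int = 3
    reference_rule: str = "mean"
    n_starts: int = 10
    n_perm: int = 999
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "r_min": self.r_min,
            "r_max": self.r_max,
            "surface_tolerance": self.surface_tolerance,
            "poly_degree": self.poly_degree,
            "reference_rule": self.reference_rule,
            "n_starts": self.n_starts,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


@dataclass
class KneeAnalysis:
    """All per-knee outputs: frame, trajectory, optimization, profiles."""

    frame: FemoralFrame
    trajectory: kinematics.Trajectory
    problem: OptimizationProblem
    result: OptimizationResult
    s_local: np.ndarray
    profile_s: metrics.LengthProfile
    profile_i: metrics.LengthProfile
    binned: pd.DataFrame = field(default=None)

    @property
    def i_local(self) -> np.ndarray:
        return self.result.i_point


def build_problem(
    sequence: KneeSequence,
    landmarks: LandmarkSet,
    config: RunConfig | None = None,
) -> tuple[OptimizationProblem, FemoralFrame, kinematics.Trajectory]:
    """Assemble the attachment program in the local anatomical frame."""
    config = config or RunConfig()
    frame = build_femoral_frame(landmarks)
    traj = kinematics.fit_trajectory(sequence, frame, degree=config.poly_degree)
    surface_local = sequence.frames[0].femur.transformed(frame)
    problem = OptimizationProblem(
        targets=traj.points,
        s_point=frame.to_local(landmarks.s_point),
        surface=surface_local,
        r_min=config.r_min,
        r_max=config.r_max,
        surface_tolerance=config.surface_tolerance,
    )
    return problem, frame, traj


def analyze_knee(
    sequence: KneeSequence,
    landmarks: LandmarkSet,
    config: RunConfig | None = None,
) -> KneeAnalysis:
    """Run the full per-knee pipeline and build both length profiles."""
    config = config or RunConfig()
    problem, frame, traj = build_problem(sequence, landmarks, config)
    result = optimize_ipoint(problem, n_starts=config.n_starts)
    s_local = frame.to_local(landmarks.s_point)
    ref = (
        "mean"
        if config.reference_rule == "mean"
        else ("at_angle", float(config.reference_rule))
    )
    profile_s = metrics.mpfl_percent(s_local, traj, reference=ref, label="S")
    profile_i = metrics.mpfl_percent(result.i_point, traj, reference=ref, label="I")
    binned = pd.DataFrame(
        {
            "angle": metrics.BIN_CENTERS,
            "mpfl_pct_S": metrics.bin_by_angle(profile_s, traj),
            "mpfl_pct_I": metrics.bin_by_angle(profile_i, traj),
        }
    )
    return KneeAnalysis(
        frame=frame,
        trajectory=traj,
        problem=problem,
        result=result,
        s_local=s_local,
        profile_s=profile_s,
        profile_i=profile_i,
        binned=binned,
    )
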