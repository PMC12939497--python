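import numpy as np
import pytest

import isopoint as ip


@pytest.fixture(scope="session")
def knee():
    """One noise-free synthetic knee with planted truth, shared read-only."""
    spec = ip.SyntheticSpec(seed=42)
    seq, surface, landmarks, truth = ip.make_knee(spec)
    return {
        "spec": spec,
        "sequence": seq,
        "surface": surface,
        "landmarks": landmarks,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def knee_problem(knee):
    problem, frame, traj = ip.build_problem(knee["sequence"], knee["landmarks"])
    return {"problem": problem, "frame": frame, "trajectory": traj, **knee}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng):
    """A random proper rigid transform (R, t)."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-50, 50, 3)
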