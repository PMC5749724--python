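import numpy as np
import pytest

import cgmkin as ck


@pytest.fixture(scope="session")
def subject():
    return ck.default_subject()


@pytest.fixture(scope="session")
def static_trial(subject):
    return ck.make_static_trial(subject, n_frames=5)


@pytest.fixture(scope="session")
def calib(static_trial, subject):
    return ck.run_static(static_trial, subject.measurements)


@pytest.fixture(scope="session")
def squat_run(subject, static_trial, calib):
    """A 41-frame squat to 120 degrees: trial, ground truth and the
    engine's recovered series — shared by the round-trip style tests."""
    program = ck.MotionProgram.squat(41, peak_knee_flexion=120.0)
    dynamic, truth = ck.make_dynamic_trial(subject, program)
    series = ck.process_trial(dynamic, calib)
    return {"program": program, "dynamic": dynamic, "truth": truth,
            "series": series}


def random_rotation(rng) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    return Q * np.linalg.det(Q)
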