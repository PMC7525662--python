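import numpy as np
import pytest

from petdosim import (
    DecayConstants,
    SubjectScan,
    TimeActivityCurve,
    default_kinetic_spec,
    generate_scan,
    load_reference_svalues,
)


@pytest.fixture(scope="session")
def decay() -> DecayConstants:
    return DecayConstants()


@pytest.fixture
def make_tac():
    """Factory for quick curves from (midpoint, %ID) pairs on 1-min frames."""

    def _make(organ, points, decay_corrected=False, width=1.0):
        points = sorted(points)
        t_mid = np.array([p[0] for p in points], dtype=float)
        act = np.array([p[1] for p in points], dtype=float)
        return TimeActivityCurve(
            organ=organ,
            t_start=t_mid - width / 2,
            t_end=t_mid + width / 2,
            activity=act,
            decay_corrected=decay_corrected,
        )

    return _make


def dense_schedule(total_min=240.0, dt=0.1):
    edges = np.arange(0.0, total_min + dt / 2, dt)
    return np.column_stack([edges[:-1], edges[1:]])


def pure_decay_scan(decay, dt=0.1, organ_fractions=None, reconstruction="FBP"):
    """Scan whose whole body decays purely physically from 100 %ID and whose
    organs are fixed fractions of it."""
    sched = dense_schedule(dt=dt)
    t_mid = sched.mean(axis=1)
    wb_act = 100.0 * np.exp(-decay.lambda_per_min * t_mid)
    organ_fractions = organ_fractions or {"kidneys": 0.3, "liver": 0.1}
    tacs = {
        organ: TimeActivityCurve(organ, sched[:, 0], sched[:, 1], frac * wb_act)
        for organ, frac in organ_fractions.items()
    }
    return SubjectScan(
        subject_id="dense",
        radiotracer="test",
        body_mass_g=330.0,
        reconstruction=reconstruction,
        whole_body=TimeActivityCurve("whole_body", sched[:, 0], sched[:, 1], wb_act),
        tacs=tacs,
    )


@pytest.fixture(scope="session")
def scan_pair():
    return generate_scan(default_kinetic_spec(), seed=11, subject_id="s01")


@pytest.fixture(scope="session")
def svalues_male():
    return load_reference_svalues("adult_male")


@pytest.fixture(scope="session")
def svalues_female():
    return load_reference_svalues("adult_female")
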