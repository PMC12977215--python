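import numpy as np
import pytest
from hypothesis import settings

from peepbayes.priors import build_protocol_priors
from peepbayes.trial_data import Arm, PatientRecord, TrialDataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    reg, het = build_protocol_priors()
    return reg, het


def make_record(
    pid,
    hospital=1,
    arm=Arm.HIGHER_PEEP,
    vfd=20,
    died=False,
    duration=4.0,
    **covariates,
):
    return PatientRecord(
        patient_id=str(pid),
        hospital_id=hospital,
        arm=arm,
        vfd=0 if died else vfd,
        died_by_day28=died,
        vent_duration_days=None if died else duration,
        **covariates,
    )


def random_dataset(n=40, n_hospitals=3, seed=0, both_arms=True, p_die=0.4):
    """Small hand-rolled dataset; outcomes carry no systematic arm effect."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        died = bool(rng.random() < p_die)
        arm = (
            (Arm.LOWER_PEEP if rng.random() < 0.5 else Arm.HIGHER_PEEP)
            if both_arms
            else Arm.HIGHER_PEEP
        )
        recs.append(
            make_record(
                f"p{i}",
                hospital=int(rng.integers(1, n_hospitals + 1)),
                arm=arm,
                vfd=int(rng.integers(0, 29)),
                died=died,
                duration=float(rng.uniform(1.0, 12.0)),
            )
        )
    if both_arms:
        recs[0].arm = Arm.LOWER_PEEP
        recs[1].arm = Arm.HIGHER_PEEP
    return TrialDataset(recs, n_hospitals)


@pytest.fixture
def no_information_dataset():
    """All patients in the reference arm: the likelihood carries nothing on theta."""
    return random_dataset(n=60, n_hospitals=3, seed=5, both_arms=False)
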