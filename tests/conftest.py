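"""Shared fixtures.

The rat model calibration is expensive relative to everything else, so it
is computed once per session and shared by the workflow and acceptance
tests (it is deterministic, so sharing cannot couple test outcomes).
"""

import pytest

from pbpkit import datasets
from pbpkit.physiology import get_physiology
from pbpkit.workflow import (
    CalibrationTarget,
    build_model,
    calibrate_rat_model,
)


@pytest.fixture(scope="session")
def rat_physiology():
    return get_physiology("rat")


@pytest.fixture(scope="session")
def human_physiology():
    return get_physiology("human")


@pytest.fixture(scope="session")
def tozadenant():
    return datasets.TOZADENANT


@pytest.fixture(scope="session")
def rat_bundle():
    return build_model("rat")


@pytest.fixture(scope="session")
def calibrated_rat():
    """Rat model calibrated to the observed IV 1 mg/kg Cl and Vd."""
    bundle = build_model("rat")
    target = CalibrationTarget(
        observed_cl=datasets.RAT_IV1_CALIBRATION_TARGET["cl"],
        observed_vd=datasets.RAT_IV1_CALIBRATION_TARGET["vd"],
    )
    outcome = calibrate_rat_model(bundle, target)
    return bundle, outcome
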