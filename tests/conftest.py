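import numpy as np
import pytest
from dataclasses import replace

from kneeplan import (PatientSpec, generate_knee, simulate_extension,
                      ma_baseline)
from kneeplan.knee_model import LigamentBundle


@pytest.fixture(scope="session")
def patient_spec():
    return PatientSpec(seed=0)


@pytest.fixture(scope="session")
def knee(patient_spec):
    return generate_knee(patient_spec)


@pytest.fixture(scope="session")
def pre_trace(knee):
    return simulate_extension(knee)


@pytest.fixture(scope="session")
def ma_knee(knee):
    return ma_baseline(knee)


@pytest.fixture(scope="session")
def ma_trace(ma_knee):
    return simulate_extension(ma_knee)


def _mirror(v):
    return np.array([v[0], v[1], -v[2]])


@pytest.fixture(scope="session")
def symmetric_knee():
    """A sagittally mirror-symmetric knee: collateral-side structures are
    exact mirror pairs and the midline structures lie in the z = 0 plane."""
    base = generate_knee(PatientSpec(seed=0, attachment_jitter_mm=0.0))
    ligs = {l.name: l for l in base.ligaments}
    sym = []
    for medial, lateral in (("sMCL", "LCL"), ("dMCL", "ALL")):
        lm = ligs[medial]
        sym.append(lm)
        sym.append(LigamentBundle(name=lateral, origin=_mirror(lm.origin),
                                  insertion=_mirror(lm.insertion),
                                  stiffness=lm.stiffness,
                                  slack_length=lm.slack_length))
    for name in ("ACL", "PCL", "OPL", "PC"):
        l = ligs[name]
        o, i = l.origin.copy(), l.insertion.copy()
        o[2] = 0.0
        i[2] = 0.0
        sym.append(LigamentBundle(name=name, origin=o, insertion=i,
                                  stiffness=l.stiffness,
                                  slack_length=float(np.linalg.norm(i - o)) / 1.02))
    return replace(base, ligaments=tuple(sym))
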