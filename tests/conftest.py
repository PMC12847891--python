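import numpy as np
import pytest

from somnipeak.preprocess import StagedRecording
from somnipeak.synthdata import (CouplingSpec, GroupSpec, HypnogramParams,
                                 generate_background, generate_cohort,
                                 generate_so)

FS = 100.0


@pytest.fixture(scope="session")
def n2_recording():
    """One 6-min single-channel N2 recording with sigma bursts + truth."""
    from somnipeak.synthdata import inject_transients

    stages = ["N2"] * 12
    so = generate_so(stages, FS, 2.0, seed=11)
    base = generate_background(len(so.signal), FS, 1.0, seed=12) + so.signal
    spec = CouplingSpec("sigma", 12.0, 15.0, 6.0, (0.5, 1.0, 1.5, 2.0),
                        phase_mu=0.0, phase_kappa=4.0)
    sig, events = inject_transients(base, so, spec, seed=13)
    rec = StagedRecording(sig[None, :], FS, ["C3"], stages)
    return rec, events, so


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-group, 3-subjects-each, 5-min cohort on one channel."""
    groups = [
        GroupSpec("control", 3, [CouplingSpec("sigma", 12.0, 15.0, 5.0,
                                              (0.5, 1.0, 1.5, 2.0),
                                              phase_kappa=4.0)]),
        GroupSpec("patient", 3, [CouplingSpec("sigma", 12.0, 15.0, 5.0,
                                              (0.5, 1.0, 1.5, 1.0),
                                              phase_kappa=4.0)]),
    ]
    recs, gt, labels = generate_cohort(groups, channels=("C3",),
                                       duration_s=300.0, fs=FS, seed=21)
    return recs, gt, labels
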