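import numpy as np
import pytest

from phasekin.kinetics import CalibrationLine, MichaelisMentenParams
from phasekin.ph_sensing import SnarfCalibration
from phasekin.two_phase import REFERENCE_PARAMS

#: substrate grid of the reference initial-rate experiments (µM)
S_LEVELS = np.array([15.6, 31.25, 62.5, 125.0, 250.0])


@pytest.fixture
def ref_params():
    """Reference two-phase parameter set of the lipase condensate system."""
    return REFERENCE_PARAMS


@pytest.fixture
def mm_homogeneous():
    """Homogeneous lipase Michaelis-Menten constants (0.5 µM enzyme)."""
    return MichaelisMentenParams(v_max=2.1, K_M=713.0, enzyme_0=0.5)


@pytest.fixture
def cal_line():
    return CalibrationLine(slope=2.0, intercept=100.0, condition_label="pH7.5")


@pytest.fixture
def snarf_cal():
    return SnarfCalibration(pKa_app=7.5, R_acid=2.0, R_base=0.5)
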