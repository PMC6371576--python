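import numpy as np
import pytest

from ardsim.calibration import default_pulmonary_bounds, realise_lung
from ardsim.mechanics import CURVE_LINEAR, LungParams


@pytest.fixture(scope="session")
def mid_lung():
    """Lung realised at the midpoint of every pulmonary bound."""
    bounds = default_pulmonary_bounds()
    genes = np.array([(b.lower + b.upper) / 2 for b in bounds])
    lung, scalars = realise_lung(genes)
    return lung, scalars


def make_single_compartment(c_ml_cmh2o=30.0, rb=1200.0, rc=3.0, top=0.0,
                            pext=0.0):
    """One linear resistive-compliant unit (analytic-oracle reduction)."""
    n = 1
    return LungParams(
        vmax=np.array([1e4]),
        d=np.array([10.0]),
        c0=np.array([15.0]),
        rb=np.array([rb]),
        top=np.array([top]),
        pext=np.array([pext]),
        q_weights=np.ones(n),
        rc=rc,
        vd_ml=0.0,
        curve=np.array([CURVE_LINEAR]),
        c_lin=np.array([c_ml_cmh2o]),
    )
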