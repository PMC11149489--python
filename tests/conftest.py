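import numpy as np
import pytest

from fluxsort.ph_core import BufferSpec, CalibrationCurve


@pytest.fixture
def cal():
    """cSNARF1-style calibration spanning ratios 0.4-1.6 around pKa 7.5."""
    return CalibrationCurve(ratio_min=0.4, ratio_max=1.6, pka_dye=7.5)


@pytest.fixture
def assay_buffer():
    """The lightly buffered plate medium (2 mM HEPES / 2 mM MES)."""
    return BufferSpec.assay_medium()


@pytest.fixture
def rng():
    return np.random.default_rng(20230612)
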